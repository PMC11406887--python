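"""End-to-end orchestration: simulate -> preprocess -> extract -> correlate
-> pca -> classify, with every artifact written as delimited text and a JSON
manifest sufficient to re-execute the run bit-identically."""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    PCAConfig,
    SpectralClassificationModel,
    SplitConfig,
    averaging_ablation,
    fit_pca,
)
from .correlations import group_mean_profile, pc_correlations, pearson_matrix
from .io import (
    write_correlation_matrix,
    write_intensity_table,
    write_spectra,
)
from .lines import default_line_library
from .peaks import PeakConfig, build_intensity_table
from .preprocess import AggregationConfig, preprocess
from .simulate import (
    DESIGN_PRESETS,
    InstrumentConfig,
    NoiseConfig,
    StudyDesign,
    default_effect_directions,
    generate_study,
)


@dataclass
class RunConfig:
    """Full configuration of one pipeline run."""

    preset: str = "paper_n80"
    seed: int = 1
    effect_size: float = 2.0
    n_biological: int | None = None  # override the preset's count
    instrument: InstrumentConfig = field(default_factory=InstrumentConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    aggregation: AggregationConfig = field(default_factory=AggregationConfig)
    peak: PeakConfig = field(default_factory=PeakConfig)
    pca: PCAConfig = field(default_factory=PCAConfig)
    split: SplitConfig = field(default_factory=SplitConfig)
    ablation_k: tuple[int, ...] = (4, 8)
    write_spectra: bool = False  # long-format spectra are bulky; opt in

    def __post_init__(self) -> None:
        if self.preset not in DESIGN_PRESETS:
            raise ValueError(
                f"unknown preset {self.preset!r}; expected one of {sorted(DESIGN_PRESETS)}"
            )

    def design(self) -> StudyDesign:
        overrides = {}
        if self.n_biological is not None:
            overrides["n_biological"] = self.n_biological
        return DESIGN_PRESETS[self.preset](seed=self.seed, **overrides)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sub = {
            "instrument": InstrumentConfig,
            "noise": NoiseConfig,
            "aggregation": AggregationConfig,
            "peak": PeakConfig,
            "pca": PCAConfig,
            "split": SplitConfig,
        }
        kwargs = {}
        for key, value in raw.items():
            if key in sub:
                kwargs[key] = sub[key](**value)
            elif key == "ablation_k":
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunManifest:
    """Provenance of one run: config snapshot, package version, per-stage
    shapes and wall-clock, and the seeds actually used."""

    config: dict
    version: str
    stages: dict
    seeds: dict
    warnings: list

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def run_pipeline(config: RunConfig, outdir) -> RunManifest:
    """Execute the full pipeline and write every stage artifact to ``outdir``.

    Identical config and seed give byte-identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    library = default_line_library()
    effects = default_effect_directions(config.effect_size)
    stages: dict = {}
    warnings_log: list[str] = []

    def stage(name):
        t0 = time.perf_counter()

        def done(**info):
            stages[name] = {"wall_s": round(time.perf_counter() - t0, 4), **info}

        return done

    # simulate
    done = stage("simulate")
    design = config.design()
    shots = generate_study(
        design, effects=effects, library=library,
        instrument=config.instrument, noise=config.noise,
    )
    done(n_shots=len(shots), n_wavelengths=shots.wavelengths.size)

    # preprocess
    done = stage("preprocess")
    analysis = preprocess(shots, config.aggregation)
    if config.write_spectra:
        write_spectra(analysis, outdir / "analysis_spectra.csv")
    done(n_spectra=len(analysis), n_wavelengths=analysis.wavelengths.size)

    # extract
    done = stage("extract")
    table = build_intensity_table(analysis, library, config.peak)
    write_intensity_table(table, outdir / "intensity_table.csv")
    done(n_rows=len(table), n_features=len(library.features))

    # correlate (per species, media pooled) + group means
    done = stage("correlate")
    for species in design.species_levels:
        cm = pearson_matrix(table, subset=(table["species"] == species).to_numpy())
        write_correlation_matrix(cm, outdir / f"correlation_{species}.csv", categories=True)
    means, folds = group_mean_profile(table, ["species", "medium"])
    means.to_csv(outdir / "group_means.csv", float_format="%.12g")
    folds.to_csv(outdir / "fold_changes.csv", float_format="%.12g")
    done(n_matrices=len(design.species_levels))

    # pca
    done = stage("pca")
    pca = fit_pca(analysis.intensities, config.pca)
    pca.scores.to_csv(outdir / "pca_scores.csv", index=False, float_format="%.12g")
    pd.DataFrame(pca.loadings).to_csv(outdir / "pca_loadings.csv", index=False, float_format="%.12g")
    pd.DataFrame(
        {"PC": [f"PC{i+1}" for i in range(pca.n_components)],
         "explained_variance_ratio": pca.explained_variance_ratio}
    ).to_csv(outdir / "pca_explained_variance.csv", index=False, float_format="%.12g")
    cm = pc_correlations(table, pca.scores)
    write_correlation_matrix(cm, outdir / "pc_correlations.csv", categories=True)
    done(n_components=pca.n_components,
         cumulative_evr=float(pca.explained_variance_ratio.sum()))

    # classify (three tasks) + shot-averaging ablation
    done = stage("classify")
    summary_rows = []
    for task in ("media", "species", "combined"):
        model = SpectralClassificationModel(
            analysis, task=task, pca_config=config.pca, split_config=config.split
        )
        res = model.fit()
        res.confusion.to_csv(outdir / f"confusion_{task}.csv")
        if res.classifier.regularized:
            warnings_log.append(f"{task}: ridge-regularised discriminant")
        summary_rows.append(
            {"task": task, "k": config.aggregation.shots_per_average,
             "seed": config.split.seed, "n_train": res.report.n_train,
             "n_test": res.report.n_test, "accuracy": res.accuracy}
        )
    for k, res in averaging_ablation(
        shots, k_values=config.ablation_k, task="combined",
        aggregation=config.aggregation, pca_config=config.pca, split_config=config.split,
    ).items():
        summary_rows.append(
            {"task": "combined", "k": k, "seed": config.split.seed,
             "n_train": res.report.n_train, "n_test": res.report.n_test,
             "accuracy": res.accuracy}
        )
    pd.DataFrame(summary_rows).to_csv(
        outdir / "classification_summary.csv", index=False, float_format="%.12g"
    )
    done(n_tasks=3, ablation_k=list(config.ablation_k))

    manifest = RunManifest(
        config=config.to_dict(),
        version=__version__,
        stages=stages,
        seeds={"design": design.seed, "split": config.split.seed},
        warnings=warnings_log,
    )
    manifest.write(outdir / "manifest.json")
    return manifest
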