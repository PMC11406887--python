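"""Spectral preprocessing: crop, shot averaging, normalization.

The pipeline order is fixed as crop -> aggregate -> normalize: raw detector
counts of consecutive shots are averaged first, then each averaged spectrum is
normalized (per-spectrum total area by default) so that shot-energy variation
does not masquerade as compositional signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra import Spectrum, SpectrumSet

NORMALIZATION_MODES = ("total_area", "max_peak", "none")


@dataclass(frozen=True)
class AggregationConfig:
    shots_per_average: int = 4
    normalization: str = "total_area"
    crop_min: float = 190.0
    crop_max: float = 900.0

    def __post_init__(self) -> None:
        if self.shots_per_average < 1:
            raise ValueError("shots_per_average must be >= 1")
        if not self.crop_min < self.crop_max:
            raise ValueError("crop_min must be below crop_max")
        if self.normalization not in NORMALIZATION_MODES:
            raise ValueError(
                f"unknown normalization {self.normalization!r}; "
                f"expected one of {NORMALIZATION_MODES}"
            )


def crop(spectra: SpectrumSet | Spectrum, crop_min: float = 190.0, crop_max: float = 900.0):
    """Keep grid points with crop_min <= lambda <= crop_max (closed interval)."""
    # tolerate float accumulation on regular grids at the closed endpoints
    eps = 1e-9 * max(abs(crop_min), abs(crop_max), 1.0)
    if isinstance(spectra, Spectrum):
        mask = (spectra.wavelengths >= crop_min - eps) & (spectra.wavelengths <= crop_max + eps)
        if not mask.any():
            raise ValueError(
                f"crop excludes all points: [{crop_min}, {crop_max}] does not "
                f"overlap the grid [{spectra.wavelengths[0]}, {spectra.wavelengths[-1]}]"
            )
        return Spectrum(spectra.wavelengths[mask], spectra.intensities[mask], dict(spectra.meta))
    mask = (spectra.wavelengths >= crop_min - eps) & (spectra.wavelengths <= crop_max + eps)
    if not mask.any():
        raise ValueError(
            f"crop excludes all points: [{crop_min}, {crop_max}] does not "
            f"overlap the grid [{spectra.wavelengths[0]}, {spectra.wavelengths[-1]}]"
        )
    return SpectrumSet(spectra.wavelengths[mask], spectra.intensities[:, mask], spectra.meta)


def aggregate_shots(shots: SpectrumSet, k: int = 4) -> SpectrumSet:
    """Average disjoint groups of k consecutive shots within each mount.

    Shots are grouped in acquisition order (shot index) within a mount
    (``sample_id``); group g collects shots [g*k, (g+1)*k).  The per-mount
    shot count must be divisible by k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if "shot" not in shots.meta.columns:
        raise ValueError("metadata lacks a 'shot' column; input must be a raw shot set")
    blocks = []
    meta_rows = []
    for sample_id, idx in shots.meta.groupby("sample_id", sort=False).groups.items():
        sub = shots.meta.loc[idx].sort_values("shot")
        n = len(sub)
        if n % k != 0:
            raise ValueError(f"mount {sample_id!r} has {n} shots, not divisible by k={k}")
        order = sub.index.to_numpy()
        for g in range(n // k):
            members = order[g * k : (g + 1) * k]
            blocks.append(shots.intensities[members].mean(axis=0))
            first = shots.meta.loc[members[0]]
            meta_rows.append(
                {
                    "sample_id": sample_id,
                    "species": first.get("species"),
                    "medium": first.get("medium"),
                    "bio_rep": first.get("bio_rep"),
                    "tech_rep": first.get("tech_rep"),
                    "group": g,
                    "n_shots": k,
                }
            )
    return SpectrumSet(shots.wavelengths, np.vstack(blocks), pd.DataFrame(meta_rows))


def normalize(spectra: SpectrumSet | Spectrum, mode: str = "total_area"):
    """Per-spectrum normalization: 'total_area' makes intensities sum to 1,
    'max_peak' makes the maximum 1, 'none' is the identity."""
    if mode not in NORMALIZATION_MODES:
        raise ValueError(f"unknown normalization {mode!r}; expected one of {NORMALIZATION_MODES}")
    if isinstance(spectra, Spectrum):
        as_set = SpectrumSet(
            spectra.wavelengths, spectra.intensities[None, :], pd.DataFrame([spectra.meta])
        )
        return normalize(as_set, mode)[0]
    if mode == "none":
        return SpectrumSet(spectra.wavelengths, spectra.intensities.copy(), spectra.meta)
    if mode == "total_area":
        denom = spectra.intensities.sum(axis=1)
    else:
        denom = spectra.intensities.max(axis=1)
    if np.any(denom <= 0):
        bad = int(np.argmax(denom <= 0))
        raise ValueError(f"cannot normalize spectrum {bad}: {mode} denominator is not positive")
    return SpectrumSet(spectra.wavelengths, spectra.intensities / denom[:, None], spectra.meta)


def preprocess(shots: SpectrumSet, cfg: AggregationConfig | None = None) -> SpectrumSet:
    """crop -> aggregate -> normalize, each applied exactly once."""
    cfg = cfg or AggregationConfig()
    out = crop(shots, cfg.crop_min, cfg.crop_max)
    out = aggregate_shots(out, cfg.shots_per_average)
    return normalize(out, cfg.normalization)
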