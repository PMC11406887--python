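"""Synthetic LIBS study generator.

The instrument deposited no public raw spectra, so analyses are exercised on
simulated per-shot spectra with a known, planted class structure.  The signal
model is deliberately simple and fully declared:

    intensity(lambda) = continuum(lambda)
                        + m_shot * b_rep * sum_lines A_line * G(lambda; center, fwhm)
                        + noise,     A_line = concentration * relative_strength

where ``G`` is a unit-peak Gaussian, ``continuum`` is a smooth exponentially
decaying background, ``m_shot`` is a per-shot lognormal ablation-mass
multiplier (shot-to-shot coupling between laser pulse and sample varies
strongly in LIBS), ``b_rep`` is a lognormal multiplier shared by all shots of
one biological replicate, and the additive noise is heteroscedastic Gaussian
with variance ``a + b * signal``.  Negative intensities are clipped at zero.
At zero noise the background-corrected peak response is exactly linear in
concentration.

Class structure (two fungal species x two growth media) is planted as
multiplicative fold changes on element concentrations, with directions taken
from the reported species/media contrasts: Zn, P, Mn, Mg, Fe, H, O and Al more
intense in *H. finlandica*; Li and Ca more intense in *M. hiemalis*; Ca and Al
more intense in potato dextrose broth (PDB); C more intense in glucose minimal
medium (GMM).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .lines import FEATURE_ORDER, LineLibrary, default_line_library
from .spectra import ShotSet, Spectrum

SPECIES_LEVELS = ("Hf", "Mh")
MEDIA_LEVELS = ("PDB", "GMM")

#: Class-independent additive concentration from sample moisture and ambient
#: air (no inert cover gas), so H, N and O are always present.
ATMOSPHERIC_BASELINE: Mapping[str, float] = {"H": 30.0, "O": 35.0, "N": 25.0}


@dataclass(frozen=True)
class InstrumentConfig:
    """Spectrometer/laser description.  Delay, integration, pulse energy and
    spot size are descriptive metadata; they do not enter the signal model."""

    wavelength_min: float = 178.0
    wavelength_max: float = 1022.0
    grid_step: float = 0.1
    line_width_fwhm: float = 0.15
    delay_time_us: float = 3.0
    integration_time_us: float = 50.0
    laser_energy_mJ: float = 100.0
    spot_size_um: float = 100.0

    def __post_init__(self) -> None:
        if not self.wavelength_min < self.wavelength_max:
            raise ValueError("wavelength_min must be below wavelength_max")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if self.line_width_fwhm < self.grid_step:
            raise ValueError("line_width_fwhm must be at least one grid step")

    @property
    def wavelength_grid(self) -> np.ndarray:
        return np.arange(
            self.wavelength_min, self.wavelength_max + self.grid_step / 2, self.grid_step
        )


@dataclass(frozen=True)
class NoiseConfig:
    """Stochastic terms and the continuum background of the signal model.

    ``additive_var``/``signal_var`` give the per-pixel Gaussian noise variance
    ``a + b*signal`` (counts^2, counts); ``shot_scale_sigma`` is the log-sd of
    the per-shot ablation-mass multiplier; ``bio_sigma`` the log-sd of the
    per-biological-replicate multiplier.  The continuum is
    ``amp * exp(-(lambda - lambda_min)/decay) + floor``.
    """

    additive_var: float = 0.05
    signal_var: float = 0.001
    shot_scale_sigma: float = 0.55
    bio_sigma: float = 0.1
    continuum_amplitude: float = 20.0
    continuum_decay_nm: float = 250.0
    continuum_floor: float = 2.0

    @classmethod
    def zero(cls) -> "NoiseConfig":
        """Noiseless configuration (continuum retained)."""
        return cls(additive_var=0.0, signal_var=0.0, shot_scale_sigma=0.0, bio_sigma=0.0)

    def continuum(self, wavelengths: np.ndarray, wavelength_min: float) -> np.ndarray:
        return (
            self.continuum_amplitude
            * np.exp(-(wavelengths - wavelength_min) / self.continuum_decay_nm)
            + self.continuum_floor
        )


@dataclass(frozen=True)
class ElementProfile:
    """Nonnegative dimensionless abundance per feature label."""

    concentration: Mapping[str, float]

    def __post_init__(self) -> None:
        for label, value in self.concentration.items():
            if value < 0:
                raise ValueError(f"negative concentration for {label}: {value}")

    def scaled(self, factor: float) -> "ElementProfile":
        return ElementProfile({k: v * factor for k, v in self.concentration.items()})

    def get(self, label: str) -> float:
        return float(self.concentration.get(label, 0.0))


def default_element_profile() -> ElementProfile:
    """Baseline abundances before class effects, chosen so every element's
    primary line is comfortably above the default noise floor while spanning
    an order of magnitude, as relative intensities in biomass spectra do."""
    return ElementProfile(
        {
            "C": 100.0, "Zn": 40.0, "P": 35.0, "Mn": 30.0, "Mg": 50.0,
            "Si": 20.0, "Fe": 45.0, "Ca": 60.0, "Al": 25.0, "Na": 55.0,
            "H": 80.0, "Li": 15.0, "K": 65.0, "O": 90.0, "N": 70.0,
            "CN": 30.0,
        }
    )


HIGHER_IN_HF = "higher_in_Hf"
HIGHER_IN_MH = "higher_in_Mh"
HIGHER_IN_PDB = "higher_in_PDB"
HIGHER_IN_GMM = "higher_in_GMM"
NEUTRAL = "neutral"


@dataclass(frozen=True)
class EffectDirectionTable:
    """Planted direction of the species and media contrasts per feature."""

    species_effects: Mapping[str, str]
    media_effects: Mapping[str, str]
    effect_size: float = 2.0

    def __post_init__(self) -> None:
        if self.effect_size <= 1:
            raise ValueError("effect_size must exceed 1")
        for name, table, allowed in (
            ("species_effects", self.species_effects, {HIGHER_IN_HF, HIGHER_IN_MH, NEUTRAL}),
            ("media_effects", self.media_effects, {HIGHER_IN_PDB, HIGHER_IN_GMM, NEUTRAL}),
        ):
            if set(table) != set(FEATURE_ORDER):
                raise ValueError(f"{name} must label every feature in {list(FEATURE_ORDER)}")
            bad = {v for v in table.values()} - allowed
            if bad:
                raise ValueError(f"{name} has invalid direction(s) {sorted(bad)}")


def default_effect_directions(effect_size: float = 2.0) -> EffectDirectionTable:
    """Directions reported for the species and media contrasts."""
    species = {f: NEUTRAL for f in FEATURE_ORDER}
    for f in ("Zn", "P", "Mn", "Mg", "Fe", "H", "O", "Al"):
        species[f] = HIGHER_IN_HF
    for f in ("Li", "Ca"):
        species[f] = HIGHER_IN_MH
    media = {f: NEUTRAL for f in FEATURE_ORDER}
    for f in ("Ca", "Al"):
        media[f] = HIGHER_IN_PDB
    media["C"] = HIGHER_IN_GMM
    return EffectDirectionTable(species_effects=species, media_effects=media, effect_size=effect_size)


def class_profile(
    species: str,
    medium: str,
    base: ElementProfile,
    effects: EffectDirectionTable,
) -> ElementProfile:
    """Apply the planted fold changes of one (species, medium) class.

    Each feature whose species direction favours ``species`` is multiplied by
    ``effect_size``, and likewise independently for the medium, so a feature
    favoured by both contrasts composes to ``effect_size**2``.
    """
    if species not in SPECIES_LEVELS:
        raise ValueError(f"unknown species {species!r}; expected one of {SPECIES_LEVELS}")
    if medium not in MEDIA_LEVELS:
        raise ValueError(f"unknown medium {medium!r}; expected one of {MEDIA_LEVELS}")
    favoured_species = HIGHER_IN_HF if species == "Hf" else HIGHER_IN_MH
    favoured_medium = HIGHER_IN_PDB if medium == "PDB" else HIGHER_IN_GMM
    out = {}
    for label, value in base.concentration.items():
        if effects.species_effects.get(label, NEUTRAL) == favoured_species:
            value = value * effects.effect_size
        if effects.media_effects.get(label, NEUTRAL) == favoured_medium:
            value = value * effects.effect_size
        out[label] = value
    return ElementProfile(out)


@dataclass(frozen=True)
class StudyDesign:
    """Crossed species x media design with biological/technical replication."""

    species_levels: tuple[str, ...] = SPECIES_LEVELS
    media_levels: tuple[str, ...] = MEDIA_LEVELS
    n_biological: int = 5
    n_technical: int = 1
    shots_per_mount: int = 16  # 4 x 4 grid, one shot per spot
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_biological, self.n_technical, self.shots_per_mount) < 1:
            raise ValueError("replicate counts and shots_per_mount must be >= 1")

    @property
    def n_mounts(self) -> int:
        return (
            len(self.species_levels) * len(self.media_levels)
            * self.n_biological * self.n_technical
        )

    @property
    def n_shots(self) -> int:
        return self.n_mounts * self.shots_per_mount


def paper_n80(seed: int = 0, **overrides) -> StudyDesign:
    """One mount per biological replicate: 20 mounts x 16 shots -> 320 raw
    shots -> 80 analysis spectra after 4-shot averaging."""
    kwargs = {"n_biological": 5, "n_technical": 1, "shots_per_mount": 16, **overrides}
    return StudyDesign(seed=seed, **kwargs)


def specimen20(seed: int = 0, **overrides) -> StudyDesign:
    """Five technical mounts per biological replicate: 20 shot-averaged
    spectra per specimen after 4-shot averaging."""
    kwargs = {"n_biological": 5, "n_technical": 5, "shots_per_mount": 16, **overrides}
    return StudyDesign(seed=seed, **kwargs)


DESIGN_PRESETS = {"paper_n80": paper_n80, "specimen20": specimen20}


def _line_matrix(library: LineLibrary, grid: np.ndarray, fwhm: float) -> np.ndarray:
    """(n_lines, n_grid) unit-peak Gaussian profile per library line."""
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    centers = np.array([ln.center_wavelength for ln in library.lines])
    return np.exp(-((grid[None, :] - centers[:, None]) ** 2) / (2.0 * sigma**2))


def _amplitudes(profile: ElementProfile, library: LineLibrary) -> np.ndarray:
    unknown = set(profile.concentration) - set(library.features)
    if unknown:
        raise ValueError(f"profile has unknown feature label(s): {sorted(unknown)}")
    return np.array(
        [profile.get(ln.feature_label) * ln.relative_strength for ln in library.lines]
    )


def _noisy(clean: np.ndarray, noise: NoiseConfig, rng: np.random.Generator) -> np.ndarray:
    var = noise.additive_var + noise.signal_var * clean
    if np.any(var > 0):
        clean = clean + rng.normal(0.0, np.sqrt(var))
    return np.clip(clean, 0.0, None)


def simulate_shot(
    profile: ElementProfile,
    library: LineLibrary | None = None,
    instrument: InstrumentConfig | None = None,
    noise: NoiseConfig | None = None,
    rng: np.random.Generator | None = None,
    meta: Mapping | None = None,
) -> Spectrum:
    """Simulate a single laser shot for a given element profile."""
    library = library or default_line_library()
    instrument = instrument or InstrumentConfig()
    noise = noise or NoiseConfig()
    rng = rng if rng is not None else np.random.default_rng(0)
    grid = instrument.wavelength_grid
    amps = _amplitudes(profile, library)
    profiles = _line_matrix(library, grid, instrument.line_width_fwhm)
    m_shot = float(np.exp(rng.normal(0.0, noise.shot_scale_sigma))) if noise.shot_scale_sigma else 1.0
    clean = noise.continuum(grid, instrument.wavelength_min) + m_shot * (amps @ profiles)
    return Spectrum(grid, _noisy(clean, noise, rng), dict(meta or {}))


def generate_study(
    design: StudyDesign,
    effects: EffectDirectionTable | None = None,
    library: LineLibrary | None = None,
    instrument: InstrumentConfig | None = None,
    noise: NoiseConfig | None = None,
    base_profile: ElementProfile | None = None,
    atmosphere: Mapping[str, float] = ATMOSPHERIC_BASELINE,
) -> ShotSet:
    """Generate labelled per-shot spectra for the full crossed design.

    Reproducible given ``design.seed``: the biological-replicate multiplier is
    drawn once per specimen and shared by all of its shots; the ablation-mass
    multiplier and pixel noise are drawn per shot.
    """
    effects = effects or default_effect_directions()
    library = library or default_line_library()
    instrument = instrument or InstrumentConfig()
    noise = noise or NoiseConfig()
    base_profile = base_profile or default_element_profile()
    rng = np.random.default_rng(design.seed)
    grid = instrument.wavelength_grid
    profiles = _line_matrix(library, grid, instrument.line_width_fwhm)
    continuum = noise.continuum(grid, instrument.wavelength_min)

    class_amps = {}
    for species in design.species_levels:
        for medium in design.media_levels:
            prof = class_profile(species, medium, base_profile, effects)
            conc = dict(prof.concentration)
            for label, extra in atmosphere.items():
                conc[label] = conc.get(label, 0.0) + extra
            class_amps[(species, medium)] = _amplitudes(ElementProfile(conc), library)

    intensities = np.empty((design.n_shots, grid.size))
    meta_rows = []
    row = 0
    for species in design.species_levels:
        for medium in design.media_levels:
            amps = class_amps[(species, medium)]
            for bio in range(1, design.n_biological + 1):
                b_rep = float(np.exp(rng.normal(0.0, noise.bio_sigma))) if noise.bio_sigma else 1.0
                for tech in range(1, design.n_technical + 1):
                    sample_id = f"{species}-{medium}-b{bio}-t{tech}"
                    for shot in range(design.shots_per_mount):
                        m_shot = (
                            float(np.exp(rng.normal(0.0, noise.shot_scale_sigma)))
                            if noise.shot_scale_sigma
                            else 1.0
                        )
                        clean = continuum + b_rep * m_shot * (amps @ profiles)
                        intensities[row] = _noisy(clean, noise, rng)
                        meta_rows.append(
                            {
                                "sample_id": sample_id,
                                "species": species,
                                "medium": medium,
                                "bio_rep": bio,
                                "tech_rep": tech,
                                "shot": shot,
                            }
                        )
                        row += 1
    return ShotSet(grid, intensities, pd.DataFrame(meta_rows))
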