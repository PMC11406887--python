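"""Background-corrected peak extraction and element identification.

For each reference line, the local continuum baseline is estimated from two
flanking windows on either side of the line (robust medians joined by a
straight line), excluding a guard region around the line centre, and the
background-corrected intensity is the in-window maximum minus the baseline
evaluated at the maximum's wavelength, floored at zero.  Elements with
several reference lines take the strongest-line value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lines import LineLibrary, LineRef
from .spectra import Spectrum, SpectrumSet

#: Consistency factor turning a median absolute deviation into a Gaussian sigma.
_MAD_TO_SIGMA = 1.4826

META_COLUMNS_PASSTHROUGH = ("sample_id", "species", "medium", "bio_rep", "tech_rep", "group", "n_shots", "shot")


@dataclass(frozen=True)
class PeakConfig:
    """Tolerances of the extraction stage (all wavelengths in nm)."""

    match_tolerance: float = 0.3
    baseline_flank: float = 1.0
    exclusion_halfwidth: float = 0.45
    snr_threshold: float = 3.0
    statistic: str = "max"  # or "area"
    include_molecular: bool = False  # count CN in identify_elements

    def __post_init__(self) -> None:
        if self.exclusion_halfwidth < self.match_tolerance:
            raise ValueError("exclusion_halfwidth must be >= match_tolerance")
        if self.baseline_flank <= 0:
            raise ValueError("baseline_flank must be positive")
        if self.statistic not in ("max", "area"):
            raise ValueError(f"unknown peak statistic {self.statistic!r}")


def _window_indices(wl: np.ndarray, lo: float, hi: float) -> np.ndarray:
    i0, i1 = np.searchsorted(wl, [lo, hi + 1e-12])
    return np.arange(i0, i1)


def _flank_windows(wl: np.ndarray, center: float, cfg: PeakConfig):
    left_lo = center - cfg.exclusion_halfwidth - cfg.baseline_flank
    left_hi = center - cfg.exclusion_halfwidth
    right_lo = center + cfg.exclusion_halfwidth
    right_hi = center + cfg.exclusion_halfwidth + cfg.baseline_flank
    left = _window_indices(wl, left_lo, left_hi)
    right = _window_indices(wl, right_lo, right_hi)
    if left.size == 0 or right.size == 0:
        raise ValueError(
            f"baseline window off-grid for line at {center} nm: "
            f"left [{left_lo:.3f}, {left_hi:.3f}] has {left.size} points, "
            f"right [{right_lo:.3f}, {right_hi:.3f}] has {right.size} points"
        )
    anchors = ((left_lo + left_hi) / 2.0, (right_lo + right_hi) / 2.0)
    return left, right, anchors


def _baseline_params(I: np.ndarray, wl: np.ndarray, center: float, cfg: PeakConfig):
    """Per-spectrum slope/intercept of the flank-median baseline line.

    ``I`` is (n_spectra, n_wavelengths); returns (slope, intercept) arrays.
    """
    left, right, (x0, x1) = _flank_windows(wl, center, cfg)
    m0 = np.median(I[:, left], axis=1)
    m1 = np.median(I[:, right], axis=1)
    slope = (m1 - m0) / (x1 - x0)
    intercept = m0 - slope * x0
    return slope, intercept


def estimate_baseline(spectrum: Spectrum, center: float, cfg: PeakConfig | None = None) -> float:
    """Baseline intensity at ``center``: linear interpolation between the
    medians of the two flanking windows."""
    cfg = cfg or PeakConfig()
    slope, intercept = _baseline_params(
        spectrum.intensities[None, :], spectrum.wavelengths, center, cfg
    )
    return float(slope[0] * center + intercept[0])


def flank_noise_sigma(spectrum: Spectrum, center: float, cfg: PeakConfig | None = None) -> float:
    """Local noise estimate: scaled median absolute deviation of the flank
    points about their own window medians, pooled over both flanks."""
    cfg = cfg or PeakConfig()
    wl = spectrum.wavelengths
    left, right, _ = _flank_windows(wl, center, cfg)
    resid = np.concatenate(
        [
            np.abs(spectrum.intensities[left] - np.median(spectrum.intensities[left])),
            np.abs(spectrum.intensities[right] - np.median(spectrum.intensities[right])),
        ]
    )
    return float(_MAD_TO_SIGMA * np.median(resid))


def _extract_many(I: np.ndarray, wl: np.ndarray, line: LineRef, cfg: PeakConfig) -> np.ndarray:
    """Background-corrected intensity of one line for every row of ``I``."""
    center = line.center_wavelength
    if center < wl[0] or center > wl[-1]:
        raise ValueError(
            f"line {line.feature_label} at {center} nm lies outside the "
            f"cropped range [{wl[0]}, {wl[-1]}] nm"
        )
    window = _window_indices(wl, center - cfg.match_tolerance, center + cfg.match_tolerance)
    if window.size == 0:
        raise ValueError(f"no grid points within {cfg.match_tolerance} nm of {center} nm")
    slope, intercept = _baseline_params(I, wl, center, cfg)
    seg = I[:, window]
    if cfg.statistic == "max":
        j = np.argmax(seg, axis=1)
        peak_wl = wl[window[j]]
        value = seg[np.arange(len(seg)), j] - (slope * peak_wl + intercept)
    else:  # area
        baseline = slope[:, None] * wl[window][None, :] + intercept[:, None]
        step = float(np.mean(np.diff(wl[window]))) if window.size > 1 else 1.0
        value = (seg - baseline).sum(axis=1) * step
    return np.clip(value, 0.0, None)


def extract_intensity(spectrum: Spectrum, line: LineRef, cfg: PeakConfig | None = None) -> float:
    """Background-corrected peak intensity of one reference line."""
    cfg = cfg or PeakConfig()
    return float(
        _extract_many(spectrum.intensities[None, :], spectrum.wavelengths, line, cfg)[0]
    )


def build_intensity_table(
    spectra: SpectrumSet,
    library: LineLibrary,
    cfg: PeakConfig | None = None,
) -> pd.DataFrame:
    """Spectra x features table of background-corrected intensities.

    One row per analysis spectrum (metadata columns first), one column per
    feature in the library's canonical order; multi-line features take the
    maximum over their lines (strongest-line rule).
    """
    cfg = cfg or PeakConfig()
    meta_cols = [c for c in META_COLUMNS_PASSTHROUGH if c in spectra.meta.columns]
    out = spectra.meta[meta_cols].copy()
    for feature in library.features:
        values = np.max(
            [
                _extract_many(spectra.intensities, spectra.wavelengths, ln, cfg)
                for ln in library.lines_for(feature)
            ],
            axis=0,
        )
        out[feature] = values
    out.attrs["features"] = list(library.features)
    out.attrs["meta_columns"] = meta_cols
    return out


def feature_columns(table: pd.DataFrame) -> list[str]:
    """The feature columns of an intensity table (canonical order)."""
    if "features" in table.attrs:
        return list(table.attrs["features"])
    from .lines import FEATURE_ORDER

    return [f for f in FEATURE_ORDER if f in table.columns]


def identify_elements(
    spectrum: Spectrum,
    library: LineLibrary,
    cfg: PeakConfig | None = None,
) -> set[str]:
    """Feature labels whose background-corrected intensity exceeds
    ``snr_threshold`` times the local flank-noise estimate for at least one
    reference line.  Molecular bands (CN) are excluded unless
    ``cfg.include_molecular`` is set."""
    cfg = cfg or PeakConfig()
    found: set[str] = set()
    for feature in library.features:
        lines = library.lines_for(feature)
        if not cfg.include_molecular and all(ln.is_molecular_band for ln in lines):
            continue
        for ln in lines:
            intensity = extract_intensity(spectrum, ln, cfg)
            sigma = flank_noise_sigma(spectrum, ln.center_wavelength, cfg)
            if (sigma > 0 and intensity > cfg.snr_threshold * sigma) or (
                sigma == 0 and intensity > 0
            ):
                found.add(feature)
                break
    return found
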