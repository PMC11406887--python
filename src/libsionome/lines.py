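"""Reference emission-line library.

Each of the 15 elements detectable in fungal biomass by LIBS (C, Zn, P, Mn,
Mg, Si, Fe, Ca, Al, Na, H, Li, K, O, N) is represented by one to three
strong persistent atomic lines from the NIST Atomic Spectra Database; the
CN violet-system molecular emission is represented as a single pseudo-line
at its band head.  The same library drives both the spectrum simulator and
the peak-extraction stage, so the assignment tolerance is testable and the
library can be replaced by the user at run time.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

#: Spectrometer coverage, nm.
INSTRUMENT_RANGE = (178.0, 1022.0)

#: The 15 element symbols plus the CN molecular band, in canonical order.
FEATURE_ORDER = (
    "C", "Zn", "P", "Mn", "Mg", "Si", "Fe", "Ca",
    "Al", "Na", "H", "Li", "K", "O", "N", "CN",
)

ELEMENT_FEATURES = tuple(f for f in FEATURE_ORDER if f != "CN")

_COLUMNS = ("feature_label", "center_wavelength", "relative_strength", "is_molecular_band")


@dataclass(frozen=True)
class LineRef:
    """One reference emission line (or molecular band head)."""

    feature_label: str
    center_wavelength: float  # nm
    relative_strength: float  # dimensionless, in (0, 1]
    is_molecular_band: bool = False

    def __post_init__(self) -> None:
        lo, hi = INSTRUMENT_RANGE
        if not lo <= self.center_wavelength <= hi:
            raise ValueError(
                f"line {self.feature_label} at {self.center_wavelength} nm is outside "
                f"the instrument range {lo}-{hi} nm"
            )
        if not 0 < self.relative_strength <= 1:
            raise ValueError(
                f"relative_strength must be in (0, 1], got {self.relative_strength} "
                f"for {self.feature_label}"
            )


@dataclass(frozen=True)
class LineLibrary:
    """An ordered collection of reference lines covering all 16 features."""

    lines: tuple[LineRef, ...]
    feature_order: tuple[str, ...] = FEATURE_ORDER

    def __post_init__(self) -> None:
        labels = {ln.feature_label for ln in self.lines}
        expected = set(self.feature_order)
        if labels != expected:
            missing = sorted(expected - labels)
            extra = sorted(labels - expected)
            raise ValueError(
                f"library must cover exactly the features {list(self.feature_order)}; "
                f"missing={missing}, unexpected={extra}"
            )
        seen: set[tuple[str, float]] = set()
        for ln in self.lines:
            key = (ln.feature_label, ln.center_wavelength)
            if key in seen:
                raise ValueError(f"duplicate line {key}")
            seen.add(key)

    def lines_for(self, feature_label: str) -> tuple[LineRef, ...]:
        out = tuple(ln for ln in self.lines if ln.feature_label == feature_label)
        if not out:
            raise KeyError(f"unknown feature label {feature_label!r}")
        return out

    def primary_line(self, feature_label: str) -> LineRef:
        """The strongest reference line of a feature."""
        return max(self.lines_for(feature_label), key=lambda ln: ln.relative_strength)

    @property
    def features(self) -> tuple[str, ...]:
        return self.feature_order

    @property
    def element_features(self) -> tuple[str, ...]:
        return tuple(f for f in self.feature_order if not all(
            ln.is_molecular_band for ln in self.lines_for(f)
        ))


def _library_from_frame(df: pd.DataFrame, source: str) -> LineLibrary:
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: missing column(s) {missing}")
    if len(df) == 0:
        raise ValueError(f"{source}: no lines")
    lines = []
    for i, row in df.iterrows():
        try:
            lines.append(
                LineRef(
                    feature_label=str(row["feature_label"]),
                    center_wavelength=float(row["center_wavelength"]),
                    relative_strength=float(row["relative_strength"]),
                    is_molecular_band=bool(int(row["is_molecular_band"])),
                )
            )
        except ValueError as err:
            raise ValueError(f"{source}, row {i}: {err}") from err
    try:
        return LineLibrary(lines=tuple(lines))
    except ValueError as err:
        raise ValueError(f"{source}: {err}") from err


def default_line_library() -> LineLibrary:
    """The packaged NIST-derived line library (deterministic and pure)."""
    ref = importlib.resources.files("libsionome.data") / "emission_lines.tsv"
    with importlib.resources.as_file(ref) as path:
        return read_line_library(path)


def read_line_library(path) -> LineLibrary:
    """Read a tab-separated line table (header row; '#' comment lines)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError as err:
        raise ValueError(f"{path}: no lines") from err
    return _library_from_frame(df, str(path))


def write_line_library(library: LineLibrary, path) -> None:
    """Write a library as the tab-separated table read_line_library accepts."""
    df = pd.DataFrame(
        {
            "feature_label": [ln.feature_label for ln in library.lines],
            "center_wavelength": [ln.center_wavelength for ln in library.lines],
            "relative_strength": [ln.relative_strength for ln in library.lines],
            "is_molecular_band": [int(ln.is_molecular_band) for ln in library.lines],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
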