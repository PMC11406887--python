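"""In-memory containers for LIBS spectra.

A :class:`Spectrum` is one wavelength grid plus one intensity vector with
acquisition metadata; a :class:`SpectrumSet` holds many spectra sharing a
grid (raw per-shot acquisitions or shot-averaged analysis spectra) together
with a metadata table, one row per spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

#: Metadata columns every per-shot table must carry.
SHOT_META_COLUMNS = ("sample_id", "species", "medium", "bio_rep", "tech_rep", "shot")


@dataclass
class Spectrum:
    """One spectrum: a strictly increasing wavelength grid (nm) and intensities
    in detector counts (arbitrary units)."""

    wavelengths: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavelengths.shape != self.intensities.shape:
            raise ValueError(
                f"wavelengths ({self.wavelengths.shape}) and intensities "
                f"({self.intensities.shape}) must have the same length"
            )
        if self.wavelengths.ndim != 1:
            raise ValueError("spectrum arrays must be one-dimensional")
        if self.wavelengths.size >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelength grid must be strictly increasing")

    def __len__(self) -> int:
        return self.wavelengths.size


class SpectrumSet:
    """A stack of spectra on a shared wavelength grid.

    Parameters
    ----------
    wavelengths
        Shared grid, strictly increasing, nm.
    intensities
        Array of shape ``(n_spectra, n_wavelengths)``.
    meta
        One row per spectrum.  Raw shot sets carry the columns in
        :data:`SHOT_META_COLUMNS`; shot-averaged sets replace ``shot`` with
        ``group`` and ``n_shots``.
    """

    def __init__(self, wavelengths: np.ndarray, intensities: np.ndarray, meta: pd.DataFrame):
        wavelengths = np.asarray(wavelengths, dtype=float)
        intensities = np.atleast_2d(np.asarray(intensities, dtype=float))
        if wavelengths.ndim != 1 or not np.all(np.diff(wavelengths) > 0):
            raise ValueError("wavelength grid must be one-dimensional and strictly increasing")
        if intensities.shape[1] != wavelengths.size:
            raise ValueError(
                f"intensity matrix has {intensities.shape[1]} columns but the "
                f"grid has {wavelengths.size} points"
            )
        if len(meta) != intensities.shape[0]:
            raise ValueError(
                f"metadata has {len(meta)} rows but there are {intensities.shape[0]} spectra"
            )
        self.wavelengths = wavelengths
        self.intensities = intensities
        self.meta = meta.reset_index(drop=True)

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return self.intensities.shape[0]

    def __getitem__(self, i: int) -> Spectrum:
        return Spectrum(self.wavelengths, self.intensities[i], self.meta.iloc[i].to_dict())

    def __iter__(self) -> Iterator[Spectrum]:
        for i in range(len(self)):
            yield self[i]

    def select(self, mask) -> "SpectrumSet":
        """Row subset by boolean mask or integer indices."""
        mask = np.asarray(mask)
        return SpectrumSet(self.wavelengths, self.intensities[mask], self.meta.iloc[mask])

    def mean_spectrum(self, meta: Mapping | None = None) -> Spectrum:
        """Pointwise mean over all spectra in the set."""
        return Spectrum(self.wavelengths, self.intensities.mean(axis=0), dict(meta or {}))

    @classmethod
    def from_spectra(cls, spectra: Sequence[Spectrum]) -> "SpectrumSet":
        if not spectra:
            raise ValueError("no spectra given")
        grid = spectra[0].wavelengths
        for s in spectra[1:]:
            if s.wavelengths.shape != grid.shape or not np.allclose(s.wavelengths, grid):
                raise ValueError("spectra do not share a wavelength grid")
        return cls(
            grid,
            np.vstack([s.intensities for s in spectra]),
            pd.DataFrame([s.meta for s in spectra]),
        )

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table: metadata columns plus wavelength/intensity."""
        n_wl = self.wavelengths.size
        out = self.meta.loc[self.meta.index.repeat(n_wl)].reset_index(drop=True)
        out["wavelength"] = np.tile(self.wavelengths, len(self))
        out["intensity"] = self.intensities.ravel()
        return out


#: Raw per-shot acquisitions use the same container.
ShotSet = SpectrumSet
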