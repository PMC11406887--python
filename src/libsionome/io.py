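"""Delimited-text readers and writers.

All artifacts are plain text: long-format spectrum tables (one row per
wavelength sample), intensity tables (metadata columns then one column per
feature in canonical order), and labelled correlation matrices.  Comment
lines start with '#'.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .correlations import CorrelationMatrix
from .lines import FEATURE_ORDER
from .spectra import SpectrumSet

_FLOAT_FMT = "%.12g"

_BASE_META = ("sample_id", "species", "medium", "bio_rep", "tech_rep")


def write_spectra(spectra: SpectrumSet, path) -> None:
    """Write a spectrum set as a long-format CSV
    (metadata columns, then wavelength and intensity)."""
    spectra.to_long_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_spectra(path) -> SpectrumSet:
    """Read a long-format spectrum table back into a :class:`SpectrumSet`.

    Rows may arrive in any order; spectra are normalised to a canonical
    metadata sort.  Every spectrum must share one wavelength grid.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    required = list(_BASE_META) + ["wavelength", "intensity"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if "shot" in df.columns:
        index_col = "shot"
    elif "group" in df.columns:
        index_col = "group"
    else:
        raise ValueError(f"{path}: missing column(s) ['shot' or 'group']")
    meta_cols = [c for c in df.columns if c not in ("wavelength", "intensity")]
    key_cols = list(_BASE_META) + [index_col]
    df = df.sort_values(key_cols + ["wavelength"], kind="mergesort").reset_index(drop=True)
    groups = df.groupby(key_cols, sort=False)
    sizes = groups.size().to_numpy()
    if not np.all(sizes == sizes[0]):
        raise ValueError(f"{path}: ragged wavelength grids across spectra (sizes {set(sizes)})")
    grid = None
    intensities = []
    meta_rows = []
    for key, sub in groups:
        wl = sub["wavelength"].to_numpy(dtype=float)
        if grid is None:
            grid = wl
        elif not np.allclose(wl, grid):
            raise ValueError(f"{path}: spectrum {key} is not on the shared wavelength grid")
        intensities.append(sub["intensity"].to_numpy(dtype=float))
        meta_rows.append(sub.iloc[0][meta_cols].to_dict())
    return SpectrumSet(grid, np.vstack(intensities), pd.DataFrame(meta_rows))


def write_intensity_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_intensity_table(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    features = [f for f in FEATURE_ORDER if f in df.columns]
    if not features:
        raise ValueError(f"{path}: no feature columns found")
    df.attrs["features"] = features
    df.attrs["meta_columns"] = [c for c in df.columns if c not in features]
    return df


def write_correlation_matrix(matrix: CorrelationMatrix, path, categories: bool = False) -> None:
    """Write the coefficient matrix (and optionally a companion file of
    verbal categories such as 'large+') with label header row/column."""
    path = Path(path)
    matrix.values.to_csv(path, float_format=_FLOAT_FMT)
    if categories:
        matrix.categories().to_csv(path.with_suffix(".categories" + path.suffix))


def read_correlation_matrix(path) -> CorrelationMatrix:
    df = pd.read_csv(path, index_col=0, comment="#")
    undefined = [str(lbl) for lbl in df.index if df.loc[lbl].isna().all()]
    return CorrelationMatrix(df, undefined)
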