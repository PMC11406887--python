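"""Pearson correlation profiling of element emission intensities.

Correlation matrices over the feature columns of an intensity table, the
verbal magnitude categories used to describe them (none / small / medium /
large for |r| < 0.1, 0.1-0.3, 0.3-0.5, 0.5-1.0), group-mean element profiles
with pairwise fold changes, and feature-vs-principal-component correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .peaks import feature_columns

#: Magnitude bins: half-open [lo, hi), except "large" which includes 1.0.
MAGNITUDE_BINS = (("none", 0.0, 0.1), ("small", 0.1, 0.3), ("medium", 0.3, 0.5), ("large", 0.5, 1.0))


@dataclass(frozen=True)
class CorrelationCategory:
    """Verbal description of one Pearson coefficient."""

    sign: str  # positive / negative / zero
    magnitude_class: str  # none / small / medium / large

    def __str__(self) -> str:
        suffix = {"positive": "+", "negative": "-", "zero": ""}[self.sign]
        return f"{self.magnitude_class}{suffix}"


@dataclass
class CorrelationMatrix:
    """Pearson coefficients with row/column labels.

    ``values`` is a DataFrame; undefined coefficients (zero-variance columns)
    are NaN and the offending labels are listed in ``undefined``, never
    silently imputed.  Square matrices over a shared label set are symmetric
    with a unit diagonal.
    """

    values: pd.DataFrame
    undefined: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = self.values
        if list(v.index) == list(v.columns):
            arr = v.to_numpy()
            finite = np.isfinite(arr)
            if not np.allclose(arr[finite & finite.T], arr.T[finite & finite.T], atol=1e-10):
                raise ValueError("square correlation matrix is not symmetric")
            diag = np.diag(arr)
            if not np.allclose(diag[np.isfinite(diag)], 1.0, atol=1e-10):
                raise ValueError("diagonal of a correlation matrix must be 1")
        finite_vals = v.to_numpy()[np.isfinite(v.to_numpy())]
        if finite_vals.size and (finite_vals.min() < -1 - 1e-9 or finite_vals.max() > 1 + 1e-9):
            raise ValueError("correlation coefficients must lie in [-1, 1]")

    @property
    def is_square(self) -> bool:
        return list(self.values.index) == list(self.values.columns)

    def loc(self, a: str, b: str) -> float:
        return float(self.values.loc[a, b])

    def categories(self) -> pd.DataFrame:
        """Element-wise verbal categories as strings (e.g. 'large+')."""
        return self.values.map(lambda r: "undef" if not np.isfinite(r) else str(categorize(r)))


def pearson_matrix(
    table: pd.DataFrame,
    subset: pd.Series | np.ndarray | None = None,
    features: list[str] | None = None,
) -> CorrelationMatrix:
    """Pearson correlation matrix over the feature columns of an intensity
    table, optionally restricted to the rows selected by ``subset``."""
    features = features or feature_columns(table)
    data = table.loc[np.asarray(subset)] if subset is not None else table
    if len(data) < 3:
        raise ValueError(f"need at least 3 rows to correlate, got {len(data)}")
    X = data[features].to_numpy(dtype=float)
    sd = X.std(axis=0)
    undefined = [f for f, s in zip(features, sd) if s == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X, rowvar=False)
    R = np.asarray(R, dtype=float)
    for f in undefined:
        i = features.index(f)
        R[i, :] = np.nan
        R[:, i] = np.nan
    defined = [i for i, f in enumerate(features) if f not in undefined]
    R[np.ix_(defined, defined)] = np.clip(R[np.ix_(defined, defined)], -1.0, 1.0)
    R = (R + R.T) / 2.0
    for i in defined:
        R[i, i] = 1.0
    return CorrelationMatrix(pd.DataFrame(R, index=features, columns=features), undefined)


def categorize(r: float) -> CorrelationCategory:
    """Verbal category of one coefficient: sign plus magnitude bin."""
    if not np.isfinite(r) or abs(r) > 1 + 1e-9:
        raise ValueError(f"correlation coefficient must lie in [-1, 1], got {r}")
    mag = min(abs(r), 1.0)
    sign = "positive" if r > 0 else ("negative" if r < 0 else "zero")
    for name, lo, hi in MAGNITUDE_BINS:
        if lo <= mag < hi or (name == "large" and mag == hi):
            return CorrelationCategory(sign=sign, magnitude_class=name)
    raise AssertionError("unreachable")


def group_mean_profile(
    table: pd.DataFrame,
    group_by: str | list[str] = "species",
    expected_groups: list | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean intensity per feature per group, plus pairwise fold changes.

    ``group_by`` is 'species', 'medium', or ['species', 'medium'] for the
    four-class profile.  Returns ``(means, fold_changes)``: means is indexed
    by group, fold_changes has one row per ordered group pair with columns
    per feature (ratio of group means).
    """
    cols = [group_by] if isinstance(group_by, str) else list(group_by)
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"grouping column(s) {missing} not in table")
    features = feature_columns(table)
    means = table.groupby(cols, sort=True)[features].mean()
    if expected_groups is not None:
        absent = [g for g in expected_groups if g not in means.index]
        if absent:
            raise ValueError(f"empty group(s): {absent}")
    rows = []
    index = []
    for a, b in combinations(list(means.index), 2):
        with np.errstate(divide="ignore", invalid="ignore"):
            rows.append(means.loc[a] / means.loc[b])
        index.append(f"{a}/{b}")
    folds = pd.DataFrame(rows, index=index) if rows else pd.DataFrame(columns=features)
    return means, folds


def pc_correlations(table: pd.DataFrame, scores: pd.DataFrame) -> CorrelationMatrix:
    """Pearson coefficient of each feature column with each PC score column.

    ``scores`` must be row-aligned with ``table`` (same number of rows, in
    the same order).
    """
    if len(scores) != len(table):
        raise ValueError(
            f"scores ({len(scores)} rows) are not aligned with the intensity "
            f"table ({len(table)} rows)"
        )
    features = feature_columns(table)
    X = table[features].to_numpy(dtype=float)
    S = scores.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    Sc = S - S.mean(axis=0)
    xsd = Xc.std(axis=0)
    ssd = Sc.std(axis=0)
    undefined = [f for f, s in zip(features, xsd) if s == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (Xc.T @ Sc) / len(X) / np.outer(xsd, ssd)
    R = np.clip(np.asarray(R, dtype=float), -1.0, 1.0)
    for f in undefined:
        R[features.index(f), :] = np.nan
    return CorrelationMatrix(
        pd.DataFrame(R, index=features, columns=list(scores.columns)), undefined
    )
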