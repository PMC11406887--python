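"""PCA decomposition and linear classification of LIBS spectra.

The modelling surface follows the fit/results idiom: a
:class:`SpectralClassificationModel` is built from preprocessed spectra (or
an intensity table), its :meth:`~SpectralClassificationModel.fit` runs PCA on
the full data matrix, draws a stratified one-third train / two-thirds test
split, trains an equal-prior, equal-covariance linear discriminant on the
training PC scores, and returns a :class:`SpectralClassificationResults`
carrying the scores, split, confusion counts, accuracy and a ``summary()``
table.  Module-level functions expose the individual steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .preprocess import AggregationConfig, preprocess
from .spectra import SpectrumSet

TASKS = ("media", "species", "combined")


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PCAConfig:
    n_components: int = 5
    input_mode: str = "full_spectrum"  # or "intensity_table"
    center: bool = True
    scale: bool = False

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.input_mode not in ("full_spectrum", "intensity_table"):
            raise ValueError(f"unknown input_mode {self.input_mode!r}")


@dataclass
class PCScores:
    """PCA decomposition: per-row scores, explained-variance ratios and
    orthonormal loadings (components x input features)."""

    scores: pd.DataFrame
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray
    mean: np.ndarray
    config: PCAConfig

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]


def fit_pca(X: np.ndarray | pd.DataFrame, cfg: PCAConfig | None = None) -> PCScores:
    """Principal component analysis of a (rows x features) matrix.

    Mean-centred (optionally unit-variance scaled) eigendecomposition;
    deterministic loading signs fixed by making each component's
    largest-magnitude element positive.
    """
    cfg = cfg or PCAConfig()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("input matrix contains non-finite values")
    max_rank = min(X.shape[0] - 1, X.shape[1])
    if cfg.n_components > max_rank:
        raise ValueError(
            f"n_components={cfg.n_components} exceeds the maximum rank "
            f"{max_rank} of a {X.shape[0]}x{X.shape[1]} matrix"
        )
    work = X
    if cfg.scale:
        sd = work.std(axis=0)
        work = (work - work.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    pca = PCA(n_components=cfg.n_components, svd_solver="full")
    if not cfg.center:
        # PCA always centres; emulate "no centring" by decomposing X'X directly.
        _, _, Vt = np.linalg.svd(work, full_matrices=False)
        comps = Vt[: cfg.n_components]
        scores = work @ comps.T
        total = np.sum(work**2)
        evr = np.sum(scores**2, axis=0) / total
        mean = np.zeros(X.shape[1])
    else:
        scores = pca.fit_transform(work)
        comps = pca.components_
        evr = pca.explained_variance_ratio_
        mean = pca.mean_
    # sign convention: largest-magnitude loading element positive
    for k in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[k])))
        if comps[k, j] < 0:
            comps[k] = -comps[k]
            scores[:, k] = -scores[:, k]
    cols = [f"PC{k + 1}" for k in range(comps.shape[0])]
    return PCScores(
        scores=pd.DataFrame(scores, columns=cols),
        explained_variance_ratio=np.asarray(evr, dtype=float),
        loadings=comps,
        mean=mean,
        config=cfg,
    )


# --------------------------------------------------------------------------
# Splitting
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitConfig:
    train_fraction: float = 1.0 / 3.0
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


def split_thirds(labels: Sequence, cfg: SplitConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Random train/test split, one-third train by default.

    Stratified: per class, ``max(1, round(count * train_fraction))`` rows go
    to training; the remainder to test.  Disjoint, exhaustive, reproducible
    by seed.
    """
    cfg = cfg or SplitConfig()
    labels = np.asarray(labels)
    rng = np.random.default_rng(cfg.seed)
    train: list[int] = []
    if cfg.stratified:
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            if idx.size < 3:
                raise ValueError(
                    f"class {cls!r} has only {idx.size} member(s); stratified "
                    "thirds splitting needs at least 3 per class"
                )
            n_train = max(1, int(round(idx.size * cfg.train_fraction)))
            train.extend(rng.permutation(idx)[:n_train].tolist())
    else:
        n_train = max(1, int(round(labels.size * cfg.train_fraction)))
        train.extend(rng.permutation(labels.size)[:n_train].tolist())
    train_idx = np.sort(np.array(train, dtype=int))
    test_idx = np.setdiff1d(np.arange(labels.size), train_idx)
    return train_idx, test_idx


def task_labels(meta: pd.DataFrame, task: str) -> np.ndarray:
    """Class labels for one classification task: growth media, fungal
    species, or the combined four-class species x media label."""
    if task == "media":
        return meta["medium"].to_numpy()
    if task == "species":
        return meta["species"].to_numpy()
    if task == "combined":
        return (meta["species"].astype(str) + "/" + meta["medium"].astype(str)).to_numpy()
    raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")


# --------------------------------------------------------------------------
# Linear discriminant
# --------------------------------------------------------------------------

@dataclass
class LinearClassifier:
    """Equal-prior linear discriminant with shared within-class covariance.

    Discriminant score of class k at x is ``x @ w_k - 0.5 * mu_k @ w_k`` with
    ``w_k = Sigma^{-1} mu_k``; prediction is the argmax (ties broken by class
    order).  A singular pooled covariance is ridge-regularised; if the
    covariance is entirely degenerate the classifier falls back to nearest
    class mean (identity covariance).
    """

    classes: np.ndarray
    means: np.ndarray
    covariance: np.ndarray
    weights: np.ndarray = field(init=False)
    offsets: np.ndarray = field(init=False)
    regularized: bool = False

    def __post_init__(self) -> None:
        self.weights = np.linalg.solve(self.covariance, self.means.T).T
        self.offsets = -0.5 * np.einsum("kd,kd->k", self.means, self.weights)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights.T + self.offsets

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes[np.argmax(self.decision_scores(X), axis=1)]


def train_linear_classifier(
    X: np.ndarray | pd.DataFrame, labels: Sequence, ridge_epsilon: float = 1e-8
) -> LinearClassifier:
    """Fit the equal-covariance linear discriminant on (rows x PC) scores."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least 2 classes to train a classifier")
    d = X.shape[1]
    means = np.vstack([X[labels == c].mean(axis=0) for c in classes])
    scatter = np.zeros((d, d))
    for c, mu in zip(classes, means):
        resid = X[labels == c] - mu
        scatter += resid.T @ resid
    dof = X.shape[0] - classes.size
    cov = scatter / dof if dof > 0 else np.zeros((d, d))
    regularized = False
    trace = np.trace(cov)
    if trace <= 0:
        cov = np.eye(d)  # nearest-class-mean fallback
        regularized = True
    elif np.linalg.cond(cov) > 1e12:
        cov = cov + ridge_epsilon * (trace / d) * np.eye(d)
        regularized = True
        warnings.warn(
            "pooled within-class covariance is singular; ridge regularisation applied",
            RuntimeWarning,
            stacklevel=2,
        )
    clf = LinearClassifier(classes=classes, means=means, covariance=cov)
    clf.regularized = regularized
    return clf


# --------------------------------------------------------------------------
# Evaluation
# --------------------------------------------------------------------------

@dataclass
class ClassifierReport:
    """Split bookkeeping, confusion counts and accuracy for one task."""

    task: str
    train_indices: np.ndarray
    test_indices: np.ndarray
    confusion: pd.DataFrame  # rows: true class; columns: predicted class
    accuracy: float
    misclassified: pd.DataFrame
    unseen_classes: list = field(default_factory=list)

    @property
    def n_train(self) -> int:
        return int(self.train_indices.size)

    @property
    def n_test(self) -> int:
        return int(self.test_indices.size)


def evaluate(
    classifier: LinearClassifier,
    X_test: np.ndarray | pd.DataFrame,
    labels_test: Sequence,
    task: str = "combined",
    train_indices: np.ndarray | None = None,
    test_indices: np.ndarray | None = None,
    meta_test: pd.DataFrame | None = None,
) -> ClassifierReport:
    """Confusion counts and accuracy on held-out rows; misclassified rows are
    listed with their metadata.  Test labels unseen in training appear as
    extra confusion rows and are flagged."""
    X_test = np.asarray(X_test, dtype=float)
    labels_test = np.asarray(labels_test)
    if labels_test.size == 0:
        raise ValueError("test set is empty")
    pred = classifier.predict(X_test)
    unseen = sorted(set(labels_test) - set(classifier.classes))
    true_classes = list(classifier.classes) + unseen
    confusion = pd.DataFrame(
        0, index=pd.Index(true_classes, name="true"),
        columns=pd.Index(list(classifier.classes), name="predicted"),
    )
    for t, p in zip(labels_test, pred):
        confusion.loc[t, p] += 1
    correct = int(np.sum(pred == labels_test))
    accuracy = correct / labels_test.size
    wrong = np.flatnonzero(pred != labels_test)
    if meta_test is not None:
        mis = meta_test.iloc[wrong].copy()
    else:
        mis = pd.DataFrame(index=wrong)
    mis["true"] = labels_test[wrong]
    mis["predicted"] = pred[wrong]
    return ClassifierReport(
        task=task,
        train_indices=np.asarray(train_indices if train_indices is not None else []),
        test_indices=np.asarray(test_indices if test_indices is not None else np.arange(labels_test.size)),
        confusion=confusion,
        accuracy=accuracy,
        misclassified=mis,
        unseen_classes=unseen,
    )


# --------------------------------------------------------------------------
# Model / Results
# --------------------------------------------------------------------------

class SpectralClassificationModel:
    """PCA-space linear classification of preprocessed LIBS spectra.

    Parameters
    ----------
    data
        Preprocessed :class:`SpectrumSet` (full-spectrum mode) or an
        intensity table DataFrame (intensity-table mode).
    task
        'media', 'species' or 'combined'.
    pca_config, split_config
        Stage configurations; defaults reproduce the five-component,
        stratified one-third/two-thirds protocol.
    """

    def __init__(
        self,
        data: SpectrumSet | pd.DataFrame,
        task: str = "combined",
        pca_config: PCAConfig | None = None,
        split_config: SplitConfig | None = None,
    ):
        if task not in TASKS:
            raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
        self.task = task
        self.pca_config = pca_config or PCAConfig()
        self.split_config = split_config or SplitConfig()
        if isinstance(data, SpectrumSet):
            self.meta = data.meta
            self.X = data.intensities
        else:
            from .peaks import feature_columns

            self.meta = data.drop(columns=feature_columns(data))
            self.X = data[feature_columns(data)].to_numpy(dtype=float)
        self.labels = task_labels(self.meta, task)

    @classmethod
    def from_shots(
        cls,
        shots: SpectrumSet,
        task: str = "combined",
        aggregation: AggregationConfig | None = None,
        pca_config: PCAConfig | None = None,
        split_config: SplitConfig | None = None,
    ) -> "SpectralClassificationModel":
        """Build the model from raw shots (crop -> average -> normalize)."""
        return cls(
            preprocess(shots, aggregation or AggregationConfig()),
            task=task,
            pca_config=pca_config,
            split_config=split_config,
        )

    def fit(self) -> "SpectralClassificationResults":
        pca = fit_pca(self.X, self.pca_config)
        train_idx, test_idx = split_thirds(self.labels, self.split_config)
        scores = pca.scores.to_numpy()
        clf = train_linear_classifier(scores[train_idx], self.labels[train_idx])
        report = evaluate(
            clf,
            scores[test_idx],
            self.labels[test_idx],
            task=self.task,
            train_indices=train_idx,
            test_indices=test_idx,
            meta_test=self.meta.iloc[test_idx],
        )
        return SpectralClassificationResults(model=self, pca=pca, classifier=clf, report=report)


@dataclass
class SpectralClassificationResults:
    """Fitted PCA + discriminant with the held-out evaluation."""

    model: SpectralClassificationModel
    pca: PCScores
    classifier: LinearClassifier
    report: ClassifierReport

    @property
    def accuracy(self) -> float:
        return self.report.accuracy

    @property
    def confusion(self) -> pd.DataFrame:
        return self.report.confusion

    def summary(self) -> str:
        evr = self.pca.explained_variance_ratio
        lines = [
            "Spectral classification results",
            "===============================",
            f"task:                {self.report.task}",
            f"n components:        {self.pca.n_components}",
            "explained variance:  "
            + ", ".join(f"PC{i + 1} {v * 100:.2f}%" for i, v in enumerate(evr)),
            f"cumulative:          {evr.sum() * 100:.2f}%",
            f"split:               {self.report.n_train} train / {self.report.n_test} test"
            f" (seed {self.model.split_config.seed})",
            f"test accuracy:       {self.accuracy * 100:.1f}%",
            "",
            "Confusion (true x predicted):",
            self.confusion.to_string(),
        ]
        if self.classifier.regularized:
            lines.append("note: pooled covariance was degenerate; regularised discriminant")
        if len(self.report.misclassified):
            lines.append("")
            lines.append("Misclassified test rows:")
            lines.append(self.report.misclassified.to_string())
        return "\n".join(lines)


# --------------------------------------------------------------------------
# Shot-averaging ablation
# --------------------------------------------------------------------------

def averaging_ablation(
    shots: SpectrumSet,
    k_values: Sequence[int] = (4, 8),
    task: str = "combined",
    aggregation: AggregationConfig | None = None,
    pca_config: PCAConfig | None = None,
    split_config: SplitConfig | None = None,
) -> dict[int, SpectralClassificationResults]:
    """Re-run preprocess -> PCA -> split -> classify per shot-averaging
    factor k on the same raw shots and the same split-seed policy."""
    base = aggregation or AggregationConfig()
    out: dict[int, SpectralClassificationResults] = {}
    for k in k_values:
        cfg = AggregationConfig(
            shots_per_average=k,
            normalization=base.normalization,
            crop_min=base.crop_min,
            crop_max=base.crop_max,
        )
        model = SpectralClassificationModel.from_shots(
            shots, task=task, aggregation=cfg, pca_config=pca_config, split_config=split_config
        )
        out[k] = model.fit()
    return out
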