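"""Missing-value imputation, abundance filtering and stratified splitting.

Estimators follow scikit-learn conventions and take ``X`` as a
samples-by-features (samples x miRNAs) table; the module-level wrapper
functions accept the domain's genes-by-samples orientation and transpose
internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import ValidationError


class ImputationError(ValueError):
    """Imputation cannot proceed (e.g. a gene with no observed value)."""


class SplitError(ValueError):
    """A stratified split cannot satisfy its invariants."""


class ContractError(ValueError):
    """A stage received input violating its precondition."""


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("expected a 2-D table of samples x features")
    return pd.DataFrame(X)


class KNNGeneImputer(TransformerMixin, BaseEstimator):
    """Impute missing intensities from the k most similar miRNAs.

    A missing cell ``(gene, sample)`` is replaced by the unweighted mean,
    at that sample, of the ``n_neighbors`` genes nearest to the gene.
    Gene-gene distance is the root-mean-square difference over the samples
    where both genes are observed (a Euclidean distance rescaled by the
    number of shared samples, so that genes sharing few samples are not
    spuriously close); genes sharing no sample are infinitely distant.
    Neighbors missing at the target sample are skipped, so each imputed
    value averages exactly ``n_neighbors`` observed values whenever enough
    observed neighbors exist.

    The imputation is computed within the table handed to
    :meth:`transform`; :meth:`fit` only validates.  Observed cells are
    never changed and a complete matrix passes through unchanged.
    """

    def __init__(self, n_neighbors: int = 10):
        self.n_neighbors = n_neighbors

    def fit(self, X, y=None):
        X = _as_frame(X)
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self)
        X = _as_frame(X)
        values = X.to_numpy(dtype=float).T  # genes x samples
        out = _knn_impute_rows(values, self.n_neighbors,
                               row_names=[str(c) for c in X.columns])
        return pd.DataFrame(out.T, index=X.index, columns=X.columns)


def _knn_impute_rows(values: np.ndarray, k: int, row_names: list[str]) -> np.ndarray:
    """Row-neighbor KNN imputation on a rows x columns array with NaNs."""
    n_rows, n_cols = values.shape
    observed = np.isfinite(values)
    empty = ~observed.any(axis=1)
    if empty.any():
        raise ImputationError(
            f"gene(s) with no observed value: {[row_names[i] for i in np.flatnonzero(empty)]}"
        )
    if not (~observed).any():
        return values.copy()
    if k > n_rows - 1:
        raise ImputationError(
            f"n_neighbors={k} exceeds the available neighbor pool of {n_rows - 1} genes"
        )

    filled = np.where(observed, values, 0.0)
    sq = filled ** 2
    obs = observed.astype(float)
    # Pairwise sum of squared differences over shared observed columns.
    shared = obs @ obs.T
    ssq = sq @ obs.T + obs @ sq.T - 2.0 * (filled @ filled.T)
    with np.errstate(divide="ignore", invalid="ignore"):
        dist = np.sqrt(np.maximum(ssq, 0.0) / shared)
    dist[shared == 0] = np.inf
    np.fill_diagonal(dist, np.inf)

    out = values.copy()
    row_means = np.nansum(values, axis=1) / observed.sum(axis=1)
    for g in np.flatnonzero((~observed).any(axis=1)):
        # stable neighbor order: distance, then row index (name order)
        order = np.argsort(dist[g], kind="stable")
        order = order[np.isfinite(dist[g, order])]
        for s in np.flatnonzero(~observed[g]):
            donors = order[observed[order, s]][:k]
            if donors.size:
                out[g, s] = values[donors, s].mean()
            else:
                out[g, s] = row_means[g]
    return out


def knn_impute(matrix: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """KNN-impute a genes-by-samples expression matrix (gene neighbors)."""
    imputer = KNNGeneImputer(n_neighbors=k)
    return imputer.fit_transform(matrix.T).T


class AbundanceFilter(TransformerMixin, BaseEstimator):
    """Keep miRNAs whose log2 intensity exceeds a threshold often enough.

    A feature is retained when its value is strictly greater than
    ``threshold`` in at least ``min_fraction`` of the samples seen at
    :meth:`fit` (the boundary fraction counts as passing).  The input must
    be fully imputed.
    """

    def __init__(self, threshold: float = 8.0, min_fraction: float = 0.5):
        self.threshold = threshold
        self.min_fraction = min_fraction

    def fit(self, X, y=None):
        X = _as_frame(X)
        values = X.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ContractError("abundance filter requires a fully imputed matrix")
        if not 0.0 < self.min_fraction <= 1.0:
            raise ValueError("min_fraction must lie in (0, 1]")
        frac = (values > self.threshold).mean(axis=0)
        self.support_ = frac >= self.min_fraction
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.selected_features_ = list(np.asarray(X.columns)[self.support_])
        return self

    def get_support(self) -> np.ndarray:
        check_is_fitted(self)
        return self.support_.copy()

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self)
        X = _as_frame(X)
        missing = [f for f in self.selected_features_ if f not in X.columns]
        if missing:
            raise KeyError(f"features absent from input: {missing}")
        return X[self.selected_features_]


def filter_abundant(matrix: pd.DataFrame, threshold: float = 8.0,
                    min_fraction: float = 0.5) -> pd.DataFrame:
    """Filter a genes-by-samples matrix to the abundant miRNAs."""
    filt = AbundanceFilter(threshold=threshold, min_fraction=min_fraction)
    return filt.fit_transform(matrix.T).T


@dataclass(frozen=True)
class SplitAssignment:
    """A stratified train/test partition of labeled samples."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    train_fraction: float
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise SplitError(f"train/test overlap: {sorted(overlap)[:5]}")


def stratified_split(labels: pd.Series, train_fraction: float = 0.75,
                     seed: int = 0) -> SplitAssignment:
    """Randomly split samples into train/test, stratified by class.

    Within each class, ``round(n_class * train_fraction)`` samples
    (round-half-up) go to training; a 3:1 split of a 402/275 cohort gives
    302 + 206 = 508 training and 169 test samples.  Deterministic under a
    fixed seed and independent of the input row order.
    """
    if not 0.0 < train_fraction < 1.0:
        raise SplitError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for cls in sorted(labels.unique()):
        ids = sorted(labels.index[labels == cls])
        n = len(ids)
        if n < 2:
            raise SplitError(f"class {cls!r} has fewer than 2 samples")
        n_train = math.floor(n * train_fraction + 0.5)
        if n_train < 1 or n_train >= n:
            raise SplitError(
                f"train_fraction={train_fraction} leaves an empty partition for class {cls!r}"
            )
        perm = rng.permutation(n)
        chosen = set(perm[:n_train])
        train.extend(ids[i] for i in range(n) if i in chosen)
        test.extend(ids[i] for i in range(n) if i not in chosen)
    order = {s: i for i, s in enumerate(labels.index)}
    train.sort(key=order.__getitem__)
    test.sort(key=order.__getitem__)
    return SplitAssignment(tuple(train), tuple(test), train_fraction, seed)
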