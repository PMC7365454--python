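"""Feature screening and rank-comparison gene-pair construction.

The central feature here is the *relative expression ordering* indicator:
for a pair (G1, G2) and a sample, the feature is 1 when the expression of
G1 is strictly smaller than that of G2 in that sample, else 0 (ties count
as 0).  Because each indicator only compares two measurements taken on
the same sample, it is invariant to any strictly increasing per-sample
intensity transform — the property that makes pair panels portable
across array platforms and batches.

Screening follows a two-stage design: miRNAs are screened by a
two-sample t-test (keep ``p < alpha``, rank by effect, cap at ``top_n``),
all pairwise indicators of the survivors are built, near-constant pairs
are dropped, and the remaining pairs are screened by the same t-test
applied to the binary indicators.

Estimator classes use scikit-learn orientation (samples x features);
the module-level functions accept the domain's genes-by-samples /
pairs-by-samples orientation.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import GenePair, HEALTHY, SARCOMA, PUBLISHED_PANEL
from .preprocess import ContractError


def two_sample_ttest(X, y, positive: str = SARCOMA, equal_var: bool = False) -> pd.DataFrame:
    """Per-feature two-sample t-test between the two label groups.

    Parameters
    ----------
    X:
        Samples x features table (expression or binary pair indicators).
    y:
        Per-sample labels aligned with the rows of ``X``.
    positive:
        Group whose mean enters the effect with positive sign.
    equal_var:
        ``False`` (default) uses the Welch unequal-variance statistic;
        ``True`` uses the pooled-variance form.

    Returns
    -------
    DataFrame indexed by feature with columns ``t``, ``p``, ``effect``
    (absolute difference of group means — for binary pair indicators this
    is the difference in indicator frequency), ``mean_diff`` (signed) and
    ``degenerate`` (both groups constant at the same value; such features
    get ``t = 0``, ``p = 1``, ``effect = 0``).
    """
    X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    y = np.asarray(y)
    values = X.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ContractError("t-test screening requires a complete matrix")
    groups = np.unique(y)
    if len(groups) != 2:
        raise ValueError(f"expected exactly two label groups, got {list(groups)}")
    pos_mask = y == positive if positive in groups else y == groups[1]
    a = values[pos_mask]
    b = values[~pos_mask]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 samples per group for a t-test")

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    p = np.atleast_1d(np.asarray(p, dtype=float))
    mean_diff = a.mean(axis=0) - b.mean(axis=0)

    var_a = a.var(axis=0, ddof=1)
    var_b = b.var(axis=0, ddof=1)
    both_const = (var_a == 0) & (var_b == 0)
    degenerate = both_const & (mean_diff == 0)
    separated = both_const & (mean_diff != 0)
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    # both groups constant at different values: perfectly separated feature
    t[separated] = np.sign(mean_diff[separated]) * np.inf
    p[separated] = 0.0

    return pd.DataFrame(
        {
            "t": t,
            "p": p,
            "effect": np.where(degenerate, 0.0, np.abs(mean_diff)),
            "mean_diff": mean_diff,
            "degenerate": degenerate,
        },
        index=X.columns,
    )


def rank_select(stats_table: pd.DataFrame, alpha: float = 0.05,
                top_n: int | None = None, by: str = "effect") -> list:
    """Top features by effect among those significant at ``alpha``.

    Ranking is by descending ``|effect|`` (or ``|t|`` with ``by='t'``),
    ties broken by ascending p-value then feature identifier; with fewer
    than ``top_n`` significant features, all of them are returned.
    """
    if by not in ("effect", "t"):
        raise ValueError("by must be 'effect' or 't'")
    sig = stats_table[stats_table["p"] < alpha]
    key = sig[by].abs()
    # mergesort is stable; pre-sort by identifier so exact ties resolve
    # to the lexicographically smaller feature id
    order = (
        sig.assign(_key=key)
        .sort_index()
        .sort_values(by=["_key", "p"], ascending=[False, True], kind="mergesort")
    )
    selected = list(order.index)
    if top_n is not None:
        selected = selected[:top_n]
    return selected


class TTestSelector(TransformerMixin, BaseEstimator):
    """Select features by two-sample t-test significance and effect rank.

    Used twice in the pipeline: on log2 miRNA intensities (``top_n=250``)
    and on binary pair indicators (``top_n=80``).
    """

    def __init__(self, alpha: float = 0.05, top_n: int | None = 250,
                 positive: str = SARCOMA, rank_by: str = "effect",
                 equal_var: bool = False):
        self.alpha = alpha
        self.top_n = top_n
        self.positive = positive
        self.rank_by = rank_by
        self.equal_var = equal_var

    def fit(self, X, y):
        X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        self.stats_ = two_sample_ttest(X, y, positive=self.positive,
                                       equal_var=self.equal_var)
        self.selected_features_ = rank_select(self.stats_, alpha=self.alpha,
                                              top_n=self.top_n, by=self.rank_by)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self)
        X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        missing = [f for f in self.selected_features_ if f not in X.columns]
        if missing:
            raise KeyError(f"features absent from input: {missing[:5]}")
        return X[self.selected_features_]


def gene_ttest(matrix: pd.DataFrame, labels: pd.Series, **kwargs) -> pd.DataFrame:
    """t-test screen on a genes-by-samples matrix (wrapper, domain orientation)."""
    return two_sample_ttest(matrix.T, labels.loc[matrix.columns], **kwargs)


def select_candidate_genes(stats_table: pd.DataFrame, alpha: float = 0.05,
                           top_n: int = 250) -> list[str]:
    """The candidate miRNA list: significant genes, top ``top_n`` by effect."""
    return rank_select(stats_table, alpha=alpha, top_n=top_n)


class PairFeaturizer(TransformerMixin, BaseEstimator):
    """Binarize all gene pairs of a candidate set by within-sample order.

    For ``k`` candidate genes the transform emits ``k * (k - 1) / 2``
    features, one per unordered combination, oriented with G1 the
    lexicographically smaller identifier and named ``"G1|G2"``.  The
    indicator is 1 iff expression(G1) < expression(G2) in the sample.

    ``genes=None`` uses every column of the table seen at fit time.
    """

    def __init__(self, genes: Sequence[str] | None = None):
        self.genes = genes

    def fit(self, X, y=None):
        X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        gene_list = list(X.columns) if self.genes is None else list(self.genes)
        missing = [g for g in gene_list if g not in X.columns]
        if missing:
            raise KeyError(f"unknown gene id(s): {missing[:5]}")
        if len(gene_list) < 2:
            raise ValueError("need at least 2 genes to form pairs")
        if len(set(gene_list)) != len(gene_list):
            raise ValueError("candidate gene list contains duplicates")
        ordered = sorted(map(str, gene_list))
        self.pairs_ = [GenePair(g1, g2) for g1, g2 in combinations(ordered, 2)]
        self.feature_names_out_ = [p.feature_id for p in self.pairs_]
        self.gene_list_ = ordered
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self)
        X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        missing = [g for g in self.gene_list_ if g not in X.columns]
        if missing:
            raise KeyError(f"unknown gene id(s): {missing[:5]}")
        values = X[self.gene_list_].to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ContractError("pair features require a complete matrix")
        idx1, idx2 = np.triu_indices(len(self.gene_list_), k=1)
        indicators = (values[:, idx1] < values[:, idx2]).astype(np.int8)
        return pd.DataFrame(indicators, index=X.index, columns=self.feature_names_out_)


def build_pair_matrix(matrix: pd.DataFrame, genes: Sequence[str]) -> pd.DataFrame:
    """Pairs-by-samples indicator matrix for a candidate gene list."""
    feat = PairFeaturizer(genes=genes)
    return feat.fit_transform(matrix.T).T


def pair_indicators(matrix: pd.DataFrame, pairs: Iterable[GenePair]) -> pd.DataFrame:
    """Indicator matrix (pairs x samples) for explicit, already-oriented pairs."""
    pairs = list(pairs)
    needed = sorted({g for p in pairs for g in (p.gene1, p.gene2)})
    absent = [g for g in needed if g not in matrix.index]
    if absent:
        raise KeyError(f"miRNA(s) absent from expression matrix: {absent}")
    values = matrix.to_numpy(dtype=float)
    if np.isnan(values[[matrix.index.get_loc(g) for g in needed]]).any():
        raise ContractError("pair features require complete values for panel miRNAs")
    rows = []
    for p in pairs:
        g1 = matrix.loc[p.gene1].to_numpy(dtype=float)
        g2 = matrix.loc[p.gene2].to_numpy(dtype=float)
        rows.append((g1 < g2).astype(np.int8))
    return pd.DataFrame(rows, index=[p.feature_id for p in pairs], columns=matrix.columns)


def compute_published_features(matrix: pd.DataFrame,
                               panel: Sequence[GenePair] = PUBLISHED_PANEL) -> pd.DataFrame:
    """Six-row indicator matrix of the published panel, printed orientation."""
    return pair_indicators(matrix, panel)


class NearConstantPairFilter(TransformerMixin, BaseEstimator):
    """Drop pair indicators that are almost constant on the training set.

    A pair is removed when its majority value (0 or 1) occurs in strictly
    more than ``max_fraction`` of the samples seen at fit time (exactly
    the boundary fraction is retained).  Such pairs carry almost no
    contrast and would only inflate the candidate universe.
    """

    def __init__(self, max_fraction: float = 0.90):
        self.max_fraction = max_fraction

    def fit(self, X, y=None):
        X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        if X.shape[0] == 0:
            raise ValueError("cannot fit the near-constant filter on an empty sample set")
        values = X.to_numpy(dtype=float)
        ones = (values == 1).mean(axis=0)
        majority = np.maximum(ones, 1.0 - ones)
        self.majority_fraction_ = pd.Series(majority, index=X.columns)
        self.support_ = majority <= self.max_fraction
        self.selected_features_ = list(np.asarray(X.columns)[self.support_])
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self)
        X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        missing = [f for f in self.selected_features_ if f not in X.columns]
        if missing:
            raise KeyError(f"features absent from input: {missing[:5]}")
        return X[self.selected_features_]


def filter_near_constant(pair_matrix: pd.DataFrame, training_ids: Iterable[str],
                         max_fraction: float = 0.90) -> pd.DataFrame:
    """Apply the near-constant filter (fit on training samples, keep all columns)."""
    training_ids = list(training_ids)
    if not training_ids:
        raise ValueError("training sample set is empty")
    filt = NearConstantPairFilter(max_fraction=max_fraction)
    filt.fit(pair_matrix[training_ids].T)
    return pair_matrix.loc[filt.selected_features_]


def select_candidate_pairs(pair_matrix: pd.DataFrame, labels: pd.Series,
                           training_ids: Iterable[str], alpha: float = 0.05,
                           top_n: int = 80, **kwargs) -> pd.DataFrame:
    """Screen pair indicators on the training samples; keep top ``top_n``.

    The t-test runs on the binary indicators over training samples only;
    the returned matrix keeps every sample column but only the selected
    pair rows.
    """
    training_ids = list(training_ids)
    sel = TTestSelector(alpha=alpha, top_n=top_n, **kwargs)
    sel.fit(pair_matrix[training_ids].T, labels.loc[training_ids].to_numpy())
    return pair_matrix.loc[sel.selected_features_]
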