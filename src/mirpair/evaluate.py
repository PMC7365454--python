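"""Confusion-matrix metrics and the end-to-end pipeline driver.

The five reported metrics, for a designated positive class:

* accuracy    = (TP + TN) / (TP + TN + FP + FN)
* sensitivity = TP / (TP + FN)
* specificity = TN / (TN + FP)
* PPV         = TP / (TP + FP)
* NPV         = TN / (TN + FN)

A zero denominator marks the metric *undefined* rather than raising.
Swapping the positive class swaps sensitivity with specificity and PPV
with NPV exactly.  The pipeline driver wires the full analysis: impute →
abundance filter → stratified split → miRNA screen → pair construction →
pair filters → RGLM fit → thinning → evaluation, with external cohorts
scored using only training-derived gene and pair lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .io import HEALTHY, SARCOMA, validate_labels
from .preprocess import SplitAssignment, knn_impute, filter_abundant, stratified_split
from .features import (
    gene_ttest, select_candidate_genes, build_pair_matrix,
    filter_near_constant, select_candidate_pairs, pair_indicators, rank_select,
)
from .io import GenePair
from .rglm import RGLMClassifier, fit_rglm, predict_rglm, thin_rglm

logger = logging.getLogger("mirpair")


class EvaluationError(ValueError):
    """Predictions and truth labels are inconsistent."""


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts for a designated positive class."""

    tp: int
    fp: int
    tn: int
    fn: int
    positive_class: str = SARCOMA

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def swapped(self) -> "ConfusionCounts":
        """The same predictions tabulated with the other class positive."""
        other = HEALTHY if self.positive_class == SARCOMA else SARCOMA
        return ConfusionCounts(tp=self.tn, fp=self.fn, tn=self.tp, fn=self.fp,
                               positive_class=other)


@dataclass(frozen=True)
class MetricsReport:
    """The five performance metrics; ``None`` marks an undefined metric."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    counts: ConfusionCounts
    undefined: tuple[str, ...] = field(default_factory=tuple)

    def as_percentages(self, decimals: int = 1) -> dict[str, str | None]:
        """Metrics as percentage strings, round-half-up to ``decimals``."""
        quantum = Decimal(1).scaleb(-decimals)
        out: dict[str, str | None] = {}
        for name in ("accuracy", "specificity", "sensitivity", "ppv", "npv"):
            value = getattr(self, name)
            if value is None:
                out[name] = None
            else:
                pct = (Decimal(repr(value)) * 100).quantize(quantum, rounding=ROUND_HALF_UP)
                out[name] = f"{pct}%"
        return out

    def to_dict(self) -> dict:
        return {
            "positive_class": self.counts.positive_class,
            "counts": {"TP": self.counts.tp, "FP": self.counts.fp,
                       "TN": self.counts.tn, "FN": self.counts.fn},
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "undefined": list(self.undefined),
        }


def confusion(predicted: pd.Series, truth: pd.Series,
              positive_class: str = SARCOMA) -> ConfusionCounts:
    """Cross-tabulate predictions against truth labels.

    ``predicted`` and ``truth`` must cover identical sample sets (in any
    order); a mismatch raises with the symmetric difference.
    """
    predicted = pd.Series(predicted)
    truth = pd.Series(truth)
    diff = set(predicted.index) ^ set(truth.index)
    if diff:
        raise EvaluationError(f"sample sets differ: {sorted(diff)[:10]}")
    aligned = predicted.loc[truth.index]
    y_true = (truth == positive_class).astype(int).to_numpy()
    y_pred = (aligned == positive_class).astype(int).to_numpy()
    tn, fp, fn, tp = _sk_confusion(y_true, y_pred, labels=[0, 1]).ravel()
    return ConfusionCounts(tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn),
                           positive_class=positive_class)


def _safe_ratio(num: int, den: int):
    return None if den == 0 else num / den


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Compute the five metrics from confusion counts."""
    if counts.total == 0:
        raise EvaluationError("cannot compute metrics on zero samples")
    values = {
        "accuracy": _safe_ratio(counts.tp + counts.tn, counts.total),
        "sensitivity": _safe_ratio(counts.tp, counts.tp + counts.fn),
        "specificity": _safe_ratio(counts.tn, counts.tn + counts.fp),
        "ppv": _safe_ratio(counts.tp, counts.tp + counts.fp),
        "npv": _safe_ratio(counts.tn, counts.tn + counts.fn),
    }
    undefined = tuple(sorted(k for k, v in values.items() if v is None))
    return MetricsReport(counts=counts, undefined=undefined, **values)


def evaluate_predictions(predicted: pd.Series, truth: pd.Series,
                         positive_class: str = SARCOMA) -> MetricsReport:
    """Convenience: confusion + metrics in one call."""
    return metrics(confusion(predicted, truth, positive_class=positive_class))


# ------------------------------------------------------------------ pipeline

@dataclass
class PipelineResult:
    """Everything the end-to-end run produces."""

    model: RGLMClassifier
    thinned: RGLMClassifier | None
    split: SplitAssignment
    candidate_genes: list[str]
    candidate_pairs: list[str]
    metrics: dict[str, MetricsReport]
    predictions: dict[str, pd.DataFrame]
    stage_log: list[dict]

    @property
    def final_model(self) -> RGLMClassifier:
        return self.thinned if self.thinned is not None else self.model

    def final_pairs(self) -> list[GenePair]:
        """Pairs actually used by the final (thinned) ensemble."""
        occ = self.final_model.occurrence_
        return [GenePair.from_feature_id(f) for f in sorted(occ) if occ[f] > 0]


def _log_stage(log: list[dict], stage: str, **info) -> None:
    entry = {"stage": stage, **info}
    log.append(entry)
    logger.info("%s: %s", stage, info)


def run_pipeline(
    expression: pd.DataFrame,
    labels: pd.Series,
    *,
    seed: int = 0,
    k_neighbors: int = 10,
    abundance_threshold: float = 8.0,
    abundance_min_fraction: float = 0.5,
    train_fraction: float = 0.75,
    gene_alpha: float = 0.05,
    gene_top_n: int = 250,
    max_constant_fraction: float = 0.90,
    pair_alpha: float = 0.05,
    pair_top_n: int = 80,
    thin: bool = True,
    thin_tolerance: float | None = None,
    positive_class: str = SARCOMA,
    rglm_params: dict | None = None,
    external_expression: pd.DataFrame | None = None,
    external_labels: pd.Series | None = None,
) -> PipelineResult:
    """Run the full serum miRNA-pair classification pipeline.

    Stages: KNN imputation and abundance filtering on the whole cohort,
    stratified 3:1 split, miRNA t-test screen on the training samples,
    pairwise indicator construction, near-constant and t-test pair
    screens (training only), RGLM fit on the training pairs, optional
    thinning, and metric reports on the training and internal-test
    partitions.  An external cohort, when given, is imputed separately
    and scored using only the pairs of the final model.

    All randomness (split, bagging) derives from ``seed``.
    """
    labels = validate_labels(labels)
    if set(labels.index) != set(expression.columns):
        raise EvaluationError("expression columns and label sample ids differ")
    log: list[dict] = []
    _log_stage(log, "input", n_genes=expression.shape[0], n_samples=expression.shape[1],
               n_missing=int(expression.isna().to_numpy().sum()))

    imputed = knn_impute(expression, k=k_neighbors)
    _log_stage(log, "impute", k=k_neighbors,
               n_missing_after=int(imputed.isna().to_numpy().sum()))

    abundant = filter_abundant(imputed, threshold=abundance_threshold,
                               min_fraction=abundance_min_fraction)
    _log_stage(log, "abundance_filter", threshold=abundance_threshold,
               n_genes=abundant.shape[0])

    split = stratified_split(labels, train_fraction=train_fraction, seed=seed)
    train_ids = list(split.train_ids)
    test_ids = list(split.test_ids)
    _log_stage(log, "split", n_train=len(train_ids), n_test=len(test_ids))

    train_stats = gene_ttest(abundant[train_ids], labels.loc[train_ids])
    candidate_genes = select_candidate_genes(train_stats, alpha=gene_alpha,
                                             top_n=gene_top_n)
    if len(candidate_genes) < 2:
        # signal-free cohorts can empty the significance screen; fall back to
        # the best-ranked miRNAs so the run degrades gracefully instead of dying
        candidate_genes = rank_select(train_stats, alpha=np.inf, top_n=gene_top_n)
        _log_stage(log, "gene_screen_fallback", n_candidates=len(candidate_genes))
    _log_stage(log, "gene_screen", alpha=gene_alpha, top_n=gene_top_n,
               n_candidates=len(candidate_genes))

    pair_matrix = build_pair_matrix(abundant, candidate_genes)
    _log_stage(log, "pair_build", n_pairs=pair_matrix.shape[0])

    filtered = filter_near_constant(pair_matrix, train_ids,
                                    max_fraction=max_constant_fraction)
    if filtered.shape[0] == 0:
        _log_stage(log, "near_constant_filter_skipped", reason="would remove every pair")
    else:
        pair_matrix = filtered
    _log_stage(log, "near_constant_filter", max_fraction=max_constant_fraction,
               n_pairs=pair_matrix.shape[0])

    candidates = select_candidate_pairs(pair_matrix, labels, train_ids,
                                        alpha=pair_alpha, top_n=pair_top_n)
    if candidates.shape[0] == 0:
        candidates = select_candidate_pairs(pair_matrix, labels, train_ids,
                                            alpha=np.inf, top_n=pair_top_n)
        _log_stage(log, "pair_screen_fallback", n_pairs=candidates.shape[0])
    if candidates.shape[0] == 0:
        raise EvaluationError("no candidate pairs available")
    _log_stage(log, "pair_screen", alpha=pair_alpha, top_n=pair_top_n,
               n_pairs=candidates.shape[0])

    params = dict(rglm_params or {})
    params.setdefault("random_state", seed)
    params.setdefault("positive_class", positive_class)
    model = fit_rglm(candidates[train_ids], labels.loc[train_ids], **params)
    _log_stage(log, "rglm_fit", n_bags=model.n_bags,
               oob_accuracy=model.oob_accuracy_,
               n_used_features=len(model.occurrence_))

    thinned = None
    if thin:
        thinned = thin_rglm(model, candidates[train_ids], labels.loc[train_ids],
                            tolerance=thin_tolerance)
        _log_stage(log, "thin", cutoff=thinned.occurrence_cutoff_,
                   n_retained=len(thinned.retained_features_ or []),
                   oob_accuracy=thinned.oob_accuracy_)
    final = thinned if thinned is not None else model

    reports: dict[str, MetricsReport] = {}
    predictions: dict[str, pd.DataFrame] = {}
    for name, ids in (("train", train_ids), ("test", test_ids)):
        pred = predict_rglm(final, candidates[ids])
        predictions[name] = pred
        reports[name] = evaluate_predictions(pred["label"], labels.loc[ids],
                                             positive_class=positive_class)
        _log_stage(log, f"evaluate_{name}",
                   **{k: v for k, v in reports[name].to_dict().items()
                      if k in ("accuracy", "sensitivity", "specificity")})

    if external_expression is not None:
        if external_labels is None:
            raise EvaluationError("external expression given without labels")
        external_labels = validate_labels(external_labels)
        ext = knn_impute(external_expression, k=min(
            k_neighbors, max(1, external_expression.shape[0] - 1)))
        final_pairs = [GenePair.from_feature_id(f)
                       for f in sorted(f for f, c in final.occurrence_.items() if c > 0)]
        ext_features = pair_indicators(ext, final_pairs)
        pred = predict_rglm(final, ext_features)
        predictions["external"] = pred
        reports["external"] = evaluate_predictions(
            pred["label"], external_labels, positive_class=positive_class)
        _log_stage(log, "evaluate_external", n_samples=len(external_labels))

    return PipelineResult(
        model=model, thinned=thinned, split=split,
        candidate_genes=candidate_genes,
        candidate_pairs=list(candidates.index),
        metrics=reports, predictions=predictions, stage_log=log,
    )
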