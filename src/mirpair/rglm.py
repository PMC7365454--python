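"""Random Generalized Linear Model (RGLM) ensemble, built from scratch.

The classifier bags forward-selected logistic GLMs:

1. each of ``n_bags`` bags draws a bootstrap sample (size n, with
   replacement) of the training samples and a random subset of the
   candidate features;
2. within a bag, candidates are pre-filtered by a point-biserial
   correlation test against the class label (keep the ``corr_keep``
   smallest p-values below ``corr_alpha``);
3. a forward stepwise binomial GLM is grown from the intercept-only
   model, admitting at each step the term with the best AIC improvement,
   until no term improves the AIC or ``max_terms`` is reached;
4. prediction is by majority vote: each bag votes for the positive class
   when its GLM probability exceeds 0.5, and the ensemble label is
   positive when the vote fraction reaches ``vote_threshold`` (ties go
   to the positive class — a screening context favours sensitivity).

Out-of-bag (OOB) accuracy scores each training sample using only the
bags that did not draw it.  *Thinning* reduces the ensemble to the
features that occur most often across the member GLMs: candidate cutoffs
are the distinct occurrence counts in descending order, the ensemble is
refit restricted to each cutoff's feature set with the same bags, and
the smallest feature set whose OOB accuracy is within ``thin_tolerance``
of the full model's wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

from .io import SARCOMA, ModelFormatError

MODEL_FORMAT_VERSION = 1
_SEPARATION_COEF = 15.0  # |log-odds| beyond which a fit is treated as separated
_PROB_EPS = 1e-9


class FitError(RuntimeError):
    """The ensemble could not be fitted (e.g. every bag failed)."""


@dataclass
class BagModel:
    """One member GLM: its bootstrap draw, feature subset and coefficients."""

    bag_index: int
    in_bag_idx: np.ndarray
    oob_idx: np.ndarray
    candidate_features: list[str]
    selected_features: list[str] = field(default_factory=list)
    intercept: float = 0.0
    coefficients: list[float] = field(default_factory=list)
    separated: bool = False
    error: str | None = None

    @property
    def intercept_only(self) -> bool:
        return not self.selected_features


def _loglik(z: np.ndarray, y: np.ndarray) -> float:
    p = expit(z)
    p = np.clip(p, _PROB_EPS, 1.0 - _PROB_EPS)
    return float(np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def _fit_glm(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, bool] | None:
    """Binomial GLM with intercept; returns (params, llf, separated) or None."""
    design = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, design, family=sm.families.Binomial()).fit(maxiter=100)
        params = np.asarray(res.params, dtype=float)
        if not np.all(np.isfinite(params)):
            return None
        llf = _loglik(design @ params, y)
        separated = bool(np.max(np.abs(params)) > _SEPARATION_COEF)
        return params, llf, separated
    except Exception:
        return None


def _ridge_logistic(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """L2-stabilized logistic refit used when a bag's GLM separates."""
    model = LogisticRegression(C=10.0, solver="lbfgs", max_iter=2000)
    model.fit(X, y)
    return float(model.intercept_[0]), model.coef_[0].astype(float)


def _pointbiserial_pvalues(Xb: np.ndarray, yb: np.ndarray) -> np.ndarray:
    """Two-sided p-values of the per-feature point-biserial correlation."""
    n = len(yb)
    yc = yb - yb.mean()
    sy = np.sqrt((yc ** 2).sum())
    Xc = Xb - Xb.mean(axis=0)
    sx = np.sqrt((Xc ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc * yc[:, None]).sum(axis=0) / (sx * sy)
    p = np.full(Xb.shape[1], np.nan)
    valid = np.isfinite(r) & (sx > 0) & (sy > 0) & (n > 2)
    r_valid = np.clip(r[valid], -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r_valid * np.sqrt((n - 2) / np.maximum(1.0 - r_valid ** 2, 1e-300))
    p[valid] = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return p


class RGLMClassifier(ClassifierMixin, BaseEstimator):
    """Bagged forward-selected logistic GLM ensemble with thinning.

    Parameters
    ----------
    n_bags:
        Number of member GLMs (default 100).
    features_per_bag:
        Fraction of candidate features drawn, without replacement, into
        each bag.
    corr_keep:
        Maximum number of features surviving a bag's correlation
        pre-filter.
    corr_alpha:
        Significance level of the point-biserial correlation pre-filter.
    max_terms:
        Maximum number of covariates the forward stepwise search may
        admit per bag.
    vote_threshold:
        Vote fraction at or above which the ensemble predicts the
        positive class.
    thin_tolerance:
        Default OOB-accuracy tolerance used by :meth:`thin` (1 OOB
        misclassification per 100 training samples).
    bootstrap:
        ``False`` disables observation resampling (every bag sees every
        training sample); a hook for oracle comparisons against a single
        plain stepwise GLM.
    positive_class:
        Label treated as the positive (log-odds > 0) class when present;
        defaults to ``"sarcoma"``.
    random_state:
        Seed of the per-bag randomness stream.

    Attributes (after fit)
    ----------------------
    classes_, positive_class_, feature_names_in_, bags_,
    occurrence_ (feature -> number of final GLMs including it),
    oob_accuracy_, and for thinned models retained_features_ and
    occurrence_cutoff_.
    """

    def __init__(self, n_bags: int = 100, features_per_bag: float = 0.3,
                 corr_keep: int = 20, corr_alpha: float = 0.05,
                 max_terms: int = 10, vote_threshold: float = 0.5,
                 thin_tolerance: float = 0.01, bootstrap: bool = True,
                 positive_class: str = SARCOMA, random_state: int = 0):
        self.n_bags = n_bags
        self.features_per_bag = features_per_bag
        self.corr_keep = corr_keep
        self.corr_alpha = corr_alpha
        self.max_terms = max_terms
        self.vote_threshold = vote_threshold
        self.thin_tolerance = thin_tolerance
        self.bootstrap = bootstrap
        self.positive_class = positive_class
        self.random_state = random_state

    # ------------------------------------------------------------------ fit

    def fit(self, X, y):
        X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        values = X.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValueError("feature matrix contains missing values")
        y = np.asarray(y)
        if len(y) != len(X):
            raise ValueError("X and y have different lengths")
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(f"RGLM is a binary classifier; got classes {list(classes)}")
        counts = {c: int((y == c).sum()) for c in classes}
        if min(counts.values()) < 2:
            raise ValueError(f"need >= 2 samples per class, got {counts}")
        if not (self.n_bags >= 1 and 0 < self.features_per_bag <= 1
                and self.corr_keep >= 1 and self.max_terms >= 1):
            raise ValueError("invalid ensemble configuration")

        self.classes_ = classes
        self.positive_class_ = (self.positive_class if self.positive_class in classes
                                else classes[-1])
        y01 = (y == self.positive_class_).astype(float)
        feature_names = [str(c) for c in X.columns]
        self.feature_names_in_ = np.asarray(feature_names, dtype=object)
        self.n_features_in_ = len(feature_names)

        specs = self._draw_bag_specs(len(y01), feature_names)
        self.bags_ = self._fit_bags(values, y01, feature_names, specs)
        if all(b.error is not None for b in self.bags_):
            raise FitError("every bag failed to fit")
        self.occurrence_ = self._count_occurrence(self.bags_)
        self.oob_accuracy_ = self._oob_accuracy(self.bags_, values, y01, feature_names)
        self.retained_features_ = None
        self.occurrence_cutoff_ = None
        self._train_values = values
        self._train_y01 = y01
        return self

    def _draw_bag_specs(self, n: int, feature_names: list[str]):
        p = len(feature_names)
        m = max(1, int(round(self.features_per_bag * p)))
        specs = []
        for i, child in enumerate(np.random.SeedSequence(self.random_state).spawn(self.n_bags)):
            rng = np.random.default_rng(child)
            if self.bootstrap:
                in_bag = np.sort(rng.integers(0, n, size=n))
            else:
                in_bag = np.arange(n)
            oob = np.setdiff1d(np.arange(n), in_bag)
            cand = sorted(feature_names[j] for j in rng.choice(p, size=m, replace=False))
            specs.append((i, in_bag, oob, cand))
        return specs

    def _fit_bags(self, values, y01, feature_names, specs,
                  restrict: set[str] | None = None) -> list[BagModel]:
        col = {f: j for j, f in enumerate(feature_names)}
        bags = []
        for i, in_bag, oob, cand in specs:
            cand_used = cand if restrict is None else [f for f in cand if f in restrict]
            bag = BagModel(bag_index=i, in_bag_idx=in_bag, oob_idx=oob,
                           candidate_features=list(cand_used))
            try:
                self._fit_one_bag(bag, values, y01, col)
            except Exception as exc:  # pragma: no cover - defensive
                bag.error = f"{type(exc).__name__}: {exc}"
            bags.append(bag)
        return bags

    def _fit_one_bag(self, bag: BagModel, values, y01, col) -> None:
        yb = y01[bag.in_bag_idx]
        if yb.min() == yb.max() or not bag.candidate_features:
            self._finish_intercept_only(bag, yb)
            return
        cols = [col[f] for f in bag.candidate_features]
        Xb = values[np.ix_(bag.in_bag_idx, cols)]

        pvals = _pointbiserial_pvalues(Xb, yb)
        order = sorted(
            (j for j in range(len(cols)) if np.isfinite(pvals[j]) and pvals[j] < self.corr_alpha),
            key=lambda j: (pvals[j], bag.candidate_features[j]),
        )[: self.corr_keep]
        if not order:
            self._finish_intercept_only(bag, yb)
            return
        kept = [bag.candidate_features[j] for j in order]
        kept_cols = {f: Xb[:, bag.candidate_features.index(f)] for f in kept}

        selected, params, separated = self._forward_stepwise(kept, kept_cols, yb)
        if not selected:
            self._finish_intercept_only(bag, yb)
            return
        if separated:
            Xs = np.column_stack([kept_cols[f] for f in selected])
            intercept, coefs = _ridge_logistic(Xs, yb)
            bag.separated = True
        else:
            intercept, coefs = float(params[0]), np.asarray(params[1:], dtype=float)
        bag.selected_features = selected
        bag.intercept = intercept
        bag.coefficients = [float(c) for c in coefs]

    @staticmethod
    def _finish_intercept_only(bag: BagModel, yb: np.ndarray) -> None:
        p = float(np.clip(yb.mean(), _PROB_EPS, 1.0 - _PROB_EPS))
        bag.intercept = float(np.log(p / (1.0 - p)))
        bag.selected_features = []
        bag.coefficients = []

    def _forward_stepwise(self, candidates, col_data, yb):
        """Forward AIC selection; returns (selected, params, separated)."""
        base = _fit_glm(np.empty((len(yb), 0)), yb)
        if base is None:  # pragma: no cover - intercept fit cannot fail
            return [], None, False
        current_aic = 2.0 * 1 - 2.0 * base[1]
        selected: list[str] = []
        params, separated = base[0], False
        while len(selected) < self.max_terms:
            best = None
            for f in candidates:
                if f in selected:
                    continue
                trial = selected + [f]
                fit = _fit_glm(np.column_stack([col_data[g] for g in trial]), yb)
                if fit is None:
                    continue
                aic = 2.0 * (len(trial) + 1) - 2.0 * fit[1]
                if best is None or aic < best[0] - 1e-12:
                    best = (aic, f, fit)
            if best is None or best[0] >= current_aic - 1e-12:
                break
            current_aic = best[0]
            selected.append(best[1])
            params, _, separated = best[2]
        return selected, params, separated

    @staticmethod
    def _count_occurrence(bags: list[BagModel]) -> dict[str, int]:
        occurrence: dict[str, int] = {}
        for bag in bags:
            if bag.error is not None:
                continue
            for f in bag.selected_features:
                occurrence[f] = occurrence.get(f, 0) + 1
        return occurrence

    # -------------------------------------------------------------- predict

    def _bag_probabilities(self, bag: BagModel, X: pd.DataFrame) -> np.ndarray:
        z = np.full(len(X), bag.intercept, dtype=float)
        for f, c in zip(bag.selected_features, bag.coefficients):
            z += c * X[f].to_numpy(dtype=float)
        return expit(z)

    def _check_features(self, X: pd.DataFrame) -> None:
        referenced = sorted({f for b in self.bags_ if b.error is None
                             for f in b.selected_features})
        absent = [f for f in referenced if f not in X.columns]
        if absent:
            raise KeyError(f"feature(s) required by the model are absent: {absent}")

    def vote_fraction(self, X) -> pd.Series:
        """Fraction of voting bags predicting the positive class, per sample."""
        check_is_fitted(self, "bags_")
        X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        self._check_features(X)
        voting = [b for b in self.bags_ if b.error is None]
        if not voting:
            raise FitError("no voting bags available")
        votes = np.zeros(len(X))
        for bag in voting:
            votes += self._bag_probabilities(bag, X) > 0.5
        return pd.Series(votes / len(voting), index=X.index, name="vote_fraction")

    def predict_proba(self, X) -> np.ndarray:
        frac = self.vote_fraction(X).to_numpy()
        proba = np.empty((len(frac), 2))
        pos_idx = int(np.argmax(self.classes_ == self.positive_class_))
        proba[:, pos_idx] = frac
        proba[:, 1 - pos_idx] = 1.0 - frac
        return proba

    def predict(self, X) -> np.ndarray:
        frac = self.vote_fraction(X).to_numpy()
        negative = self.classes_[self.classes_ != self.positive_class_][0]
        return np.where(frac >= self.vote_threshold, self.positive_class_, negative)

    # ----------------------------------------------------------------- thin

    def thin(self, X=None, y=None, tolerance: float | None = None) -> "RGLMClassifier":
        """Refit restricted to the most frequently occurring features.

        Candidate cutoffs are the distinct occurrence counts in
        descending order; for each cutoff the ensemble is refit (same
        bags, same bootstrap draws) on the features occurring at least
        that often, and the smallest feature set whose OOB accuracy is
        within ``tolerance`` of the full model's is returned.  With no
        cutoff within tolerance the lowest cutoff (all used features)
        is returned.
        """
        check_is_fitted(self, "bags_")
        if X is None:
            values, y01 = self._train_values, self._train_y01
        else:
            X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
            values = X[list(self.feature_names_in_)].to_numpy(dtype=float)
            y01 = (np.asarray(y) == self.positive_class_).astype(float)
        tol = self.thin_tolerance if tolerance is None else tolerance

        cutoffs = sorted(set(self.occurrence_.values()), reverse=True)
        if not cutoffs:
            return self
        last = None
        for cutoff in cutoffs:
            retained = sorted(f for f, c in self.occurrence_.items() if c >= cutoff)
            last = self._refit_restricted(values, y01, retained, cutoff)
            if last.oob_accuracy_ >= self.oob_accuracy_ - tol:
                return last
        return last

    def _refit_restricted(self, values, y01, retained: list[str], cutoff: int):
        thinned: RGLMClassifier = clone(self)
        thinned.classes_ = self.classes_.copy()
        thinned.positive_class_ = self.positive_class_
        thinned.feature_names_in_ = self.feature_names_in_.copy()
        thinned.n_features_in_ = self.n_features_in_
        feature_names = [str(f) for f in self.feature_names_in_]
        specs = [(b.bag_index, b.in_bag_idx, b.oob_idx, b.candidate_features)
                 for b in self.bags_]
        thinned.bags_ = thinned._fit_bags(values, y01, feature_names, specs,
                                          restrict=set(retained))
        thinned.occurrence_ = thinned._count_occurrence(thinned.bags_)
        thinned.oob_accuracy_ = thinned._oob_accuracy(
            thinned.bags_, values, y01, feature_names)
        thinned.retained_features_ = list(retained)
        thinned.occurrence_cutoff_ = cutoff
        thinned._train_values = values
        thinned._train_y01 = y01
        return thinned

    # ------------------------------------------------------------------ oob

    def _oob_accuracy(self, bags, values, y01, feature_names) -> float:
        frame = pd.DataFrame(values, columns=feature_names)
        pos_votes = np.zeros(len(y01))
        n_votes = np.zeros(len(y01))
        for bag in bags:
            if bag.error is not None or len(bag.oob_idx) == 0:
                continue
            probs = self._bag_probabilities(bag, frame.iloc[bag.oob_idx])
            pos_votes[bag.oob_idx] += probs > 0.5
            n_votes[bag.oob_idx] += 1
        covered = n_votes > 0
        if not covered.any():
            return float("nan")
        frac = pos_votes[covered] / n_votes[covered]
        pred = frac >= self.vote_threshold
        return float((pred == (y01[covered] == 1.0)).mean())

    # -------------------------------------------------------- serialization

    def to_dict(self) -> dict:
        check_is_fitted(self, "bags_")
        return {
            "format": "mirpair-rglm",
            "version": MODEL_FORMAT_VERSION,
            "params": self.get_params(),
            "classes": [str(c) for c in self.classes_],
            "positive_class": str(self.positive_class_),
            "feature_names": [str(f) for f in self.feature_names_in_],
            "oob_accuracy": self.oob_accuracy_,
            "occurrence": dict(self.occurrence_),
            "retained_features": self.retained_features_,
            "occurrence_cutoff": self.occurrence_cutoff_,
            "bags": [
                {
                    "bag_index": b.bag_index,
                    "in_bag_idx": [int(i) for i in b.in_bag_idx],
                    "oob_idx": [int(i) for i in b.oob_idx],
                    "candidate_features": list(b.candidate_features),
                    "selected_features": list(b.selected_features),
                    "intercept": b.intercept,
                    "coefficients": list(b.coefficients),
                    "separated": b.separated,
                    "error": b.error,
                }
                for b in self.bags_
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "RGLMClassifier":
        if payload.get("format") != "mirpair-rglm":
            raise ModelFormatError("not an RGLM model document")
        if payload.get("version") != MODEL_FORMAT_VERSION:
            raise ModelFormatError(
                f"unsupported model format version {payload.get('version')!r}")
        try:
            model = cls(**payload["params"])
            model.classes_ = np.asarray(payload["classes"], dtype=object)
            model.positive_class_ = payload["positive_class"]
            model.feature_names_in_ = np.asarray(payload["feature_names"], dtype=object)
            model.n_features_in_ = len(model.feature_names_in_)
            model.oob_accuracy_ = payload["oob_accuracy"]
            model.occurrence_ = {str(k): int(v) for k, v in payload["occurrence"].items()}
            model.retained_features_ = payload.get("retained_features")
            model.occurrence_cutoff_ = payload.get("occurrence_cutoff")
            model.bags_ = [
                BagModel(
                    bag_index=int(b["bag_index"]),
                    in_bag_idx=np.asarray(b["in_bag_idx"], dtype=int),
                    oob_idx=np.asarray(b["oob_idx"], dtype=int),
                    candidate_features=list(b["candidate_features"]),
                    selected_features=list(b["selected_features"]),
                    intercept=float(b["intercept"]),
                    coefficients=[float(c) for c in b["coefficients"]],
                    separated=bool(b["separated"]),
                    error=b["error"],
                )
                for b in payload["bags"]
            ]
        except (KeyError, TypeError, ValueError) as exc:
            raise ModelFormatError(f"corrupt model document: {exc}") from exc
        return model


# ------------------------------------------------------- functional wrappers

def fit_rglm(pair_matrix: pd.DataFrame, labels: pd.Series, **params) -> RGLMClassifier:
    """Fit an RGLM on a pairs-by-samples indicator matrix (domain orientation)."""
    model = RGLMClassifier(**params)
    X = pair_matrix.T
    return model.fit(X, labels.loc[X.index].to_numpy())


def predict_rglm(model: RGLMClassifier, pair_matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-sample vote fractions and labels for a pairs-by-samples matrix."""
    X = pair_matrix.T
    frac = model.vote_fraction(X)
    labels = model.predict(X)
    return pd.DataFrame(
        {"vote_fraction": frac.to_numpy(), "label": labels},
        index=pd.Index(X.index, name="sample_id"),
    )


def thin_rglm(model: RGLMClassifier, pair_matrix: pd.DataFrame, labels: pd.Series,
              tolerance: float | None = None) -> RGLMClassifier:
    """Thin a fitted RGLM using the given training data."""
    X = pair_matrix.T
    return model.thin(X, labels.loc[X.index].to_numpy(), tolerance=tolerance)
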