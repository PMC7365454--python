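"""Synthetic serum-miRNA cohorts with planted pair and differential signal.

The generator emulates the statistical structure the pipeline assumes in a
log2-intensity serum miRNA array cohort:

* an *abundant* stratum of miRNAs whose log2 intensity exceeds the
  abundance threshold (8) in most samples, and a low stratum that the
  abundance filter should discard;
* a configurable set of differentially expressed miRNAs with a class mean
  shift (``effect_size`` log2 units);
* a configurable set of *planted pairs* — gene pairs whose within-sample
  rank order (which member is larger) flips between classes.  Both
  members of a pair share a base mean; per sample, two exchangeable
  intensities are drawn and assigned to the members so that the class's
  favoured orientation holds with probability exactly ``flip_prob``
  (a Bernoulli draw decides each sample's orientation).  Pair base means
  are spaced across the upper abundant band so that *cross* pairs —
  combinations of genes from different planted pairs — carry markedly
  weaker class signal than the planted pairs themselves;
* missing cells, completely at random, at rate ``missing_rate``.

Strictly monotone per-sample intensity distortions
(:func:`apply_monotone_distortion`) emulate cross-platform or batch shifts:
they change every intensity but no within-sample ranking, which is exactly
the perturbation rank-based pair features are designed to ignore.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .io import GenePair, HEALTHY, SARCOMA, validate_expression


class ConfigError(ValueError):
    """A synthetic-cohort configuration violates an invariant."""


class ContractError(ValueError):
    """A caller-supplied callable violates its stated contract."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of a synthetic two-class serum miRNA cohort.

    Defaults emulate the discovery cohort the pipeline targets: 275
    healthy and 402 sarcoma sera, 362 abundant miRNAs out of a larger
    probe set, with a modest differential stratum and ten planted pairs.
    """

    n_healthy: int = 275
    n_sarcoma: int = 402
    n_genes: int = 800
    n_abundant: int = 362
    n_differential: int = 50
    effect_size: float = 1.0
    noise_sd: float = 1.0
    n_planted_pairs: int = 10
    flip_prob: float = 0.95
    missing_rate: float = 0.02
    seed: int = 0

    def validate(self) -> "SyntheticConfig":
        counts = {
            "n_healthy": self.n_healthy, "n_sarcoma": self.n_sarcoma,
            "n_genes": self.n_genes, "n_abundant": self.n_abundant,
            "n_differential": self.n_differential,
            "n_planted_pairs": self.n_planted_pairs,
        }
        for name, value in counts.items():
            if value < 0 or int(value) != value:
                raise ConfigError(f"{name} must be a nonnegative integer, got {value!r}")
        if self.n_abundant > self.n_genes:
            raise ConfigError("n_abundant cannot exceed n_genes")
        if self.n_differential > self.n_abundant:
            raise ConfigError("n_differential cannot exceed n_abundant")
        if self.n_differential + 2 * self.n_planted_pairs > self.n_abundant:
            raise ConfigError(
                "abundant stratum too small: needs n_differential + "
                "2 * n_planted_pairs genes"
            )
        if not 0.5 < self.flip_prob <= 1.0:
            raise ConfigError("flip_prob must lie in (0.5, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        return self

    @classmethod
    def from_json(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            return cls(**json.load(fh)).validate()


@dataclass(frozen=True)
class PlantedPair:
    """A planted pair and the indicator value expected in healthy samples."""

    pair: GenePair
    healthy_indicator: int  # value of 1{expr(gene1) < expr(gene2)} favoured in healthy


@dataclass
class GroundTruth:
    """What the generator planted, for recovery checks downstream."""

    differential_genes: tuple[str, ...]
    planted_pairs: tuple[PlantedPair, ...] = field(default_factory=tuple)

    def planted_feature_ids(self) -> tuple[str, ...]:
        return tuple(p.pair.feature_id for p in self.planted_pairs)

    def to_dict(self) -> dict:
        return {
            "differential_genes": list(self.differential_genes),
            "planted_pairs": [
                {"gene1": p.pair.gene1, "gene2": p.pair.gene2,
                 "healthy_indicator": p.healthy_indicator}
                for p in self.planted_pairs
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "GroundTruth":
        return cls(
            differential_genes=tuple(payload["differential_genes"]),
            planted_pairs=tuple(
                PlantedPair(GenePair(p["gene1"], p["gene2"]), int(p["healthy_indicator"]))
                for p in payload["planted_pairs"]
            ),
        )


ABUNDANCE_THRESHOLD = 8.0  # log2 intensity; matches the preprocessing filter


def planted_benchmark_config(seed: int = 1) -> SyntheticConfig:
    """The reference planted-signal benchmark cohort.

    A strongly separable scaled-down cohort used to exercise the whole
    pipeline: 150 samples per class, 300 miRNAs of which 150 are abundant,
    30 differential miRNAs shifted by 1.5 log2 units, 10 planted pairs at
    orientation probability 0.95, and 2% missing cells.
    """
    return SyntheticConfig(
        n_healthy=150, n_sarcoma=150, n_genes=300, n_abundant=150,
        n_differential=30, effect_size=1.5, noise_sd=1.0,
        n_planted_pairs=10, flip_prob=0.95, missing_rate=0.02, seed=seed,
    )


def generate_cohort(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Generate a cohort: (expression genes x samples, labels, ground truth).

    Layout of the gene axis: the first ``n_abundant`` genes form the
    abundant stratum (per-gene means uniform on [9, 13]); the rest get
    means uniform on [5, 7.5], below the abundance threshold.  Within the
    abundant stratum, the first ``n_differential`` genes carry the class
    mean shift (alternating sign) and the next ``2 * n_planted_pairs``
    genes are consumed, pairwise, by the planted pairs.

    Deterministic: identical config (including seed) gives bit-identical
    output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_samples = config.n_healthy + config.n_sarcoma
    if n_samples == 0 or config.n_genes == 0:
        raise ConfigError("cohort must contain at least one gene and one sample")

    genes = [f"syn-miR-{i:04d}" for i in range(1, config.n_genes + 1)]
    sample_ids = (
        [f"H{i:04d}" for i in range(1, config.n_healthy + 1)]
        + [f"S{i:04d}" for i in range(1, config.n_sarcoma + 1)]
    )
    labels = pd.Series(
        [HEALTHY] * config.n_healthy + [SARCOMA] * config.n_sarcoma,
        index=pd.Index(sample_ids, name="sample_id"), name="label",
    )
    is_sarcoma = (labels == SARCOMA).to_numpy()

    means = np.empty(config.n_genes)
    means[: config.n_abundant] = rng.uniform(9.0, 13.0, config.n_abundant)
    means[config.n_abundant:] = rng.uniform(5.0, 7.5, config.n_genes - config.n_abundant)

    # Planted pairs: both members share a base mean; base means are spread
    # over the upper abundant band so cross-pair combinations stay weak.
    pair_start = config.n_differential
    if config.n_planted_pairs:
        pair_means = np.linspace(9.5, 13.5, config.n_planted_pairs)
        for j in range(config.n_planted_pairs):
            means[pair_start + 2 * j] = pair_means[j]
            means[pair_start + 2 * j + 1] = pair_means[j]

    # Differential miRNAs are shifted in the same direction (elevated in
    # sarcoma), the usual picture for tumor-secreted circulating miRNAs;
    # same-direction shifts also cancel in within-sample comparisons, so
    # differential genes do not by themselves create strong pair features.
    offset = np.zeros((config.n_genes, n_samples))
    diff_genes = tuple(genes[: config.n_differential])
    offset[: config.n_differential, :][:, is_sarcoma] += config.effect_size

    values = (
        means[:, None]
        + offset
        + rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))
    )

    # Enforce planted orientations by an exchangeable within-sample swap:
    # the two draws keep their values, only their assignment to the pair's
    # members depends on a Bernoulli(flip_prob) orientation draw, so the
    # empirical orientation frequency is exactly binomial.
    planted: list[PlantedPair] = []
    for j in range(config.n_planted_pairs):
        a = pair_start + 2 * j
        b = a + 1
        lo = np.minimum(values[a], values[b])
        hi = np.maximum(values[a], values[b])
        favoured = rng.random(n_samples) < config.flip_prob
        # gene_a < gene_b favoured in healthy, reversed in sarcoma
        a_less = np.where(is_sarcoma, ~favoured, favoured)
        values[a] = np.where(a_less, lo, hi)
        values[b] = np.where(a_less, hi, lo)
        planted.append(PlantedPair(GenePair(genes[a], genes[b]), healthy_indicator=1))

    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        fully_missing = mask.all(axis=1)
        for g in np.flatnonzero(fully_missing):
            mask[g, rng.integers(0, n_samples)] = False
        values = np.where(mask, np.nan, values)

    matrix = pd.DataFrame(values, index=pd.Index(genes, name="miRNA"), columns=sample_ids)
    truth = GroundTruth(differential_genes=diff_genes, planted_pairs=tuple(planted))
    return validate_expression(matrix), labels, truth


def _check_monotone(transform: Callable[[np.ndarray], np.ndarray],
                    lo: float, hi: float, n_grid: int = 257) -> None:
    if not np.isfinite(lo) or not np.isfinite(hi) or lo == hi:
        return
    grid = np.linspace(lo, hi, n_grid)
    out = np.asarray(transform(grid), dtype=float)
    if out.shape != grid.shape or not np.all(np.diff(out) > 0):
        raise ContractError("transform is not strictly increasing on the data range")


def apply_monotone_distortion(
    matrix: pd.DataFrame,
    transform: Callable[[np.ndarray], np.ndarray],
    sample_ids: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Apply a strictly increasing scalar map to the selected samples.

    Returns a copy; missingness is unchanged.  The transform is verified
    to be strictly increasing on a grid spanning the data's observed
    range, as a guard against accidental non-monotone maps.
    """
    out = matrix.copy()
    cols = list(matrix.columns) if sample_ids is None else list(sample_ids)
    missing_cols = [c for c in cols if c not in matrix.columns]
    if missing_cols:
        raise KeyError(f"unknown sample id(s): {missing_cols}")
    block = out[cols].to_numpy(dtype=float)
    finite = np.isfinite(block)
    if finite.any():
        _check_monotone(transform, float(block[finite].min()), float(block[finite].max()))
        transformed = np.where(finite, transform(np.where(finite, block, 0.0)), np.nan)
        out[cols] = transformed
    return out


def random_increasing_map(rng: np.random.Generator) -> Callable[[np.ndarray], np.ndarray]:
    """Draw a random strictly increasing scalar map.

    Mixes affine maps, odd-power warps and random monotone interpolants —
    a stand-in family for cross-platform intensity response curves.
    """
    kind = rng.integers(0, 3)
    if kind == 0:
        a = rng.uniform(0.2, 5.0)
        b = rng.uniform(-10.0, 10.0)
        return lambda x: a * np.asarray(x, dtype=float) + b
    if kind == 1:
        power = rng.choice([1.0, 3.0, 5.0])
        scale = rng.uniform(0.05, 0.5)
        shift = rng.uniform(-2.0, 2.0)
        return lambda x: np.sign(np.asarray(x) - shift) * (
            scale * np.abs(np.asarray(x, dtype=float) - shift)
        ) ** power + 0.01 * np.asarray(x, dtype=float)
    knots_x = np.linspace(-50.0, 80.0, 33)
    knots_y = np.cumsum(rng.exponential(1.0, size=33)) + 0.01 * knots_x
    slope_lo = (knots_y[1] - knots_y[0]) / (knots_x[1] - knots_x[0])
    slope_hi = (knots_y[-1] - knots_y[-2]) / (knots_x[-1] - knots_x[-2])

    def interp(x):
        x = np.asarray(x, dtype=float)
        inner = np.interp(x, knots_x, knots_y)
        below = knots_y[0] + slope_lo * (x - knots_x[0])
        above = knots_y[-1] + slope_hi * (x - knots_x[-1])
        return np.where(x < knots_x[0], below, np.where(x > knots_x[-1], above, inner))

    return interp
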