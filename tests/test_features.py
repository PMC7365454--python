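import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from mirpair import (
    NearConstantPairFilter, PairFeaturizer, TTestSelector,
    build_pair_matrix, compute_published_features, filter_near_constant,
    gene_ttest, generate_cohort, pair_indicators, published_panel,
    published_panel_genes, rank_select, select_candidate_genes,
    select_candidate_pairs, two_sample_ttest, SyntheticConfig,
)
from mirpair.preprocess import ContractError


def welch_oracle(a, b):
    """Textbook Welch statistic computed from first principles."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return t, p


class TestTwoSampleTTest:
    def test_matches_welch_formula_on_toy_vectors(self):
        a = [8.1, 9.4, 10.2]
        b = [7.0, 7.3, 8.9]
        X = pd.DataFrame({"g": a + b})
        y = np.array(["sarcoma"] * 3 + ["healthy"] * 3)
        res = two_sample_ttest(X, y).iloc[0]
        t_exp, p_exp = welch_oracle(a, b)
        assert res["t"] == pytest.approx(t_exp, rel=1e-12)
        assert res["p"] == pytest.approx(p_exp, rel=1e-12)
        assert res["effect"] == pytest.approx(abs(np.mean(a) - np.mean(b)))

    def test_identical_class_distributions_give_null_result(self):
        X = pd.DataFrame({"g": [5.0, 6.0, 7.0, 5.0, 6.0, 7.0]})
        y = np.array(["healthy"] * 3 + ["sarcoma"] * 3)
        res = two_sample_ttest(X, y).iloc[0]
        assert res["t"] == 0.0
        assert res["p"] == pytest.approx(1.0)

    def test_degenerate_constant_feature_flagged(self):
        X = pd.DataFrame({"flat": [1.0] * 6, "split": [0.0] * 3 + [1.0] * 3})
        y = np.array(["healthy"] * 3 + ["sarcoma"] * 3)
        res = two_sample_ttest(X, y)
        assert bool(res.loc["flat", "degenerate"])
        assert res.loc["flat", "p"] == 1.0 and res.loc["flat", "effect"] == 0.0
        # both classes constant at different values: perfect separation
        assert res.loc["split", "p"] == 0.0
        assert res.loc["split", "effect"] == 1.0

    def test_null_calibration_about_five_percent(self):
        rng = np.random.default_rng(42)
        n_genes, n = 200, 60
        X = pd.DataFrame(rng.normal(size=(n, n_genes)))
        y = np.array(["healthy"] * 30 + ["sarcoma"] * 30)
        frac = (two_sample_ttest(X, y)["p"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / n_genes)
        assert abs(frac - 0.05) < 3 * se

    def test_pooled_variance_option(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [2.0, 4.0, 6.0, 9.0]
        X = pd.DataFrame({"g": a + b})
        y = np.array(["sarcoma"] * 4 + ["healthy"] * 4)
        res = two_sample_ttest(X, y, equal_var=True).iloc[0]
        t_exp, p_exp = sps.ttest_ind(a, b, equal_var=True)
        assert res["t"] == pytest.approx(t_exp)
        assert res["p"] == pytest.approx(p_exp)


class TestRankSelect:
    def _stats(self, effects, pvals, ids=None):
        ids = ids or [f"g{i:03d}" for i in range(len(effects))]
        return pd.DataFrame({"effect": effects, "p": pvals,
                             "t": effects, "mean_diff": effects},
                            index=ids)

    def test_caps_at_top_n(self):
        rng = np.random.default_rng(0)
        table = self._stats(rng.uniform(0.1, 2, 300), np.full(300, 0.01))
        assert len(select_candidate_genes(table, top_n=250)) == 250

    def test_returns_all_when_fewer_significant(self):
        table = self._stats([1.0] * 100, [0.01] * 100)
        assert len(select_candidate_genes(table, top_n=250)) == 100

    def test_insignificant_features_excluded(self):
        table = self._stats([5.0, 1.0], [0.2, 0.01])
        assert select_candidate_genes(table) == ["g001"]

    def test_ranked_by_descending_absolute_effect(self):
        table = self._stats([0.5, -2.0, 1.0], [0.01, 0.01, 0.01])
        table["effect"] = table["effect"].abs()
        assert select_candidate_genes(table, top_n=2) == ["g001", "g002"]

    def test_tie_breaks_by_p_then_identifier(self):
        table = self._stats([1.0, 1.0, 1.0], [0.02, 0.01, 0.02],
                            ids=["gb", "gc", "ga"])
        assert rank_select(table, top_n=2) == ["gc", "ga"]


class TestBuildPairMatrix:
    def test_pair_count_for_250_genes(self, rng):
        genes = [f"mir-{i:03d}" for i in range(250)]
        matrix = pd.DataFrame(rng.normal(10, 1, size=(250, 4)),
                              index=genes, columns=list("abcd"))
        pairs = build_pair_matrix(matrix, genes)
        assert pairs.shape == (31_125, 4)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(k=st.integers(2, 40))
    def test_pair_count_combinatorics(self, k):
        rng = np.random.default_rng(k)
        genes = [f"g{i:02d}" for i in range(k)]
        matrix = pd.DataFrame(rng.normal(size=(k, 3)), index=genes,
                              columns=["s1", "s2", "s3"])
        assert build_pair_matrix(matrix, genes).shape[0] == k * (k - 1) // 2

    def test_indicator_rule_and_tie_convention(self):
        matrix = pd.DataFrame({"s1": [7.2, 8.1], "s2": [8.1, 7.2],
                               "s3": [5.0, 5.0]}, index=["g1", "g2"])
        pairs = build_pair_matrix(matrix, ["g1", "g2"])
        assert list(pairs.loc["g1|g2"]) == [1, 0, 0]

    def test_matches_exhaustive_enumeration_on_toy(self, toy_expression):
        pairs = build_pair_matrix(toy_expression, list(toy_expression.index))
        assert pairs.shape == (6, 3)
        for pair_id in pairs.index:
            g1, g2 = pair_id.split("|")
            for s in toy_expression.columns:
                expected = int(toy_expression.loc[g1, s] < toy_expression.loc[g2, s])
                assert pairs.loc[pair_id, s] == expected

    def test_orientation_is_lexicographic(self, toy_expression):
        pairs = build_pair_matrix(toy_expression, ["mir-d", "mir-a"])
        assert list(pairs.index) == ["mir-a|mir-d"]

    def test_unknown_gene_rejected(self, toy_expression):
        with pytest.raises(KeyError, match="mir-zz"):
            build_pair_matrix(toy_expression, ["mir-a", "mir-zz"])

    def test_featurizer_rejects_missing_values(self):
        X = pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, 3.0]})
        feat = PairFeaturizer().fit(X.fillna(0))
        with pytest.raises(ContractError):
            feat.transform(X)


class TestPublishedFeatures:
    def _panel_matrix(self, rng):
        genes = sorted(published_panel_genes())
        return pd.DataFrame(rng.normal(10, 2, size=(9, 5)), index=genes,
                            columns=[f"s{i}" for i in range(5)])

    def test_six_rows_in_panel_order(self, rng):
        matrix = self._panel_matrix(rng)
        feats = compute_published_features(matrix)
        assert list(feats.index) == [p.feature_id for p in published_panel()]

    def test_indicator_follows_printed_orientation(self, rng):
        matrix = self._panel_matrix(rng)
        matrix.loc["hsa-miR-378c", "s0"] = 5.0
        matrix.loc["hsa-miR-380-5p", "s0"] = 6.0
        feats = compute_published_features(matrix)
        assert feats.loc["hsa-miR-378c|hsa-miR-380-5p", "s0"] == 1

    def test_missing_panel_mirna_listed(self, rng):
        matrix = self._panel_matrix(rng).drop(index="hsa-miR-571")
        with pytest.raises(KeyError, match="hsa-miR-571"):
            compute_published_features(matrix)

    def test_invariant_under_increasing_transform(self, rng):
        matrix = self._panel_matrix(rng)
        warped = np.exp(matrix / 4) * 3 + 1
        pd.testing.assert_frame_equal(compute_published_features(matrix),
                                      compute_published_features(warped))


class TestNearConstantFilter:
    def _pairs(self, ones_per_pair, n=100):
        rows = []
        for k in ones_per_pair:
            row = np.zeros(n, dtype=np.int8)
            row[:k] = 1
            rows.append(row)
        return pd.DataFrame(rows, index=[f"p{i}" for i in range(len(rows))],
                            columns=[f"s{j}" for j in range(n)])

    def test_majority_above_threshold_removed(self):
        pairs = self._pairs([95, 5, 50])
        out = filter_near_constant(pairs, pairs.columns, max_fraction=0.90)
        assert list(out.index) == ["p2"]

    def test_boundary_exactly_ninety_percent_retained(self):
        pairs = self._pairs([90, 91, 10, 9])
        out = filter_near_constant(pairs, pairs.columns, max_fraction=0.90)
        assert list(out.index) == ["p0", "p2"]

    def test_engineered_three_of_ten_removed(self):
        ones = [50, 60, 95, 40, 30, 99, 45, 55, 3, 70]
        pairs = self._pairs(ones)
        out = filter_near_constant(pairs, pairs.columns)
        assert out.shape[0] == 7
        assert set(out.index) == {f"p{i}" for i, k in enumerate(ones)
                                  if 10 <= k <= 90}

    def test_evaluated_on_training_samples_only(self):
        # 95% ones overall (would be removed), but only 87.5% within training
        row = np.zeros(100, dtype=np.int8)
        row[:20] = 1
        row[25:] = 1
        pairs = pd.DataFrame([row], index=["p0"],
                             columns=[f"s{j}" for j in range(100)])
        train = [f"s{j}" for j in range(40)]
        out = filter_near_constant(pairs, train)
        assert list(out.index) == ["p0"]
        assert out.shape[1] == 100  # every sample column retained
        removed = filter_near_constant(pairs, list(pairs.columns))
        assert removed.shape[0] == 0

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            filter_near_constant(self._pairs([50]), [])

    def test_estimator_support(self):
        pairs = self._pairs([95, 50])
        filt = NearConstantPairFilter().fit(pairs.T)
        assert list(filt.support_) == [False, True]


class TestSelectCandidatePairs:
    def test_caps_at_top_n(self, rng):
        n = 60
        y = pd.Series(["healthy"] * 30 + ["sarcoma"] * 30,
                      index=[f"s{j}" for j in range(n)])
        signal = np.r_[np.zeros(30), np.ones(30)]
        rows = [np.where(rng.random(n) < 0.9, signal, 1 - signal)
                for _ in range(200)]
        pairs = pd.DataFrame(rows, index=[f"p{i:03d}" for i in range(200)],
                             columns=y.index)
        out = select_candidate_pairs(pairs, y, y.index, top_n=80)
        assert out.shape[0] == 80

    def test_returns_all_when_few_significant(self, rng):
        n = 40
        y = pd.Series(["healthy"] * 20 + ["sarcoma"] * 20,
                      index=[f"s{j}" for j in range(n)])
        signal = np.r_[np.zeros(20), np.ones(20)]
        strong = [np.where(rng.random(n) < 0.95, signal, 1 - signal)
                  for _ in range(10)]
        noise = [rng.integers(0, 2, n) for _ in range(50)]
        pairs = pd.DataFrame(strong + noise,
                             index=[f"p{i:03d}" for i in range(60)],
                             columns=y.index)
        out = select_candidate_pairs(pairs, y, y.index, top_n=80)
        assert set(f"p{i:03d}" for i in range(10)) <= set(out.index)

    def test_planted_pairs_recovered_from_synthetic_cohort(self):
        cfg = SyntheticConfig(n_healthy=120, n_sarcoma=120, n_genes=80,
                              n_abundant=60, n_differential=10,
                              effect_size=1.5, n_planted_pairs=5,
                              flip_prob=0.95, missing_rate=0.0, seed=21)
        matrix, labels, truth = generate_cohort(cfg)
        pairs = build_pair_matrix(matrix, list(matrix.index[:60]))
        pairs = filter_near_constant(pairs, matrix.columns)
        out = select_candidate_pairs(pairs, labels, matrix.columns, top_n=80)
        assert set(truth.planted_feature_ids()) <= set(out.index)


def test_gene_ttest_wrapper_uses_domain_orientation(small_cohort):
    matrix, labels, truth = small_cohort
    complete = matrix.fillna(matrix.mean(axis=1).mean())
    res = gene_ttest(complete, labels)
    assert len(res) == complete.shape[0]
    diff = res.loc[list(truth.differential_genes), "p"]
    assert (diff < 0.05).all()
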