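"""Feature ranking, variance filter, size scan with the 1-SEM rule, and
stability selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from p53sig import cohort, discovery


def _matrix(values, features=None, samples=None):
    values = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=features, columns=samples)


class TestVarianceFilter:
    def test_keeps_highest_variance_half_preserving_order(self):
        m = _matrix([[0, 0, 0], [1, 2, 3], [0, 4, 8], [0, 8, 16]],
                    features=["a", "b", "c", "d"])
        out = discovery.variance_filter(m, 0.5)
        assert list(out.index) == ["c", "d"]

    def test_fraction_one_is_identity(self):
        m = _matrix(np.random.default_rng(0).normal(size=(5, 4)))
        assert discovery.variance_filter(m, 1.0).equals(m)

    def test_invalid_fraction(self):
        m = _matrix([[1.0, 2.0]])
        with pytest.raises(ValueError):
            discovery.variance_filter(m, 0.0)


class TestWilcoxon:
    def test_exact_p_for_complete_separation_3v3(self):
        # 20 rank configurations for C(6,3); the extreme one has two-sided
        # exact p = 2/20 = 0.1
        p = discovery.wilcoxon_pvalues([[1.0, 2.0, 3.0]], [[4.0, 5.0, 6.0]])
        assert p[0] == pytest.approx(0.1, abs=1e-12)

    @given(st.integers(0, 2 ** 31 - 1), st.integers(3, 40), st.integers(3, 40))
    @settings(max_examples=30, deadline=None)
    def test_matches_scipy_reference(self, seed, n1, n2):
        rng = np.random.default_rng(seed)
        X1 = rng.normal(size=(4, n1))
        X2 = rng.normal(0.5, 1, size=(4, n2))
        mine = discovery.wilcoxon_pvalues(X1, X2)
        method = "exact" if max(n1, n2) <= discovery.EXACT_MAX_N else "asymptotic"
        ref = np.array([stats.mannwhitneyu(X1[i], X2[i], method=method,
                                           alternative="two-sided").pvalue
                        for i in range(4)])
        np.testing.assert_allclose(mine, ref, rtol=1e-9, atol=1e-12)

    def test_tie_handling_matches_scipy(self):
        rng = np.random.default_rng(1)
        X1 = rng.integers(0, 4, size=(3, 30)).astype(float)
        X2 = rng.integers(0, 4, size=(3, 40)).astype(float)
        mine = discovery.wilcoxon_pvalues(X1, X2)
        ref = np.array([stats.mannwhitneyu(X1[i], X2[i], method="asymptotic",
                                           alternative="two-sided").pvalue
                        for i in range(3)])
        np.testing.assert_allclose(mine, ref, rtol=1e-9)


class TestRankFeatures:
    def test_fold_change_arithmetic(self):
        # mean log2 difference of ~1.956 corresponds to linear FC 3.88
        base = np.array([[0.0, 0.2, -0.2, 0.1, -0.1, 0.0]])
        sens = base[:, :3] + np.log2(3.88)
        m = _matrix(np.hstack([sens, base[:, 3:]]))
        ranked = discovery.rank_features(m, np.array([True] * 3 + [False] * 3))
        assert ranked.loc[0, "fold_change"] == pytest.approx(3.88, rel=1e-9)
        assert ranked.loc[0, "direction"] == "up"

    def test_single_class_is_an_error(self):
        m = _matrix(np.ones((2, 4)))
        with pytest.raises(ValueError):
            discovery.rank_features(m, np.array([True] * 4))

    def test_null_pvalues_not_degenerate(self, null_cohort):
        ranked = discovery.rank_features(null_cohort.expression,
                                         null_cohort.annotation["true_class"])
        assert ranked["p_value"].min() > 1e-6
        # roughly uniform: about half the p-values above 0.5
        assert 0.3 < (ranked["p_value"] > 0.5).mean() < 0.7


class TestSplitsAndLeakage:
    def test_stratified_split_preserves_proportions(self, rng):
        mask = np.array([True] * 30 + [False] * 60)
        train, test = discovery.stratified_split(mask, 2 / 3, rng)
        assert len(train) + len(test) == 90
        assert mask[train].sum() == 20 and (~mask[train]).sum() == 40
        assert np.intersect1d(train, test).size == 0

    def test_split_rejects_tiny_class(self, rng):
        with pytest.raises(ValueError):
            discovery.stratified_split(np.array([True] * 2 + [False] * 10),
                                       2 / 3, rng)

    def test_ranking_ignores_held_out_samples(self, rng):
        """A canary feature that encodes the class labels only on the
        held-out samples (constant on the training split) must not be
        selected: selection sees the training split alone."""
        n = 90
        mask = np.array([True] * 30 + [False] * 60)
        train, test = discovery.stratified_split(mask, 2 / 3, rng)
        X = rng.normal(size=(50, n))
        X[0] = rng.normal(size=n) + mask * 2.0        # genuinely informative
        X[1, :] = 0.0
        X[1, test] = mask[test].astype(float)          # leak-only canary
        m = _matrix(X)
        top = discovery._top_k_features(m, mask, train, 5)
        assert "f0" in top
        assert "f1" not in top


class TestSizeScan:
    def test_separable_data_scores_perfectly(self):
        rng = np.random.default_rng(0)
        mask = np.array([True] * 12 + [False] * 24)
        X = rng.normal(size=(30, 36)) * 0.01
        X[:10] += mask * 5.0
        scan = discovery.size_scan(_matrix(X), mask, sizes=range(2, 8),
                                   repeats=4, seed=1)
        assert (scan["mean_accuracy"] > 0.999).all()

    def test_single_repeat_warns_and_reports_zero_sem(self):
        rng = np.random.default_rng(0)
        mask = np.array([True] * 10 + [False] * 10)
        m = _matrix(rng.normal(size=(12, 20)))
        with pytest.warns(UserWarning, match="repeats=1"):
            scan = discovery.size_scan(m, mask, sizes=[3, 4], repeats=1, seed=0)
        assert (scan["sem_accuracy"] == 0).all()

    def test_size_exceeding_features_is_an_error(self):
        m = _matrix(np.random.default_rng(0).normal(size=(4, 20)))
        mask = np.array([True] * 10 + [False] * 10)
        with pytest.raises(ValueError):
            discovery.size_scan(m, mask, sizes=[10], repeats=2, seed=0)

    def test_seed_fixes_the_scan(self, small_cohort, small_labels):
        f = discovery.variance_filter(small_cohort.expression, 0.5)
        a = discovery.size_scan(f, small_labels, sizes=[5, 10], repeats=3, seed=9)
        b = discovery.size_scan(f, small_labels, sizes=[5, 10], repeats=3, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestOneSemRule:
    def test_reported_narrative_example(self):
        # accuracy peaks at k=17 (~93%) but k=13 is within one SEM
        scan = pd.DataFrame({
            "mean_accuracy": [0.90, 0.92, 0.93],
            "sem_accuracy": [0.01, 0.02, 0.023],
        }, index=pd.Index([5, 13, 17], name="k"))
        assert discovery.select_size_1sem(scan) == 13

    def test_zero_sem_returns_argmax(self):
        scan = pd.DataFrame({"mean_accuracy": [0.7, 0.8, 0.9],
                             "sem_accuracy": [0.0, 0.0, 0.0]},
                            index=pd.Index([5, 6, 7], name="k"))
        assert discovery.select_size_1sem(scan) == 7

    def test_flat_accuracy_returns_smallest_size(self):
        scan = pd.DataFrame({"mean_accuracy": [0.8, 0.8, 0.8],
                             "sem_accuracy": [0.01, 0.01, 0.01]},
                            index=pd.Index([5, 6, 7], name="k"))
        assert discovery.select_size_1sem(scan) == 5


class TestStabilitySelection:
    def test_planted_signature_dominates_counts(self, small_cohort, small_labels):
        f = discovery.variance_filter(small_cohort.expression, 0.5)
        res = discovery.stability_select(f, small_labels, k=13, repeats=30,
                                         seed=0)
        recovered = set(res.signature) & set(cohort.SIGNATURE_FOLD_CHANGES)
        assert len(recovered) >= 12
        assert res.counts.iloc[0] == 30

    def test_single_informative_feature_always_selected(self):
        rng = np.random.default_rng(0)
        mask = np.array([True] * 10 + [False] * 20)
        X = rng.normal(size=(20, 30))
        X[5] += mask * 4.0
        res = discovery.stability_select(_matrix(X), mask, k=1, repeats=15,
                                         seed=2)
        assert res.signature == ["f5"]
        assert res.counts["f5"] == 15

    def test_exclusion_list_substitutes_next_candidate(self, small_cohort,
                                                       small_labels):
        f = discovery.variance_filter(small_cohort.expression, 0.5)
        full = discovery.stability_select(f, small_labels, k=5, repeats=20,
                                          seed=4)
        top = full.signature[0]
        excl = discovery.stability_select(f, small_labels, k=5, repeats=20,
                                          seed=4, exclusion_list=[top])
        assert top not in excl.signature
        assert excl.signature[:4] == full.signature[1:5]

    def test_exclusion_list_exhausting_pool_is_an_error(self):
        rng = np.random.default_rng(0)
        mask = np.array([True] * 5 + [False] * 10)
        m = _matrix(rng.normal(size=(3, 15)))
        with pytest.raises(ValueError):
            discovery.stability_select(m, mask, k=3, repeats=5, seed=0,
                                       exclusion_list=["f0", "f1", "f2"])
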