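"""Multi-type association tests, local BH FDR, affinity propagation and
set assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from itertools import combinations

from p53sig import landscape
from p53sig.landscape import affinity_propagation, assemble_set, bh_fdr


def _long_table(rows):
    return pd.DataFrame(rows, columns=["feature_id", "feature_type",
                                       "sample_id", "value"])


def _continuous_feature(fid, ftype, values, samples):
    return [(fid, ftype, s, v) for s, v in zip(samples, values)]


class TestBH:
    def test_single_p_is_its_own_q(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_step_up_collapses_equal_spacing(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_two_values(self):
        np.testing.assert_allclose(bh_fdr([0.5, 1.0]), [1.0, 1.0])

    def test_empty_input(self):
        assert bh_fdr([]).size == 0

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=200))
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_step_up(self, ps):
        """q_i = min over j with p_j >= p_i of p_j * m / rank_j."""
        p = np.array(ps)
        m = p.size
        order = np.argsort(p, kind="stable")
        q_sorted = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
        expect = np.empty(m)
        expect[order] = np.minimum(q_sorted, 1.0)
        np.testing.assert_allclose(bh_fdr(p), expect, rtol=1e-10)


class TestTestFeatures:
    def test_binary_mutation_feature_reproduces_screen_association(self):
        samples = [f"s{i}" for i in range(356)]
        labels = pd.Series(["sensitive"] * 47 + ["insensitive"] * 309,
                           index=samples)
        # 43 of 47 sensitive are WT; 57 of 309 insensitive are WT
        status = ["WT"] * 43 + ["MUT"] * 4 + ["WT"] * 57 + ["MUT"] * 252
        table = _long_table([("tp53", "mutation", s, v)
                             for s, v in zip(samples, status)])
        res = landscape.test_features(table, labels)
        assert res.loc[0, "test"] == "fisher"
        assert 4.6e-23 < res.loc[0, "p_value"] < 5.6e-23

    def test_constant_feature_is_flagged(self):
        samples = [f"s{i}" for i in range(10)]
        labels = pd.Series(["sensitive"] * 4 + ["insensitive"] * 6,
                           index=samples)
        table = _long_table(
            _continuous_feature("flat", "expression", [1.0] * 10, samples)
            + [("lin", "lineage", s, "lung") for s in samples])
        res = landscape.test_features(table, labels).set_index("feature_id")
        assert res.loc["flat", "p_value"] == 1.0 and res.loc["flat", "constant"]
        assert res.loc["lin", "p_value"] == 1.0 and res.loc["lin", "constant"]

    def test_continuous_feature_uses_wilcoxon(self, rng):
        samples = [f"s{i}" for i in range(30)]
        labels = pd.Series(["sensitive"] * 10 + ["insensitive"] * 20,
                           index=samples)
        x = rng.normal(size=30) + np.r_[np.ones(10) * 3, np.zeros(20)]
        table = _long_table(_continuous_feature("g", "expression", x, samples))
        res = landscape.test_features(table, labels)
        assert res.loc[0, "test"] == "wilcoxon"
        assert res.loc[0, "p_value"] < 1e-4
        assert res.loc[0, "direction"] == "up"

    def test_multilevel_lineage_uses_level_vs_rest(self, rng):
        samples = [f"s{i}" for i in range(40)]
        labels = pd.Series(["sensitive"] * 20 + ["insensitive"] * 20,
                           index=samples)
        lin = ["lung"] * 18 + ["skin"] * 2 + ["skin"] * 18 + ["colon"] * 2
        table = _long_table([("lin", "lineage", s, v)
                             for s, v in zip(samples, lin)])
        res = landscape.test_features(table, labels)
        assert res.loc[0, "test"] == "fisher_levels"
        assert res.loc[0, "p_value"] < 0.01


class TestAffinityPropagation:
    @staticmethod
    def _net_similarity(S, preference, exemplars, labels):
        E = set(int(e) for e in exemplars)
        return sum(preference if i in E else S[i, labels[i]]
                   for i in range(S.shape[0]))

    @staticmethod
    def _brute_force_optimum(S, preference):
        n = S.shape[0]
        best = -np.inf
        for r in range(1, n + 1):
            for E in combinations(range(n), r):
                score = preference * len(E)
                others = [i for i in range(n) if i not in E]
                if others:
                    score += S[np.ix_(others, list(E))].max(axis=1).sum()
                best = max(best, score)
        return best

    def test_two_duplicate_groups_yield_two_exemplars(self):
        S = np.zeros((6, 6))
        S[:3, :3] = 1.0
        S[3:, 3:] = 1.0
        res = affinity_propagation(S)
        assert len(res.exemplars) == 2
        assert len(set(res.labels[:3])) == 1 and res.labels[0] < 3
        assert len(set(res.labels[3:])) == 1 and res.labels[3] >= 3

    def test_single_point_is_its_own_exemplar(self):
        res = affinity_propagation([[0.0]])
        assert list(res.exemplars) == [0] and list(res.labels) == [0]

    def test_dominant_preference_makes_every_point_an_exemplar(self):
        S = np.full((5, 5), 0.3)
        res = affinity_propagation(S, preference=10.0)
        assert list(res.exemplars) == [0, 1, 2, 3, 4]

    def test_matches_exhaustive_scoring_on_duplicate_groups(self):
        """On balanced exact-duplicate groups the message-passing fixed
        point attains the exhaustive-search optimum (any group member is an
        equally optimal exemplar).  Unbalanced or singleton groups with
        strongly negative preferences can settle on suboptimal fixed
        points - a known property of affinity propagation."""
        rng = np.random.default_rng(0)
        for _ in range(30):
            k = int(rng.integers(1, 4))
            m = int(rng.integers(2, 5))
            if k * m > 8:
                continue
            pts = np.repeat(np.arange(k) * 10.0, m)
            n = len(pts)
            S = -np.abs(pts[:, None] - pts[None, :]) ** 2
            pref = float(np.median(S[~np.eye(n, dtype=bool)])) if n > 1 else 0.0
            res = affinity_propagation(S, preference=pref)
            got = self._net_similarity(S, pref, res.exemplars, res.labels)
            assert got == pytest.approx(self._brute_force_optimum(S, pref),
                                        abs=1e-6)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            affinity_propagation(np.zeros((2, 3)))
        with pytest.raises(ValueError):
            affinity_propagation([[0, 1], [2, 0]])
        with pytest.raises(ValueError):
            affinity_propagation(np.zeros((2, 2)), damping=0.3)


class TestAssembleSet:
    def test_fdr_gate(self):
        tested = pd.DataFrame({
            "feature_id": ["a", "b", "c"], "feature_type": "expression",
            "p_value": [0.05, 0.15, 0.3]})  # BH q = 0.15, 0.225, 0.3
        out = assemble_set(tested, q_cutoff=0.25)
        assert out["selected"].tolist() == [True, True, False]
        assert not out["forced"].any()

    def test_min_per_type_forces_best_p(self):
        tested = pd.DataFrame({
            "feature_id": ["a", "b", "c"], "feature_type": "mutation",
            "p_value": [0.6, 0.4, 0.9]})
        out = assemble_set(tested, q_cutoff=0.25, min_per_type=2)
        sel = out[out["selected"]]
        assert set(sel["feature_id"]) == {"a", "b"}
        assert sel["forced"].all()

    def test_max_per_type_truncates_by_p(self):
        tested = pd.DataFrame({
            "feature_id": ["a", "b", "c"], "feature_type": "expression",
            "p_value": [0.001, 0.002, 0.003]})
        out = assemble_set(tested, q_cutoff=0.25, max_per_type=1)
        assert out[out["selected"]]["feature_id"].tolist() == ["a"]

    def test_min_above_max_is_an_error(self):
        tested = pd.DataFrame({"feature_id": ["a"],
                               "feature_type": "expression",
                               "p_value": [0.5]})
        with pytest.raises(ValueError):
            assemble_set(tested, min_per_type=3, max_per_type=1)

    def test_local_fdr_is_invariant_to_other_types(self, rng):
        expr = pd.DataFrame({
            "feature_id": [f"g{i}" for i in range(6)],
            "feature_type": "expression",
            "p_value": rng.uniform(0.001, 1.0, 6)})
        other = pd.DataFrame({
            "feature_id": [f"m{i}" for i in range(4)],
            "feature_type": "mutation",
            "p_value": rng.uniform(0.001, 1.0, 4)})
        alone = assemble_set(expr).set_index("feature_id")["q"]
        joint = assemble_set(pd.concat([expr, other], ignore_index=True))
        joint = joint.set_index("feature_id")["q"].loc[alone.index]
        np.testing.assert_allclose(alone, joint)


def test_significant_features_end_to_end(small_cohort, small_labels):
    """Exemplar deduplication keeps one representative per duplicate group
    and the planted signature type yields selections."""
    samples = list(small_cohort.expression.columns)
    rows = []
    for g in ["CDKN1A", "HDM2", "G00001", "G00002"]:
        rows += _continuous_feature(g, "expression",
                                    small_cohort.expression.loc[g], samples)
    # exact duplicate of CDKN1A under another id: should be deduplicated
    rows += _continuous_feature("CDKN1A_copy", "expression",
                                small_cohort.expression.loc["CDKN1A"], samples)
    status = small_cohort.annotation["tp53_status"]
    rows += [("tp53", "mutation", s, status[s]) for s in samples]
    table = _long_table(rows)
    out = landscape.significant_features(table, small_labels)
    expr_kept = set(out.loc[out["feature_type"] == "expression", "feature_id"])
    assert not {"CDKN1A", "CDKN1A_copy"} <= expr_kept
    assert out[out["selected"]].shape[0] >= 1
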