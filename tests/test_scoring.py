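"""Scoring primitives: Hill probability, aFC, EI, BH, kinase scores, PDS family."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from incytr import (
    ScoringConfig,
    adjust_bh,
    afc,
    ds_multimodal,
    exclusiveness_index,
    hill_probability,
    k_pds,
    pds,
    pds_transform,
    permutation_pvalue,
    permutation_test,
    score_all,
    sik_score,
)
from incytr.pathways import PATHWAY_COLUMNS, PathwayTable
from incytr.scoring import identify_kinases

from conftest import tiny_expression

CFG = ScoringConfig()

pos = st.floats(1e-6, 1e6, allow_nan=False, allow_infinity=False)


class TestHillProbability:
    def test_half_saturation_point(self):
        # every consecutive product equals Kh -> each factor 1/2 -> P = 1/8
        ae = math.sqrt(CFG.kh)
        assert hill_probability(ae, ae, ae, ae) == pytest.approx(0.125)

    def test_zero_expression_kills_probability(self):
        assert hill_probability(0.0, 3.0, 3.0, 3.0) == 0.0

    def test_direct_formula(self):
        # AE = 2 everywhere: each product 4, factor 16/(16+0.0625)... computed independently
        prod = 2.0 * 2.0
        factor = prod**2 / (prod**2 + 0.5**2)
        assert hill_probability(2, 2, 2, 2) == pytest.approx(factor**3)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=4, max_size=4), pos)
    def test_monotone_in_each_argument(self, aes, bump):
        base = hill_probability(*aes)
        for i in range(4):
            raised = list(aes)
            raised[i] += bump
            assert hill_probability(*raised) >= base - 1e-12
        assert 0.0 <= base < 1.0

    def test_consecutive_product_dominance_preserves_order(self):
        # pathway A's products all dominate B's -> P_A >= P_B for any Kh
        for kh in (0.1, 0.5, 3.0):
            cfg = ScoringConfig(kh=kh)
            pa = hill_probability(2, 3, 1.5, 2, cfg)
            pb = hill_probability(1, 2, 1.0, 1, cfg)
            assert pa >= pb


class TestAdjustedFoldChange:
    def test_saturated_factor_leaves_log2_untouched(self):
        assert afc(4, 2, a=1) == pytest.approx(1.0)

    def test_equal_values_give_zero(self):
        assert afc(3.3, 3.3, a=10) == 0.0

    def test_small_values_shrunk(self):
        x, y, a = 1e-4, 1e-6, 0.5
        expected = math.log2(x / y) * (2 * x * x / (x * x + a * a))
        assert afc(x, y, a) == pytest.approx(expected)
        assert abs(afc(x, y, a)) < abs(math.log2(x / y))

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError, match="pseudo-count"):
            afc(0.0, 1.0, a=1)

    @settings(max_examples=80, derandomize=True)
    @given(pos, pos, st.floats(0, 1e3, allow_nan=False))
    def test_antisymmetry_and_shrinkage(self, x, y, a):
        assert afc(x, y, a) == pytest.approx(-afc(y, x, a), rel=1e-9, abs=1e-12)
        assert abs(afc(x, y, a)) <= abs(math.log2(x / y)) + 1e-12
        if max(x, y) >= a:
            assert afc(x, y, a) == pytest.approx(math.log2(x / y), rel=1e-9, abs=1e-12)


class TestPdsTransform:
    def test_unit_afc_default_sensitivity(self):
        assert pds_transform(1, k=2) == pytest.approx(0.7616, abs=5e-5)

    def test_zero_maps_to_zero(self):
        assert pds_transform(0.0, 2.0) == 0.0

    @settings(max_examples=60, derandomize=True)
    @given(st.floats(-8, 8, allow_nan=False), st.floats(0.1, 2.5))
    def test_odd_increasing_bounded(self, x, k):
        y = pds_transform(x, k)
        assert -1.0 < y < 1.0
        assert pds_transform(-x, k) == pytest.approx(-y, abs=1e-12)
        assert pds_transform(x + 0.1, k) > y


class TestBenjaminiHochberg:
    def test_step_up_small_example(self):
        np.testing.assert_allclose(adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_constant_vectors(self):
        np.testing.assert_allclose(adjust_bh([0.2]), [0.2])
        np.testing.assert_allclose(adjust_bh([0.4, 0.4, 0.4]), [0.4, 0.4, 0.4])

    def test_matches_hand_rolled_step_up(self):
        def bh_oracle(ps):
            ps = np.asarray(ps, dtype=float)
            n = len(ps)
            order = np.argsort(ps)
            adj = np.empty(n)
            running = 1.0
            for rank in range(n, 0, -1):
                i = order[rank - 1]
                running = min(running, ps[i] * n / rank)
                adj[i] = running
            return np.clip(adj, 0, 1)

        rng = np.random.default_rng(0)
        for _ in range(20):
            ps = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(adjust_bh(ps), bh_oracle(ps), atol=1e-12)

    def test_nan_passthrough(self):
        out = adjust_bh([0.01, np.nan, 0.5])
        assert np.isnan(out[1]) and not np.isnan(out[0])


class TestExclusivenessIndex:
    def test_alpha_dominant_group_scores_one(self):
        ae = {"focal": 10.0, "b": 0.5, "c": 0.2}
        assert exclusiveness_index(ae, "focal", alpha=10) == 1.0

    def test_flat_expression_scores_zero(self):
        assert exclusiveness_index({"a": 2.0, "b": 2.0}, "a") == 0.0

    def test_minimum_group_scores_zero(self):
        assert exclusiveness_index({"a": 1.0, "b": 5.0, "c": 9.0}, "a") == 0.0

    def test_intermediate_rescaling_capped(self):
        ae = {"a": 3.0, "b": 1.0, "c": 5.0}
        assert exclusiveness_index(ae, "a") == pytest.approx(0.99 * (3 - 1) / (5 - 1))
        # the maximum without alpha-dominance stays below 1
        assert exclusiveness_index(ae, "c") == pytest.approx(0.99)

    def test_tied_maxima_cannot_reach_one(self):
        # second order statistic equals the max -> alpha-dominance impossible
        ae = {"a": 5.0, "b": 5.0, "c": 0.1}
        assert exclusiveness_index(ae, "a", alpha=10) == pytest.approx(0.99)

    @settings(max_examples=60, derandomize=True)
    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=6))
    def test_bounded_unit_interval(self, vals):
        ae = {f"g{i}": v for i, v in enumerate(vals)}
        for grp in ae:
            assert 0.0 <= exclusiveness_index(ae, grp) <= 1.0


class TestKinaseScores:
    def test_sik_score_extremes_and_single_pair(self):
        assert sik_score([(1, 1.0)] * 6) == 1.0
        assert sik_score([(0, 0.9)] * 6) == 0.0
        pairs = [(1, 0.6)] + [(0, 0.0)] * 5
        assert sik_score(pairs) == pytest.approx(0.1)

    def test_sik_score_requires_six_pairs(self):
        with pytest.raises(ValueError):
            sik_score([(1, 1.0)] * 5)

    @pytest.mark.parametrize(
        "ds,sik,expected",
        [(0.3, (0.5, 0.1), 0.5), (0.0, (0.4, 0.2), 0.3), (-0.3, (0.5, 0.1), 0.1)],
    )
    def test_k_pds_three_branches(self, ds, sik, expected):
        assert k_pds(ds, *sik) == pytest.approx(expected)

    def test_identify_kinases_membership_and_srk(self):
        pathway = {"ligand": "L", "receptor": "R", "em": "E", "target": "T"}
        ei = {"c1": {"E": 0.8, "X": 0.4}, "c2": {"E": 0.2, "X": 0.9}}
        pairs, srk = identify_kinases(
            pathway,
            frozenset({("E", "T")}),
            {"T": {"E"}, "R": {"X"}},
            ei,
        )
        chis = [chi for chi, _ in pairs["c1"]]
        assert chis == [0, 0, 1, 0, 0, 0]  # only the EM->T pair is predicted
        assert pairs["c1"][2] == (1, 0.8)
        assert pairs["c2"][2] == (1, 0.2)
        # X phosphorylates the receptor but is not a pathway member -> SrK
        assert srk == "receptor:X(0.900)"

    def test_pathway_member_kinase_not_an_srk(self):
        pathway = {"ligand": "L", "receptor": "R", "em": "E", "target": "T"}
        pairs, srk = identify_kinases(
            pathway, frozenset({("E", "T")}), {"T": {"E"}}, {"c1": {"E": 1.0}}
        )
        assert srk == ""

    def test_empty_predictions(self):
        pathway = {"ligand": "L", "receptor": "R", "em": "E", "target": "T"}
        pairs, srk = identify_kinases(pathway, frozenset(), {}, {"c1": {}})
        assert all(chi == 0 for chi, _ in pairs["c1"]) and srk == ""
        assert sik_score(pairs["c1"]) == 0.0


class TestScoreComposition:
    def test_multimodal_reduces_to_transcriptomic(self):
        assert ds_multimodal(0.42, None, None, None, CFG) == 0.42

    def test_multimodal_weighted_sum(self):
        assert ds_multimodal(0.2, 0.5, None, None, CFG) == pytest.approx(0.45)

    def test_opposing_modalities_counteract(self):
        with_support = ds_multimodal(0.5, 0.4, None, None, CFG)
        with_conflict = ds_multimodal(0.5, -0.4, None, None, CFG)
        assert abs(with_conflict) < 0.5 < abs(with_support)

    def test_pds_sign_aware_vs_literal(self):
        assert pds(0.5, 0.4, CFG) == pytest.approx(0.7)
        assert pds(0.5, 0.0, CFG) == pytest.approx(0.5)
        assert pds(-0.5, 0.4, CFG) == pytest.approx(-0.7)
        literal = ScoringConfig(pds_literal=True)
        assert pds(-0.5, 0.4, literal) == pytest.approx(-0.3)


def _two_group_data(rng, n_genes=4, n_cells=40, effect=None):
    # baseline around 0.4 keeps Hill products near the half-saturation point
    vals = 0.4 * rng.lognormal(0, 0.3, size=(n_genes, 2 * n_cells))
    groups = ["a"] * n_cells + ["b"] * n_cells
    if effect:
        # receiver-group (b) elevation of receptor/EM/target only
        vals[1:, n_cells:] *= effect
    expr, ann = tiny_expression(vals, groups, ["x"] * 2 * n_cells)
    return expr, ann


PATHWAY = {
    "sender_group": "a",
    "receiver_group": "b",
    "ligand": "g0",
    "receptor": "g1",
    "em": "g2",
    "target": "g3",
}


class TestPermutationTest:
    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(0)
        expr, ann = _two_group_data(rng)
        cfg = ScoringConfig(seed=5, m_permutations=20)
        p1, perms1 = permutation_pvalue(expr, ann, PATHWAY, "x", cfg)
        p2, perms2 = permutation_pvalue(expr, ann, PATHWAY, "x", cfg)
        assert p1 == p2 and perms1 == perms2

    def test_strong_group_effect_detected(self):
        rng = np.random.default_rng(1)
        expr, ann = _two_group_data(rng, effect=6.0)
        cfg = ScoringConfig(seed=5, m_permutations=50)
        p, _ = permutation_pvalue(expr, ann, PATHWAY, "x", cfg)
        assert p == 0.0

    def test_identical_cells_tie_gives_zero(self):
        # all permuted probabilities equal the observed one; the strict
        # inequality in the counting rule then yields p = 0
        vals = np.ones((4, 20))
        expr, ann = tiny_expression(vals, ["a", "b"] * 10, ["x"] * 20)
        cfg = ScoringConfig(seed=0, m_permutations=10)
        p, perms = permutation_pvalue(expr, ann, PATHWAY, "x", cfg)
        assert p == 0.0
        assert len(set(np.round(perms, 12))) == 1

    def test_single_group_flagged_undefined(self):
        rng = np.random.default_rng(2)
        vals = rng.lognormal(0, 0.5, size=(4, 10))
        expr, ann = tiny_expression(vals, ["a"] * 10, ["x"] * 10)
        p, _ = permutation_pvalue(expr, ann, PATHWAY | {"receiver_group": "a", "sender_group": "a"}, "x", ScoringConfig())
        assert math.isnan(p)


class TestScoreAll:
    def _table(self):
        return PathwayTable(table=pd.DataFrame([PATHWAY], columns=PATHWAY_COLUMNS))

    def test_empty_pathway_table(self):
        from incytr.scoring import SCORE_COLUMNS

        rng = np.random.default_rng(0)
        vals = rng.lognormal(0, 0.5, size=(4, 8))
        expr, ann = tiny_expression(vals, ["a", "b"] * 4, ["x", "x", "y", "y"] * 2)
        out = score_all(PathwayTable(table=pd.DataFrame(columns=PATHWAY_COLUMNS)), expr, ann, ScoringConfig(m_permutations=5))
        assert out.empty and list(out.columns) == SCORE_COLUMNS

    def test_identical_conditions_give_zero_t_pds(self):
        rng = np.random.default_rng(3)
        half = rng.lognormal(0, 0.5, size=(4, 20))
        vals = np.concatenate([half, half], axis=1)
        groups = (["a"] * 10 + ["b"] * 10) * 2
        conds = ["x"] * 20 + ["y"] * 20
        expr, ann = tiny_expression(vals, groups, conds)
        out = score_all(self._table(), expr, ann, ScoringConfig(m_permutations=5))
        assert out["T_PDS"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out["afc_P"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_condition_swap_flips_t_pds_sign(self):
        rng = np.random.default_rng(4)
        vals = rng.lognormal(0, 0.5, size=(4, 40))
        vals[:, :10] *= 4.0  # condition x, group a+b cells elevated? keep simple: x elevated
        groups = (["a"] * 10 + ["b"] * 10) * 2
        conds = ["x"] * 20 + ["y"] * 20
        expr, ann = tiny_expression(vals, groups, conds)
        cfg1 = ScoringConfig(m_permutations=5, conditions=("x", "y"))
        cfg2 = ScoringConfig(m_permutations=5, conditions=("y", "x"))
        out1 = score_all(self._table(), expr, ann, cfg1)
        out2 = score_all(self._table(), expr, ann, cfg2)
        assert out1["T_PDS"].iloc[0] == pytest.approx(-out2["T_PDS"].iloc[0], abs=1e-9)

    def test_bit_reproducible_under_seed(self):
        rng = np.random.default_rng(5)
        vals = rng.lognormal(0, 0.5, size=(4, 40))
        groups = (["a"] * 10 + ["b"] * 10) * 2
        conds = ["x"] * 20 + ["y"] * 20
        expr, ann = tiny_expression(vals, groups, conds)
        cfg = ScoringConfig(m_permutations=10, seed=9)
        out1 = score_all(self._table(), expr, ann, cfg)
        out2 = score_all(self._table(), expr, ann, cfg)
        pd.testing.assert_frame_equal(out1, out2)

    def test_score_ranges(self):
        rng = np.random.default_rng(6)
        vals = rng.lognormal(0, 0.8, size=(4, 60))
        groups = (["a"] * 15 + ["b"] * 15) * 2
        conds = ["x"] * 30 + ["y"] * 30
        expr, ann = tiny_expression(vals, groups, conds)
        out = score_all(self._table(), expr, ann, ScoringConfig(m_permutations=10))
        r = out.iloc[0]
        assert 0 <= r["P_cond1"] < 1 and 0 <= r["P_cond2"] < 1
        assert 0 <= r["pval_cond1"] <= 1
        assert -1 < r["T_PDS"] < 1
        assert 0 <= r["K_PDS"] <= 1
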