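"""Conditional-probability, McNemar and FDR contracts against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from ebmseq import atlas as atlas_mod, pairwise, synthetic
from ebmseq.progression import modal_sequence, simulate, SimulationConfig


def counting_conditional(w, X, Y):
    """Oracle: enumerate patients with binary weights."""
    x = w[X].to_numpy() > 0.5
    y = w[Y].to_numpy() > 0.5
    denom = np.sum(~y)
    return np.sum(x & ~y) / denom if denom else 0.0


class TestConditionalProbability:
    def test_counting_example(self):
        # 3 patients X+Y-, 1 X-Y+, 6 X-Y-, 0 X+Y+
        w = pd.DataFrame(
            {"X": [1, 1, 1, 0, 0, 0, 0, 0, 0, 0], "Y": [0, 0, 0, 1, 0, 0, 0, 0, 0, 0]},
            dtype=float,
        )
        assert pairwise.conditional_probability(w, "X", "Y") == pytest.approx(3 / 9)

    def test_fuzzy_hand_arithmetic(self):
        w = pd.DataFrame({"X": [0.5, 0.5], "Y": [0.5, 0.5]})
        # P(X+ and Y-) = 0.25, P(Y-) = 0.5
        assert pairwise.conditional_probability(w, "X", "Y") == pytest.approx(0.5)

    def test_all_zero_weights(self):
        w = pd.DataFrame({"X": [0.0, 0.0], "Y": [0.0, 0.0]})
        assert pairwise.conditional_probability(w, "X", "Y") == 0.0

    def test_saturated_conditioning_event_returns_zero(self):
        w = pd.DataFrame({"X": [0.3, 0.7], "Y": [1.0, 1.0]})
        assert pairwise.conditional_probability(w, "X", "Y") == 0.0

    def test_same_event_rejected(self):
        w = pd.DataFrame({"X": [0.1]})
        with pytest.raises(ValueError):
            pairwise.conditional_probability(w, "X", "X")

    def test_matches_counting_on_binary_fixture(self, binary_fixture):
        w = binary_fixture
        for X in w.columns:
            for Y in w.columns:
                if X == Y:
                    continue
                assert pairwise.conditional_probability(w, X, Y) == pytest.approx(
                    counting_conditional(w, X, Y)
                )

    def test_matrix_agrees_with_scalar(self, binary_fixture):
        mat = pairwise.conditional_probability_matrix(binary_fixture)
        for X in binary_fixture.columns:
            for Y in binary_fixture.columns:
                if X != Y:
                    assert mat.loc[X, Y] == pytest.approx(
                        pairwise.conditional_probability(binary_fixture, X, Y)
                    )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_law_of_total_probability(self, seed):
        """P(X+|Y-)P(Y-) + P(X-|Y-)P(Y-) = P(Y-) for fuzzy weights."""
        rng = np.random.default_rng(seed)
        w = pd.DataFrame(rng.random((6, 3)), columns=list("abc"))
        for X in "abc":
            for Y in "abc":
                if X == Y:
                    continue
                p_y_minus = float((1 - w[Y]).mean())
                p_x_plus = pairwise.conditional_probability(w, X, Y)
                p_x_minus = float(((1 - w[X]) * (1 - w[Y])).mean()) / p_y_minus
                assert p_x_plus * p_y_minus + p_x_minus * p_y_minus == pytest.approx(p_y_minus)


def binary_pair(b, c, n_extra=6):
    """Weight table with b X+Y- patients, c X-Y+ patients, rest double-negative."""
    rows = [(1.0, 0.0)] * b + [(0.0, 1.0)] * c + [(0.0, 0.0)] * n_extra
    return pd.DataFrame(rows, columns=["X", "Y"])


class TestMcNemar:
    @pytest.mark.parametrize(
        "b, c, p_expected, direction",
        [
            (4, 4, 1.0, 0),
            (3, 1, 0.625, 1),   # 2 * P(Bin(4, 1/2) >= 3) = 10/16
            (0, 0, 1.0, 0),
            (1, 3, 0.625, -1),
        ],
    )
    def test_exact_branch_hand_values(self, b, c, p_expected, direction):
        stat, p, d = pairwise.mcnemar_pair(binary_pair(b, c), "X", "Y")
        assert p == pytest.approx(p_expected)
        assert d == direction

    @pytest.mark.parametrize("b, c", [(3, 1), (10, 5), (30, 10), (40, 38)])
    def test_matches_statsmodels(self, b, c):
        """Dual route: statsmodels' mcnemar with the same exact/chi2 switch."""
        stat, p, _ = pairwise.mcnemar_pair(binary_pair(b, c), "X", "Y")
        exact = (b + c) < pairwise.EXACT_SWITCH
        table = [[0, b], [c, 0]]
        ref = sm_mcnemar(table, exact=exact, correction=True)
        assert p == pytest.approx(ref.pvalue)

    def test_swap_symmetry(self, binary_fixture):
        for X, Y in [("e0", "e3"), ("e1", "e5")]:
            _, p_xy, d_xy = pairwise.mcnemar_pair(binary_fixture, X, Y)
            _, p_yx, d_yx = pairwise.mcnemar_pair(binary_fixture, Y, X)
            assert p_xy == pytest.approx(p_yx)
            assert d_xy == -d_yx


def bh_oracle(p):
    """Brute-force Benjamini-Hochberg step-up."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestFdr:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.05], [0.05]),
            ([0.01, 0.02, 0.9], [0.03, 0.03, 0.9]),
            ([], []),
        ],
    )
    def test_hand_cases(self, p, expected):
        np.testing.assert_allclose(pairwise.fdr_adjust(p), expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            pairwise.fdr_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_matches_oracle_and_never_decreases(self, p):
        adj = pairwise.fdr_adjust(p)
        np.testing.assert_allclose(adj, bh_oracle(p), atol=1e-12)
        assert (adj >= np.asarray(p) - 1e-12).all()
        assert (adj <= 1.0).all()


class TestCrossTissue:
    def test_single_pair_mean_is_the_value(self):
        w = pd.DataFrame({"g": [0.8, 0.1], "m": [0.2, 0.0]})
        atlas = pd.DataFrame(
            {"region_id": ["g", "m"], "region_name": ["g", "m"], "tissue": ["GM", "WM"]}
        )
        cpt = pairwise.build_cpt(w, atlas, pairs="cross_tissue")
        res = pairwise.cross_tissue_summary(cpt, atlas).summary.set_index("region_id")
        assert res.loc["g", "precedence"] == pytest.approx(
            pairwise.conditional_probability(w, "g", "m")
        )

    def test_constant_table_gives_constant_means(self):
        atlas = atlas_mod.synthetic_atlas(2, 3)
        events = atlas["region_id"].tolist()
        cond = pd.DataFrame(0.4, index=events, columns=events)
        np.fill_diagonal(cond.to_numpy(), np.nan)
        cpt = pairwise.ConditionalProbabilityTable(
            cond=cond, marginals=pd.Series(0.5, index=events),
            tests=pd.DataFrame(columns=["X", "Y", "direction", "significant"]),
            fdr_level=0.05,
        )
        res = pairwise.cross_tissue_summary(cpt, atlas).summary
        np.testing.assert_allclose(res["precedence"], 0.4)
        np.testing.assert_allclose(res["difference"], 0.0, atol=1e-12)

    def test_means_match_brute_force(self):
        rng = np.random.default_rng(3)
        atlas = atlas_mod.synthetic_atlas(3, 4)
        w = pd.DataFrame(rng.random((15, 7)), columns=atlas["region_id"])
        cpt = pairwise.build_cpt(w, atlas, pairs="cross_tissue")
        res = pairwise.cross_tissue_summary(cpt, atlas).summary.set_index("region_id")
        gm = atlas[atlas["tissue"] == "GM"]["region_id"]
        wm = atlas[atlas["tissue"] == "WM"]["region_id"]
        for g in gm:
            brute = np.mean([pairwise.conditional_probability(w, g, y) for y in wm])
            assert res.loc[g, "precedence"] == pytest.approx(brute)
        for y in wm:
            brute = np.mean([pairwise.conditional_probability(w, y, g) for g in gm])
            assert res.loc[y, "precedence"] == pytest.approx(brute)

    def test_single_tissue_rejected(self):
        atlas = atlas_mod.synthetic_atlas(3, 0)
        w = pd.DataFrame(np.eye(3), columns=atlas["region_id"])
        with pytest.raises(ValueError):
            pairwise.build_cpt(w, atlas, pairs="cross_tissue")


class TestCensus:
    def test_no_significant_pairs(self):
        rng = np.random.default_rng(0)
        atlas = atlas_mod.synthetic_atlas(2, 2)
        # symmetric noise: nothing should be significant
        w = pd.DataFrame(rng.random((8, 4)).round(), columns=atlas["region_id"])
        cpt = pairwise.build_cpt(w, atlas, pairs="cross_tissue")
        census = pairwise.pairwise_significance_census(cpt, atlas)
        assert census.total_pairs == 4
        assert census.wm_precedes_gm == 0 and census.gm_precedes_wm == 0

    def test_wm_first_guttman_points_one_way(self, guttman_cohort):
        """WM events planted before GM: every significant pair says WM precedes."""
        cfg, _, gt, w = guttman_cohort
        atlas = cfg.resolve_atlas()
        cpt = pairwise.build_cpt(w, atlas, pairs="cross_tissue")
        census = pairwise.pairwise_significance_census(cpt, atlas)
        assert census.total_pairs == cfg.n_gm_regions * cfg.n_wm_regions
        assert census.gm_precedes_wm == 0
        assert census.wm_precedes_gm > 0

    def test_ordered_totals(self, binary_fixture):
        cpt = pairwise.build_cpt(binary_fixture, pairs="all")
        sig, total = pairwise.all_regions_census(cpt)
        assert total == 6 * 5
        assert sig % 2 == 0
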