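import logging

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dpcnet import corrnet
from dpcnet.config import SignificanceConfig
from dpcnet.datatypes import DataError, ExpressionMatrix, SampleGroups


def _expr(values: np.ndarray, groups: dict[str, str]) -> tuple[ExpressionMatrix, SampleGroups]:
    values = values - values.min() + 0.01  # FPKM scale is non-negative
    samples = list(groups)
    genes = [f"g{i}" for i in range(values.shape[0])]
    return (
        ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples)),
        SampleGroups(groups),
    )


def residual_partial_oracle(x, y, z):
    """Partial correlation via regression residuals — the brute-force route."""
    rx = x - np.polyval(np.polyfit(z, x, 1), z)
    ry = y - np.polyval(np.polyfit(z, y, 1), z)
    return np.corrcoef(rx, ry)[0, 1]


class TestPearson:
    def test_identity_and_antisymmetry(self):
        x = np.arange(10, dtype=float)
        assert corrnet.pearson_r_p(x, x) == (1.0, 0.0)
        r, p = corrnet.pearson_r_p(x, -x)
        assert r == -1.0 and p == 0.0

    def test_p_value_matches_t_distribution_oracle(self):
        # r = 0.6 at n = 27: t = 0.6*sqrt(25)/0.8 = 3.75 on 25 df
        rng = np.random.default_rng(3)
        # construct vectors with sample correlation exactly 0.6 via Gram-Schmidt
        x = rng.standard_normal(27)
        e = rng.standard_normal(27)
        x = (x - x.mean()) / x.std()
        e -= e.mean() + (e @ x / (x @ x)) * x
        e /= e.std()
        y = 0.6 * x + np.sqrt(1 - 0.36) * e
        r, p = corrnet.pearson_r_p(x, y)
        assert r == pytest.approx(0.6, abs=1e-12)
        assert p == pytest.approx(9.387786152672149e-04, rel=1e-9)

    def test_matches_scipy_pearsonr(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            x, y = rng.standard_normal((2, 15))
            r, p = corrnet.pearson_r_p(x, y)
            ref = stats.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_vector_is_non_significant(self, caplog):
        with caplog.at_level(logging.WARNING):
            r, p = corrnet.pearson_r_p(np.ones(5), np.arange(5.0))
        assert (r, p) == (0.0, 1.0)


class TestAdjustments:
    @pytest.mark.parametrize(
        "p_in,expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.5], [0.5]),
            ([0.001, 0.04], [0.002, 0.04]),
        ],
    )
    def test_bh_step_up_examples(self, p_in, expected):
        assert corrnet.bh_adjust(p_in) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "p_in,expected",
        [([0.001] + [0.5] * 9, [0.01] + [1.0] * 9), ([0.2] * 10, [1.0] * 10), ([0.3], [0.3])],
    )
    def test_bonferroni_examples(self, p_in, expected):
        assert corrnet.bonferroni_adjust(p_in) == pytest.approx(expected)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40), st.randoms())
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_adjustments_match_statsmodels(self, p, _):
        from statsmodels.stats.multitest import multipletests

        p = np.asarray(p)
        assert corrnet.bh_adjust(p) == pytest.approx(
            multipletests(p, method="fdr_bh")[1], abs=1e-12
        )
        assert corrnet.bonferroni_adjust(p) == pytest.approx(
            multipletests(p, method="bonferroni")[1], abs=1e-12
        )

    def test_rejects_invalid_probabilities(self):
        with pytest.raises(DataError):
            corrnet.bh_adjust([0.5, 1.5])


class TestFirstOrderPartial:
    @pytest.mark.parametrize(
        "r_ij,r_ik,r_jk,expected",
        [
            (0.8, 0.5, 0.5, 0.55 / 0.75),
            (0.6, 0.0, 0.0, 0.6),
            (0.42, 0.6, 0.7, 0.0),
        ],
    )
    def test_hand_examples(self, r_ij, r_ik, r_jk, expected):
        assert corrnet.first_order_partial(r_ij, r_ik, r_jk) == pytest.approx(expected)

    def test_degenerate_conditioning_raises(self):
        with pytest.raises(DataError, match="degenerate"):
            corrnet.first_order_partial(0.5, 1.0, 0.2)

    def test_agrees_with_residual_regression_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            x, y, z = rng.standard_normal((3, 30))
            r_ij = np.corrcoef(x, y)[0, 1]
            r_ik = np.corrcoef(x, z)[0, 1]
            r_jk = np.corrcoef(y, z)[0, 1]
            ours = corrnet.first_order_partial(r_ij, r_ik, r_jk)
            assert ours == pytest.approx(residual_partial_oracle(x, y, z), abs=1e-10)


class TestPartialT:
    @pytest.mark.parametrize(
        "r,n,q,t_expected",
        [
            (0.5, 52, 1, 4.041451884327381),
            (0.0, 20, 1, 0.0),
            (0.7, 12, 1, 2.94058817645882),
        ],
    )
    def test_hand_examples(self, r, n, q, t_expected):
        t, p = corrnet.partial_t_statistic(r, n, q)
        assert t == pytest.approx(t_expected, abs=1e-12)
        if r == 0:
            assert p == 1.0

    def test_perfect_correlation_gives_zero_p(self):
        t, p = corrnet.partial_t_statistic(1.0, 10, 1)
        assert p == 0.0

    def test_insufficient_samples_error(self):
        with pytest.raises(DataError, match="order"):
            corrnet.partial_t_statistic(0.5, 3, 1)


class TestEdgePartialTest:
    def test_min_abs_partial_candidate_selected(self):
        rng = np.random.default_rng(8)
        vals = rng.standard_normal((4, 40))
        groups = {f"s{i}": "tumor" for i in range(40)}
        expr, sg = _expr(vals, groups)
        pccn = nx.Graph()
        # edge (g0, g1) with both g2 and g3 as common neighbors
        for e in [("g0", "g1"), ("g0", "g2"), ("g1", "g2"), ("g0", "g3"), ("g1", "g3")]:
            pccn.add_edge(*e)
        cache = corrnet.PearsonCache(expr, sg, "tumor")
        res = corrnet.edge_partial_test(("g0", "g1"), pccn, cache)
        # brute-force the expected selection
        r01 = cache.r("g0", "g1")
        parts = {
            k: corrnet.first_order_partial(r01, cache.r("g0", k), cache.r("g1", k))
            for k in ("g2", "g3")
        }
        k_best = min(sorted(parts), key=lambda k: abs(parts[k]))
        assert res.k_selected == k_best
        assert res.r_partial == pytest.approx(parts[k_best])
        assert res.order == 1

    def test_no_common_neighbor_falls_back_to_zero_order(self):
        rng = np.random.default_rng(9)
        expr, sg = _expr(rng.standard_normal((2, 10)), {f"s{i}": "tumor" for i in range(10)})
        pccn = nx.Graph()
        pccn.add_edge("g0", "g1")
        cache = corrnet.PearsonCache(expr, sg, "tumor")
        res = corrnet.edge_partial_test(("g0", "g1"), pccn, cache)
        assert res.order == 0 and res.k_selected is None
        assert res.r_partial == pytest.approx(cache.r("g0", "g1"))

    def test_chain_confound_collapses_under_conditioning(self):
        rng = np.random.default_rng(10)
        n = 200
        k = rng.standard_normal(n)
        i = 0.8 * k + 0.6 * rng.standard_normal(n)
        j = 0.8 * k + 0.6 * rng.standard_normal(n)
        vals = np.vstack([i, k, j])
        expr, sg = _expr(vals, {f"s{x}": "tumor" for x in range(n)})
        pccn = nx.Graph()
        pccn.add_edge("g0", "g2")
        pccn.add_edge("g0", "g1")
        pccn.add_edge("g1", "g2")
        cache = corrnet.PearsonCache(expr, sg, "tumor")
        assert abs(cache.r("g0", "g2")) > 0.3  # marginally correlated
        res = corrnet.edge_partial_test(("g0", "g2"), pccn, cache)
        assert res.k_selected == "g1"
        assert abs(res.r_partial) < 0.15


class TestNetworkBuilders:
    def test_planted_pair_survives_among_nulls(self):
        rng = np.random.default_rng(12)
        n = 50
        x = rng.standard_normal(n)
        y = 0.9 * x + np.sqrt(1 - 0.81) * rng.standard_normal(n)
        nulls = rng.standard_normal((100, n))
        vals = np.vstack([x, y, nulls])
        expr, sg = _expr(vals, {f"s{i}": "tumor" for i in range(n)})
        bg = nx.Graph()
        bg.add_edge("g0", "g1", confidence=900)
        for i in range(2, 101):
            bg.add_edge(f"g{i}", f"g{i + 1}", confidence=900)
        net = corrnet.build_pccn(expr, bg, sg, "tumor")
        assert net.has_edge("g0", "g1")

    def test_null_network_keeps_few_edges(self):
        rng = np.random.default_rng(13)
        kept = []
        for _ in range(200):
            vals = rng.standard_normal((20, 30))
            expr, sg = _expr(vals, {f"s{i}": "tumor" for i in range(30)})
            bg = nx.Graph()
            for i in range(0, 20, 2):
                bg.add_edge(f"g{i}", f"g{i + 1}", confidence=900)
            net = corrnet.build_pccn(expr, bg, sg, "tumor")
            kept.append(net.number_of_edges() / bg.number_of_edges())
        assert np.mean(kept) <= 0.01  # BH controls the expected kept fraction

    def test_empty_background_gives_empty_networks(self, toy_expr, toy_groups):
        net = corrnet.build_pccn(toy_expr, nx.Graph(), toy_groups, "tumor")
        assert net.number_of_edges() == 0
        pcorn = corrnet.build_pcorn(net, toy_expr, toy_groups, "tumor")
        assert pcorn.number_of_edges() == 0

    def test_group_too_small_errors(self, toy_expr):
        sg = SampleGroups({s: ("tumor" if i < 2 else "normal")
                           for i, s in enumerate(toy_expr.samples)})
        with pytest.raises(DataError, match="at least 3"):
            corrnet.build_pccn(toy_expr, nx.Graph(), sg, "tumor")

    def test_pcorn_subset_of_pccn_and_chain_edge_removed(self):
        rng = np.random.default_rng(14)
        n = 200
        k = rng.standard_normal(n)
        i = 0.85 * k + 0.5 * rng.standard_normal(n)
        j = 0.85 * k + 0.5 * rng.standard_normal(n)
        direct_a = rng.standard_normal(n)
        direct_b = 0.8 * direct_a + 0.6 * rng.standard_normal(n)
        vals = np.vstack([i, k, j, direct_a, direct_b])
        expr, sg = _expr(vals, {f"s{x}": "tumor" for x in range(n)})
        bg = nx.Graph()
        for e in [("g0", "g1"), ("g1", "g2"), ("g0", "g2"), ("g3", "g4")]:
            bg.add_edge(*e, confidence=900)
        pccn = corrnet.build_pccn(expr, bg, sg, "tumor")
        pcorn = corrnet.build_pcorn(pccn, expr, sg, "tumor")
        pccn_edges = set(map(frozenset, pccn.edges()))
        pcorn_edges = set(map(frozenset, pcorn.edges()))
        assert pcorn_edges <= pccn_edges
        assert frozenset(("g0", "g2")) in pccn_edges  # confound in PCCN...
        assert frozenset(("g0", "g2")) not in pcorn_edges  # ...removed by PCORN
        assert frozenset(("g3", "g4")) in pcorn_edges  # direct edge retained
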