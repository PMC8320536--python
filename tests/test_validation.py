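import itertools
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dpcnet import validation
from dpcnet.datatypes import DataError, ExpressionMatrix, SampleGroups


def enumeration_tail(N, M, n, x):
    """Exact tail by enumerating every size-n draw from N items (M successes)."""
    hit = total = 0
    for comb in itertools.combinations(range(N), n):
        total += 1
        if sum(1 for c in comb if c < M) >= x:
            hit += 1
    return Fraction(hit, total)


class TestHypergeomTail:
    @pytest.mark.parametrize(
        "N,M,n,x,expected",
        [(10, 4, 3, 2, Fraction(1, 3)), (6, 3, 3, 3, Fraction(1, 20))],
    )
    def test_known_exact_values(self, N, M, n, x, expected):
        assert validation.hypergeom_tail(N, M, n, x) == pytest.approx(float(expected), rel=1e-12)

    def test_zero_overlap_gives_one(self):
        assert validation.hypergeom_tail(100, 10, 5, 0) == 1.0

    @pytest.mark.parametrize("N,M,n", [(8, 3, 4), (10, 5, 5), (12, 6, 3), (11, 2, 7)])
    def test_matches_full_enumeration(self, N, M, n):
        for x in range(min(M, n) + 1):
            expected = float(enumeration_tail(N, M, n, x))
            assert validation.hypergeom_tail(N, M, n, x) == pytest.approx(expected, rel=1e-10)

    def test_matches_reference_sf_for_large_universe(self):
        for N, M, n, x in [(19600, 723, 15, 9), (100000, 500, 50, 5), (16264, 531, 15, 4)]:
            ref = stats.hypergeom.sf(x - 1, N, M, n)
            assert validation.hypergeom_tail(N, M, n, x) == pytest.approx(ref, abs=1e-12)

    def test_infeasible_overlap_errors(self):
        with pytest.raises(DataError, match="infeasible"):
            validation.hypergeom_tail(10, 3, 4, 5)


def _two_group_expr(shift, n_per_group=40, n_genes=8, seed=0):
    rng = np.random.default_rng(seed)
    samples = [f"T{i}" for i in range(n_per_group)] + [f"N{i}" for i in range(n_per_group)]
    groups = SampleGroups({s: ("tumor" if s.startswith("T") else "normal") for s in samples})
    vals = rng.lognormal(1.0, 0.5, size=(n_genes, 2 * n_per_group))
    vals[:, :n_per_group] *= np.exp(shift)
    expr = ExpressionMatrix(pd.DataFrame(vals, index=[f"g{i}" for i in range(n_genes)],
                                         columns=samples))
    return expr, groups


class TestClassifyCv:
    def test_separable_data_has_near_perfect_auc(self):
        expr, groups = _two_group_expr(shift=2.0)
        rep = validation.classify_cv(expr, set(expr.genes), groups, seed=0)
        assert rep.auc >= 0.99
        assert rep.fold_count == 5 and rep.oversampled

    def test_auc_invariant_under_monotone_score_transform(self):
        expr, groups = _two_group_expr(shift=0.5)
        rep = validation.classify_cv(expr, set(expr.genes), groups, seed=1)
        from sklearn.metrics import roc_auc_score

        transformed = np.tanh(rep.scores) + 3.0
        assert roc_auc_score(rep.y_true, transformed) == pytest.approx(rep.auc, abs=1e-12)

    def test_roc_points_monotone(self):
        expr, groups = _two_group_expr(shift=1.0)
        rep = validation.classify_cv(expr, set(expr.genes), groups, seed=2)
        fpr = [p[0] for p in rep.roc_points]
        tpr = [p[1] for p in rep.roc_points]
        assert fpr == sorted(fpr) and tpr == sorted(tpr)

    def test_too_many_folds_for_minority_errors(self):
        expr, groups = _two_group_expr(shift=1.0, n_per_group=4)
        with pytest.raises(DataError, match="folds"):
            validation.classify_cv(expr, set(expr.genes), groups, folds=5)

    def test_unknown_gene_errors(self):
        expr, groups = _two_group_expr(shift=1.0)
        with pytest.raises(DataError, match="not in expression"):
            validation.classify_cv(expr, {"nope"}, groups)


class TestClusterSamples:
    def test_separated_blobs_recover_normals_perfectly(self):
        expr, groups = _two_group_expr(shift=4.0, seed=3)
        rep = validation.cluster_samples(expr, set(expr.genes), groups)
        assert rep.normal_cluster_recall == 1.0
        assert rep.linkage == "single" and rep.metric == "cityblock"
        assert len(set(rep.cluster_assignment.values())) == 2

    def test_invariant_to_sample_order(self):
        expr, groups = _two_group_expr(shift=4.0, seed=4)
        rep1 = validation.cluster_samples(expr, set(expr.genes), groups)
        shuffled = ExpressionMatrix(expr.values[list(reversed(expr.samples))])
        rep2 = validation.cluster_samples(shuffled, set(expr.genes), groups)
        assert rep1.normal_cluster_recall == rep2.normal_cluster_recall

    def test_degenerate_identical_vectors_warn(self, caplog):
        import logging

        samples = ["T0", "T1", "N0", "N1"]
        groups = SampleGroups({"T0": "tumor", "T1": "tumor", "N0": "normal", "N1": "normal"})
        expr = ExpressionMatrix(pd.DataFrame(np.ones((3, 4)),
                                             index=["a", "b", "c"], columns=samples))
        with caplog.at_level(logging.WARNING):
            rep = validation.cluster_samples(expr, {"a", "b", "c"}, groups)
        assert any("degenerate" in r.message for r in caplog.records)
        assert 0.0 <= rep.normal_cluster_recall <= 1.0


class TestPerGeneDifferentialTest:
    def test_mean_shift_detected(self):
        expr, groups = _two_group_expr(shift=3.0, n_per_group=50, seed=5)
        table = validation.per_gene_differential_test(expr, set(expr.genes), groups)
        assert (table["p"] < 1e-6).all()
        assert (table["direction"] == "up_in_tumor").all()

    def test_matches_welch_formula_on_toy_vectors(self):
        samples = ["T0", "T1", "T2", "N0", "N1", "N2"]
        groups = SampleGroups({s: ("tumor" if s.startswith("T") else "normal") for s in samples})
        xt, xn = np.array([3.0, 4.0, 5.0]), np.array([1.0, 2.0, 3.0])
        expr = ExpressionMatrix(pd.DataFrame([np.concatenate([xt, xn])],
                                             index=["g"], columns=samples))
        table = validation.per_gene_differential_test(expr, {"g"}, groups)
        # hand Welch t: equal variances 1, n = 3 each -> t = 2 / sqrt(2/3)
        assert table.loc[0, "t"] == pytest.approx(2.0 / np.sqrt(2.0 / 3.0))

    def test_null_data_not_significant(self):
        expr, groups = _two_group_expr(shift=0.0, n_per_group=50, seed=6)
        table = validation.per_gene_differential_test(expr, set(expr.genes), groups)
        assert (table["p"] > 0.01).any()  # no systematic signal at this seed


class TestEnrichmentTest:
    def test_counts_restricted_to_universe(self):
        universe = {f"g{i}" for i in range(100)}
        predicted = {"g1", "g2", "g3", "outside"}
        reference = {"g1", "g2", "g50", "also_outside"}
        res = validation.enrichment_test(predicted, reference, universe)
        assert (res.N, res.M, res.n, res.x) == (100, 3, 3, 2)
        assert 0 < res.p < 1
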