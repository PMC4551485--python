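"""Permutation tests, FDR adjustment, DE tests, and rankings."""

import numpy as np
import pytest

from conftest import random_graph
from coexgraph import CoExpressionGraph
from coexgraph.coexpression import AssociationConfig
from coexgraph.data_io import ExpressionMatrix, GeneSetCollection, PhenotypeLabels
from coexgraph import testing as tst


def make_expr(values: np.ndarray) -> ExpressionMatrix:
    g, s = values.shape
    return ExpressionMatrix(values, [f"G{i}" for i in range(g)], [f"S{j}" for j in range(s)])


def make_labels(n1: int, n2: int) -> PhenotypeLabels:
    assignment = {f"S{j}": ("A" if j < n1 else "B") for j in range(n1 + n2)}
    return PhenotypeLabels(assignment)


@pytest.fixture
def mirrored_expr():
    """Both phenotypes see identical sample data (columns duplicated)."""
    rng = np.random.default_rng(10)
    half = rng.standard_normal((8, 5))
    return make_expr(np.hstack([half, half])), make_labels(5, 5)


class TestObservedStatistic:
    def test_identical_groups_give_zero_entropy_diff(self, mirrored_expr):
        expr, labels = mirrored_expr
        theta = tst.observed_statistic(expr, labels, expr.gene_ids, kind="entropy_absdiff")
        assert theta == pytest.approx(0.0, abs=1e-10)

    def test_invariant_to_label_swap(self, mirrored_expr):
        expr, _ = mirrored_expr
        rng = np.random.default_rng(11)
        expr = make_expr(rng.standard_normal((8, 10)))
        fwd = make_labels(5, 5)
        swapped = PhenotypeLabels({s: ("B" if v == "A" else "A")
                                   for s, v in fwd.assignment.items()})
        t1 = tst.observed_statistic(expr, fwd, expr.gene_ids)
        t2 = tst.observed_statistic(expr, swapped, expr.gene_ids)
        assert t1 == pytest.approx(t2, abs=1e-12)

    def test_scrambling_one_group_raises_statistic(self):
        rng = np.random.default_rng(12)
        # 20 correlated genes: shared latent factor
        latent = rng.standard_normal(40)
        base = 0.8 * latent + 0.6 * rng.standard_normal((20, 40))
        theta_null = tst.observed_statistic(make_expr(base), make_labels(20, 20),
                                            [f"G{i}" for i in range(20)])
        scrambled = base.copy()
        for i in range(20):
            scrambled[i, 20:] = scrambled[i, 20 + rng.permutation(20)]
        theta_alt = tst.observed_statistic(make_expr(scrambled), make_labels(20, 20),
                                           [f"G{i}" for i in range(20)])
        assert theta_alt > theta_null

    def test_undersized_set_rejected(self, mirrored_expr):
        expr, labels = mirrored_expr
        with pytest.raises(ValueError, match="at least 2"):
            tst.observed_statistic(expr, labels, ["G0"])


class TestPermutationTest:
    def test_p_value_formula(self, monkeypatch, mirrored_expr):
        expr, labels = mirrored_expr
        # scripted statistics: observed first, then B permuted values
        script = iter([1.0, 0.2, 0.5, 0.9])
        monkeypatch.setattr(tst, "_statistic", lambda *a, **k: next(script))
        res = tst.permutation_test(expr, labels, expr.gene_ids, B=3, seed=0)
        assert res.p_value == pytest.approx(1.0 / 4.0)

    def test_all_permutations_tie_gives_p_one(self, mirrored_expr):
        # identical group data: theta_obs = 0, every permuted theta >= 0
        expr, labels = mirrored_expr
        res = tst.permutation_test(expr, labels, expr.gene_ids, B=3, seed=5,
                                   kind="entropy_absdiff")
        assert res.p_value == 1.0

    def test_same_seed_bitwise_identical(self, mirrored_expr):
        expr, labels = mirrored_expr
        rng = np.random.default_rng(13)
        expr = make_expr(rng.standard_normal((6, 12)))
        labels = make_labels(6, 6)
        r1 = tst.permutation_test(expr, labels, expr.gene_ids, B=25, seed=99)
        r2 = tst.permutation_test(expr, labels, expr.gene_ids, B=25, seed=99)
        assert r1.p_value == r2.p_value
        assert r1.statistic == r2.statistic

    def test_p_values_on_permutation_lattice(self):
        rng = np.random.default_rng(14)
        B = 19
        for seed in range(5):
            expr = make_expr(rng.standard_normal((5, 10)))
            res = tst.permutation_test(expr, make_labels(5, 5), expr.gene_ids,
                                       B=B, seed=seed)
            lattice = np.arange(1, B + 2) / (B + 1)
            assert np.isclose(lattice, res.p_value).any()

    def test_monotone_statistic_rescaling_keeps_p(self, monkeypatch):
        rng = np.random.default_rng(15)
        expr = make_expr(rng.standard_normal((6, 14)))
        labels = make_labels(7, 7)
        base = tst.permutation_test(expr, labels, expr.gene_ids, B=30, seed=3)
        orig = tst._statistic
        monkeypatch.setattr(tst, "_statistic", lambda *a, **k: 10.0 * orig(*a, **k))
        scaled = tst.permutation_test(expr, labels, expr.gene_ids, B=30, seed=3)
        assert scaled.p_value == base.p_value

    def test_null_p_values_superuniform(self):
        # two groups drawn from one pool: rejection rate tracks alpha
        rng = np.random.default_rng(16)
        B = 39
        pvals = np.array([
            tst.permutation_test(make_expr(rng.standard_normal((8, 16))),
                                 make_labels(8, 8),
                                 [f"G{i}" for i in range(8)],
                                 B=B, seed=rep).p_value
            for rep in range(200)
        ])
        for alpha in (0.05, 0.1, 0.2):
            rate = (pvals <= alpha).mean()
            se = np.sqrt(alpha * (1 - alpha) / 200)
            assert abs(rate - alpha) <= 3 * se


class TestBHAdjust:
    def test_hand_step_up(self):
        np.testing.assert_allclose(tst.bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(tst.bh_adjust([0.37]), [0.37])

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(tst.bh_adjust([0.2] * 5), [0.2] * 5)

    def test_matches_brute_force_oracle(self, rng):
        def oracle(p):
            m = len(p)
            order = np.argsort(p)
            q = np.empty(m)
            for pos, idx in enumerate(order):
                # min over tail of scaled order statistics
                tail = [p[order[j]] * m / (j + 1) for j in range(pos, m)]
                q[idx] = min(1.0, min(tail))
            return q

        for _ in range(50):
            p = rng.uniform(0, 1, rng.integers(1, 25))
            np.testing.assert_allclose(tst.bh_adjust(p), oracle(p), atol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(0, 1, 40)
        _, q, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(tst.bh_adjust(p), q, atol=1e-12)


class TestAnalyzeCollection:
    def _setup(self, rng, n_genes=35, n_samples=14):
        expr = make_expr(rng.standard_normal((n_genes, n_samples)))
        labels = make_labels(n_samples // 2, n_samples - n_samples // 2)
        coll = GeneSetCollection()
        coll.add("big_a", "", [f"G{i}" for i in range(25)])
        coll.add("small", "", [f"G{i}" for i in range(10)])
        coll.add("big_b", "", [f"G{i}" for i in range(5, 35)])
        return expr, labels, coll

    def test_min_size_filter(self, rng):
        expr, labels, coll = self._setup(rng)
        results = tst.analyze_collection(expr, labels, coll, B=9, min_size=20, seed=1)
        assert sorted(r.set_name for r in results) == ["big_a", "big_b"]
        assert all(r.set_size >= 20 for r in results)

    def test_q_values_are_bh_of_p_column(self, rng):
        expr, labels, coll = self._setup(rng)
        results = tst.analyze_collection(expr, labels, coll, B=9, min_size=10, seed=1)
        qs = tst.bh_adjust([r.p_value for r in results])
        np.testing.assert_allclose([r.q_value for r in results], qs)

    def test_deterministic_under_seed(self, rng):
        expr, labels, coll = self._setup(rng)
        r1 = tst.analyze_collection(expr, labels, coll, B=9, min_size=10, seed=4)
        r2 = tst.analyze_collection(expr, labels, coll, B=9, min_size=10, seed=4)
        assert [(r.set_name, r.p_value, r.q_value) for r in r1] == \
               [(r.set_name, r.p_value, r.q_value) for r in r2]

    def test_adding_a_set_does_not_perturb_other_p_values(self, rng):
        expr, labels, coll = self._setup(rng)
        r1 = {r.set_name: r.p_value
              for r in tst.analyze_collection(expr, labels, coll, B=9, min_size=10, seed=4)}
        coll.add("extra", "", [f"G{i}" for i in range(12, 32)])
        r2 = {r.set_name: r.p_value
              for r in tst.analyze_collection(expr, labels, coll, B=9, min_size=10, seed=4)}
        for name, p in r1.items():
            assert r2[name] == p

    def test_no_surviving_sets_rejected(self, rng):
        expr, labels, coll = self._setup(rng)
        with pytest.raises(ValueError, match="no gene set"):
            tst.analyze_collection(expr, labels, coll, B=9, min_size=100, seed=1)


class TestDifferentialExpression:
    def test_identical_groups_p_one(self):
        vals = np.tile(np.array([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]]), (2, 1))
        expr = make_expr(vals)
        res = tst.differential_expression(expr, make_labels(3, 3), expr.gene_ids)
        for r in res:
            assert r.t_p == pytest.approx(1.0)
            assert r.mean_diff == pytest.approx(0.0)

    def test_strong_separation_tiny_p(self):
        rng = np.random.default_rng(17)
        vals = np.hstack([rng.normal(0, 1, (3, 50)), rng.normal(5, 1, (3, 50))])
        expr = make_expr(vals)
        res = tst.differential_expression(expr, make_labels(50, 50), expr.gene_ids)
        for r in res:
            assert r.t_p < 1e-10
            assert r.wilcoxon_p < 1e-10
            assert r.mean_diff == pytest.approx(-5.0, abs=0.8)

    def test_output_length_is_intersection_size(self):
        rng = np.random.default_rng(18)
        expr = make_expr(rng.standard_normal((6, 10)))
        res = tst.differential_expression(expr, make_labels(5, 5),
                                          ["G1", "G3", "G5", "ABSENT"])
        assert [r.gene for r in res] == ["G1", "G3", "G5"]

    def test_constant_gene_warns(self):
        vals = np.vstack([np.ones(8), np.arange(8.0)])
        expr = make_expr(vals)
        with pytest.warns(UserWarning, match="constant"):
            res = tst.differential_expression(expr, make_labels(4, 4), expr.gene_ids)
        assert res[0].t_p == 1.0


class TestRankGenes:
    def test_star_degree_ranks_center_first(self):
        A = np.zeros((4, 4))
        A[0, 1:] = A[1:, 0] = 1.0
        g = CoExpressionGraph(["hub", "a", "b", "c"], A)
        ranked = tst.rank_genes(g, "degree")
        assert ranked[0][0] == "hub"

    def test_equal_scores_alphabetical(self, unit_k3):
        g = CoExpressionGraph(["zz", "aa", "mm"], unit_k3.adjacency)
        assert [g for g, _ in tst.rank_genes(g, "degree")] == ["aa", "mm", "zz"]

    def test_ranking_is_permutation_of_nodes(self, rng):
        g = random_graph(rng, 9)
        for kind in ("degree", "eigenvector", "clustering"):
            ranked = tst.rank_genes(g, kind)
            assert sorted(g_ for g_, _ in ranked) == sorted(g.nodes)

    def test_path_kinds_require_unweighted(self):
        g = CoExpressionGraph(list("abc"), np.array([[0, 0.5, 0.5],
                                                     [0.5, 0, 0.5],
                                                     [0.5, 0.5, 0]]))
        with pytest.raises(ValueError, match="unweighted"):
            tst.rank_genes(g, "betweenness")
        with pytest.raises(ValueError, match="unknown"):
            tst.rank_genes(g, "pagerank")


class TestEdgeDifferenceMatrix:
    def test_identical_graphs_zero_matrix(self, rng):
        g = random_graph(rng, 6)
        np.testing.assert_array_equal(tst.edge_difference_matrix(g, g), np.zeros((6, 6)))

    def test_antisymmetric_under_swap(self, rng):
        g1 = random_graph(rng, 6)
        g2 = CoExpressionGraph(g1.nodes, random_graph(rng, 6).adjacency)
        np.testing.assert_array_equal(tst.edge_difference_matrix(g1, g2),
                                      -tst.edge_difference_matrix(g2, g1))

    def test_single_differing_edge(self, unit_k3):
        A = unit_k3.adjacency.copy()
        A[0, 1] = A[1, 0] = 0.3
        g2 = CoExpressionGraph(unit_k3.nodes, A)
        diff = tst.edge_difference_matrix(unit_k3, g2)
        assert (diff != 0).sum() == 2
        assert diff[0, 1] == pytest.approx(0.7)
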