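"""BC3Net inference machinery: Gaussian MI, the C3NET max-MI rule,
permutation nulls, bootstrap ensembling and the binomial edge test."""

from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bcgrn


def numeric_bivariate_gaussian_mi(rho: float, n_quad: int = 400) -> float:
    """Independent oracle: Gauss-Legendre integration of
    E[ln(f(x,y) / (f(x) f(y)))] under the standard bivariate Gaussian."""
    if rho == 0.0:
        return 0.0
    nodes, weights = np.polynomial.legendre.leggauss(n_quad)
    lim = 8.0
    x = lim * nodes
    w = lim * weights
    xx, yy = np.meshgrid(x, x, indexing="ij")
    det = 1.0 - rho**2
    log_joint = (-0.5 * (xx**2 - 2 * rho * xx * yy + yy**2) / det
                 - np.log(2 * np.pi) - 0.5 * np.log(det))
    log_marg = -0.5 * (xx**2 + yy**2) - np.log(2 * np.pi)
    joint = np.exp(log_joint)
    integrand = joint * (log_joint - log_marg)
    return float(np.einsum("i,j,ij->", w, w, integrand))


class TestGaussianMI:
    def test_independence_gives_zero(self):
        assert bcgrn.gaussian_mi(0.0) == 0.0

    def test_closed_form_value(self):
        assert bcgrn.gaussian_mi(0.9) == pytest.approx(-0.5 * np.log(0.19))
        assert bcgrn.gaussian_mi(0.9) == pytest.approx(0.8304, abs=1e-4)

    @pytest.mark.parametrize("rho", [0.0, 0.3, 0.6, 0.9])
    def test_matches_numerical_integration(self, rho):
        assert bcgrn.gaussian_mi(rho) == pytest.approx(
            numeric_bivariate_gaussian_mi(rho), abs=1e-6)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(min_value=-1.0, max_value=1.0))
    def test_sign_symmetric_and_nonnegative(self, rho):
        assert bcgrn.gaussian_mi(rho) == bcgrn.gaussian_mi(-rho)
        assert bcgrn.gaussian_mi(rho) >= 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bcgrn.gaussian_mi(1.5)


class TestMIMatrix:
    def test_duplicated_rows_hit_clamp_ceiling(self, rng):
        x = rng.normal(size=(1, 50))
        expr = pd.DataFrame(np.vstack([x, x, rng.normal(size=(1, 50))]),
                            index=["A", "B", "C"])
        mi = bcgrn.estimate_mi_matrix(expr)
        assert np.isfinite(mi.loc["A", "B"])
        assert mi.loc["A", "B"] == pytest.approx(-0.5 * np.log(1e-12))

    def test_symmetric_exactly(self, rng):
        expr = pd.DataFrame(rng.normal(size=(8, 40)))
        mi = bcgrn.estimate_mi_matrix(expr)
        assert (mi.to_numpy() == mi.to_numpy().T).all()

    def test_independent_rows_near_zero(self):
        r = np.random.default_rng(42)
        expr = pd.DataFrame(r.normal(size=(10, 1000)))
        mi = bcgrn.estimate_mi_matrix(expr).to_numpy()
        np.fill_diagonal(mi, 0.0)
        assert mi.max() < 0.01

    def test_zero_variance_gene_named(self):
        expr = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]],
                            index=["FLAT", "OK"])
        with pytest.raises(ValueError, match="FLAT"):
            bcgrn.estimate_mi_matrix(expr)


class TestMINull:
    def test_self_calibration_at_five_percent(self):
        r = np.random.default_rng(7)
        expr = pd.DataFrame(r.normal(size=(20, 100)))
        pool = bcgrn.mi_null(expr, n_resample=20_000, seed=1)
        fresh = pd.DataFrame(r.normal(size=(20, 100)))
        mi = bcgrn.estimate_mi_matrix(fresh).to_numpy()
        vals = mi[np.triu_indices(20, k=1)]
        frac = np.mean(bcgrn.empirical_pvalue(vals, pool) <= 0.05)
        assert 0.01 <= frac <= 0.10

    def test_boundary_pseudo_count(self):
        pool = np.sort(np.linspace(0.0, 0.5, 999))
        assert bcgrn.empirical_pvalue(0.9, pool) == pytest.approx(1 / 1000)

    def test_fixed_seed_identical_pool(self, rng):
        expr = pd.DataFrame(rng.normal(size=(10, 30)))
        p1 = bcgrn.mi_null(expr, n_resample=1000, seed=3)
        p2 = bcgrn.mi_null(expr, n_resample=1000, seed=3)
        assert (p1 == p2).all()


def _mi_frame(ab, ac, bc):
    m = pd.DataFrame(0.0, index=list("ABC"), columns=list("ABC"))
    m.loc["A", "B"] = m.loc["B", "A"] = ab
    m.loc["A", "C"] = m.loc["C", "A"] = ac
    m.loc["B", "C"] = m.loc["C", "B"] = bc
    return m


class TestC3Net:
    def test_per_gene_max_rule(self):
        """A picks B, B picks A, C picks B -> edges {A-B, B-C}."""
        mi = _mi_frame(0.9, 0.2, 0.5)
        permissive_null = np.zeros(10_000)  # everything significant
        g = bcgrn.c3net(mi, permissive_null, alpha=0.05)
        assert {tuple(sorted(e)) for e in g.edges()} == {("A", "B"), ("B", "C")}

    def test_nothing_significant_gives_empty_network(self):
        mi = _mi_frame(0.9, 0.2, 0.5)
        blocking_null = np.full(10_000, 5.0)  # null above every observed MI
        g = bcgrn.c3net(mi, blocking_null, alpha=0.05)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 3

    def test_edge_count_bounded_by_gene_count(self, rng):
        p = 15
        expr = pd.DataFrame(rng.normal(size=(p, 60)),
                            index=[f"G{i}" for i in range(p)])
        mi = bcgrn.estimate_mi_matrix(expr)
        g = bcgrn.c3net(mi, np.zeros(1000), alpha=0.5)
        assert g.number_of_edges() <= p


class TestBinomialEdgeTest:
    def test_maximal_count_kept(self):
        g = bcgrn.binomial_edge_test({("A", "B"): 100}, B=100,
                                     ensemble_alpha=0.05, p0=0.2)
        assert g.has_edge("A", "B")

    def test_tail_probability_matches_exact_summation(self):
        """k=10, B=100, p0=0.01: a ~1e-7 tail, kept at alpha=0.05.

        (The Poisson approximation puts this tail at 1.1e-7; the exact
        binomial summation gives 7.63e-8.)"""
        p = Fraction(1, 100)
        exact = sum(comb(100, i) * p**i * (1 - p)**(100 - i)
                    for i in range(10, 101))
        assert float(exact) == pytest.approx(7.631587e-8, rel=1e-5)
        from scipy import stats
        assert float(stats.binom.sf(9, 100, 0.01)) == pytest.approx(
            float(exact), abs=1e-12)
        g = bcgrn.binomial_edge_test({("A", "B"): 10}, B=100, p0=0.01)
        assert g.has_edge("A", "B")

    def test_sub_null_count_dropped(self):
        g = bcgrn.binomial_edge_test({("A", "B"): 1}, B=100, p0=0.5)
        assert not g.has_edge("A", "B")

    def test_monotone_in_alpha_and_count(self):
        freq = {("A", "B"): 9, ("C", "D"): 3, ("E", "F"): 1}
        kept = {}
        for alpha in (0.01, 0.05, 0.2):
            g = bcgrn.binomial_edge_test(freq, B=10, ensemble_alpha=alpha,
                                         p0=0.3)
            kept[alpha] = {tuple(sorted(e)) for e in g.edges()}
        assert kept[0.01] <= kept[0.05] <= kept[0.2]
        # raising a count never flips kept -> dropped
        for k in range(1, 11):
            g = bcgrn.binomial_edge_test({("A", "B"): k}, B=10, p0=0.3)
            if k > 1 and prev_kept:
                assert g.has_edge("A", "B")
            prev_kept = g.has_edge("A", "B")


@pytest.fixture(scope="module")
def small_expr():
    net = bcgrn.generate_network(30, model="random", mean_degree=2, seed=2)
    truth = bcgrn.PlantedTruth(network=net, edge_strength=0.8)
    return bcgrn.simulate_expression(truth, n_samples=100, seed=3), net


class TestEnsemble:

    def test_member_count_and_gene_set(self, small_expr):
        expr, _ = small_expr
        members = bcgrn.bootstrap_ensemble(expr, B=5, seed=4,
                                           null_pool_size=2000)
        assert len(members) == 5
        assert all(set(m.nodes()) == set(expr.index) for m in members)

    def test_fixed_seed_identical_ensemble(self, small_expr):
        expr, _ = small_expr
        e1 = bcgrn.bootstrap_ensemble(expr, B=3, seed=8, null_pool_size=2000)
        e2 = bcgrn.bootstrap_ensemble(expr, B=3, seed=8, null_pool_size=2000)
        for a, b in zip(e1, e2):
            assert set(a.edges()) == set(b.edges())

    def test_true_edges_more_frequent_than_non_edges(self, small_expr):
        expr, net = small_expr
        members = bcgrn.bootstrap_ensemble(expr, B=10, seed=5,
                                           null_pool_size=5000)
        freq = bcgrn.aggregate(members)
        true_edges = {tuple(sorted(e)) for e in net.edges()}
        f_true = np.mean([freq.get(e, 0) for e in true_edges])
        non = [e for e in freq if e not in true_edges]
        f_non = np.mean([freq[e] for e in non]) if non else 0.0
        assert f_true > f_non

    def test_final_network_subset_of_union(self, small_expr):
        expr, _ = small_expr
        g, freq = bcgrn.bc3net(expr, B=5, seed=6, null_pool_size=2000)
        final = {tuple(sorted(e)) for e in g.edges()}
        assert final <= set(freq)
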