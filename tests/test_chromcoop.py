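"""Chromosome cooperation: interaction counts and the gene-label
permutation test."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import bcgrn


def _catalog(assignment):
    return pd.DataFrame(
        {"chromosome": list(assignment.values()), "census": 0},
        index=pd.Index(list(assignment.keys()), name="gene"))


class TestIntraFraction:
    def test_all_one_chromosome(self):
        g = nx.Graph([("A", "B"), ("B", "C")])
        cat = _catalog({"A": "1", "B": "1", "C": "1"})
        assert bcgrn.intra_fraction(g, cat) == 1.0

    def test_one_of_five_intra(self):
        g = nx.Graph([("A", "B"), ("A", "C"), ("A", "D"), ("A", "E"),
                      ("B", "C")])
        cat = _catalog({"A": "1", "B": "2", "C": "2", "D": "3", "E": "4"})
        # only B-C shares a chromosome
        assert bcgrn.intra_fraction(g, cat) == pytest.approx(0.2)

    def test_missing_gene_named(self):
        g = nx.Graph([("A", "B")])
        cat = _catalog({"A": "1"})
        with pytest.raises(KeyError, match="B"):
            bcgrn.intra_fraction(g, cat)

    def test_uniform_assignment_fraction_near_reciprocal_c(self):
        """Uniform labels over c equal chromosomes give intra fraction
        ~1/c (analytic expectation, checked by simulation at c=4)."""
        g = bcgrn.generate_network(400, model="random", mean_degree=4, seed=0)
        rng = np.random.default_rng(1)
        genes = sorted(g.nodes())
        cat = _catalog({x: str(rng.integers(1, 5)) for x in genes})
        frac = bcgrn.intra_fraction(g, cat)
        assert frac == pytest.approx(0.25, abs=0.06)


class TestPairCounts:
    def test_single_cross_edge(self):
        g = nx.Graph([("A", "B")])
        cat = _catalog({"A": "4", "B": "21"})
        s = bcgrn.chrom_pair_counts(g, cat)
        assert s.loc["4", "21"] == 1
        assert s.loc["21", "4"] == 1
        assert s.to_numpy().sum() == 2  # one symmetric off-diagonal entry

    def test_triangle_within_y(self):
        g = nx.Graph([("A", "B"), ("B", "C"), ("A", "C")])
        cat = _catalog({"A": "Y", "B": "Y", "C": "Y"})
        s = bcgrn.chrom_pair_counts(g, cat)
        assert s.loc["Y", "Y"] == 3

    def test_conservation_upper_triangle_sums_to_edge_count(self, planted):
        s = bcgrn.chrom_pair_counts(planted["network"], planted["catalog"])
        arr = s.to_numpy()
        iu = np.triu_indices(24)
        assert arr[iu].sum() == planted["network"].number_of_edges()


class TestPermutationPvalue:
    def test_strict_exceedance_example(self):
        assert bcgrn.permutation_pvalue(4, [2, 3, 5, 7]) == 0.5

    def test_observed_above_all_replicates_gives_zero(self):
        assert bcgrn.permutation_pvalue(9, [2, 3, 5, 7]) == 0.0

    def test_zero_observed_is_never_an_excess(self):
        assert bcgrn.permutation_pvalue(0, [0, 0, 0, 0]) == 1.0

    def test_smoothed_variant_uses_ties_and_pseudocount(self):
        assert bcgrn.permutation_pvalue(4, [2, 3, 5, 7], smoothed=True) \
            == pytest.approx(3 / 5)
        assert bcgrn.permutation_pvalue(0, [0, 0, 0, 0], smoothed=True) == 1.0


class TestPermutationTest:
    def test_three_hundred_pairs_tested(self, planted):
        res = bcgrn.permutation_test(planted["network"], planted["catalog"],
                                     E=50, seed=0)
        assert len(res) == 300  # (24^2 - 24)/2 + 24

    def test_null_mean_scales_with_chromosome_sizes(self):
        """Under label permutation the expected pair count follows the
        product of chromosome gene counts (analytic expectation for a
        fixed graph)."""
        g = bcgrn.generate_network(120, model="random", mean_degree=4, seed=3)
        genes = sorted(g.nodes())
        # chromosome 1 gets 60 genes, 2 gets 40, 3 gets 20
        assignment = {x: "1" for x in genes[:60]}
        assignment.update({x: "2" for x in genes[60:100]})
        assignment.update({x: "3" for x in genes[100:]})
        cat = _catalog(assignment)
        res = bcgrn.permutation_test(g, cat, E=3000, seed=4)
        n = len(genes)
        n_edges = g.number_of_edges()
        sizes = {"1": 60, "2": 40, "3": 20}
        for t in res:
            if t.chrom_i in sizes and t.chrom_j in sizes:
                ni, nj = sizes[t.chrom_i], sizes[t.chrom_j]
                if t.chrom_i == t.chrom_j:
                    expect = n_edges * ni * (ni - 1) / (n * (n - 1))
                else:
                    expect = n_edges * 2 * ni * nj / (n * (n - 1))
                assert t.s_null_mean == pytest.approx(expect, rel=0.15)

    def test_planted_pair_discovered_null_pairs_not(self):
        net = bcgrn.generate_network(200, model="random", mean_degree=3,
                                     seed=7)
        cat = bcgrn.generate_catalog(net.nodes(), coop_pairs=[("4", "21")],
                                     seed=8, network=net, coop_fraction=0.2)
        res = bcgrn.permutation_test(net, cat, E=2000, seed=9)
        sig = {(t.chrom_i, t.chrom_j) for t in res if t.significant}
        assert ("4", "21") in sig

    def test_smoothed_null_calibration(self):
        discoveries = 0
        for rep in range(3):
            g = bcgrn.generate_network(200, model="random", mean_degree=3,
                                       seed=20 + rep)
            cat = bcgrn.generate_catalog(g.nodes(), seed=30 + rep)
            res = bcgrn.permutation_test(g, cat, E=1000, seed=rep,
                                         smoothed=True)
            discoveries += sum(t.significant for t in res)
        assert discoveries == 0

    def test_invalid_chromosome_rejected(self):
        g = nx.Graph([("A", "B")])
        cat = pd.DataFrame({"chromosome": ["1", "25"], "census": 0},
                           index=pd.Index(["A", "B"], name="gene"))
        with pytest.raises(ValueError):
            bcgrn.permutation_test(g, cat, E=10)
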