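"""Chromosome-cooperation permutation test with a planted positive.

Genes are assigned to the 24 chromosomes (realistically uneven sizes);
20% of the network's edges are then relabelled to join chromosomes 4 and
21.  Permuting gene labels E times while holding the graph fixed yields
each chromosome pair's own null interaction-count distribution; the
planted pair should be the (only) BH-significant one.
"""

import bcgrn

net = bcgrn.generate_network(200, model="random", mean_degree=3, seed=7)
catalog = bcgrn.generate_catalog(net.nodes(), coop_pairs=[("4", "21")],
                                 seed=8, network=net, coop_fraction=0.2)

frac = bcgrn.intra_fraction(net, catalog)
print(f"intra-chromosome (cis) edge fraction: {frac:.3f}")

tests = bcgrn.permutation_test(net, catalog, E=2000, seed=9)
sig = [t for t in tests if t.significant]
print(f"{len(tests)} chromosome pairs tested, {len(sig)} significant:")
for t in sig:
    print(f"  chr{t.chrom_i}-chr{t.chrom_j}: observed {t.s_observed} edges, "
          f"null mean {t.s_null_mean:.1f}, p={t.p_value:.4g} "
          f"(BH {t.p_adjusted:.4g})")
print("-> the planted 4-21 pair carries far more edges than label")
print("   permutation can explain; every other pair is consistent with")
print("   its own chromosome-size-aware null.")
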