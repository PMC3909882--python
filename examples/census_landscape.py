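"""Landscape of census (cancer) genes inside a network.

With a census gene set in hand, the module answers: how close are census
genes to each other compared with arbitrary gene pairs (empirical
closeness test with BH correction), which census genes are directly
wired (components), and which genes act as hubs on the shortest paths
connecting census pairs (path-union degree ranking)?
"""

import numpy as np

import bcgrn

net = bcgrn.generate_network(150, model="scale-free", mean_degree=2, seed=2)
gcc = bcgrn.giant_component(net)
rng = np.random.default_rng(3)
census = sorted(rng.choice(sorted(gcc.nodes()), size=12, replace=False))

table = bcgrn.pairwise_path_table(net, census)
print("closest census pairs:")
print(table.head(5).to_string(index=False))

tests = bcgrn.closeness_test(net, census, smoothed=True)
n_sig = sum(t.significant for t in tests)
print(f"\ncloseness test: {len(tests)} pairs, {n_sig} significantly closer "
      "than the network background (expected ~0 for random labels)")

components = bcgrn.census_components(net, census)
print(f"directly-connected census components: {components}")

_, ranking = bcgrn.census_path_union(net, census)
print("\ntop hubs of the census-pair shortest-path network:")
print(ranking.head(5).to_string(index=False))
print("-> high-degree nodes here sit on many census-to-census geodesics,")
print("   making them candidate mediators between disease genes.")
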