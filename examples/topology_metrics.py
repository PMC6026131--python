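"""Backbone/offshoot decomposition and loop metrics of one network.

The backbone is the loop-bearing (bridgeless) core closed by the
anastomoses; offshoots are the short bridge subtrees that leave it and
dive into cortex as penetrating arterioles.
"""

import numpy as np

from pialnet import GeneratorParams, generate_animal_network, generate_geometry
from pialnet.topology import (attachment_region, decompose, identify_lma_edges,
                              loop_count, vertex_offshoot_ratio,
                              watershed_polyline)

params = GeneratorParams(seed=7)
rng = np.random.default_rng(7)
regions = generate_geometry(params, rng)
sample = generate_animal_network(regions, params, "sham", rng)
net = sample.network

print(f"nodes: {len(net.nodes)}, edges: {len(net.edges)}")
print(f"independent loops (anastomoses): {loop_count(net)}")

geo = identify_lma_edges(net, mode="geometric")
truth = sample.truth.lma_edge_ids
print(f"geometric LMA detection: {len(geo & truth)}/{len(truth)} recovered, "
      f"{len(geo - truth)} false positives")

dec = decompose(net)
print(f"backbone edges: {len(dec.backbone_edge_ids)}, "
      f"offshoots: {len(dec.offshoots)}")
ratios = vertex_offshoot_ratio(dec, attachment_region(dec, net, regions),
                               regions=sorted(regions.regions))
for rid, r in ratios.items():
    val = f"{r.ratio:.2f}" if r.defined else "undefined"
    print(f"  vertices/offshoot in {rid:<9}: {val}  ({r.n_offshoots} offshoots)")
# ratios near 1 + 2*offshoot_bifurcation_prob: most offshoots carry a
# single PA; a quarter carry a bifurcation with two.

ws = watershed_polyline(net, regions)
print(f"watershed line through {len(ws)} bisected cross-territory LMAs")
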