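"""Generate a random spatial multi-layer network and pick a disaster
epicenter.

Nodes are scattered in the unit square, linked whenever they fall within
the radius solved for the target mean degree, then stitched together
with minimum-spanning-tree edges so trade and migration can reach every
node.  Half of the nodes produce mostly food.
"""

import numpy as np

from vrank_cascade import (
    epicenter_radius_for_fraction,
    generate_network,
    normalized_distances,
    select_epicenter,
)

net = generate_network(n_nodes=80, food_frac=0.5, target_mean_degree=8, seed=0)
deg = net.degree()
print(f"nodes: {net.n_nodes}, food producers: {net.is_food.sum()}")
print(f"mean degree {deg.mean():.2f} (min {deg.min()}, max {deg.max()}), "
      f"connected: {net.is_connected()}")

center = (0.25, 0.25)  # centroid of the low corner quadrant
radius = epicenter_radius_for_fraction(net, center, 0.2)
epicenter = select_epicenter(net, center, radius)
print(f"epicenter: radius {radius:.3f} holds {len(epicenter)} nodes, "
      f"{net.is_food[epicenter].sum()} of them food producers (these get shocked)")

nd = normalized_distances(net, int(epicenter[0]))
print(f"node {epicenter[0]} neighbor distance fractions (farthest = 1): "
      + ", ".join(f"{j}:{v:.2f}" for j, v in sorted(nd.items())))
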