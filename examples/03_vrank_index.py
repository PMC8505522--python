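"""The VRank vulnerability index: closed form and a shocked trajectory.

VRank is the dampened geometric mean of a node's own minimum-bundle
cost-to-income ratio and its neighborhood's aggregate ratio; higher
means more vulnerable.  On an all-identical network with ratio r it is
exactly r * sqrt(beta).
"""

import numpy as np

from vrank_cascade import generate_network, run, vrank_panel, vrank_values
from vrank_cascade.fixtures import experiment_scenario
from vrank_cascade.metrics import node_distance_to_epicenter

# closed form on an identical network
net = generate_network(80, 0.5, 8, seed=0)
r, c_bar = 0.5, 0.35
vr, own, nbr, _ = vrank_values(
    np.full(80, r * 0.82 / c_bar), np.full(80, 0.82), np.full(80, 100.0),
    net, c_bar, beta_damp=0.85,
)
print(f"identical nodes at ratio {r}: VRank = {vr[0]:.6f} "
      f"(closed form r*sqrt(0.85) = {r * np.sqrt(0.85):.6f})")

# spatial gradient after an 80% food shock
traj = run(experiment_scenario(seed=0))
panel = vrank_panel(traj)
dist = node_distance_to_epicenter(traj.net, traj.epicenter)
post = panel[panel.tick > traj.shock_tick].copy()
post["band"] = np.where(dist[post["node"]] <= 0.33, "near",
                        np.where(dist[post["node"]] >= 0.67, "far", "mid"))
for band in ("near", "mid", "far"):
    v = post[post.band == band]["vrank_pct_change"].mean()
    print(f"mean post-shock VRank change, {band:>4} band: {v:+.2f}%")
print("vulnerability rises most where the disaster struck and decays with "
      "distance — but it does spill over, carried by trade and migration")
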