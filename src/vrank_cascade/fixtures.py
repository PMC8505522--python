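"""Deterministic tiny networks and scenario presets.

These fixtures make every module testable with hand-checkable arithmetic:
a two-node pair (one food, one non-food producer) with a configurable
wage gap, a hub-and-leaves star that exercises share normalization, and
the default experiment scenario (80 nodes, half food producers, shock
levels 40-80%, ten network seeds).

Expected values attached to each fixture carry provenance tags so
regression tests never assert a number whose origin is unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .config import (
    ConvergenceParams,
    DiffusionParams,
    EconomyParams,
    NetworkParams,
    ScenarioConfig,
    ShockParams,
)
from .errors import ConfigurationError
from .netgen import LAYERS, MultiLayerNetwork

__all__ = ["Fixture", "two_node_fixture", "star_fixture", "experiment_scenario", "FIXTURES"]


@dataclass
class Fixture:
    """A named deterministic network + initial conditions + expectations.

    ``expected`` maps a short key to ``{"value": ..., "provenance": ...}``
    where provenance is one of "trivial" (direct arithmetic), "derived"
    (computed by the brute-force oracle in the test tree) or "worked
    example" (a published illustration of the method).
    """

    name: str
    net: MultiLayerNetwork
    config: ScenarioConfig
    initial_L: np.ndarray | None = None
    expected: dict = field(default_factory=dict)


def _net_from_coords(coords: np.ndarray, is_food: np.ndarray, edges) -> MultiLayerNetwork:
    n = coords.shape[0]
    adj = np.zeros((n, n), dtype=bool)
    for u, v in edges:
        adj[u, v] = adj[v, u] = True
    return MultiLayerNetwork(
        coords=coords,
        is_food=is_food,
        layers={name: adj.copy() for name in LAYERS},
        dist=squareform(pdist(coords)),
    )


def two_node_fixture(wage_gap: float = 0.5) -> Fixture:
    """One food and one non-food node joined by a single link.

    ``wage_gap`` is the initial relative wage advantage of the non-food
    node, produced by giving it fewer workers: L_1 = L0 / (1 + gap), so
    w_1 = (1 + gap) * w_0.  Under tick iteration the real-wage gap decays
    monotonically toward the equal-real-wage fixed point; total labor is
    conserved exactly.  gap = 0 is a zero-flow fixed point by symmetry.
    """
    if wage_gap < 0:
        raise ConfigurationError(f"wage_gap must be >= 0, got {wage_gap}")
    coords = np.array([[0.25, 0.5], [0.75, 0.5]])
    net = _net_from_coords(coords, np.array([True, False]), [(0, 1)])
    cfg = ScenarioConfig(
        network=NetworkParams(n_nodes=2),
        shock=ShockParams(magnitude=0.0, center=(0.25, 0.5), radius=0.05, t_shock=500),
        convergence=ConvergenceParams(t_max=1000),
    ).validate()
    L0 = cfg.economy.L0
    initial_L = np.array([L0, L0 / (1.0 + wage_gap)])
    return Fixture(
        name="two_node",
        net=net,
        config=cfg,
        initial_L=initial_L,
        expected={
            "total_labor": {
                "value": float(initial_L.sum()),
                "provenance": "trivial: conservation",
            },
            "zero_gap_net_flow": {
                "value": 0.0,
                "provenance": "trivial: symmetric fixed point",
            },
            "wage_gap_decay": {
                "value": "monotone",
                "provenance": "derived: brute-force iteration (tests/oracles.py)",
            },
        },
    )


#: the published share-normalization illustration: a four-neighbor
#: probability vector and the destination shares it implies.
WORKED_EXAMPLE_PROBS = (0.2, 0.5, 0.7, 0.7)
WORKED_EXAMPLE_SHARES_2DP = (0.10, 0.24, 0.33, 0.33)


def star_fixture(n_leaves: int = 4) -> Fixture:
    """A hub with ``n_leaves`` identical leaves at unit distance.

    Identical leaves must receive equal shares 1/n of anything the hub
    diffuses; injecting the four-destination worked-example probability
    vector {0.2, 0.5, 0.7, 0.7} must yield shares {0.10, 0.24, 0.33,
    0.33} after 2-dp rounding (vector sum 2.1).
    """
    if n_leaves < 2:
        raise ConfigurationError(f"n_leaves must be >= 2, got {n_leaves}")
    angles = 2 * np.pi * np.arange(n_leaves) / n_leaves
    r = 0.4
    coords = np.vstack([[0.5, 0.5], np.column_stack(
        [0.5 + r * np.cos(angles), 0.5 + r * np.sin(angles)])])
    is_food = np.zeros(n_leaves + 1, dtype=bool)
    is_food[0] = True  # food hub, non-food leaves
    net = _net_from_coords(coords, is_food, [(0, j) for j in range(1, n_leaves + 1)])
    cfg = ScenarioConfig(
        network=NetworkParams(n_nodes=n_leaves + 1),
        shock=ShockParams(magnitude=0.0, center=(0.5, 0.5), radius=0.05, t_shock=500),
        convergence=ConvergenceParams(t_max=1000),
    ).validate()
    return Fixture(
        name="star",
        net=net,
        config=cfg,
        expected={
            "equal_leaf_share": {
                "value": 1.0 / n_leaves,
                "provenance": "trivial: identical leaves",
            },
            "worked_example_shares": {
                "value": list(WORKED_EXAMPLE_SHARES_2DP),
                "provenance": "worked example: probabilities {0.2,0.5,0.7,0.7}, sum 2.1",
            },
        },
    )


def experiment_scenario(seed: int = 0) -> ScenarioConfig:
    """The default experiment scenario: 80-node networks, 50% food
    producers, shock grid {0.4, ..., 0.8} x 10 network seeds (50 runs),
    VRank dampening 0.85."""
    return ScenarioConfig(
        network=NetworkParams(n_nodes=80, food_frac=0.5, target_mean_degree=8.0),
        economy=EconomyParams(),
        diffusion=DiffusionParams(),
        shock=ShockParams(magnitude=0.8),
        convergence=ConvergenceParams(),
        seed=seed,
    ).validate()


FIXTURES = {
    "two_node": two_node_fixture,
    "star": star_fixture,
}
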