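"""Random spatial multi-layer network generation.

Nodes live in the unit square.  Edges come from a random-geometric rule
(connect every pair closer than a radius solved so the mean degree hits a
target), augmented with the Euclidean minimum spanning tree so that the
union graph is always connected — diffusion must be able to reach every
node.  The same base topology is replicated to the three named link sets
(population, food, nonfood goods flows); per-layer masks can thin them.

Producer types split the node set into food producers and non-food
producers (default: a random half of the nodes produce mostly food).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from .errors import ConfigurationError, IsolatedNodeError, ScenarioError

LAYERS = ("population", "food", "nonfood")

__all__ = [
    "LAYERS",
    "MultiLayerNetwork",
    "generate_network",
    "select_epicenter",
    "epicenter_radius_for_fraction",
    "normalized_distances",
]


@dataclass
class MultiLayerNetwork:
    """A node set with planar coordinates, per-layer adjacency, pairwise
    distances and producer types.

    Layer adjacency matrices are boolean, symmetric, with an empty
    diagonal (undirected topology; the flows routed on them are
    directed).
    """

    coords: np.ndarray  # (n, 2) positions in the unit square
    is_food: np.ndarray  # (n,) bool, True for food producers
    layers: dict[str, np.ndarray] = field(repr=False)  # name -> (n, n) bool
    dist: np.ndarray = field(repr=False)  # (n, n) Euclidean distances

    def __post_init__(self) -> None:
        n = self.n_nodes
        for name, adj in self.layers.items():
            if adj.shape != (n, n) or not np.array_equal(adj, adj.T):
                raise ConfigurationError(f"layer {name!r} adjacency must be symmetric {n}x{n}")
            if adj.diagonal().any():
                raise ConfigurationError(f"layer {name!r} has self-links")

    # ---- basic queries --------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return int(self.coords.shape[0])

    @property
    def nodes(self) -> np.ndarray:
        return np.arange(self.n_nodes)

    @property
    def producer_type(self) -> np.ndarray:
        return np.where(self.is_food, "food", "nonfood")

    @property
    def union_adjacency(self) -> np.ndarray:
        out = np.zeros((self.n_nodes, self.n_nodes), dtype=bool)
        for adj in self.layers.values():
            out |= adj
        return out

    def degree(self, layer: str | None = None) -> np.ndarray:
        """Per-node link count in one layer, or in the union graph."""
        adj = self.union_adjacency if layer is None else self.layers[layer]
        return adj.sum(axis=1).astype(int)

    def neighbors(self, i: int, layer: str | None = None) -> np.ndarray:
        adj = self.union_adjacency if layer is None else self.layers[layer]
        return np.flatnonzero(adj[i])

    def is_connected(self) -> bool:
        n_comp, _ = connected_components(self.union_adjacency, directed=False)
        return n_comp == 1

    # ---- tabular export / import ----------------------------------------

    def nodes_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.nodes,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "producer_type": self.producer_type,
            }
        )

    def edges_table(self) -> pd.DataFrame:
        rows = []
        for name in LAYERS:
            adj = self.layers[name]
            us, vs = np.nonzero(np.triu(adj, k=1))
            for u, v in zip(us, vs):
                rows.append((name, int(u), int(v), float(self.dist[u, v])))
        return pd.DataFrame(rows, columns=["layer", "u", "v", "distance"])

    @classmethod
    def from_tables(cls, nodes: pd.DataFrame, edges: pd.DataFrame) -> "MultiLayerNetwork":
        """Rebuild a network from node/edge tables (as written by
        :meth:`nodes_table` / :meth:`edges_table`)."""
        nodes = nodes.sort_values("id").reset_index(drop=True)
        coords = nodes[["x", "y"]].to_numpy(dtype=float)
        is_food = (nodes["producer_type"].to_numpy() == "food")
        n = len(nodes)
        dist = squareform(pdist(coords))
        layers = {name: np.zeros((n, n), dtype=bool) for name in LAYERS}
        for layer, u, v in edges[["layer", "u", "v"]].itertuples(index=False):
            layers[layer][int(u), int(v)] = True
            layers[layer][int(v), int(u)] = True
        return cls(coords=coords, is_food=is_food, layers=layers, dist=dist)

    def to_graphml(self, path) -> None:
        """Export the union graph (with layer membership edge attributes)
        in GraphML for external visualization."""
        import networkx as nx

        g = nx.Graph()
        for i in self.nodes:
            g.add_node(
                int(i),
                x=float(self.coords[i, 0]),
                y=float(self.coords[i, 1]),
                producer_type=str(self.producer_type[i]),
            )
        us, vs = np.nonzero(np.triu(self.union_adjacency, k=1))
        for u, v in zip(us, vs):
            g.add_edge(
                int(u),
                int(v),
                distance=float(self.dist[u, v]),
                **{name: bool(self.layers[name][u, v]) for name in LAYERS},
            )
        nx.write_graphml(g, path)


def _geometric_radius(dist: np.ndarray, target_mean_degree: float) -> float:
    """Radius whose distance threshold yields the target mean degree.

    Mean degree 2E/n hits the target when E = round(n * target / 2), so
    the radius is the E-th smallest pairwise distance.
    """
    n = dist.shape[0]
    condensed = np.sort(dist[np.triu_indices(n, k=1)])
    n_edges = int(round(n * target_mean_degree / 2.0))
    n_edges = min(max(n_edges, 1), condensed.size)
    return float(condensed[n_edges - 1])


def generate_network(
    n_nodes: int = 80,
    food_frac: float = 0.5,
    target_mean_degree: float = 8.0,
    seed: int = 0,
    layer_masks: dict | None = None,
) -> MultiLayerNetwork:
    """Generate a random spatial multi-layer network.

    Parameters
    ----------
    n_nodes : int
        Number of location nodes (>= 2).
    food_frac : float
        Fraction of nodes that are food producers, strictly in (0, 1);
        exactly ``floor(food_frac * n_nodes)`` nodes get the food type.
    target_mean_degree : float
        Mean degree the random-geometric radius is solved for (before
        MST augmentation, which adds at most n-1 edges).
    seed : int
        Single integer seed; identical seeds give byte-identical
        networks.
    layer_masks : dict, optional
        Optional ``{layer_name: (n, n) bool mask}`` thinning individual
        layers; the union graph is still forced connected via the MST.
    """
    if n_nodes < 2:
        raise ConfigurationError(f"n_nodes must be >= 2, got {n_nodes}")
    if not (0.0 < food_frac < 1.0):
        raise ConfigurationError(f"food_frac must lie strictly in (0, 1), got {food_frac}")
    if target_mean_degree < 2:
        raise ConfigurationError(f"target_mean_degree must be >= 2, got {target_mean_degree}")

    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, 1.0, size=(n_nodes, 2))
    dist = squareform(pdist(coords))

    radius = _geometric_radius(dist, target_mean_degree)
    adj = (dist <= radius) & ~np.eye(n_nodes, dtype=bool)

    # force connectivity with Euclidean MST edges
    mst = minimum_spanning_tree(dist).toarray()
    adj |= (mst > 0) | (mst.T > 0)

    n_food = int(np.floor(food_frac * n_nodes))
    n_food = min(max(n_food, 1), n_nodes - 1)  # keep both types present
    is_food = np.zeros(n_nodes, dtype=bool)
    is_food[rng.choice(n_nodes, size=n_food, replace=False)] = True

    layers = {}
    for name in LAYERS:
        layer_adj = adj.copy()
        if layer_masks and name in layer_masks:
            mask = np.asarray(layer_masks[name], dtype=bool)
            layer_adj &= mask & mask.T
        layers[name] = layer_adj

    return MultiLayerNetwork(coords=coords, is_food=is_food, layers=layers, dist=dist)


def select_epicenter(
    net: MultiLayerNetwork, center: tuple[float, float], radius: float
) -> np.ndarray:
    """Nodes within Euclidean ``radius`` of ``center``.

    The disaster later shocks only the food-producing members of this
    set, so an epicenter without food nodes is a scenario error (the
    shock would be a no-op).
    """
    if radius <= 0:
        raise ConfigurationError(f"epicenter radius must be positive, got {radius}")
    d = np.linalg.norm(net.coords - np.asarray(center, dtype=float), axis=1)
    members = np.flatnonzero(d <= radius)
    if members.size == 0:
        raise ScenarioError("epicenter contains no nodes")
    if not net.is_food[members].any():
        raise ScenarioError("epicenter contains no food-producing nodes; the shock would be a no-op")
    return members


def epicenter_radius_for_fraction(
    net: MultiLayerNetwork, center: tuple[float, float], node_fraction: float
) -> float:
    """Smallest radius whose epicenter circle holds at least
    ``ceil(node_fraction * n)`` nodes."""
    if not (0 < node_fraction <= 1):
        raise ConfigurationError(f"node_fraction must lie in (0, 1], got {node_fraction}")
    d = np.sort(np.linalg.norm(net.coords - np.asarray(center, dtype=float), axis=1))
    k = int(np.ceil(node_fraction * net.n_nodes))
    return float(d[k - 1])


def normalized_distances(
    net: MultiLayerNetwork, i: int, layer: str | None = None
) -> dict[int, float]:
    """Per-neighbor distance fractions d_ij / max_j d_ij in (0, 1].

    The farthest connected neighbor maps to exactly 1, so after the
    logistic reversal it carries the heaviest distance penalty.  The
    normalization is scale invariant: rescaling all coordinates leaves
    the fractions unchanged.
    """
    nbrs = net.neighbors(i, layer)
    if nbrs.size == 0:
        raise IsolatedNodeError(f"node {i} has no neighbors; cannot normalize distances")
    d = net.dist[i, nbrs]
    return {int(j): float(v) for j, v in zip(nbrs, d / d.max())}
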