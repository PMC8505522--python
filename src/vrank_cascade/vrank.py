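"""The VRank multi-layer vulnerability index.

VRank measures how hard it is for a location — and for its neighborhood,
which it depends on for imports, out-migration and income opportunities —
to afford the minimum food consumption bundle.  For node i at tick t,

    VRank_it = sqrt( (p_it * cbar_i) / (w_it * L_it)
                     * beta
                     * sum_{j!=i} p_jt * cbar_j / sum_{j!=i} w_jt * L_jt )

where p is the equal-weight price index, cbar_i = c_bar * L_i is the
node-level minimum bundle (per-worker bundle times workers, making the
ratio population-size invariant), w*L is total income, j ranges over i's
neighbors in the union graph, and beta is a dampening factor (default
0.85).  Higher VRank means higher vulnerability: the index is increasing
in own and neighborhood bundle cost and decreasing in own and
neighborhood income.  On a network of identical nodes with
cost-to-income ratio r, VRank = r * sqrt(beta) exactly.

Isolated nodes have no neighbor term; they fall back to the undamped own
ratio (strictly above the identical-network value, consistent with
isolation increasing vulnerability) and are flagged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DomainError
from .netgen import MultiLayerNetwork
from .simulator import Trajectory

__all__ = ["vrank_values", "vrank_node", "vrank_panel"]

#: incomes are floored at this value so a depopulated node yields a
#: huge-but-finite index instead of a division by zero.
INCOME_FLOOR = 1e-12


def vrank_values(
    p: np.ndarray,
    w: np.ndarray,
    L: np.ndarray,
    net: MultiLayerNetwork,
    c_bar: float,
    beta_damp: float = 0.85,
    layer: str | None = None,
):
    """Vectorized VRank for all nodes at one tick.

    Returns ``(vrank, own_ratio, neighbor_ratio, isolated)`` arrays.
    ``layer`` selects the neighborhood (default: union graph, since the
    index is explicitly multi-layer).
    """
    if beta_damp <= 0:
        raise DomainError("beta_damp must be positive")
    p = np.asarray(p, dtype=float)
    w = np.asarray(w, dtype=float)
    L = np.asarray(L, dtype=float)
    adj = net.union_adjacency if layer is None else net.layers[layer]

    bundle = p * c_bar * L  # cost of the node-level minimum bundle
    income = np.maximum(w * L, INCOME_FLOOR)
    own_ratio = bundle / income

    nbr_bundle = adj @ bundle
    nbr_income = np.maximum(adj @ income, INCOME_FLOOR)
    neighbor_ratio = nbr_bundle / nbr_income

    isolated = ~adj.any(axis=1)
    vrank = np.sqrt(own_ratio * beta_damp * neighbor_ratio)
    vrank = np.where(isolated, own_ratio, vrank)
    neighbor_ratio = np.where(isolated, np.nan, neighbor_ratio)
    return vrank, own_ratio, neighbor_ratio, isolated


def vrank_node(
    i: int,
    p: np.ndarray,
    w: np.ndarray,
    L: np.ndarray,
    net: MultiLayerNetwork,
    c_bar: float,
    beta_damp: float = 0.85,
    layer: str | None = None,
) -> float:
    """VRank of a single node (scalar convenience wrapper)."""
    vrank, _, _, _ = vrank_values(p, w, L, net, c_bar, beta_damp, layer)
    return float(vrank[i])


def vrank_panel(
    trajectory: Trajectory,
    net: MultiLayerNetwork | None = None,
    c_bar: float | None = None,
    beta_damp: float = 0.85,
    layer: str | None = None,
) -> pd.DataFrame:
    """Per-node, per-tick VRank series for a whole trajectory.

    Adds ``vrank_pct_change``: the percent change of each node's index
    relative to its own value at the last pre-shock tick (the converged
    baseline the figures report against).  For a no-shock run the percent
    change is identically zero once the system has converged.
    """
    net = net or trajectory.net
    if c_bar is None:
        c_bar = trajectory.manifest["config"]["economy"]["c_bar"]
    panel = trajectory.panel.sort_values(["tick", "node"])
    n = net.n_nodes
    ticks = panel["tick"].to_numpy()[::n]
    T = ticks.size
    adj = (net.union_adjacency if layer is None else net.layers[layer]).astype(float)

    P = panel["p"].to_numpy().reshape(T, n)
    W = panel["w"].to_numpy().reshape(T, n)
    L = panel["L"].to_numpy().reshape(T, n)

    bundle = P * c_bar * L
    income = np.maximum(W * L, INCOME_FLOOR)
    own = bundle / income
    nbr = (bundle @ adj.T) / np.maximum(income @ adj.T, INCOME_FLOOR)
    isolated = ~adj.any(axis=1)
    vr = np.sqrt(own * beta_damp * nbr)
    vr[:, isolated] = own[:, isolated]
    nbr[:, isolated] = np.nan

    t0 = trajectory.shock_tick
    base = vr[np.searchsorted(ticks, t0)]
    pct = (vr - base) / base * 100.0

    return pd.DataFrame({
        "tick": np.repeat(ticks, n),
        "node": np.tile(np.arange(n), T),
        "vrank": vr.ravel(),
        "own_ratio": own.ravel(),
        "neighbor_ratio": nbr.ravel(),
        "isolated": np.tile(isolated, T),
        "vrank_pct_change": pct.ravel(),
    })
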