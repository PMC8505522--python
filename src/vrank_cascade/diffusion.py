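"""Gravity-model diffusion of labor (migration) and goods (trade).

Agents compare their own market signals with those of connected
neighbors.  Relative gains map through a logistic onto a probability,
distance enters as a reversed logistic of the normalized neighbor
distance, and the joint probability Pi_ij = Pi_q * (1 - Pi_d) weighs
gain against proximity.  Probabilities (for migration) or raw profit
margins (for trade) are normalized to shares that split the mobile
fraction mu of the source stock across destinations.

Two allocation modes exist: deterministic expected-share splits (default;
conservation is exact and runs are bit-reproducible) and multinomial
sampling under the run seed, preserving the "agents may choose next-best
options" interpretation.
"""

from __future__ import annotations

import numpy as np

from .config import DiffusionParams
from .errors import ConsistencyError
from .netgen import MultiLayerNetwork, normalized_distances

__all__ = [
    "logistic_prob",
    "gain_probability",
    "distance_penalty",
    "joint_prob",
    "normalize_shares",
    "migration_candidates",
    "trade_candidates",
    "migration_flow_matrix",
    "trade_flow_matrix",
    "apply_flows",
]


# ---------------------------------------------------------------------------
# probability primitives
# ---------------------------------------------------------------------------

def logistic_prob(z, a: float = 1.0, b: float = 1.0):
    """Generic logistic probability Pi(z) = 1 / (a + b*exp(-z)).

    With a = b = 1 this is the standard logistic: 0.5 at z = 0, tending
    to 1 for large gains and to 0 for large losses; it saturates rather
    than erroring at extreme arguments.
    """
    arr = np.asarray(z, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    # split by sign for overflow-free evaluation
    out = np.empty_like(arr)
    pos = arr >= 0
    out[pos] = 1.0 / (a + b * np.exp(-arr[pos]))
    ez = np.exp(arr[~pos])
    out[~pos] = ez / (a * ez + b)
    return float(out[0]) if scalar else out


def gain_probability(z, params: DiffusionParams | None = None):
    """Gain probability Pi_q for relative (dimensionless) gains.

    The logistic is centered at ``gain_center`` with width ``gain_scale``:
    Pi_q = logistic((z - center)/scale).  A small net gain maps to a
    probability close to zero, a gain at the center to 1/2, and very high
    gains to probabilities close to one, so flows shrink smoothly as the
    system approaches equilibrium instead of overshooting it.
    """
    p = params or DiffusionParams()
    return logistic_prob((np.asarray(z, dtype=float) - p.gain_center) / p.gain_scale, p.a, p.b)


def distance_penalty(d_norm, params: DiffusionParams | None = None):
    """Distance probability Pi_d for normalized distances in [0, 1].

    The logistic is re-centered so the unit interval covers its s-curve:
    Pi_d = logistic((d_norm - center)/width).  Nearby neighbors get a
    penalty near zero, the farthest neighbor (d_norm = 1) a penalty near
    one — i.e. after the (1 - Pi_d) reversal the closest nodes have a
    probability close to one.
    """
    p = params or DiffusionParams()
    return logistic_prob((np.asarray(d_norm, dtype=float) - p.dist_center) / p.dist_width, p.a, p.b)


def joint_prob(gain_prob, dist_frac):
    """Joint decision probability Pi = Pi_q * (1 - Pi_d).

    Positively affected by the relative economic gain, negatively by
    distance; both arguments in [0, 1].
    """
    return np.asarray(gain_prob, dtype=float) * (1.0 - np.asarray(dist_frac, dtype=float))


def normalize_shares(probs):
    """Normalize a probability/weight vector to destination shares.

    Shares sum to one, so destinations with higher net gains pull a
    larger share of the diffused quantity.  An all-zero vector is the
    no-flow signal and returns all-zero shares (not an error).
    """
    probs = np.asarray(probs, dtype=float)
    if np.any(probs < 0):
        raise ConsistencyError("probabilities must be non-negative")
    total = probs.sum()
    if total == 0.0:
        return np.zeros_like(probs)
    return probs / total


# ---------------------------------------------------------------------------
# per-node candidate views (scalar API used in tests and diagnostics)
# ---------------------------------------------------------------------------

def migration_candidates(
    net: MultiLayerNetwork, w: np.ndarray, p: np.ndarray, i: int
) -> dict[int, float]:
    """Relative real-income gains z_ij for node i's union-graph neighbors.

    z_ij = (w_j/p_j - w_i/p_i) / (w_i/p_i); only destinations with a net
    positive gain (z > 0) are retained.  An empty dict means no migration
    from i this tick.
    """
    rw = np.asarray(w, dtype=float) / np.asarray(p, dtype=float)
    out = {}
    for j in net.neighbors(i, "population"):
        z = (rw[j] - rw[i]) / rw[i]
        if z > 0:
            out[int(j)] = float(z)
    return out


def trade_candidates(
    net: MultiLayerNetwork,
    prices_k: np.ndarray,
    i: int,
    rho: float = 1.0,
    layer: str = "food",
) -> dict[int, float]:
    """Relative profit margins z_ij = (p_jk - rho)/rho for markets that
    cover the unit cost (p_jk >= rho).

    Candidate markets are node i's neighbors in the good's layer plus
    the home market; markets priced below cost are excluded.  Margins of
    exactly zero are retained at the margin (the producer just covers
    cost).  An empty dict flags a producer with nowhere to sell.
    """
    prices_k = np.asarray(prices_k, dtype=float)
    out = {}
    for j in [i, *net.neighbors(i, layer)]:
        if prices_k[j] >= rho:
            out[int(j)] = float((prices_k[j] - rho) / rho)
    return out


# ---------------------------------------------------------------------------
# vectorized flow matrices (used by the simulator)
# ---------------------------------------------------------------------------

def _normalized_distance_matrix(net: MultiLayerNetwork, adj: np.ndarray) -> np.ndarray:
    """Row-wise d_ij / max_j d_ij over each node's neighbors (0 off-edge)."""
    d = np.where(adj, net.dist, 0.0)
    row_max = d.max(axis=1, keepdims=True)
    row_max[row_max == 0.0] = 1.0
    return d / row_max


def migration_flow_matrix(
    net: MultiLayerNetwork,
    w: np.ndarray,
    p: np.ndarray,
    L: np.ndarray,
    params: DiffusionParams,
    rng: np.random.Generator | None = None,
    min_emit_L: float = 1.0,
) -> np.ndarray:
    """Directed worker flows for one tick, as an (n, n) matrix.

    Gains are relative real-income differences mapped through the
    centered gain logistic; the joint probability with the distance
    penalty is normalized to shares.  The total emitted is
    mu * L_i * (best joint probability), so a node with only marginal
    destinations moves few workers and the flows vanish smoothly as real
    incomes equalize; gains below ``min_gain`` are ignored altogether.
    Nodes below ``min_emit_L`` workers emit no labor (their market stays
    open but the ghost town sends nobody).  With ``rng`` given, integer
    migrants are drawn multinomially instead of the expected split.
    """
    adj = net.layers["population"]
    rw = np.asarray(w, dtype=float) / np.asarray(p, dtype=float)
    z = (rw[None, :] - rw[:, None]) / rw[:, None]
    gain_ok = adj & (z > params.min_gain)
    pq = gain_probability(z, params)
    pd_ = distance_penalty(_normalized_distance_matrix(net, adj), params)
    # weights ramp up from zero across [min_gain, 2*min_gain] so flows
    # vanish continuously at the dead band (no chattering around it)
    ramp = np.clip((z - params.min_gain) / max(params.min_gain, 1e-12), 0.0, 1.0)
    weights = np.where(gain_ok, joint_prob(pq, pd_) * ramp, 0.0)
    propensity = weights.max(axis=1)
    mobile = params.mu * np.where(L >= min_emit_L, L, 0.0) * propensity
    return _allocate(weights, mobile, rng)


def trade_flow_matrix(
    net: MultiLayerNetwork,
    prices_k: np.ndarray,
    x_k: np.ndarray,
    params: DiffusionParams,
    rho: float,
    layer: str,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Directed goods shipments of good k for one tick, (n, n).

    Candidate markets are layer neighbors plus the home market, filtered
    by the profit threshold p_jk >= rho (a market exactly at cost stays
    in the destination set but carries zero weight).  Shares are the
    normalized profit margins (default) or the joint gain x distance
    probabilities (``trade_share_mode="probability"``).  The total
    diffused is mu * x_ik scaled by the best candidate weight capped at
    one, so shipments taper off smoothly as margins vanish; margins below
    ``min_gain`` are not acted on.  The diagonal carries the home-bound
    part; producers with no admissible market keep the mobile share at
    home (flagged by the simulator).
    """
    adj_home = net.layers[layer] | np.eye(net.n_nodes, dtype=bool)
    prices_k = np.asarray(prices_k, dtype=float)
    margin = (prices_k[None, :] - rho) / rho
    ok = adj_home & (margin > params.min_gain)
    if params.trade_share_mode == "probability":
        pq = gain_probability(margin, params)
        dn = _normalized_distance_matrix(net, net.layers[layer])  # home distance = 0
        weights = np.where(ok, joint_prob(pq, distance_penalty(dn, params)), 0.0)
        propensity = weights.max(axis=1)
    else:
        weights = np.where(ok, np.maximum(margin, 0.0), 0.0)
        propensity = np.minimum(weights.max(axis=1), 1.0)
    mobile = params.mu * np.asarray(x_k, dtype=float)
    flows = _allocate(weights, mobile * propensity, rng)
    # mobile goods with no admissible destination stay on the home market
    unallocated = params.mu * np.asarray(x_k, dtype=float) - flows.sum(axis=1)
    np.fill_diagonal(flows, flows.diagonal() + np.maximum(unallocated, 0.0))
    return flows


def _allocate(
    weights: np.ndarray, mobile: np.ndarray, rng: np.random.Generator | None
) -> np.ndarray:
    """Split each row's mobile stock across destinations by row-normalized
    weights; all-zero rows send nothing."""
    totals = weights.sum(axis=1, keepdims=True)
    shares = np.divide(weights, totals, out=np.zeros_like(weights), where=totals > 0)
    if rng is None:
        return shares * mobile[:, None]
    flows = np.zeros_like(shares)
    for i in np.flatnonzero(totals[:, 0] > 0):
        n_units = int(round(mobile[i]))
        if n_units > 0:
            flows[i] = rng.multinomial(n_units, shares[i])
        # sub-unit remainders move as expected shares so mass is conserved
        flows[i] += shares[i] * (mobile[i] - n_units)
    return flows


def apply_flows(stocks: np.ndarray, flows: np.ndarray, atol: float = 1e-9) -> np.ndarray:
    """Apply a directed flow matrix to per-node stocks.

    Off-diagonal entries move quantity between nodes; totals are
    conserved exactly.  A row shipping more than its stock is an internal
    consistency error (bug trap), not a user error.
    """
    stocks = np.asarray(stocks, dtype=float)
    out_total = flows.sum(axis=1) - flows.diagonal()
    if np.any(out_total > stocks + atol):
        raise ConsistencyError("flow exceeds source stock")
    return stocks - out_total + (flows.sum(axis=0) - flows.diagonal())
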