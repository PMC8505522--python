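"""Time-stepping scheduler.

A run has two phases: a burn-in that iterates the coupled trade/migration
dynamics until wages and price indices stabilize (max relative per-tick
change below tolerance for a window of consecutive ticks), then a
permanent food-capacity shock to the epicenter's food producers, after
which the run continues to post-shock convergence or t_max.

Each tick is one synchronous update computed from start-of-tick values
throughout, so node order never matters:

1. production at capacity;
2. wages w = rho*y/L;
3. trade candidate selection (previous tick's prices) and goods flows;
4. market clearing -> prices on post-trade marketed quantities;
5. food-share (alpha) update;
6. migration candidate selection (previous prices, current wages) and
   population flows;
7. record.

The full node x time panel is returned as a :class:`Trajectory` together
with a manifest (config hash, seed, convergence ticks) that makes runs
reproducible and pairable with their no-shock baselines.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import economy
from .config import ScenarioConfig
from .diffusion import apply_flows, migration_flow_matrix, trade_flow_matrix
from .errors import ConsistencyError
from .netgen import (
    MultiLayerNetwork,
    epicenter_radius_for_fraction,
    generate_network,
    select_epicenter,
)

__all__ = ["SimState", "Trajectory", "init_state", "tick", "apply_shock", "run", "sweep_plan", "sweep"]

#: labor stocks below this count emit no migrants ("ghost town": the
#: market stays open but nobody leaves an emptied node).
MIN_EMIT_L = 1.0


@dataclass
class SimState:
    """Vectorized per-node state at one tick (arrays of length n)."""

    L: np.ndarray  # workers
    x_F: np.ndarray  # food production capacity (post-shock if shocked)
    x_G: np.ndarray  # non-food production capacity
    beta_F: np.ndarray
    beta_G: np.ndarray
    alpha: np.ndarray  # food budget share used for next tick's clearing
    # market outcomes of the most recent tick:
    mkt_F: np.ndarray  # marketed food after trade
    mkt_G: np.ndarray
    w: np.ndarray
    p_F: np.ndarray
    p_G: np.ndarray
    p: np.ndarray  # price index
    # exponentially smoothed decision signals (adaptive expectations);
    # equal to the actual values when signal_smoothing = 1
    sig_w: np.ndarray = field(default=None)
    sig_p_F: np.ndarray = field(default=None)
    sig_p_G: np.ndarray = field(default=None)
    sig_p: np.ndarray = field(default=None)
    no_market_F: np.ndarray = field(default=None)  # producer had no admissible market
    no_market_G: np.ndarray = field(default=None)

    def copy(self) -> "SimState":
        return SimState(**{
            f.name: (getattr(self, f.name).copy() if getattr(self, f.name) is not None else None)
            for f in dataclasses.fields(self)
        })


@dataclass
class Trajectory:
    """Node x time panel of states plus the run manifest.

    ``panel`` has one row per (tick, node) with columns L, x_F, x_G,
    mkt_F, mkt_G, w, p_F, p_G, p, alpha, consumption_pc and flag columns.
    ``manifest`` records the config dict/hash, seed, shock tick and the
    convergence ticks of both phases ("unconverged" phases record -1).
    """

    panel: pd.DataFrame
    manifest: dict
    net: MultiLayerNetwork
    epicenter: np.ndarray
    flows: pd.DataFrame | None = None

    @property
    def shock_tick(self) -> int:
        return self.manifest["shock_tick"]

    def state_at(self, t: int) -> pd.DataFrame:
        return self.panel[self.panel["tick"] == t].set_index("node")


def init_state(
    net: MultiLayerNetwork, cfg: ScenarioConfig, initial_L: np.ndarray | None = None
) -> SimState:
    """Initial conditions: every node starts with L0 workers (unless
    ``initial_L`` overrides the per-node labor, e.g. for wage-gap
    fixtures) and the same real output; food nodes produce
    (x_major, x_minor) = (90, 10) food/non-food and non-food nodes the
    reverse, so y is identical by symmetry of the beta weights.  Prices
    start at their autarky values (each node clears its own
    production)."""
    e = cfg.economy
    n = net.n_nodes
    is_food = net.is_food
    x_F = np.where(is_food, e.x_major, e.x_minor).astype(float)
    x_G = np.where(is_food, e.x_minor, e.x_major).astype(float)
    beta_F = np.where(is_food, e.beta_major, e.beta_minor).astype(float)
    beta_G = np.where(is_food, e.beta_minor, e.beta_major).astype(float)
    L = np.full(n, float(e.L0)) if initial_L is None else np.asarray(initial_L, dtype=float).copy()
    alpha = np.full(n, float(e.alpha0))

    y = economy.real_output(x_F, x_G, beta_F, beta_G)
    w = economy.wage(y, L, e.rho)
    mkt_F, mkt_G = x_F.copy(), x_G.copy()
    p_F, p_G = economy.prices(alpha, w, L, np.maximum(mkt_F, economy.QUANTITY_FLOOR),
                              np.maximum(mkt_G, economy.QUANTITY_FLOOR))
    p = economy.price_index(p_F, p_G, e.gamma_F, e.gamma_G)
    zeros = np.zeros(n, dtype=bool)
    return SimState(L=L, x_F=x_F, x_G=x_G, beta_F=beta_F, beta_G=beta_G, alpha=alpha,
                    mkt_F=mkt_F, mkt_G=mkt_G, w=w, p_F=p_F, p_G=p_G, p=p,
                    sig_w=w.copy(), sig_p_F=p_F.copy(), sig_p_G=p_G.copy(), sig_p=p.copy(),
                    no_market_F=zeros.copy(), no_market_G=zeros.copy())


def apply_shock(state: SimState, epicenter_food_nodes: np.ndarray, s: float) -> SimState:
    """Cut food capacity of the epicenter's food producers by the factor
    s, permanently (no recovery).  s = 0 leaves the state untouched."""
    if not (0.0 <= s <= 1.0):
        raise ConsistencyError(f"shock magnitude must lie in [0, 1], got {s}")
    out = state.copy()
    out.x_F[epicenter_food_nodes] *= (1.0 - s)
    return out


def tick(
    state: SimState,
    net: MultiLayerNetwork,
    cfg: ScenarioConfig,
    rng: np.random.Generator | None = None,
    collect_flows: bool = False,
):
    """One synchronous update; returns the new state (and optionally the
    three flow matrices for the flow log)."""
    e, d = cfg.economy, cfg.diffusion

    # 1-2: production at capacity, wages
    y = economy.real_output(state.x_F, state.x_G, state.beta_F, state.beta_G)
    L_safe = np.maximum(state.L, economy.QUANTITY_FLOOR)
    w = e.rho * y / L_safe

    # 3: trade flows against the smoothed start-of-tick price signals
    flows_F = trade_flow_matrix(net, state.sig_p_F, state.x_F, d, e.rho, "food", rng)
    flows_G = trade_flow_matrix(net, state.sig_p_G, state.x_G, d, e.rho, "nonfood", rng)
    mkt_F = (1.0 - d.mu) * state.x_F + flows_F.sum(axis=0)
    mkt_G = (1.0 - d.mu) * state.x_G + flows_G.sum(axis=0)
    # a producer is flagged when no market (neighbors or home) covers cost
    eye = np.eye(net.n_nodes, dtype=bool)
    cand_F = (net.layers["food"] | eye) & (state.sig_p_F[None, :] >= e.rho)
    cand_G = (net.layers["nonfood"] | eye) & (state.sig_p_G[None, :] >= e.rho)
    no_market_F = (state.x_F > 0) & ~cand_F.any(axis=1)
    no_market_G = (state.x_G > 0) & ~cand_G.any(axis=1)

    # 4: market clearing on post-trade quantities (floored)
    p_F, p_G = economy.prices(state.alpha, w, state.L,
                              np.maximum(mkt_F, economy.QUANTITY_FLOOR),
                              np.maximum(mkt_G, economy.QUANTITY_FLOOR))
    p = economy.price_index(p_F, p_G, e.gamma_F, e.gamma_G)

    # 5: households defend the minimum bundle
    alpha = economy.update_alpha(p_F, w, L_safe, e.c_bar, e.alpha_min)

    # 6: migration against start-of-tick real incomes (wages respond to
    # labor immediately, so the raw signal is already smooth; lagging it
    # would make workers overshoot equalized real wages)
    flows_L = migration_flow_matrix(net, w, state.p, state.L, d, rng, MIN_EMIT_L)
    L_new = apply_flows(state.L, flows_L)

    if np.any(~np.isfinite(L_new)) or np.any(L_new < -1e-9):
        raise ConsistencyError("NaN or negative labor stock after tick")

    # 7 (bookkeeping): update the smoothed decision signals
    lam = d.signal_smoothing
    new = SimState(L=L_new, x_F=state.x_F.copy(), x_G=state.x_G.copy(),
                   beta_F=state.beta_F, beta_G=state.beta_G, alpha=alpha,
                   mkt_F=mkt_F, mkt_G=mkt_G, w=w, p_F=p_F, p_G=p_G, p=p,
                   sig_w=(1 - lam) * state.sig_w + lam * w,
                   sig_p_F=(1 - lam) * state.sig_p_F + lam * p_F,
                   sig_p_G=(1 - lam) * state.sig_p_G + lam * p_G,
                   sig_p=(1 - lam) * state.sig_p + lam * p,
                   no_market_F=no_market_F, no_market_G=no_market_G)
    if collect_flows:
        return new, {"population": flows_L, "food": flows_F, "nonfood": flows_G}
    return new


_PANEL_COLUMNS = ("L", "x_F", "x_G", "mkt_F", "mkt_G", "w", "p_F", "p_G", "p",
                  "alpha", "consumption_pc", "market_collapsed", "no_market", "depopulated")


def _record(rows: list, t: int, state: SimState, used_alpha: np.ndarray) -> None:
    # buffered as raw arrays; one DataFrame is assembled at the end of the run
    cons_pc = used_alpha * state.w / np.maximum(state.p_F, economy.QUANTITY_FLOOR)
    rows.append((t, (
        state.L, state.x_F, state.x_G, state.mkt_F, state.mkt_G,
        state.w, state.p_F, state.p_G, state.p, state.alpha, cons_pc,
        ((state.mkt_F <= economy.QUANTITY_FLOOR) | (state.mkt_G <= economy.QUANTITY_FLOOR)).astype(float),
        (state.no_market_F | state.no_market_G).astype(float),
        (state.L < MIN_EMIT_L).astype(float),
    )))


def _assemble_panel(rows: list, n: int) -> pd.DataFrame:
    ticks = np.repeat([t for t, _ in rows], n)
    nodes = np.tile(np.arange(n), len(rows))
    data = {"tick": ticks, "node": nodes}
    for k, name in enumerate(_PANEL_COLUMNS):
        data[name] = np.concatenate([arrs[k] for _, arrs in rows])
    panel = pd.DataFrame(data)
    for flag in ("market_collapsed", "no_market", "depopulated"):
        panel[flag] = panel[flag].astype(bool)
    return panel


def _flow_rows(t: int, mats: dict[str, np.ndarray]) -> pd.DataFrame:
    frames = []
    for layer, m in mats.items():
        off = m.copy()
        np.fill_diagonal(off, 0.0)
        src, dst = np.nonzero(off > 0)
        if src.size:
            frames.append(pd.DataFrame({
                "tick": t, "layer": layer, "source": src, "destination": dst,
                "amount": off[src, dst],
            }))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["tick", "layer", "source", "destination", "amount"])


def run(
    cfg: ScenarioConfig,
    net: MultiLayerNetwork | None = None,
    collect_flows: bool = False,
    initial_L: np.ndarray | None = None,
) -> Trajectory:
    """Execute one full scenario: burn-in, shock, post-shock evolution.

    The shock lands at the burn-in convergence tick (or at
    ``shock.t_shock`` if burn-in has not converged by then).  A phase
    that fails to converge before t_max is flagged in the manifest, not
    raised.  In expected-share mode, identical config+seed gives an
    identical panel.
    """
    cfg.validate()
    if net is None:
        net = generate_network(cfg.network.n_nodes, cfg.network.food_frac,
                               cfg.network.target_mean_degree, cfg.seed,
                               cfg.network.layer_masks)
    rng = np.random.default_rng(cfg.seed) if cfg.mode == "sampled" else None

    radius = cfg.shock.radius
    if radius is None:
        radius = epicenter_radius_for_fraction(net, cfg.shock.center, cfg.shock.node_fraction)
    epicenter = select_epicenter(net, cfg.shock.center, radius)
    epi_food = epicenter[net.is_food[epicenter]]

    conv = cfg.convergence
    state = init_state(net, cfg, initial_L)
    rows: list = []
    flow_frames: list[pd.DataFrame] = []
    _record(rows, 0, state, state.alpha)

    def _step(state, t):
        used_alpha = state.alpha
        if collect_flows:
            new, mats = tick(state, net, cfg, rng, collect_flows=True)
            flow_frames.append(_flow_rows(t, mats))
        else:
            new = tick(state, net, cfg, rng)
        _record(rows, t, new, used_alpha)
        return new

    def _rel_change(a, b):
        return float(np.max(np.abs(a - b) / np.maximum(np.abs(b), 1e-300)))

    # ---- burn-in phase ----
    t = 0
    stable = 0
    burnin_converged_at = -1
    while t < cfg.shock.t_shock:
        prev_w, prev_p = state.w, state.p
        t += 1
        state = _step(state, t)
        delta = max(_rel_change(state.w, prev_w), _rel_change(state.p, prev_p))
        stable = stable + 1 if delta < conv.tolerance else 0
        if stable >= conv.window:
            burnin_converged_at = t
            break

    # ---- shock ----
    shock_tick = t
    state = apply_shock(state, epi_food, cfg.shock.magnitude)

    # ---- post-shock phase ----
    stable = 0
    post_converged_at = -1
    while t < conv.t_max:
        prev_w, prev_p = state.w, state.p
        t += 1
        state = _step(state, t)
        delta = max(_rel_change(state.w, prev_w), _rel_change(state.p, prev_p))
        stable = stable + 1 if delta < conv.tolerance else 0
        if stable >= conv.window:
            post_converged_at = t
            break

    panel = _assemble_panel(rows, net.n_nodes)
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "mode": cfg.mode,
        "shock_tick": shock_tick,
        "burnin_converged_at": burnin_converged_at,
        "post_converged_at": post_converged_at,
        "unconverged": post_converged_at < 0,
        "final_tick": t,
        "epicenter": [int(i) for i in epicenter],
        "epicenter_food_nodes": [int(i) for i in epi_food],
    }
    flows = pd.concat(flow_frames, ignore_index=True) if collect_flows and flow_frames else None
    return Trajectory(panel=panel, manifest=manifest, net=net, epicenter=epicenter, flows=flows)


DEFAULT_SHOCK_LEVELS = (0.4, 0.5, 0.6, 0.7, 0.8)


def sweep_plan(
    base_config: ScenarioConfig,
    shock_levels=DEFAULT_SHOCK_LEVELS,
    n_networks: int = 10,
) -> list[ScenarioConfig]:
    """Enumerate the experiment grid: one config per (shock level,
    network seed) pair — the default 5 levels x 10 networks = 50 runs.
    Network seeds are base seed, base seed + 1, ..."""
    if not shock_levels:
        raise ConsistencyError("shock_levels must be non-empty")
    plan = []
    for level in shock_levels:
        for k in range(n_networks):
            shock = dataclasses.replace(base_config.shock, magnitude=float(level))
            plan.append(base_config.replace(shock=shock, seed=base_config.seed + k))
    return plan


def sweep(
    base_config: ScenarioConfig,
    shock_levels=DEFAULT_SHOCK_LEVELS,
    n_networks: int = 10,
    include_baselines: bool = True,
):
    """Run the full grid plus one no-shock baseline per network.

    Returns ``(runs, baselines)`` where ``runs`` is the list of shocked
    trajectories in plan order and ``baselines`` maps network seed to the
    s = 0 trajectory on the same network.  Per-run failures are recorded
    as manifest flags; the grid itself never aborts on one failure.
    """
    plan = sweep_plan(base_config, shock_levels, n_networks)
    baselines: dict[int, Trajectory] = {}
    nets: dict[int, MultiLayerNetwork] = {}
    if include_baselines:
        for k in range(n_networks):
            seed = base_config.seed + k
            shock0 = dataclasses.replace(base_config.shock, magnitude=0.0)
            cfg0 = base_config.replace(shock=shock0, seed=seed)
            nets[seed] = generate_network(cfg0.network.n_nodes, cfg0.network.food_frac,
                                          cfg0.network.target_mean_degree, seed,
                                          cfg0.network.layer_masks)
            baselines[seed] = run(cfg0, net=nets[seed])
    runs = []
    for cfg in plan:
        net = nets.get(cfg.seed)
        runs.append(run(cfg, net=net))
    return runs, baselines
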