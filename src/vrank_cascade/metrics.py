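"""Analysis layer: indicators, baseline-relative changes, spatio-temporal
binning and cycle trajectories.

Two node-level indicators summarize food access:

* ``food_labor_ratio`` = p_F / w — the food-to-labor price ratio; a rise
  captures the dual squeeze of dearer food and weaker earnings.
* ``consumption_pc`` = alpha * w / p_F — per-capita real food
  consumption (exactly the marketed food per worker when the market
  clears).

Both are also reported as percent change against the no-shock baseline
run on the same network and seed.  The distance x density heat bins track
how the shock wave travels outward from the epicenter, and the cycle
trace follows the economy's loop through the (ratio, consumption) plane
during the post-shock adjustment (counter-clockwise = negative shoelace
area).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigurationError, PairingError
from .netgen import MultiLayerNetwork
from .simulator import Trajectory

__all__ = [
    "indicators",
    "box_summary",
    "node_distance_to_epicenter",
    "heat_bins",
    "cycle_trace",
    "signed_area",
]


def indicators(trajectory: Trajectory, baseline: Trajectory) -> pd.DataFrame:
    """Per (tick, node) indicator panel with percent changes vs baseline.

    The two runs must share a network and seed (checked via the manifest)
    so that the comparison isolates the shock.  Baseline ticks beyond the
    baseline's end are extended with its final converged values.
    """
    if trajectory.manifest["seed"] != baseline.manifest["seed"]:
        raise PairingError("trajectory and baseline were run with different seeds")
    cfg_a = dict(trajectory.manifest["config"])
    cfg_b = dict(baseline.manifest["config"])
    if cfg_a["network"] != cfg_b["network"]:
        raise PairingError("trajectory and baseline use different network parameters")

    def _panel(traj: Trajectory) -> pd.DataFrame:
        df = traj.panel[["tick", "node", "w", "p_F", "alpha", "consumption_pc"]].copy()
        df["food_labor_ratio"] = df["p_F"] / df["w"]
        return df[["tick", "node", "food_labor_ratio", "consumption_pc"]]

    shocked = _panel(trajectory)
    base = _panel(baseline)

    # extend the baseline forward with its last recorded tick if needed
    last_tick = base["tick"].max()
    extra_ticks = np.setdiff1d(shocked["tick"].unique(), base["tick"].unique())
    extra_ticks = extra_ticks[extra_ticks > last_tick]
    if extra_ticks.size:
        tail = base[base["tick"] == last_tick]
        base = pd.concat(
            [base] + [tail.assign(tick=t) for t in extra_ticks], ignore_index=True
        )

    merged = shocked.merge(base, on=["tick", "node"], suffixes=("", "_base"))
    for col in ("food_labor_ratio", "consumption_pc"):
        merged[f"{col}_pct"] = (
            (merged[col] - merged[f"{col}_base"]) / merged[f"{col}_base"] * 100.0
        )
    return merged


def box_summary(values: pd.Series | np.ndarray) -> dict:
    """Median, inter-quartile range and outliers (1.5 IQR whisker rule) —
    the box-plot summary used to aggregate runs within a shock level."""
    v = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "iqr": float(iqr),
        "outliers": v[(v < lo) | (v > hi)].tolist(),
    }


def node_distance_to_epicenter(
    net: MultiLayerNetwork, epicenter: np.ndarray, mode: str = "centroid"
) -> np.ndarray:
    """Normalized distance of every node to the epicenter, in [0, 1].

    ``centroid`` (default) measures from the centroid of the epicenter
    region; ``nearest`` from the nearest epicenter member.  Divided by
    the network's maximum so 0 is the epicenter and 1 the farthest node.
    """
    if mode == "centroid":
        ref = net.coords[epicenter].mean(axis=0)
        d = np.linalg.norm(net.coords - ref, axis=1)
    elif mode == "nearest":
        d = np.min(
            np.linalg.norm(net.coords[:, None, :] - net.coords[None, epicenter, :], axis=2),
            axis=1,
        )
    else:
        raise ConfigurationError(f"unknown distance mode {mode!r}")
    dmax = d.max()
    return d / dmax if dmax > 0 else d


def _quantile_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Quantile bin index per value (bins guaranteed populated)."""
    edges = np.quantile(values, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    idx = np.clip(np.searchsorted(edges, values, side="right") - 1, 0, len(edges) - 2)
    return idx


def heat_bins(
    panel: pd.DataFrame,
    net: MultiLayerNetwork,
    epicenter: np.ndarray,
    value: str,
    n_dist_bins: int = 5,
    n_dens_bins: int = 4,
    snapshot_ticks=None,
    distance_mode: str = "centroid",
) -> pd.DataFrame:
    """Distance-to-epicenter x node-density binned means per snapshot.

    Every node maps to exactly one (distance, density) cell; density is
    the union-graph degree, binned by quantiles so cells are populated.
    Cells with no nodes are absent from the output (empty, not zero).
    Returns a tidy frame (snapshot_tick, dist_bin, dens_bin, mean, n).
    """
    if n_dist_bins < 1 or n_dens_bins < 1:
        raise ConfigurationError("bin counts must be >= 1")
    if value not in panel.columns:
        raise ConfigurationError(f"panel has no column {value!r}")
    ticks_avail = panel["tick"].unique()
    if snapshot_ticks is None:
        snapshot_ticks = default_snapshots(ticks_avail)
    missing = np.setdiff1d(np.asarray(snapshot_ticks), ticks_avail)
    if missing.size:
        raise ConfigurationError(f"snapshot ticks {missing.tolist()} not in the trajectory")

    dist = node_distance_to_epicenter(net, epicenter, distance_mode)
    # linear distance bins: epicenter members land in bin 0, the farthest
    # node in the last bin
    dist_bin = np.clip((dist * n_dist_bins).astype(int), 0, n_dist_bins - 1)
    dens_bin = _quantile_bins(net.degree().astype(float), n_dens_bins)

    node_map = pd.DataFrame({
        "node": np.arange(net.n_nodes), "dist_bin": dist_bin, "dens_bin": dens_bin,
    })
    snap = panel[panel["tick"].isin(snapshot_ticks)].merge(node_map, on="node")
    out = (
        snap.groupby(["tick", "dist_bin", "dens_bin"])[value]
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"tick": "snapshot_tick", "size": "n"})
    )
    return out


def default_snapshots(ticks: np.ndarray, n_snapshots: int = 8) -> np.ndarray:
    """Evenly spaced snapshot ticks across the available range."""
    ticks = np.sort(np.asarray(ticks))
    idx = np.linspace(0, ticks.size - 1, min(n_snapshots, ticks.size)).round().astype(int)
    return ticks[np.unique(idx)]


def signed_area(path: np.ndarray) -> float:
    """Shoelace signed area of a closed 2-D path (standard orientation:
    positive = counter-clockwise)."""
    pts = np.asarray(path, dtype=float)
    if pts.shape[0] < 3:
        return 0.0
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def cycle_trace(indicator_panel: pd.DataFrame, shock_tick: int) -> pd.DataFrame:
    """Time-ordered mean-indicator path from the shock to the end of the
    run, with orientation diagnostics.

    Returns a frame of per-tick means of (food_labor_ratio_pct,
    consumption_pc_pct) whose ``attrs`` carry the shoelace ``signed_area``
    (positive = counter-clockwise loop, the adjustment direction these
    cascades exhibit) and the loop ``amplitude`` (bounding-box diagonal).
    A no-shock run yields a degenerate single-point path with zero area.
    """
    post = indicator_panel[indicator_panel["tick"] >= shock_tick]
    path = (
        post.groupby("tick")[["food_labor_ratio_pct", "consumption_pc_pct"]]
        .mean()
        .reset_index()
    )
    pts = path[["food_labor_ratio_pct", "consumption_pc_pct"]].to_numpy()
    area = signed_area(pts)
    span = pts.max(axis=0) - pts.min(axis=0) if len(pts) else np.zeros(2)
    path.attrs["signed_area"] = area
    path.attrs["counter_clockwise"] = bool(area > 0)
    path.attrs["amplitude"] = float(np.hypot(*span))
    return path
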