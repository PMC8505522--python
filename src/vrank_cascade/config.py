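"""Scenario configuration.

A :class:`ScenarioConfig` bundles every parameter of a simulation run:
network generation, node economy, diffusion behavior, the disaster shock,
convergence control and the master seed.  Configs round-trip through YAML
and hash deterministically so a run manifest can prove which scenario
produced a trajectory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import yaml

from .errors import ConfigurationError

__all__ = [
    "NetworkParams",
    "EconomyParams",
    "DiffusionParams",
    "ShockParams",
    "ConvergenceParams",
    "ScenarioConfig",
]


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigurationError(msg)


@dataclass
class NetworkParams:
    """Random spatial multi-layer network parameters.

    Nodes are placed uniformly in the unit square, linked by a
    random-geometric rule whose radius is solved to hit
    ``target_mean_degree``, then augmented with minimum-spanning-tree
    edges so the union graph is connected.
    """

    n_nodes: int = 80
    food_frac: float = 0.5
    target_mean_degree: float = 8.0
    #: optional per-layer edge masks; None means identical topology
    #: across the population, food and nonfood layers.
    layer_masks: dict[str, Any] | None = None

    def validate(self) -> None:
        _require(self.n_nodes >= 2, f"n_nodes must be >= 2, got {self.n_nodes}")
        _require(
            0.0 < self.food_frac < 1.0,
            f"food_frac must lie strictly in (0, 1), got {self.food_frac}",
        )
        _require(
            self.target_mean_degree >= 2,
            f"target_mean_degree must be >= 2, got {self.target_mean_degree}",
        )


@dataclass
class EconomyParams:
    """Node-level circular-flow economy parameters.

    rho
        Unit cost of production; labor is the only input so the wage bill
        equals rho * real output.
    alpha0, alpha_min
        Initial food budget share and its lower bound (the share
        households spend on food is clamped to [alpha_min, 1]).
    c_bar
        Minimum per-capita food consumption bundle, in goods units per
        worker.  A household unable to afford c_bar is food insecure.
    gamma_F, gamma_G
        Price-index weights; both 1 by default (equal-weight index).
    L0
        Initial workers per node.
    x_major, x_minor
        Output quantities of a node's major/minor good (food nodes
        produce (x_major food, x_minor non-food) and vice versa), chosen
        so real output y is identical across node types.
    beta_major, beta_minor
        Product weights of the major/minor good in real output.
    """

    rho: float = 1.0
    alpha0: float = 0.5
    alpha_min: float = 0.3
    c_bar: float = 0.35
    gamma_F: float = 1.0
    gamma_G: float = 1.0
    L0: float = 100.0
    x_major: float = 90.0
    x_minor: float = 10.0
    beta_major: float = 0.9
    beta_minor: float = 0.1

    def validate(self) -> None:
        _require(self.rho > 0, f"rho must be positive, got {self.rho}")
        _require(
            0 < self.alpha_min <= self.alpha0 <= 1,
            f"need 0 < alpha_min <= alpha0 <= 1, got alpha_min={self.alpha_min}, alpha0={self.alpha0}",
        )
        _require(self.c_bar > 0, f"c_bar must be positive, got {self.c_bar}")
        _require(self.L0 > 0, f"L0 must be positive, got {self.L0}")
        _require(
            self.x_major >= 0 and self.x_minor >= 0,
            "output quantities must be non-negative",
        )
        _require(
            abs(self.beta_major + self.beta_minor - 1.0) < 1e-12,
            "beta_major + beta_minor must equal 1",
        )


@dataclass
class DiffusionParams:
    """Gravity-model diffusion parameters (shared by both layers).

    mu
        Fraction of a node's mobile stock (workers or goods) diffused per
        tick, identical for the household and production layers.
    a, b
        Logistic parameters: Pi(z) = 1 / (a + b * exp(-z)).
    gain_center, gain_scale
        The gain probability is the logistic applied to
        (relative_gain - gain_center) / gain_scale: a gain equal to
        gain_center moves with probability 1/2, small gains map close to
        zero and large gains close to one.
    min_gain
        Relative gains below this dead band are not acted on (agents
        ignore negligible gains), so the coupled dynamics reach an exact
        fixed point instead of chattering at the profit threshold.
    dist_center, dist_width
        The distance penalty is the logistic applied to
        (d_norm - dist_center) / dist_width, so normalized distance in
        [0, 1] covers the s-curve and the farthest neighbor is penalized
        most.
    signal_smoothing
        Weight lambda of the newest observation in the exponentially
        smoothed price/wage signals agents act on (adaptive
        expectations); 1.0 means agents react to raw last-tick values.
        Market clearing itself always uses actual quantities, so fixed
        points do not depend on lambda — only the adjustment path does.
    trade_share_mode
        "margin": trade shares are normalized profit margins (default);
        "probability": trade uses the same joint gain x distance
        probability route as migration.
    """

    mu: float = 0.1
    a: float = 1.0
    b: float = 1.0
    gain_center: float = 0.2
    gain_scale: float = 0.1
    min_gain: float = 0.01
    dist_center: float = 0.5
    dist_width: float = 0.25
    signal_smoothing: float = 0.1
    trade_share_mode: str = "margin"

    def validate(self) -> None:
        _require(0 < self.mu <= 1, f"mu must lie in (0, 1], got {self.mu}")
        _require(self.a > 0 and self.b > 0, "logistic parameters a, b must be positive")
        _require(self.gain_scale > 0, "gain_scale must be positive")
        _require(self.min_gain >= 0, "min_gain must be non-negative")
        _require(
            0 < self.signal_smoothing <= 1,
            f"signal_smoothing must lie in (0, 1], got {self.signal_smoothing}",
        )
        _require(self.dist_width > 0, "dist_width must be positive")
        _require(
            self.trade_share_mode in ("margin", "probability"),
            f"trade_share_mode must be 'margin' or 'probability', got {self.trade_share_mode!r}",
        )


@dataclass
class ShockParams:
    """Disaster shock: food output of epicenter food nodes is cut by a
    factor ``magnitude``, permanently, once the pre-shock burn-in has
    converged (or at ``t_shock`` if burn-in has not converged by then)."""

    magnitude: float = 0.0
    #: epicenter circle center in unit-square coordinates; default is the
    #: centroid of the low-x/low-y corner quadrant.
    center: tuple[float, float] = (0.25, 0.25)
    #: fraction of nodes the epicenter circle should contain (the radius
    #: is solved per network); ignored when ``radius`` is given.
    node_fraction: float = 0.2
    radius: float | None = None
    #: latest tick at which the shock is applied if burn-in has not
    #: converged earlier.
    t_shock: int = 2000

    def validate(self) -> None:
        _require(
            0.0 <= self.magnitude <= 1.0,
            f"shock magnitude must lie in [0, 1], got {self.magnitude}",
        )
        _require(
            0 < self.node_fraction <= 1,
            f"node_fraction must lie in (0, 1], got {self.node_fraction}",
        )
        if self.radius is not None:
            _require(self.radius > 0, f"radius must be positive, got {self.radius}")
        _require(self.t_shock >= 0, "t_shock must be >= 0")


@dataclass
class ConvergenceParams:
    """A phase is converged when the maximum relative per-tick change of
    all wages and price indices stays below ``tolerance`` for ``window``
    consecutive ticks; ``t_max`` caps the total run length."""

    tolerance: float = 1e-6
    window: int = 10
    t_max: int = 5000

    def validate(self) -> None:
        _require(self.tolerance > 0, "tolerance must be positive")
        _require(self.window >= 1, "window must be >= 1")
        _require(self.t_max > 0, "t_max must be positive")


@dataclass
class ScenarioConfig:
    """Full scenario: all blocks plus the master seed and the flow mode.

    mode
        "expected_share": flows are deterministic expected-value splits
        (exact conservation, bit-reproducible);
        "sampled": destinations are drawn multinomially under the seed.
    """

    network: NetworkParams = field(default_factory=NetworkParams)
    economy: EconomyParams = field(default_factory=EconomyParams)
    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    shock: ShockParams = field(default_factory=ShockParams)
    convergence: ConvergenceParams = field(default_factory=ConvergenceParams)
    seed: int = 0
    mode: str = "expected_share"

    def validate(self) -> "ScenarioConfig":
        self.network.validate()
        self.economy.validate()
        self.diffusion.validate()
        self.shock.validate()
        self.convergence.validate()
        _require(
            self.shock.t_shock < self.convergence.t_max,
            "t_shock must be smaller than t_max",
        )
        _require(
            self.mode in ("expected_share", "sampled"),
            f"mode must be 'expected_share' or 'sampled', got {self.mode!r}",
        )
        return self

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["shock"]["center"] = list(self.shock.center)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        kwargs: dict[str, Any] = {}
        blocks = {
            "network": NetworkParams,
            "economy": EconomyParams,
            "diffusion": DiffusionParams,
            "shock": ShockParams,
            "convergence": ConvergenceParams,
        }
        for name, klass in blocks.items():
            if name in d:
                block = dict(d.pop(name))
                if name == "shock" and "center" in block:
                    block["center"] = tuple(block["center"])
                kwargs[name] = klass(**block)
        for scalar in ("seed", "mode"):
            if scalar in d:
                kwargs[scalar] = d.pop(scalar)
        if d:
            raise ConfigurationError(f"unknown config fields: {sorted(d)}")
        return cls(**kwargs).validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        """Deterministic short hash of the canonical config JSON."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def replace(self, **kwargs) -> "ScenarioConfig":
        """Return a copy with top-level blocks/fields replaced."""
        return dataclasses.replace(self, **kwargs)
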