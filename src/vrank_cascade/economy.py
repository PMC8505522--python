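"""Node-level circular-flow economy.

Each location employs all of its labor L to produce two goods — food F
and non-food G — at fixed capacity.  Real output is the product-weighted
sum y = beta_F*x_F + beta_G*x_G; the wage bill exhausts the value of
production (w = rho*y/L with unit cost rho), and income is fully spent:
a share alpha on food, 1-alpha on the other good.  Local market clearing
then yields the goods prices, the equal-weight price index, and nominal
output.  The household threshold adjusts alpha so the minimum per-capita
food bundle c_bar stays affordable when food prices rise or incomes fall,
within the bounds [alpha_min, 1].

All functions accept scalars or aligned numpy arrays (one entry per
node).
"""

from __future__ import annotations

import numpy as np

from .errors import DomainError, EmptiedNodeError

#: marketed quantities are floored at this value before price computation
#: so a fully abandoned market yields a huge-but-finite price instead of a
#: division by zero; nodes hitting the floor are flagged market-collapsed.
QUANTITY_FLOOR = 1e-9

__all__ = [
    "QUANTITY_FLOOR",
    "real_output",
    "wage",
    "prices",
    "price_index",
    "nominal_output",
    "update_alpha",
]


def _check_nonneg(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise DomainError(f"{name} must be non-negative")
    return arr


def real_output(x_F, x_G, beta_F=0.9, beta_G=0.1):
    """Real output y = beta_F * x_F + beta_G * x_G.

    beta_k is the weight of product k at the node; food producers default
    to (0.9, 0.1) and non-food producers to (0.1, 0.9).
    """
    x_F = _check_nonneg("x_F", x_F)
    x_G = _check_nonneg("x_G", x_G)
    return beta_F * x_F + beta_G * x_G


def wage(y, L, rho=1.0):
    """Income per worker w = rho * y / L (labor is the only cost)."""
    y = _check_nonneg("y", y)
    L = np.asarray(L, dtype=float)
    if np.any(L <= 0):
        raise EmptiedNodeError("wage undefined for a node with no workers (L <= 0)")
    return rho * y / L


def prices(alpha, w, L, x_F, x_G):
    """Local market-clearing prices.

    Households spend alpha*w*L on food and (1-alpha)*w*L on the other
    good; the marketed quantities x_F, x_G (post-trade) clear at
    p_F = alpha*w*L/x_F and p_G = (1-alpha)*w*L/x_G, so the budget
    identity p_F*x_F + p_G*x_G = w*L holds exactly.

    Quantities must be strictly positive; the simulator floors abandoned
    markets at :data:`QUANTITY_FLOOR` before calling this.
    """
    x_F = np.asarray(x_F, dtype=float)
    x_G = np.asarray(x_G, dtype=float)
    if np.any(x_F <= 0) or np.any(x_G <= 0):
        raise DomainError("marketed quantities must be strictly positive (apply the quantity floor)")
    alpha = np.asarray(alpha, dtype=float)
    budget = np.asarray(w, dtype=float) * np.asarray(L, dtype=float)
    return alpha * budget / x_F, (1.0 - alpha) * budget / x_G


def price_index(p_F, p_G, gamma_F=1.0, gamma_G=1.0):
    """Average price index p = (gamma_F*p_F + gamma_G*p_G) / K with K=2.

    Both goods carry equal weight by default, collapsing to the simple
    mean (p_F + p_G) / 2.
    """
    p_F = _check_nonneg("p_F", p_F)
    p_G = _check_nonneg("p_G", p_G)
    return (gamma_F * p_F + gamma_G * p_G) / 2.0


def nominal_output(x_F, x_G, p_F, p_G):
    """Nominal value of production Y = x_F*p_F + x_G*p_G."""
    x_F = _check_nonneg("x_F", x_F)
    x_G = _check_nonneg("x_G", x_G)
    return x_F * np.asarray(p_F, dtype=float) + x_G * np.asarray(p_G, dtype=float)


def update_alpha(p_F, w, L, c_bar, alpha_min):
    """Food budget share needed to defend the minimum bundle.

    The node-level bundle is c_bar * L (per-worker bundle times workers),
    so the required share of total income w*L is p_F*c_bar*L/(w*L) =
    p_F*c_bar/w.  The share is floored at alpha_min (households always
    consume at least that share) and capped at 1 (they cannot spend more
    than they earn; a binding cap marks the node food insecure).
    """
    w = np.asarray(w, dtype=float)
    L = np.asarray(L, dtype=float)
    if np.any(w * L <= 0):
        raise EmptiedNodeError("alpha update undefined for a node with no income (w*L <= 0)")
    required = np.asarray(p_F, dtype=float) * c_bar / w
    return np.clip(np.maximum(required, alpha_min), alpha_min, 1.0)
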