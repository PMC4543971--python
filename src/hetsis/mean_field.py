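"""Closed-form mean-field predictions for the adapted network.

Rewiring drains links from frequently infected nodes and deposits them on
susceptible ones, so the per-type mean degrees k_a, k_b self-organize.  Two
balance arguments pin down the stationary degree ratio q = k_b / k_a:

* *rewiring balance*: a type-i node loses links in proportion to how often
  it is infected and gains them in proportion to how often it is
  susceptible, so in the steady state [I_i]/[S_i] is proportional to 1/k_i
  (the per-type factors cancel in the ratio);
* *epidemic balance*: in the mean field a type-i node is infected at rate
  proportional to psi_i k_i, so [I_i]/[S_i] is proportional to psi_i k_i.

Equating the two across types gives psi_a k_a^2 = psi_b k_b^2, i.e. the
self-organized ratio q = sqrt(psi_a / psi_b).  It lies strictly between the
trivial lower bound q = 1 and the equal-infection-rate upper bound
q = psi_a / psi_b (where psi_a k_a = psi_b k_b).

A link-centric percolation argument rates the robustness of a degree-ratio
configuration: given one active (S-I) link, the expected number of
secondary active links created by transmission along it is

    Z0(q) = C (p_a psi_a k_a^2 + p_b psi_b k_b^2) / <k>,

with k_a = <k>/(p_a + p_b q), k_b = q k_a (the mean degree is conserved).
A random active link reaches a type-i susceptible with probability
proportional to p_i k_i, infects it at rate proportional to psi_i, and the
new infected node then carries ~k_i links.  The prefactor C collects the
rate constants (here C = beta/(mu + omega): transmission relative to the
rates that deactivate a link); every conclusion drawn from Z0 -- in
particular its minimizer q* = psi_a/psi_b -- is invariant to C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .params import ModelParams

__all__ = [
    "DegreeRatioPrediction",
    "PercolationCurve",
    "predict_degree_ratio",
    "link_reproductive_number",
    "optimal_degree_ratio",
    "percolation_curve",
]


@dataclass(frozen=True)
class DegreeRatioPrediction:
    """Self-organized degree ratio k_b/k_a and its bounds."""

    ratio: float          # sqrt(psi_a / psi_b)
    lower_bound: float    # 1: equal degrees
    upper_bound: float    # psi_a / psi_b: equal infection rates


@dataclass
class PercolationCurve:
    """Z0 sampled on a grid of degree ratios, with its minimizer."""

    q: np.ndarray
    z0: np.ndarray
    q_optimal: float


def predict_degree_ratio(psi_a: float, psi_b: float) -> DegreeRatioPrediction:
    """Predicted stationary degree ratio ``k_b/k_a = sqrt(psi_a/psi_b)``.

    Requires psi_a >= psi_b > 0.  For psi_a = psi_b the ratio is 1 and the
    bounds collapse.
    """
    if not psi_b > 0:
        raise ValueError(f"psi_b must be positive, got {psi_b}")
    if not psi_a >= psi_b:
        raise ValueError(f"psi_a must be >= psi_b, got {psi_a} < {psi_b}")
    return DegreeRatioPrediction(
        ratio=float(np.sqrt(psi_a / psi_b)),
        lower_bound=1.0,
        upper_bound=psi_a / psi_b,
    )


def _type_degrees(q: float, params: ModelParams) -> tuple[float, float]:
    """(k_a, k_b) for degree ratio q at fixed mean degree <k>."""
    k_a = params.mean_degree / (params.p_a + params.p_b * q)
    return k_a, q * k_a


def link_reproductive_number(q: float, params: ModelParams) -> float:
    """Expected secondary active links per focal active link, Z0(q)."""
    if q <= 0:
        raise ValueError(f"degree ratio q must be positive, got {q}")
    k_a, k_b = _type_degrees(q, params)
    prefactor = params.beta / (params.mu + params.omega)
    return (
        prefactor
        * (params.p_a * params.psi_a * k_a**2 + params.p_b * params.psi_b * k_b**2)
        / params.mean_degree
    )


def optimal_degree_ratio(
    params: ModelParams, q_min: float = 1e-2, q_max: float = 1e3
) -> float:
    """Degree ratio minimizing Z0, found numerically.

    A coarse log-grid scan brackets the minimum, which golden-section /
    parabolic refinement then resolves.  Analytically the constrained
    minimum satisfies psi_a k_a = psi_b k_b (equal per-node infection
    rates), i.e. q* = psi_a / psi_b, independent of beta, mu, omega, <k>
    and p_a; the numerical route makes no use of that result.
    """
    grid = np.geomspace(q_min, q_max, 241)
    vals = [link_reproductive_number(q, params) for q in grid]
    j = int(np.argmin(vals))
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, grid.size - 1)]
    res = minimize_scalar(
        lambda q: link_reproductive_number(q, params),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def percolation_curve(
    params: ModelParams, q_min: float = 1e-2, q_max: float = 1e3, n: int = 200
) -> PercolationCurve:
    """Z0 on a log grid of degree ratios, plus the refined minimizer."""
    q = np.geomspace(q_min, q_max, n)
    z0 = np.array([link_reproductive_number(v, params) for v in q])
    return PercolationCurve(q=q, z0=z0, q_optimal=optimal_degree_ratio(params, q_min, q_max))
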