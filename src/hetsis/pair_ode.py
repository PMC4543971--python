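"""Pair-approximation (moment-closure) ODEs of the adaptive two-type SIS model.

The hierarchy of network moments is truncated at the pair level: the density
of a triplet chain X_u - Y_v - Z_w is approximated, in the ordered
convention, by ``[X_u Y_v] [Y_v Z_w] / [Y_v]`` -- the number of focal pairs
times the expected number of Z_w-neighbours of the middle node.  In the
unordered bookkeeping this same closure carries symmetry factors delta in
{4, 2, 1}; the ordered convention absorbs them.

The resulting system has 12 variables and one conservation law (total
ordered link density = <k>), i.e. 11 independent ODEs.  The right-hand side
is written so that it also accepts complex input, which lets every Jacobian
in the package be computed by complex-step differentiation to machine
precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .moments import DROP_INDEX, MomentState
from .params import ModelParams

__all__ = [
    "rhs",
    "closure_triplet",
    "integrate",
    "Trajectory",
    "find_steady_state",
    "jacobian",
    "reduce_state",
    "expand_state",
]

#: susceptible fractions below this are treated as exactly zero in
#: denominators, which makes the extinct plane invariant in floating point
EPS_GUARD = 1e-12

_CSTEP = 1e-200  # complex-step size; rhs is analytic so any tiny h works


def closure_triplet(xy_density, yz_density, y_fraction):
    """Pair-approximation closure for an ordered triplet chain density.

    Returns ``xy * yz / y``: the density of X_u - Y_v pairs times the
    expected number of Z_w-neighbours per Y_v node.  Bilinear in the two
    pair densities.  If the middle-node fraction is (numerically) zero the
    chain density is returned as 0; the numerator pair densities vanish at
    least as fast, so this guard only regularizes the absorbing boundary.
    """
    if np.real(y_fraction) < EPS_GUARD:
        return 0.0 * (xy_density + yz_density)
    return xy_density * yz_density / y_fraction


def _rhs_raw(y, beta, psi, p, mu, omega):
    """Right-hand side on the flat 12-vector; psi and p are length-2 arrays.

    Works elementwise on scalars (real or complex).  Layout matches
    :data:`hetsis.moments.FIELDS`.
    """
    i = [y[0], y[1]]
    ss = [[y[2], y[3]], [y[3], y[4]]]
    si = [[y[5], y[6]], [y[7], y[8]]]
    ii = [[y[9], y[10]], [y[10], y[11]]]

    s = [p[0] - i[0], p[1] - i[1]]
    # G_u: total density of S-I links anchored on a type-u susceptible node;
    # W_u: expected number of infected neighbours per type-u susceptible.
    g = [si[0][0] + si[0][1], si[1][0] + si[1][1]]
    w = [0.0, 0.0]
    for u in (0, 1):
        if np.real(s[u]) >= EPS_GUARD:
            w[u] = g[u] / s[u]
    s_sum = s[0] + s[1]
    if np.real(s_sum) >= EPS_GUARD:
        inv_s_sum = 1.0 / s_sum
    else:
        inv_s_sum = 0.0

    di = [0.0, 0.0]
    dss = [[0.0, 0.0], [0.0, 0.0]]
    dsi = [[0.0, 0.0], [0.0, 0.0]]
    dii = [[0.0, 0.0], [0.0, 0.0]]

    for u in (0, 1):
        # infection of susceptible type-u nodes along their S-I links,
        # recovery of infected type-u nodes
        di[u] = -mu * i[u] + beta * psi[u] * g[u]
        for v in (0, 1):
            # S-S links: created by recovery of the I-end of S-I links and by
            # rewiring (the S-end of any S-I link reconnects to a random
            # susceptible, of type v with probability S_v / (S_a + S_b));
            # destroyed when either S-end is infected by a neighbour external
            # to the link (closed triplet chains).
            dss[u][v] = (
                mu * (si[u][v] + si[v][u])
                - beta * ss[u][v] * (psi[u] * w[u] + psi[v] * w[v])
                + omega * (g[u] * s[v] + g[v] * s[u]) * inv_s_sum
            )
            # S-I links (S-end type u, I-end type v): created by recovery of
            # one end of I-I links and by external infection of the far end
            # of S-S links; destroyed by recovery of the I-end, by internal
            # transmission, by rewiring, and by external infection of the
            # S-end.
            dsi[u][v] = (
                mu * ii[u][v]
                - (mu + beta * psi[u] + omega) * si[u][v]
                + beta * psi[v] * ss[u][v] * w[v]
                - beta * psi[u] * si[u][v] * w[u]
            )
            # I-I links: created by internal transmission across an S-I link
            # and by external infection of the S-end of an S-I link;
            # destroyed by recovery of either end.
            dii[u][v] = (
                -2.0 * mu * ii[u][v]
                + beta * (psi[u] * si[u][v] + psi[v] * si[v][u])
                + beta * (psi[u] * si[u][v] * w[u] + psi[v] * si[v][u] * w[v])
            )

    out = np.empty(12, dtype=np.result_type(y, float))
    out[0], out[1] = di
    out[2], out[3], out[4] = dss[0][0], dss[0][1], dss[1][1]
    out[5], out[6], out[7], out[8] = dsi[0][0], dsi[0][1], dsi[1][0], dsi[1][1]
    out[9], out[10], out[11] = dii[0][0], dii[0][1], dii[1][1]
    return out


def rhs_vector(y, params: ModelParams):
    """Flat-vector right-hand side (the workhorse for solvers)."""
    return _rhs_raw(
        np.asarray(y),
        params.beta,
        np.asarray(params.psi),
        np.asarray(params.p),
        params.mu,
        params.omega,
    )


def rhs(state: MomentState, params: ModelParams) -> MomentState:
    """Time derivative of a :class:`MomentState` under the pair equations."""
    return MomentState.from_vector(rhs_vector(state.to_vector(), params))


# ---------------------------------------------------------------------------
# conservation-reduced coordinates
# ---------------------------------------------------------------------------

def reduce_state(y: np.ndarray) -> np.ndarray:
    """Drop the dependent coordinate (ss_bb) from a 12-vector."""
    return np.delete(np.asarray(y), DROP_INDEX)


def expand_state(y_red: np.ndarray, params: ModelParams) -> np.ndarray:
    """Reconstruct the full 12-vector from 11 independent coordinates.

    ss_bb is recovered from link conservation:
    ss_bb = <k> - ss_aa - 2 ss_ab - 2 (sum SI) - ii_aa - 2 ii_ab - ii_bb.
    """
    y_red = np.asarray(y_red)
    y = np.empty(12, dtype=y_red.dtype)
    y[:DROP_INDEX] = y_red[:DROP_INDEX]
    y[DROP_INDEX + 1:] = y_red[DROP_INDEX:]
    ia, ib, ss_aa, ss_ab = y[0], y[1], y[2], y[3]
    si_sum = y[5] + y[6] + y[7] + y[8]
    ii_tot = y[9] + 2 * y[10] + y[11]
    y[DROP_INDEX] = params.mean_degree - ss_aa - 2 * ss_ab - 2 * si_sum - ii_tot
    return y


def _rhs_reduced(y_red, params: ModelParams):
    return reduce_state(rhs_vector(expand_state(y_red, params), params))


def _jac_reduced(y_red, params: ModelParams) -> np.ndarray:
    """11x11 Jacobian of the reduced system by complex-step differentiation."""
    n = y_red.size
    jac = np.empty((n, n))
    for j in range(n):
        yc = y_red.astype(complex)
        yc[j] += 1j * _CSTEP
        jac[:, j] = np.imag(_rhs_reduced(yc, params)) / _CSTEP
    return jac


def jacobian(state: MomentState, params: ModelParams) -> np.ndarray:
    """Jacobian of the dynamics restricted to the 11 independent coordinates.

    Computed by complex-step differentiation of the analytic right-hand side
    (exact to round-off).  Its eigenvalues determine the stability of fixed
    points within the conservation manifold.
    """
    return _jac_reduced(reduce_state(state.to_vector()), params)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Sampled solution of the pair ODEs."""

    times: np.ndarray
    states: np.ndarray  # (n_times, 12)
    params: ModelParams
    clipped: bool = False  # negative undershoots within -atol were clipped

    def final_state(self) -> MomentState:
        return MomentState.from_vector(self.states[-1])

    def prevalence(self) -> np.ndarray:
        return self.states[:, 0] + self.states[:, 1]

    def conservation_drift(self) -> float:
        totals = np.array(
            [MomentState.from_vector(s).ordered_link_total() for s in self.states]
        )
        return float(np.max(np.abs(totals - self.params.mean_degree)))

    def to_frame(self):
        """Trajectory as a DataFrame in the unordered link-density
        convention (one column per node fraction and link class)."""
        import pandas as pd

        from .moments import to_unordered_convention

        rows = [
            to_unordered_convention(MomentState.from_vector(s)) for s in self.states
        ]
        df = pd.DataFrame(rows)
        df.insert(0, "t", self.times)
        return df


def integrate(
    state0: MomentState,
    params: ModelParams,
    t_max: float,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_samples: int = 200,
) -> Trajectory:
    """Integrate the pair equations with a stiff-capable adaptive solver."""
    y0 = state0.to_vector()
    t_eval = np.linspace(0.0, t_max, n_samples)
    sol = solve_ivp(
        lambda t, y: rhs_vector(y, params),
        (0.0, t_max),
        y0,
        method="LSODA",
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
    )
    if not sol.success:
        raise RuntimeError(
            f"ODE integration failed at t = {sol.t[-1] if sol.t.size else 0.0}: "
            f"{sol.message}"
        )
    states = sol.y.T.copy()
    clipped = False
    undershoot = states < 0
    if np.any(undershoot):
        if np.min(states) < -10 * atol:
            raise RuntimeError(
                f"integration produced a negative density of {np.min(states)}"
            )
        states[undershoot] = 0.0
        clipped = True
    return Trajectory(times=sol.t, states=states, params=params, clipped=clipped)


# ---------------------------------------------------------------------------
# steady states
# ---------------------------------------------------------------------------

def find_steady_state(
    guess: MomentState,
    params: ModelParams,
    tol: float = 1e-11,
    max_iter: int = 50,
) -> MomentState:
    """Newton iteration for a fixed point of the pair equations.

    The search runs in the 11 independent coordinates (link conservation is
    enforced structurally, not by projection).  Converges quadratically near
    hyperbolic fixed points; raises with the last residual on failure.
    """
    y = reduce_state(guess.to_vector())
    for _ in range(max_iter):
        f = _rhs_reduced(y, params)
        res = float(np.max(np.abs(f)))
        if res < tol:
            return MomentState.from_vector(expand_state(y, params))
        jac = _jac_reduced(y, params)
        try:
            step = np.linalg.solve(jac, -f)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(
                f"singular Jacobian in Newton iteration (residual {res})"
            ) from exc
        # damped update: backtrack if the residual does not decrease
        lam = 1.0
        for _ in range(30):
            y_new = y + lam * step
            res_new = float(np.max(np.abs(_rhs_reduced(y_new, params))))
            if res_new < res or res_new < tol:
                break
            lam *= 0.5
        y = y_new
    res = float(np.max(np.abs(_rhs_reduced(y, params))))
    raise RuntimeError(
        f"Newton iteration did not converge in {max_iter} steps "
        f"(last residual {res})"
    )
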