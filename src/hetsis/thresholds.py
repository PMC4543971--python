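"""Bifurcation analysis: invasion and persistence thresholds.

The adaptive SIS model has two kinds of epidemic threshold in the
infectivity beta:

* the *invasion threshold* beta_inv, a transcritical bifurcation at which a
  disease-free state loses stability to a growing epidemic;
* the *persistence threshold* beta_per, a fold (saddle-node) bifurcation at
  which the endemic branch and an unstable saddle branch annihilate.

Because the disease-free states form a two-dimensional plane (any split of
the link budget among the S-S classes is stationary once the disease is
extinct), the invasion threshold depends on *which* disease-free link
configuration is probed.  The threshold of the well-mixed Erdos-Renyi
configuration is the *initial* invasion threshold; the unstable branch
emanating from the fold lands on a unique self-organized point of the plane,
and the threshold there is the *adapted* invasion threshold.

Continuation of equilibrium branches is done by pseudo-arclength
predictor-corrector iteration on the 11 conservation-reduced coordinates
plus beta.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .moments import MomentState, disease_free_state, random_mixing_state
from .pair_ode import (
    _CSTEP,
    _jac_reduced,
    _rhs_reduced,
    expand_state,
    find_steady_state,
    integrate,
    reduce_state,
)
from .params import ModelParams

__all__ = [
    "invasion_threshold_at",
    "continue_branch",
    "persistence_threshold",
    "adapted_invasion_threshold",
    "threshold_report",
    "EquilibriumBranch",
    "BranchPoint",
    "ThresholdReport",
]


# ---------------------------------------------------------------------------
# transcritical threshold of a disease-free configuration
# ---------------------------------------------------------------------------

def _infected_subsystem_matrix(
    beta: float, ss: np.ndarray, params: ModelParams
) -> np.ndarray:
    """Linearization of the infected moments about a disease-free state.

    The extinct state is non-isolated (a plane), so the full Jacobian always
    carries neutral directions there.  Stability against invasion is instead
    governed by the closed linear subsystem of the 7 infected moments:
    SI_aa, SI_ab, SI_ba, SI_bb, II_aa, II_ab, II_bb.  About [I]=0 with S-S
    configuration ``ss`` (2x2 ordered block) and S_u = p_u:

        d SI[u][v] = mu II[u][v] - (mu + beta psi_u + omega) SI[u][v]
                     + beta psi_v (SS[u][v] / p_v) sum_w SI[v][w]
        d II[u][v] = -2 mu II[u][v] + beta (psi_u SI[u][v] + psi_v SI[v][u])
    """
    mu, om = params.mu, params.omega
    psi, p = params.psi, params.p
    si_idx = {(0, 0): 0, (0, 1): 1, (1, 0): 2, (1, 1): 3}
    ii_idx = {(0, 0): 4, (0, 1): 5, (1, 0): 5, (1, 1): 6}
    m = np.zeros((7, 7))
    for u in (0, 1):
        for v in (0, 1):
            r = si_idx[(u, v)]
            m[r, si_idx[(u, v)]] -= mu + beta * psi[u] + om
            m[r, ii_idx[(u, v)]] += mu
            for w in (0, 1):
                m[r, si_idx[(v, w)]] += beta * psi[v] * ss[u][v] / p[v]
    for (u, v), r in (((0, 0), 4), ((0, 1), 5), ((1, 1), 6)):
        m[r, ii_idx[(u, v)]] -= 2.0 * mu
        m[r, si_idx[(u, v)]] += beta * psi[u]
        m[r, si_idx[(v, u)]] += beta * psi[v]
    return m


def _leading_growth_rate(beta: float, ss: np.ndarray, params: ModelParams) -> float:
    return float(
        np.max(np.linalg.eigvals(_infected_subsystem_matrix(beta, ss, params)).real)
    )


def invasion_threshold_at(
    df_state: MomentState,
    params: ModelParams,
    beta_max: float = 1e3,
    rtol: float = 1e-8,
) -> float:
    """Transcritical beta at which the given disease-free state can be invaded.

    Bisects the leading eigenvalue of the 7-dimensional infected subsystem.
    ``df_state`` must lie on the extinct plane (all infected moments zero).

    Raises
    ------
    ValueError
        If the state is not disease-free, or no eigenvalue sign change is
        bracketed below ``beta_max``.
    """
    y = df_state.to_vector()
    if np.max(np.abs(y[[0, 1, 5, 6, 7, 8, 9, 10, 11]])) > 1e-8:
        raise ValueError("df_state must lie on the disease-free plane")
    ss = np.array([[df_state.ss_aa, df_state.ss_ab],
                   [df_state.ss_ab, df_state.ss_bb]])
    lo = 0.0
    # the disease-free plane is stable as beta -> 0 (all rates are losses)
    hi = (params.mu + params.omega) / (max(params.psi) * max(params.mean_degree, 1.0))
    while _leading_growth_rate(hi, ss, params) < 0:
        hi *= 2.0
        if hi > beta_max:
            raise ValueError(
                f"threshold not bracketed: disease-free state still stable "
                f"at beta = {beta_max}"
            )
    while hi - lo > rtol * hi:
        mid = 0.5 * (lo + hi)
        if _leading_growth_rate(mid, ss, params) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# pseudo-arclength continuation
# ---------------------------------------------------------------------------

@dataclass
class BranchPoint:
    beta: float
    state: MomentState
    leading_eig: float
    stable: bool


@dataclass
class EquilibriumBranch:
    """A continued branch of equilibria with detected special points."""

    points: list[BranchPoint] = field(default_factory=list)
    fold_indices: list[int] = field(default_factory=list)
    plane_crossing: BranchPoint | None = None  # where the branch meets [I]=0
    warning: str | None = None

    @property
    def folds(self) -> list[BranchPoint]:
        return [self.points[i] for i in self.fold_indices]

    @property
    def betas(self) -> np.ndarray:
        return np.array([p.beta for p in self.points])

    @property
    def prevalences(self) -> np.ndarray:
        return np.array([p.state.prevalence for p in self.points])


# characteristic scales for the arclength metric: beta moves on the scale of
# the thresholds (~1e-2), link densities on the scale of <k>
_BETA_SCALE = 0.01


def _scales(params: ModelParams) -> np.ndarray:
    w = np.ones(12)
    w[2:] = max(params.mean_degree, 1.0) / 2.0
    return np.append(reduce_state(w), _BETA_SCALE)


def _corrector(
    z: np.ndarray,
    tangent: np.ndarray,
    z_pred: np.ndarray,
    params: ModelParams,
    scales: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 12,
) -> tuple[np.ndarray, bool, int]:
    """Newton iteration for F(y, beta) = 0 plus the arclength normalization."""
    for it in range(max_iter):
        y, beta = z[:-1], z[-1]
        pb = params.replace(beta=float(np.real(beta)))
        f = _rhs_reduced(y, pb)
        g = float(tangent @ ((z - z_pred) / scales))
        if max(np.max(np.abs(f)), abs(g)) < tol:
            return z, True, it
        jac = np.empty((12, 12))
        jac[:11, :11] = _jac_reduced(y, pb)
        # d rhs / d beta by complex step
        pc = _ComplexBeta(params, beta + 1j * _CSTEP)
        jac[:11, 11] = np.imag(_rhs_reduced(y.astype(complex), pc)) / _CSTEP
        jac[11, :] = tangent / scales
        rhs_vec = np.append(-f, -g)
        try:
            step = np.linalg.solve(jac, rhs_vec)
        except np.linalg.LinAlgError:
            return z, False, it
        z = z + step
        if not np.all(np.isfinite(z)):
            return z, False, it
    return z, False, max_iter


class _ComplexBeta:
    """Parameter view with a complex beta, for complex-step d/d beta."""

    def __init__(self, params: ModelParams, beta):
        self._p = params
        self.beta = beta

    def __getattr__(self, name):
        return getattr(self._p, name)


def _branch_point(y_red: np.ndarray, beta: float, params: ModelParams) -> BranchPoint:
    pb = params.replace(beta=beta)
    state = MomentState.from_vector(expand_state(y_red, pb))
    eigs = np.linalg.eigvals(_jac_reduced(y_red, pb))
    lead = float(np.max(eigs.real))
    return BranchPoint(beta=beta, state=state, leading_eig=lead, stable=lead < 0)


def continue_branch(
    params: ModelParams,
    beta_start: float,
    beta_end: float,
    start_state: MomentState,
    h0: float = 1e-3,
    h_min: float = 1e-7,
    h_max: float = 1e-2,
    stop_at_plane: bool = True,
    max_points: int = 20000,
) -> EquilibriumBranch:
    """Pseudo-arclength continuation of an equilibrium branch in beta.

    Secant predictor, Newton corrector, adaptive step halving/doubling in the
    scaled arclength metric.  The continuation passes around folds (recorded
    in ``branch.folds``); if ``stop_at_plane`` it terminates where the total
    prevalence crosses zero (recorded in ``branch.plane_crossing`` by linear
    interpolation of the last step).

    ``start_state`` must be a converged fixed point at ``beta_start``.
    """
    scales = _scales(params)
    branch = EquilibriumBranch()

    start = find_steady_state(start_state, params.replace(beta=beta_start))
    z = np.append(reduce_state(start.to_vector()), beta_start)
    branch.points.append(_branch_point(z[:-1], beta_start, params))

    direction = 1.0 if beta_end >= beta_start else -1.0
    # first predictor: straight in beta
    tangent = np.zeros(12)
    tangent[-1] = direction
    h = h0
    prev_dbeta = None

    while len(branch.points) < max_points:
        # resolve the approach to the extinct plane finely so that the
        # landing configuration interpolates accurately
        h_cap = h_max
        if stop_at_plane and branch.points[-1].state.prevalence < 0.02:
            h_cap = min(h_max, 2e-4)
        h = min(h, h_cap)
        z_pred = z + h * tangent * scales
        z_new, ok, n_iter = _corrector(z_pred.copy(), tangent, z_pred, params, scales)
        if not ok:
            h *= 0.5
            if h < h_min:
                branch.warning = "step-size underflow before reaching beta_end"
                break
            continue

        dz = (z_new - z) / scales
        norm = np.linalg.norm(dz)
        new_tangent = dz / norm if norm > 0 else tangent
        dbeta = z_new[-1] - z[-1]

        pt = _branch_point(z_new[:-1], float(z_new[-1]), params)
        branch.points.append(pt)

        # fold: the beta-component of the step changes sign along arclength
        if prev_dbeta is not None and dbeta * prev_dbeta < 0 and abs(prev_dbeta) > 0:
            branch.fold_indices.append(len(branch.points) - 2)
        prev_dbeta = dbeta

        # termination at the extinct plane
        prev_pt = branch.points[-2]
        if stop_at_plane and pt.state.prevalence < 0 <= prev_pt.state.prevalence:
            lam = prev_pt.state.prevalence / (
                prev_pt.state.prevalence - pt.state.prevalence
            )
            y_cross = (1 - lam) * np.append(
                reduce_state(prev_pt.state.to_vector()), prev_pt.beta
            ) + lam * np.append(reduce_state(pt.state.to_vector()), pt.beta)
            branch.plane_crossing = _branch_point(
                y_cross[:-1], float(y_cross[-1]), params
            )
            break

        # termination in beta
        if (z_new[-1] - beta_end) * direction >= 0 and abs(dbeta) > 0:
            break

        z, tangent = z_new, new_tangent
        if n_iter <= 4:
            h = min(2.0 * h, h_cap)
    else:
        branch.warning = "max_points reached"

    return branch


def _refine_fold(
    branch: EquilibriumBranch,
    fold_index: int,
    params: ModelParams,
) -> BranchPoint:
    """Polish a fold location bracketed along a downward-continued branch.

    Restarts a short continuation a few accepted points before the bracketed
    fold with steps reduced ~100-fold, then resolves the extremum of beta
    below the step size with a parabola through the extremal triple.
    """
    start_idx = max(fold_index - 3, 0)
    start_pt = branch.points[start_idx]
    local = continue_branch(
        params,
        beta_start=start_pt.beta,
        beta_end=start_pt.beta - 1.0,  # run downward, past the fold
        start_state=start_pt.state,
        h0=1e-4,
        h_min=1e-9,
        h_max=1e-4,
        stop_at_plane=False,
        max_points=800,
    )
    betas = local.betas
    if betas.size < 5:
        return branch.points[fold_index]
    k = int(np.argmin(betas))
    # parabola through the extremal triple for sub-step resolution of beta
    if 0 < k < betas.size - 1:
        b0, b1, b2 = betas[k - 1], betas[k], betas[k + 1]
        denom = b0 - 2 * b1 + b2
        if abs(denom) > 0:
            beta_fold = b1 - 0.125 * (b2 - b0) ** 2 / denom
        else:
            beta_fold = b1
    else:
        beta_fold = betas[k]
    pt = local.points[k]
    return BranchPoint(
        beta=float(beta_fold), state=pt.state,
        leading_eig=pt.leading_eig, stable=pt.stable,
    )


# ---------------------------------------------------------------------------
# thresholds from continuation
# ---------------------------------------------------------------------------

def _endemic_anchor(params: ModelParams, beta_hi: float) -> MomentState:
    """A converged endemic fixed point at a supercritical beta."""
    pb = params.replace(beta=beta_hi)
    traj = integrate(random_mixing_state(pb, 0.05), pb, t_max=50.0 / pb.mu,
                     n_samples=20)
    final = traj.final_state()
    if final.prevalence < 1e-4:
        raise RuntimeError(
            f"no endemic state reached at beta = {beta_hi}; "
            "increase the upper end of the scanned range"
        )
    return find_steady_state(final, pb)


def _downward_branch(params: ModelParams, beta_hi: float) -> EquilibriumBranch:
    anchor = _endemic_anchor(params, beta_hi)
    return continue_branch(
        params,
        beta_start=beta_hi,
        beta_end=1e-6,
        start_state=anchor,
        stop_at_plane=True,
    )


def persistence_threshold(
    params: ModelParams, beta_hi: float | None = None
) -> tuple[float, MomentState]:
    """Locate the fold (saddle-node) of the endemic branch.

    Continues the endemic branch downward in beta from ``beta_hi`` (default:
    four times the initial invasion threshold) until the step direction in
    beta reverses, then polishes the fold with reduced steps.

    Raises
    ------
    RuntimeError
        If no fold is found in range (transition continuous or out of range).
    """
    if beta_hi is None:
        beta_hi = 4.0 * invasion_threshold_at(disease_free_state(params), params)
    branch = _downward_branch(params, beta_hi)
    if not branch.fold_indices:
        raise RuntimeError(
            "no fold found: transition continuous or outside scanned range"
        )
    fold = _refine_fold(branch, branch.fold_indices[0], params)
    return fold.beta, fold.state


def adapted_invasion_threshold(
    params: ModelParams, beta_hi: float | None = None
) -> tuple[float, tuple[float, float, float]]:
    """Invasion threshold of the self-organized (adapted) link configuration.

    The unstable branch beyond the fold is continued until the prevalence
    crosses zero; the landing S-S configuration on the extinct plane is
    extracted by linear interpolation of the crossing step, and the returned
    threshold is re-derived from that configuration through
    :func:`invasion_threshold_at` (mandatory self-consistency: the branch
    beta at the crossing must agree with the re-derived value).
    """
    if beta_hi is None:
        beta_hi = 4.0 * invasion_threshold_at(disease_free_state(params), params)
    branch = _downward_branch(params, beta_hi)
    if branch.plane_crossing is None:
        raise RuntimeError(
            "unstable branch did not reach the extinct plane in range"
            + (f" ({branch.warning})" if branch.warning else "")
        )
    cross = branch.plane_crossing
    st = cross.state
    landing = (max(st.ss_aa, 0.0), max(st.ss_ab, 0.0), max(st.ss_bb, 0.0))
    # renormalize the interpolated configuration onto the plane exactly
    total = landing[0] + 2 * landing[1] + landing[2]
    scale = params.mean_degree / total
    landing = tuple(v * scale for v in landing)
    beta_t = invasion_threshold_at(disease_free_state(params, landing), params)
    if abs(beta_t - cross.beta) > 5e-3 * beta_t:
        raise RuntimeError(
            f"landing-point inconsistency: branch crossing at beta = "
            f"{cross.beta}, re-derived transcritical at beta = {beta_t}"
        )
    return beta_t, landing


@dataclass
class ThresholdReport:
    """The three critical infectivities and their link configurations."""

    beta_per: float | None
    beta_inv_initial: float
    beta_inv_adapted: float | None
    initial_ss_config: tuple[float, float, float]
    landing_ss_config: tuple[float, float, float] | None
    params: ModelParams

    def to_dict(self) -> dict:
        return {
            "beta_per": self.beta_per,
            "beta_inv_initial": self.beta_inv_initial,
            "beta_inv_adapted": self.beta_inv_adapted,
            "initial_ss_config": list(self.initial_ss_config),
            "landing_ss_config": (
                list(self.landing_ss_config)
                if self.landing_ss_config is not None else None
            ),
            "params": self.params.as_dict(),
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)


def threshold_report(
    params: ModelParams, beta_hi: float | None = None
) -> ThresholdReport:
    """Compute all three thresholds for one parameter set.

    ``beta_per <= beta_inv_adapted`` (the bistable interval, possibly
    degenerate) and for heterogeneous susceptibilities
    ``beta_inv_initial < beta_inv_adapted``.
    """
    df = disease_free_state(params)
    initial_cfg = (df.ss_aa, df.ss_ab, df.ss_bb)
    beta_inv_initial = invasion_threshold_at(df, params)
    if beta_hi is None:
        beta_hi = 4.0 * beta_inv_initial
    beta_per = landing = beta_adapt = None
    try:
        beta_per, _ = persistence_threshold(params, beta_hi)
        beta_adapt, landing = adapted_invasion_threshold(params, beta_hi)
    except RuntimeError:
        # continuous transition: the invasion threshold is the only one
        if beta_per is None:
            beta_adapt = beta_inv_initial
    return ThresholdReport(
        beta_per=beta_per,
        beta_inv_initial=beta_inv_initial,
        beta_inv_adapted=beta_adapt,
        initial_ss_config=initial_cfg,
        landing_ss_config=landing,
        params=params,
    )
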