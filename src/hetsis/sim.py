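"""Stochastic simulation of the adaptive two-type SIS model.

Networks are simple undirected graphs with per-node immutable type (A/B)
and mutable epidemic state (S/I).  The contact structure is initialized as
an Erdos-Renyi random graph G(N, K) -- exactly K distinct edges drawn
uniformly -- and evolves only through rewiring, which conserves the link
count.  The event-driven simulation itself runs in a compiled kernel
(:mod:`hetsis._kernel`); this module provides the network container, the
measurement protocols (stationarity runs, adapted restarts, invasion
threshold scans) and reference implementations of single events used in
testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from ._kernel import STATUS_ESTABLISHED, STATUS_EXTINCT, STATUS_TMAX, run_kernel
from .params import ModelParams

__all__ = [
    "NetworkState",
    "TimeSeries",
    "StationarySummary",
    "generate_er_network",
    "assign_initial_condition",
    "gillespie_run",
    "rewire_event",
    "run_to_stationarity",
    "run_quasi_stationary",
    "QuasiStationarySummary",
    "adapted_restart_state",
    "estimate_invasion_threshold_sim",
    "ThresholdScanResult",
    "degree_stats",
    "DegreeStats",
]

TYPE_A, TYPE_B = 0, 1
STATE_S, STATE_I = 0, 1


@dataclass
class NetworkState:
    """A simple undirected graph with node types and epidemic states.

    ``node_type`` (0 = A, 1 = B) is immutable during a run; ``node_state``
    (0 = S, 1 = I) evolves.  Edges are stored as two endpoint arrays of
    length K; the edge count is invariant under the dynamics.
    """

    node_type: np.ndarray
    node_state: np.ndarray
    edge_u: np.ndarray
    edge_v: np.ndarray
    rng_seed: int | None = None

    @property
    def n_nodes(self) -> int:
        return int(self.node_type.shape[0])

    @property
    def n_links(self) -> int:
        return int(self.edge_u.shape[0])

    def edge_set(self) -> set[tuple[int, int]]:
        return {
            (int(min(u, v)), int(max(u, v)))
            for u, v in zip(self.edge_u, self.edge_v)
        }

    def adjacency(self) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in range(self.n_nodes)]
        for u, v in zip(self.edge_u, self.edge_v):
            adj[int(u)].add(int(v))
            adj[int(v)].add(int(u))
        return adj

    def si_links(self) -> set[tuple[int, int]]:
        """The active (S-I) links, recomputed from scratch: (s_node, i_node)."""
        st = self.node_state
        out = set()
        for u, v in zip(self.edge_u, self.edge_v):
            if st[u] != st[v]:
                s, i = (u, v) if st[u] == STATE_S else (v, u)
                out.add((int(s), int(i)))
        return out

    def copy(self) -> "NetworkState":
        return NetworkState(
            node_type=self.node_type.copy(),
            node_state=self.node_state.copy(),
            edge_u=self.edge_u.copy(),
            edge_v=self.edge_v.copy(),
            rng_seed=self.rng_seed,
        )

    def n_infected(self) -> int:
        return int(self.node_state.sum())

    def check_consistency(self) -> None:
        """Assert the structural invariants (simple graph, valid labels)."""
        n = self.n_nodes
        if self.edge_u.shape != self.edge_v.shape:
            raise AssertionError("edge endpoint arrays differ in length")
        if np.any(self.edge_u == self.edge_v):
            raise AssertionError("self-loop present")
        if self.edge_u.size and (
            min(self.edge_u.min(), self.edge_v.min()) < 0
            or max(self.edge_u.max(), self.edge_v.max()) >= n
        ):
            raise AssertionError("edge endpoint out of range")
        if len(self.edge_set()) != self.n_links:
            raise AssertionError("duplicate edge present")
        for arr, name in ((self.node_type, "type"), (self.node_state, "state")):
            if not np.all((arr == 0) | (arr == 1)):
                raise AssertionError(f"invalid node {name} label")


@dataclass
class TimeSeries:
    """Sampled output of a simulation run.

    Prevalences are node fractions ([I_a] + [I_b] = [I]); ``k_a``/``k_b``
    are the per-type mean degrees, satisfying p_a k_a + p_b k_b = <k> at all
    times.  ``si_a``/``si_b`` are per-node densities of active links whose
    susceptible end has the given type.
    """

    times: np.ndarray
    i_a: np.ndarray
    i_b: np.ndarray
    k_a: np.ndarray
    k_b: np.ndarray
    si_a: np.ndarray
    si_b: np.ndarray
    status: int
    t_end: float
    n_events: int
    seed: int

    @property
    def prevalence(self) -> np.ndarray:
        return self.i_a + self.i_b

    @property
    def extinct(self) -> bool:
        return self.status == STATUS_EXTINCT

    @property
    def established(self) -> bool:
        return self.status == STATUS_ESTABLISHED

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.times,
                "I": self.prevalence,
                "I_a": self.i_a,
                "I_b": self.i_b,
                "k_a": self.k_a,
                "k_b": self.k_b,
                "si_a": self.si_a,
                "si_b": self.si_b,
            }
        )


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def generate_er_network(n_nodes: int, n_links: int, seed: int) -> NetworkState:
    """Draw G(N, K): exactly ``n_links`` distinct edges, uniform over simple
    graphs with that edge count.  Node types and states are left unset (all
    zero); use :func:`assign_initial_condition`.
    """
    n, k = int(n_nodes), int(n_links)
    max_edges = n * (n - 1) // 2
    if k > max_edges:
        raise ValueError(f"n_links={k} exceeds the {max_edges} possible edges")
    rng = np.random.default_rng(seed)
    if k > max_edges // 2:
        # dense regime (only reachable for small n): enumerate all pairs and
        # sample rows without replacement
        iu, iv = np.triu_indices(n, 1)
        chosen = rng.choice(max_edges, size=k, replace=False)
        edges = np.stack([iu[chosen], iv[chosen]], axis=1).astype(np.int64)
    else:
        # sparse regime: rejection sampling of distinct pairs
        seen: set[tuple[int, int]] = set()
        us, vs = [], []
        while len(seen) < k:
            m = k - len(seen)
            cand_u = rng.integers(0, n, size=2 * m + 8)
            cand_v = rng.integers(0, n, size=2 * m + 8)
            for u, v in zip(cand_u, cand_v):
                if u == v:
                    continue
                pair = (int(min(u, v)), int(max(u, v)))
                if pair in seen:
                    continue
                seen.add(pair)
                us.append(pair[0])
                vs.append(pair[1])
                if len(seen) == k:
                    break
        edges = np.array([us, vs], dtype=np.int64).T
    net = NetworkState(
        node_type=np.zeros(n, dtype=np.uint8),
        node_state=np.zeros(n, dtype=np.uint8),
        edge_u=edges[:, 0].astype(np.int64),
        edge_v=edges[:, 1].astype(np.int64),
        rng_seed=int(seed),
    )
    return net


def assign_initial_condition(
    net: NetworkState, p_a: float, initial_prevalence: float, seed: int
) -> NetworkState:
    """Assign types and epidemic states uniformly at random, independently.

    Exactly ``round(N p_a)`` nodes become type A and ``round(N I_0)`` nodes
    infected, in two independent uniform draws.
    """
    if not 0 <= p_a <= 1:
        raise ValueError(f"p_a must lie in [0, 1], got {p_a}")
    if not 0 <= initial_prevalence <= 1:
        raise ValueError(
            f"initial_prevalence must lie in [0, 1], got {initial_prevalence}"
        )
    rng = np.random.default_rng(seed)
    n = net.n_nodes
    net = net.copy()
    n_a = round(n * p_a)
    n_i = round(n * initial_prevalence)
    types = np.ones(n, dtype=np.uint8)
    types[rng.choice(n, size=n_a, replace=False)] = TYPE_A
    states = np.zeros(n, dtype=np.uint8)
    states[rng.choice(n, size=n_i, replace=False)] = STATE_I
    net.node_type = types
    net.node_state = states
    net.rng_seed = int(seed)
    return net


# ---------------------------------------------------------------------------
# events and runs
# ---------------------------------------------------------------------------

def rewire_event(net: NetworkState, si_link: tuple[int, int], rng) -> None:
    """Apply one rewiring event in place (reference implementation).

    ``si_link = (s, i)`` must currently connect a susceptible and an
    infected node.  The link is cut and the susceptible end reconnects to a
    target drawn uniformly from the susceptible nodes excluding ``s`` itself
    and its current neighbours (the graph stays simple).  If no eligible
    target exists the event is a no-op.
    """
    s, i = si_link
    st = net.node_state
    if st[s] == STATE_I and st[i] == STATE_S:
        s, i = i, s
    if not (st[s] == STATE_S and st[i] == STATE_I):
        raise AssertionError(
            f"rewire_event called on a non-S-I link ({si_link}): "
            "S-I bookkeeping is inconsistent"
        )
    adj = net.adjacency()
    if i not in adj[s]:
        raise AssertionError(f"{si_link} is not an edge of the network")
    eligible = [
        x
        for x in range(net.n_nodes)
        if st[x] == STATE_S and x != s and x not in adj[s]
    ]
    if not eligible:
        return
    target = eligible[int(rng.integers(len(eligible)))]
    for e in range(net.n_links):
        u, v = int(net.edge_u[e]), int(net.edge_v[e])
        if (u, v) in ((s, i), (i, s)):
            if u == i:
                net.edge_u[e] = target
            else:
                net.edge_v[e] = target
            return
    raise AssertionError("edge not found")  # unreachable after the adj check


def _alloc_samples(t0: float, t_max: float, sample_dt: float):
    n = int(np.ceil((t_max - t0) / sample_dt)) + 2
    return (
        np.empty(n),
        np.empty(n, dtype=np.int64),
        np.empty(n, dtype=np.int64),
        np.empty(n, dtype=np.int64),
        np.empty(n, dtype=np.int64),
        np.empty(n, dtype=np.int64),
        np.empty(n, dtype=np.int64),
    )


def gillespie_run(
    net: NetworkState,
    params: ModelParams,
    t_max: float,
    stop_on_extinction: bool = True,
    sample_interval: float = 1.0,
    seed: int = 0,
    t0: float = 0.0,
    stop_above_ninf: int = 0,
    in_place: bool = False,
) -> TimeSeries:
    """Exact event-driven simulation of the adaptive SIS process.

    Simulates recovery (rate mu per infected node), rewiring (rate omega per
    S-I link) and contagion (rate beta * psi of the susceptible end, per S-I
    link) until ``t_max``, extinction, or -- if ``stop_above_ninf > 0`` --
    until the infected count reaches that mark (used by invasion scans).

    Unless ``in_place``, the input network is not modified.
    """
    if sample_interval <= 0:
        raise ValueError("sample_interval must be positive")
    work = net if in_place else net.copy()
    bufs = _alloc_samples(t0, t_max, sample_interval)
    idx, t_end, status, n_events = run_kernel(
        work.node_type,
        work.node_state,
        work.edge_u,
        work.edge_v,
        params.beta,
        params.psi_a,
        params.psi_b,
        params.mu,
        params.omega,
        t0,
        t_max,
        sample_interval,
        stop_on_extinction,
        stop_above_ninf,
        int(seed) & 0x7FFFFFFF,
        *bufs,
    )
    times, ia, ib, ka, kb, sia, sib = (b[:idx] for b in bufs)
    n = work.n_nodes
    n_a = int(np.sum(work.node_type == TYPE_A))
    n_b = n - n_a
    with np.errstate(divide="ignore", invalid="ignore"):
        k_a = ka / n_a if n_a else np.full(idx, np.nan)
        k_b = kb / n_b if n_b else np.full(idx, np.nan)
    ts = TimeSeries(
        times=times.copy(),
        i_a=ia / n,
        i_b=ib / n,
        k_a=k_a,
        k_b=k_b,
        si_a=sia / n,
        si_b=sib / n,
        status=int(status),
        t_end=float(t_end),
        n_events=int(n_events),
        seed=int(seed),
    )
    return ts


# ---------------------------------------------------------------------------
# measurement protocols
# ---------------------------------------------------------------------------

@dataclass
class StationarySummary:
    """Time-averaged observables of a (quasi-)stationary epidemic state."""

    prevalence: float
    prevalence_se: float
    i_a: float
    i_b: float
    k_a: float
    k_b: float
    degree_ratio: float | None
    extinct: bool
    t_end: float
    n_windows: int
    seed: int


def _window_stats(ts: TimeSeries):
    prev = ts.prevalence
    n = prev.size
    se = float(np.std(prev) / np.sqrt(max(n, 1)))
    return float(np.mean(prev)), se


def run_to_stationarity(
    net: NetworkState,
    params: ModelParams,
    seed: int = 0,
    window: float | None = None,
    t_cap: float = 1e5,
    n_avg_windows: int = 1,
    samples_per_window: int = 200,
) -> tuple[NetworkState, StationarySummary]:
    """Evolve until the prevalence is stationary, then time-average.

    Stationarity criterion: the mean prevalence over two consecutive windows
    of length ``window`` (default 50/mu, scale-free in the recovery rate)
    differs by less than two standard errors.  A further ``n_avg_windows``
    windows are then averaged for the reported observables.  Extinction
    before stationarity is a normal outcome, flagged in the summary.
    """
    if window is None:
        window = 50.0 / params.mu
    sample_dt = window / samples_per_window
    work = net.copy()
    rng = np.random.default_rng(seed)

    def one_window(t0):
        return gillespie_run(
            work, params, t_max=t0 + window, t0=t0,
            sample_interval=sample_dt,
            seed=int(rng.integers(2**31 - 1)),
            in_place=True,
        )

    t = 0.0
    prev_stats = None
    n_windows = 0
    stationary = False
    while t < t_cap:
        ts = one_window(t)
        t = ts.t_end
        n_windows += 1
        if ts.extinct:
            summary = StationarySummary(
                prevalence=0.0, prevalence_se=0.0, i_a=0.0, i_b=0.0,
                k_a=float(ts.k_a[-1]), k_b=float(ts.k_b[-1]),
                degree_ratio=None, extinct=True, t_end=t,
                n_windows=n_windows, seed=seed,
            )
            return work, summary
        stats = _window_stats(ts)
        if prev_stats is not None:
            m1, se1 = prev_stats
            m2, se2 = stats
            if abs(m1 - m2) < 2.0 * math.hypot(se1, se2):
                stationary = True
                break
        prev_stats = stats
    if not stationary and t >= t_cap:
        pass  # report averages anyway; t_end records the cap

    # averaging pass
    prevs, ias, ibs, kas, kbs = [], [], [], [], []
    ses = []
    for _ in range(max(n_avg_windows, 1)):
        ts = one_window(t)
        t = ts.t_end
        n_windows += 1
        if ts.extinct:
            summary = StationarySummary(
                prevalence=0.0, prevalence_se=0.0, i_a=0.0, i_b=0.0,
                k_a=float(ts.k_a[-1]), k_b=float(ts.k_b[-1]),
                degree_ratio=None, extinct=True, t_end=t,
                n_windows=n_windows, seed=seed,
            )
            return work, summary
        m, se = _window_stats(ts)
        prevs.append(m)
        ses.append(se)
        ias.append(float(np.mean(ts.i_a)))
        ibs.append(float(np.mean(ts.i_b)))
        kas.append(float(np.mean(ts.k_a)))
        kbs.append(float(np.mean(ts.k_b)))
    k_a, k_b = float(np.mean(kas)), float(np.mean(kbs))
    summary = StationarySummary(
        prevalence=float(np.mean(prevs)),
        prevalence_se=float(np.linalg.norm(ses) / len(ses)),
        i_a=float(np.mean(ias)),
        i_b=float(np.mean(ibs)),
        k_a=k_a,
        k_b=k_b,
        degree_ratio=(k_b / k_a if k_a > 0 else None),
        extinct=False,
        t_end=t,
        n_windows=n_windows,
        seed=seed,
    )
    return work, summary


@dataclass
class QuasiStationarySummary:
    """Window-averaged observables of the survival-conditioned endemic state."""

    prevalence: float
    degree_ratio: float
    window_ratios: list[float]
    window_prevalences: list[float]
    n_restarts: int
    t_end: float
    seed: int


def run_quasi_stationary(
    net: NetworkState,
    params: ModelParams,
    seed: int = 0,
    window: float = 1e4,
    n_burnin: int = 2,
    n_avg: int = 6,
    max_restarts: int = 30,
    samples_per_window: int = 100,
    collapse_frac: float = 0.75,
) -> tuple[NetworkState, QuasiStationarySummary]:
    """Measure the quasi-stationary endemic state near a metastable regime.

    At finite N an endemic state close to the persistence threshold is
    metastable: stochastic escape through the nearby saddle eventually
    extinguishes the epidemic.  The standard estimator of the
    quasi-stationary (survival-conditioned) ensemble restarts any window
    that escaped -- went extinct, or collapsed below ``collapse_frac``
    times its starting prevalence (past the saddle the decay to extinction
    is slow, so the collapse must be detected before the absorbing state
    is reached) -- from the state at the window's start, with fresh
    randomness.  After ``n_burnin`` burn-in windows, prevalence and degree
    ratio are averaged over ``n_avg`` windows.

    Raises
    ------
    RuntimeError
        If more than ``max_restarts`` windows go extinct (the state is not
        meaningfully metastable at these parameters).
    """
    rng = np.random.default_rng(seed)
    work = net.copy()
    t = 0.0
    restarts = 0
    ratios: list[float] = []
    prevs: list[float] = []
    w = 0
    while w < n_burnin + n_avg:
        snapshot = work.copy()
        ts = gillespie_run(
            work, params, t_max=t + window, t0=t,
            sample_interval=window / samples_per_window,
            seed=int(rng.integers(2**31 - 1)), in_place=True,
        )
        start_prev = float(ts.prevalence[0])
        escaped = ts.extinct or (
            float(ts.prevalence[-1]) < collapse_frac * start_prev
        )
        if escaped:
            restarts += 1
            if restarts > max_restarts:
                raise RuntimeError(
                    f"exceeded {max_restarts} extinction restarts: no "
                    f"metastable endemic state at beta={params.beta}"
                )
            work = snapshot
            continue
        t = ts.t_end
        if w >= n_burnin:
            ratios.append(float(np.mean(ts.k_b / ts.k_a)))
            prevs.append(float(np.mean(ts.prevalence)))
        w += 1
    summary = QuasiStationarySummary(
        prevalence=float(np.mean(prevs)),
        degree_ratio=float(np.mean(ratios)),
        window_ratios=ratios,
        window_prevalences=prevs,
        n_restarts=restarts,
        t_end=t,
        seed=seed,
    )
    return work, summary


def adapted_restart_state(
    stationary_net: NetworkState, n_infected: int = 20, seed: int = 0
) -> NetworkState:
    """Reset epidemic states on a self-organized network.

    Keeps the edge set and node types; all agents become susceptible except
    ``n_infected`` chosen uniformly at random.
    """
    n = stationary_net.n_nodes
    if n_infected > n:
        raise ValueError(f"n_infected={n_infected} exceeds N={n}")
    rng = np.random.default_rng(seed)
    net = stationary_net.copy()
    net.node_state = np.zeros(n, dtype=np.uint8)
    net.node_state[rng.choice(n, size=n_infected, replace=False)] = STATE_I
    net.rng_seed = int(seed)
    return net


@dataclass
class ThresholdScanResult:
    """Simulated invasion threshold with its confidence band.

    ``(beta_lo, beta_hi)`` is the final bisection bracket; ``(ci_lo,
    ci_hi)`` is the binomial confidence band: the beta range over which the
    Wilson 95% interval of the measured extinction probability straddles
    ``p_cut``, i.e. where the data cannot exclude the threshold.
    """

    beta_estimate: float
    beta_lo: float
    beta_hi: float
    ci_lo: float
    ci_hi: float
    grid_betas: list[float] = field(default_factory=list)
    extinction_probs: list[float] = field(default_factory=list)
    p_cut: float = 0.05
    n_runs: int = 100


def _wilson_interval(p_hat: float, n: int, z: float = 1.96):
    denom = 1 + z**2 / n
    center = (p_hat + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p_hat * (1 - p_hat) / n + z**2 / (4 * n**2)) / denom
    return center - half, center + half


def _extinction_probability(
    make_initial, params, beta, n_runs, rng, established_frac, t_max
):
    n_ext = 0
    pb = params.replace(beta=beta)
    for _ in range(n_runs):
        net0 = make_initial(int(rng.integers(2**31 - 1)))
        stop_above = max(int(established_frac * net0.n_nodes), 1)
        ts = gillespie_run(
            net0, pb, t_max=t_max,
            sample_interval=t_max,
            seed=int(rng.integers(2**31 - 1)),
            stop_above_ninf=stop_above,
        )
        if ts.extinct:
            n_ext += 1
    return n_ext / n_runs


def estimate_invasion_threshold_sim(
    net_factory,
    params: ModelParams,
    beta_grid,
    n_runs: int = 100,
    seed: int = 0,
    p_cut: float = 0.05,
    established_frac: float = 0.05,
    t_max: float = 2e4,
    n_bisect: int = 4,
) -> ThresholdScanResult:
    """Locate the invasion threshold from repeated stochastic invasions.

    ``net_factory(seed)`` must return an initial :class:`NetworkState` (e.g.
    an adapted restart with 20 infected).  For each beta on the ordered grid
    the extinction probability is estimated from ``n_runs`` independent runs
    (a run counts as invaded once the infected count reaches
    ``established_frac * N``).  The threshold is the point where the
    extinction probability drops below ``p_cut`` ("the probability to reach
    the disease-free state becomes zero"), refined by bisection between the
    bracketing grid points; the final bracket is reported as the confidence
    band.
    """
    beta_grid = sorted(float(b) for b in beta_grid)
    if len(beta_grid) < 2:
        raise ValueError("beta_grid needs at least two points")
    if n_runs < 20:
        raise ValueError("n_runs must be at least 20 for a usable estimate")
    rng = np.random.default_rng(seed)
    probs = [
        _extinction_probability(
            net_factory, params, b, n_runs, rng, established_frac, t_max
        )
        for b in beta_grid
    ]
    above = [p < p_cut for p in probs]
    if not above[-1] or above[0]:
        raise ValueError(
            "threshold outside scanned range: extinction probability does "
            f"not cross p_cut={p_cut} on the grid (probs={probs})"
        )
    j = next(i for i, a in enumerate(above) if a)
    lo, hi = beta_grid[j - 1], beta_grid[j]
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        p_mid = _extinction_probability(
            net_factory, params, mid, n_runs, rng, established_frac, t_max
        )
        if p_mid < p_cut:
            hi = mid
        else:
            lo = mid
    # binomial confidence band: where the Wilson interval straddles p_cut
    wilson = [_wilson_interval(p, n_runs) for p in probs]
    ci_lo = beta_grid[0]
    ci_hi = beta_grid[-1]
    for b, (w_lo, _) in zip(beta_grid, wilson):
        if w_lo > p_cut:
            ci_lo = b  # extinction still significantly above the cutoff
    for b, (_, w_hi) in zip(reversed(beta_grid), reversed(wilson)):
        if w_hi < p_cut:
            ci_hi = b  # extinction already significantly below the cutoff
    return ThresholdScanResult(
        beta_estimate=0.5 * (lo + hi),
        beta_lo=lo,
        beta_hi=hi,
        ci_lo=min(ci_lo, lo),
        ci_hi=max(ci_hi, hi),
        grid_betas=beta_grid,
        extinction_probs=probs,
        p_cut=p_cut,
        n_runs=n_runs,
    )


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------

@dataclass
class DegreeStats:
    k_a: float | None
    k_b: float | None
    degree_ratio: float | None  # k_b / k_a
    hist_a: np.ndarray
    hist_b: np.ndarray
    variance: float
    variance_a: float | None
    variance_b: float | None


def degree_stats(net: NetworkState) -> DegreeStats:
    """Exact per-type degree statistics of a network.

    Satisfies p_a k_a + p_b k_b = <k> identically.  If a type has no nodes
    its mean degree (and the ratio) is reported as missing (None).
    """
    n = net.n_nodes
    deg = np.bincount(
        np.concatenate([net.edge_u, net.edge_v]), minlength=n
    )
    mask_a = net.node_type == TYPE_A
    deg_a, deg_b = deg[mask_a], deg[~mask_a]
    k_a = float(deg_a.mean()) if deg_a.size else None
    k_b = float(deg_b.mean()) if deg_b.size else None
    ratio = (k_b / k_a) if (k_a and k_b is not None) else None
    return DegreeStats(
        k_a=k_a,
        k_b=k_b,
        degree_ratio=ratio,
        hist_a=np.bincount(deg_a) if deg_a.size else np.array([], dtype=int),
        hist_b=np.bincount(deg_b) if deg_b.size else np.array([], dtype=int),
        variance=float(deg.var()),
        variance_a=float(deg_a.var()) if deg_a.size else None,
        variance_b=float(deg_b.var()) if deg_b.size else None,
    )
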