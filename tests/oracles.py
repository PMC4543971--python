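"""Independent brute-force oracles used by the test suite.

These implementations deliberately share no code with the package: the
master equation enumerates the exact continuous-time Markov chain over
(graph, epidemic-state) configurations directly from the process rules, and
the one-type pair equations are written in the unordered link-density
convention with explicit symmetry factors.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm


# ---------------------------------------------------------------------------
# exact master equation on tiny graphs
# ---------------------------------------------------------------------------

def _eligible_targets(edges, states, s):
    nbrs = {v for (u, v) in edges if u == s} | {u for (u, v) in edges if v == s}
    return [
        x for x in range(len(states))
        if states[x] == 0 and x != s and x not in nbrs
    ]


def enumerate_chain(n, edges0, types, states0, beta, psi, mu, omega):
    """Build the exact generator of the adaptive SIS chain from an initial
    configuration, over all reachable (edges, states) configurations.

    Returns (index map, generator matrix Q) with Q[i, j] the rate i -> j.
    """
    def canon(edges):
        return frozenset((min(u, v), max(u, v)) for u, v in edges)

    start = (canon(edges0), tuple(states0))
    index = {start: 0}
    order = [start]
    transitions = []  # (i, j, rate)
    frontier = [start]
    while frontier:
        cfg = frontier.pop()
        i = index[cfg]
        edges, states = cfg
        states = list(states)

        def visit(new_edges, new_states, rate):
            tgt = (canon(new_edges), tuple(new_states))
            if tgt not in index:
                index[tgt] = len(order)
                order.append(tgt)
                frontier.append(tgt)
            transitions.append((i, index[tgt], rate))

        # recovery
        for x in range(n):
            if states[x] == 1:
                ns = states.copy()
                ns[x] = 0
                visit(edges, ns, mu)
        for (u, v) in edges:
            su, sv = states[u], states[v]
            if su == sv:
                continue
            s, inf = (u, v) if su == 0 else (v, u)
            # contagion
            ns = states.copy()
            ns[s] = 1
            visit(edges, ns, beta * psi[types[s]])
            # rewiring: uniform over eligible targets; no-op if none
            targets = _eligible_targets(edges, states, s)
            if targets:
                for t in targets:
                    ne = set(edges)
                    ne.remove((min(s, inf), max(s, inf)))
                    ne.add((min(s, t), max(s, t)))
                    visit(ne, states, omega / len(targets))
    m = len(order)
    q = np.zeros((m, m))
    for i, j, rate in transitions:
        q[i, j] += rate
        q[i, i] -= rate
    return index, order, q


def infected_count_distribution(
    n, edges0, types, states0, beta, psi, mu, omega, t
):
    """Exact P(number infected = j at time t) for j = 0..n."""
    index, order, q = enumerate_chain(
        n, edges0, types, states0, beta, psi, mu, omega
    )
    p0 = np.zeros(len(order))
    p0[0] = 1.0
    pt = p0 @ expm(q * t)
    dist = np.zeros(n + 1)
    for cfg, i in index.items():
        dist[sum(cfg[1])] += pt[i]
    return dist


# ---------------------------------------------------------------------------
# one-type adaptive SIS pair approximation (unordered convention)
# ---------------------------------------------------------------------------

def one_type_pair_rhs(y, beta_psi, mu, omega, k_half):
    """d/dt of ([I], [SS], [SI], [II]) in the unordered convention.

    Independent derivation with explicit symmetry factors: each S node of an
    S-S link sees [SI]/[S] expected infected neighbours; rewiring converts
    S-I links into S-S links at rate omega; internal transmission converts
    S-I into I-I.  ``k_half`` = K/N is the conserved unordered link total.
    """
    i, ss, si, ii = y
    s = 1.0 - i
    w = si / s if s > 1e-12 else 0.0
    di = beta_psi * si - mu * i
    dss = (mu + omega) * si - 2.0 * beta_psi * ss * w
    dsi = (
        2.0 * mu * ii
        - (mu + omega + beta_psi) * si
        + 2.0 * beta_psi * ss * w
        - beta_psi * si * w
    )
    dii = beta_psi * si * (1.0 + w) - 2.0 * mu * ii
    return np.array([di, dss, dsi, dii])
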