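"""Event-driven (Gillespie) core of the adaptive SIS simulation.

The kernel operates on flat arrays so it can be compiled by numba:

* the graph is held as a half-edge incidence structure (edge ``e`` owns
  half-edges ``2e`` and ``2e+1``; each node keeps a doubly linked list of its
  incident half-edges), which makes rewiring, neighbour iteration and
  adjacency tests O(degree);
* three index registries support O(1) uniform sampling with swap-removal:
  infected nodes, susceptible nodes, and the S-I (active) links split by the
  type of the susceptible end, so that channel rates
  ``mu * n_inf``, ``beta * psi_u * n_si[u]`` and ``omega * (n_si[0]+n_si[1])``
  are available in O(1) per event.

Exact Gillespie scheduling: exponential waiting times with total rate equal
to the sum of the channel rates, channel chosen proportionally, event chosen
uniformly within its channel.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by the kernel
STATUS_TMAX = 0
STATUS_EXTINCT = 1
STATUS_ESTABLISHED = 2


@njit(cache=True)
def _adjacent(s, t, head, he_next, he_node):
    h = head[s]
    while h != -1:
        if he_node[h ^ 1] == t:
            return True
        h = he_next[h]
    return False


@njit(cache=True)
def _unlink(h, node, head, he_next, he_prev):
    nxt = he_next[h]
    prv = he_prev[h]
    if prv == -1:
        head[node] = nxt
    else:
        he_next[prv] = nxt
    if nxt != -1:
        he_prev[nxt] = prv


@njit(cache=True)
def _link(h, node, head, he_next, he_prev, he_node):
    he_node[h] = node
    he_next[h] = head[node]
    he_prev[h] = -1
    if head[node] != -1:
        he_prev[head[node]] = h
    head[node] = h


@njit(cache=True)
def _si_add(e, stype, si_list, si_pos, si_reg, si_n):
    si_list[stype, si_n[stype]] = e
    si_pos[e] = si_n[stype]
    si_reg[e] = stype
    si_n[stype] += 1


@njit(cache=True)
def _si_remove(e, si_list, si_pos, si_reg, si_n):
    r = si_reg[e]
    pos = si_pos[e]
    last = si_list[r, si_n[r] - 1]
    si_list[r, pos] = last
    si_pos[last] = pos
    si_n[r] -= 1
    si_reg[e] = -1


@njit(cache=True)
def _list_remove(x, lst, pos, n):
    p = pos[x]
    last = lst[n - 1]
    lst[p] = last
    pos[last] = p
    return n - 1


@njit(cache=True)
def _list_add(x, lst, pos, n):
    lst[n] = x
    pos[x] = n
    return n + 1


@njit(cache=True)
def run_kernel(
    types, states, eu, ev,
    beta, psi_a, psi_b, mu, omega,
    t0, t_max, sample_dt,
    stop_on_extinction, stop_above_ninf,
    seed,
    times_out, ia_out, ib_out, ka_out, kb_out, sia_out, sib_out,
):
    """Run the process from time ``t0`` to ``t_max``; mutates states/eu/ev.

    Returns (n_samples_written, t_end, status, n_events).
    Samples are taken on the fixed grid t0, t0+sample_dt, ... with the state
    held piecewise constant between events.
    """
    np.random.seed(seed)
    n = types.shape[0]
    k = eu.shape[0]
    psi = np.empty(2)
    psi[0] = psi_a
    psi[1] = psi_b

    # --- build incidence structure and registries ---
    head = np.full(n, -1, dtype=np.int64)
    he_node = np.empty(2 * k, dtype=np.int64)
    he_next = np.empty(2 * k, dtype=np.int64)
    he_prev = np.empty(2 * k, dtype=np.int64)
    for e in range(k):
        _link(2 * e, eu[e], head, he_next, he_prev, he_node)
        _link(2 * e + 1, ev[e], head, he_next, he_prev, he_node)

    deg = np.zeros(n, dtype=np.int64)
    for e in range(k):
        deg[eu[e]] += 1
        deg[ev[e]] += 1
    sumdeg = np.zeros(2, dtype=np.int64)
    ntype = np.zeros(2, dtype=np.int64)
    for x in range(n):
        sumdeg[types[x]] += deg[x]
        ntype[types[x]] += 1

    inf_list = np.empty(n, dtype=np.int64)
    inf_pos = np.full(n, -1, dtype=np.int64)
    sus_list = np.empty(n, dtype=np.int64)
    sus_pos = np.full(n, -1, dtype=np.int64)
    n_inf = 0
    n_sus = 0
    n_inf_type = np.zeros(2, dtype=np.int64)
    for x in range(n):
        if states[x] == 1:
            n_inf = _list_add(x, inf_list, inf_pos, n_inf)
            n_inf_type[types[x]] += 1
        else:
            n_sus = _list_add(x, sus_list, sus_pos, n_sus)

    si_list = np.empty((2, k), dtype=np.int64)
    si_pos = np.full(k, -1, dtype=np.int64)
    si_reg = np.full(k, -1, dtype=np.int8)
    si_n = np.zeros(2, dtype=np.int64)
    for e in range(k):
        su, sv = states[eu[e]], states[ev[e]]
        if su != sv:
            snode = eu[e] if su == 0 else ev[e]
            _si_add(e, types[snode], si_list, si_pos, si_reg, si_n)

    # --- main loop ---
    t = t0
    next_sample = t0
    idx = 0
    n_events = 0
    status = STATUS_TMAX
    max_samples = times_out.shape[0]

    while True:
        total = (
            mu * n_inf
            + beta * (psi[0] * si_n[0] + psi[1] * si_n[1])
            + omega * (si_n[0] + si_n[1])
        )
        if n_inf == 0 and stop_on_extinction:
            status = STATUS_EXTINCT
            break
        if stop_above_ninf > 0 and n_inf >= stop_above_ninf:
            status = STATUS_ESTABLISHED
            break
        if total <= 0.0:
            # frozen state (e.g. no infected but extinction-stop disabled):
            # emit the remaining sample grid unchanged and stop at t_max
            while next_sample <= t_max and idx < max_samples:
                times_out[idx] = next_sample
                ia_out[idx] = n_inf_type[0]
                ib_out[idx] = n_inf_type[1]
                ka_out[idx] = sumdeg[0]
                kb_out[idx] = sumdeg[1]
                sia_out[idx] = si_n[0]
                sib_out[idx] = si_n[1]
                idx += 1
                next_sample += sample_dt
            t = t_max
            status = STATUS_EXTINCT if n_inf == 0 else STATUS_TMAX
            break
        t_next = t + (-np.log(1.0 - np.random.random())) / total
        # emit samples for the interval [t, min(t_next, t_max))
        while next_sample <= t_next and next_sample <= t_max and idx < max_samples:
            times_out[idx] = next_sample
            ia_out[idx] = n_inf_type[0]
            ib_out[idx] = n_inf_type[1]
            ka_out[idx] = sumdeg[0]
            kb_out[idx] = sumdeg[1]
            sia_out[idx] = si_n[0]
            sib_out[idx] = si_n[1]
            idx += 1
            next_sample += sample_dt
        if t_next > t_max:
            t = t_max
            break
        t = t_next
        n_events += 1

        r = np.random.random() * total
        if r < mu * n_inf:
            # --- recovery ---
            x = inf_list[np.int64(np.random.random() * n_inf)]
            h = head[x]
            while h != -1:
                e = h >> 1
                y = he_node[h ^ 1]
                if states[y] == 0:
                    _si_remove(e, si_list, si_pos, si_reg, si_n)
                else:
                    _si_add(e, types[x], si_list, si_pos, si_reg, si_n)
                h = he_next[h]
            states[x] = 0
            n_inf = _list_remove(x, inf_list, inf_pos, n_inf)
            n_sus = _list_add(x, sus_list, sus_pos, n_sus)
            n_inf_type[types[x]] -= 1
        else:
            r -= mu * n_inf
            infect = -1
            if r < beta * psi[0] * si_n[0]:
                infect = 0
            else:
                r -= beta * psi[0] * si_n[0]
                if r < beta * psi[1] * si_n[1]:
                    infect = 1
                else:
                    r -= beta * psi[1] * si_n[1]
            if infect >= 0:
                # --- contagion along an S-I link with S-end of type `infect`
                e = si_list[infect, np.int64(np.random.random() * si_n[infect])]
                x = eu[e] if states[eu[e]] == 0 else ev[e]
                h = head[x]
                while h != -1:
                    ee = h >> 1
                    y = he_node[h ^ 1]
                    if states[y] == 0:
                        _si_add(ee, types[y], si_list, si_pos, si_reg, si_n)
                    else:
                        _si_remove(ee, si_list, si_pos, si_reg, si_n)
                    h = he_next[h]
                states[x] = 1
                n_sus = _list_remove(x, sus_list, sus_pos, n_sus)
                n_inf = _list_add(x, inf_list, inf_pos, n_inf)
                n_inf_type[types[x]] += 1
            else:
                # --- rewiring of a uniformly chosen S-I link ---
                j = np.int64(np.random.random() * (si_n[0] + si_n[1]))
                if j < si_n[0]:
                    e = si_list[0, j]
                else:
                    e = si_list[1, j - si_n[0]]
                if states[eu[e]] == 0:
                    s, i_node = eu[e], ev[e]
                else:
                    s, i_node = ev[e], eu[e]
                # uniform eligible target: susceptible, not s, not neighbour
                target = np.int64(-1)
                if n_sus > 1:
                    for _ in range(60):
                        c = sus_list[np.int64(np.random.random() * n_sus)]
                        if c == s:
                            continue
                        # walk the shorter incidence list
                        a0, a1 = (c, s) if deg[c] <= deg[s] else (s, c)
                        if not _adjacent(a0, a1, head, he_next, he_node):
                            target = c
                            break
                    if target == -1:
                        # exact fallback: reservoir-uniform over eligibles
                        cnt = 0
                        for jj in range(n_sus):
                            c = sus_list[jj]
                            if c == s:
                                continue
                            a0, a1 = (c, s) if deg[c] <= deg[s] else (s, c)
                            if not _adjacent(a0, a1, head, he_next, he_node):
                                cnt += 1
                                if np.random.random() * cnt < 1.0:
                                    target = c
                if target != -1:
                    _si_remove(e, si_list, si_pos, si_reg, si_n)
                    h = 2 * e if he_node[2 * e] == i_node else 2 * e + 1
                    _unlink(h, i_node, head, he_next, he_prev)
                    _link(h, target, head, he_next, he_prev, he_node)
                    if eu[e] == i_node:
                        eu[e] = target
                    else:
                        ev[e] = target
                    deg[i_node] -= 1
                    deg[target] += 1
                    sumdeg[types[i_node]] -= 1
                    sumdeg[types[target]] += 1
                # no eligible target: the event is a no-op

    # final sample at the stopping time
    if idx < max_samples:
        times_out[idx] = t
        ia_out[idx] = n_inf_type[0]
        ib_out[idx] = n_inf_type[1]
        ka_out[idx] = sumdeg[0]
        kb_out[idx] = sumdeg[1]
        sia_out[idx] = si_n[0]
        sib_out[idx] = si_n[1]
        idx += 1

    return idx, t, status, n_events
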