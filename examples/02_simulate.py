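"""Run one stochastic realization and compare with the pair-approximation ODE.

Generates a G(N, K) network at desk scale (N = 5000, <k> = 20), infects
half the population, and simulates the adaptive SIS process to
stationarity.  The stationary prevalence is then compared with the endemic
fixed point of the 11-dimensional moment-closure ODE.
"""

import numpy as np

from hetsis import (
    ModelParams,
    assign_initial_condition,
    find_steady_state,
    generate_er_network,
    integrate,
    run_to_stationarity,
)
from hetsis.moments import random_mixing_state

params = ModelParams(
    beta=0.032, psi_a=0.65, psi_b=0.05, p_a=0.75,
    mu=0.002, omega=0.2, n_nodes=5000, n_links=50_000,
)

# --- stochastic run ---
net = generate_er_network(params.n_nodes, params.n_links, seed=1)
net = assign_initial_condition(net, params.p_a, 0.5, seed=2)
adapted, summary = run_to_stationarity(net, params, seed=3, window=5000.0)
print(f"simulation: prevalence = {summary.prevalence:.4f} "
      f"(se {summary.prevalence_se:.4f}), k_b/k_a = {summary.degree_ratio:.3f}")

# --- pair ODE ---
traj = integrate(random_mixing_state(params, 0.05), params, 30_000.0)
fix = find_steady_state(traj.final_state(), params)
k_a, k_b = fix.degree_marginals(params)
print(f"pair ODE:   prevalence = {fix.prevalence:.4f}, "
      f"k_b/k_a = {k_b / k_a:.3f}")
rel = abs(summary.prevalence - fix.prevalence) / fix.prevalence
print(f"relative prevalence difference: {100 * rel:.1f}%")

# The stationary prevalence agrees with the moment closure at the percent
# level; the simulated degree ratio sits below the ODE value at this N
# because the susceptible pool carrying the self-organization is only ~1.7%
# of the network (see docs/methods.md).
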