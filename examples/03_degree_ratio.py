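"""Self-organized degree heterogeneity and the mean-field sqrt prediction.

Adapts a network in the endemic state, anneals down the hysteresis loop to
just above the persistence threshold (where the susceptible pool is
largest), and compares the stationary degree ratio k_b/k_a with the
mean-field prediction sqrt(psi_a/psi_b) and its bounds.
"""

import numpy as np

from hetsis import (
    ModelParams,
    assign_initial_condition,
    degree_stats,
    generate_er_network,
    predict_degree_ratio,
    optimal_degree_ratio,
    run_to_stationarity,
)
from hetsis.sim import run_quasi_stationary

params = ModelParams(
    beta=0.032, psi_a=0.65, psi_b=0.05, p_a=0.75,
    mu=0.002, omega=0.2, n_nodes=5000, n_links=50_000,
)

pred = predict_degree_ratio(params.psi_a, params.psi_b)
print(f"mean-field prediction sqrt(psi_a/psi_b) = {pred.ratio:.4f}")
print(f"bounds: ({pred.lower_bound}, {pred.upper_bound})")
print(f"most invasion-robust ratio argmin Z0    = "
      f"{optimal_degree_ratio(params):.4f}")

net = generate_er_network(params.n_nodes, params.n_links, seed=1)
net = assign_initial_condition(net, params.p_a, 0.5, seed=2)
print("adapting at beta=0.032 ...")
adapted, _ = run_to_stationarity(net, params, seed=3, window=5000.0)
print("annealing at beta=0.016 (largest sustainable susceptible pool) ...")
adapted, summary = run_quasi_stationary(
    adapted, params.replace(beta=0.016), seed=4,
)
ds = degree_stats(adapted)
print(f"simulated quasi-stationary k_b/k_a = {summary.degree_ratio:.3f} "
      f"(prevalence {summary.prevalence:.3f}, "
      f"{summary.n_restarts} extinction restarts)")
print(f"initial ER degree variance ~ <k> = 20; "
      f"adapted variance = {ds.variance:.1f}")

# The simulated ratio lands near the sqrt prediction and far below the
# naive upper bound psi_a/psi_b = 13: rewiring compensates the resistant
# nodes' lower susceptibility only partially.  The adapted network is much
# more heterogeneous than the initial ER graph yet harder to invade.
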