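# Methods

## Model

`hetsis` implements a susceptible–infected–susceptible (SIS) epidemic on an
adaptive contact network of `N` agents and `K` undirected links.  Agents
carry an immutable type, A or B, with population fractions `p_a` and
`p_b = 1 - p_a`; the types differ only in the susceptibility multipliers
`psi_a > psi_b > 0`.  Three continuous-time Markov processes drive the
dynamics:

| process  | rate | unit |
|----------|------|------|
| recovery | `mu` | per infected node |
| rewiring | `omega` | per S–I link |
| contagion | `beta * psi(type of S end)` | per S–I link |

In a rewiring event the susceptible end of an S–I ("active") link cuts the
link and reconnects to another susceptible node chosen uniformly at random.
Rewiring conserves the link count, so the mean degree `<k> = 2K/N` is an
invariant of the dynamics.  All rates are in arbitrary reciprocal time
units; only rate ratios matter.

Default parameters follow the main heterogeneous study condition:
`psi_a = 0.65`, `psi_b = 0.05`, `p_a = 0.75` (giving mean susceptibility
`<psi> = 0.5`), `mu = 0.002`, `omega = 0.2`, `<k> = 20`.  In "balanced
families" of parameter sets the heterogeneity `psi_a` is varied while
`<psi>` is held fixed by solving `p_a = (<psi> - psi_b)/(psi_a - psi_b)`;
the package treats `<psi>` as a free input (0.5 reproduces the default
composition).

## Stochastic simulation

The simulator is an exact Gillespie algorithm: exponential waiting times at
the total event rate, channel selection proportional to channel rates,
uniform selection within a channel.  Channel rates are maintained
incrementally — registries of infected nodes, susceptible nodes, and active
links split by the type of the susceptible end are updated in O(degree) per
event, never by rescanning the network.  The graph lives in a half-edge
incidence structure so a rewiring event is O(1) plus an O(degree) adjacency
check.  The event loop is compiled with numba.

Rewiring target choice: the model text fixes only "another susceptible
node".  We additionally keep the graph simple (no self-loops, no duplicate
edges) and treat an event with no eligible target as a no-op.  At the
default densities the correction is negligible (a susceptible's neighbours
are a vanishing fraction of the susceptible pool); on tiny test graphs the
no-op rule is part of the exact master-equation oracle, so the convention
is tested, not just assumed.  Target sampling is uniform over eligible
nodes: rejection sampling from the susceptible registry with an exact
reservoir-sampling fallback, which preserves uniformity in both paths.

Erdős–Rényi initial graphs are G(N, K): exactly K distinct edges uniform
over simple graphs.  Types and epidemic states are assigned in two
independent uniform draws realizing the requested counts exactly.

### Stationarity protocol

The study protocol "evolve until a stationary prevalence level is
approached" is not quantitative, so the package uses: the mean prevalence
over two consecutive windows of `50/mu` time units (scale-free in the
recovery rate) must differ by less than two standard errors; observables
are then time-averaged over further windows.  Window length, cap and the
number of averaging windows are arguments.  The invasion-scan criterion
"probability to reach the disease-free state becomes zero" is
operationalized as extinction probability `< p_cut` (default 0.05) over
`n_runs` (default 100) independent runs, with the threshold refined by
bisection between bracketing grid points; both knobs are exposed because
the original criterion is qualitative.  A run counts as invaded once its
infected count reaches an `established_frac` of N (default 5%), which cuts
the cost of supercritical runs without touching the extinction statistics.

## Pair-approximation ODEs

The moment hierarchy is closed at the pair level.  Internally all link
densities use the *ordered* convention — each undirected link contributes
two ordered pairs — under which the triplet closure is simply
`[X_u Y_v Z_w] = [X_u Y_v][Y_v Z_w]/[Y_v]` and no symmetry factors appear.
The conventional unordered bookkeeping (same-class pairs counted once,
symmetry factors delta in {4, 2, 1} in the closure, kappa factors in the
equations) is provided as an I/O view and the equivalence of the two
closures is a tested property for every unambiguously defined chain class.
The ordered convention was chosen normative because the delta-factor table
is ambiguous for palindromic chains with equal end classes but a distinct
middle (e.g. I_a–S_a–I_a); the ordered form has no such ambiguity.

The system has 12 variables ([I_a], [I_b], three S–S, four S–I, three I–I
ordered densities) and one conservation law (total ordered density =
`<k>`), hence 11 independent equations.  The right-hand side, per ordered
cell (u, v):

    dI_u    = -mu I_u + beta psi_u G_u
    dSS[uv] =  mu (SI[uv] + SI[vu]) - beta SS[uv] (psi_u W_u + psi_v W_v)
               + omega (G_u S_v + G_v S_u)/(S_a + S_b)
    dSI[uv] =  mu II[uv] - (mu + beta psi_u + omega) SI[uv]
               + beta psi_v SS[uv] W_v - beta psi_u SI[uv] W_u
    dII[uv] = -2 mu II[uv] + beta (psi_u SI[uv] + psi_v SI[vu])
               + beta (psi_u SI[uv] W_u + psi_v SI[vu] W_v)

with `G_u = sum_w SI[uw]` (active links anchored on type-u susceptibles)
and `W_u = G_u / S_u` (expected infected neighbours per type-u
susceptible).  The closure for I–S–I chains does not subtract the focal
link from the neighbour sum (standard pair approximation).  For
`psi_a = psi_b` the aggregated system reduces exactly to the classic
one-type adaptive-SIS pair approximation; this reduction is verified
numerically against an independently derived unordered-convention
implementation.

### Numerical choices

* **Denominator guards.**  Whenever a susceptible fraction `S_u < 1e-12`
  every term with `S_u` in a denominator is set to zero.  The numerators
  vanish at least as fast, and the guard makes the extinct plane exactly
  invariant in floating point.
* **Jacobians** are computed by complex-step differentiation of the
  analytic right-hand side (step 1e-200), exact to round-off; they are
  verified against central finite differences in the tests.
* **Conservation** is enforced structurally: Newton iteration and
  continuation operate on 11 independent coordinates with `ss_bb`
  reconstructed from the link total (the dropped coordinate is arbitrary
  but fixed).  The integrator (LSODA via scipy) runs on the full
  12-vector; its conservation drift is bounded by solver tolerance and
  checked.  Negative undershoots within `-atol` are clipped and flagged.
* **Steady states**: damped Newton, residual max-norm `< 1e-10`.

## Thresholds and continuation

The extinct states form a 2-parameter plane (any S–S composition is
stationary once [I] = 0), so the full Jacobian always has neutral
directions there.  Invasion thresholds are therefore computed from the
closed 7-dimensional linear subsystem of the infected moments (4 S–I, 3
I–I) about the chosen disease-free configuration; the threshold is the
beta at which its leading eigenvalue crosses zero, bisected to 1e-8
relative.  In the homogeneous limit this reduces to the closed form
`beta* psi <k> = mu + omega`, used as an oracle in the tests.

Equilibrium branches are continued in beta by pseudo-arclength
predictor–corrector iteration (secant predictor, Newton corrector, adaptive
step halving/doubling between 1e-7 and 1e-2 in a scaled arclength metric
where beta is measured in units of 0.01 and densities in units of
`<k>/2`).  A fold is detected where the beta-component of the step changes
sign; it is polished by re-running the local continuation at ~100-fold
smaller steps and resolving the extremum with a parabola through the
extremal triple.  The unstable branch beyond the fold is followed until the
prevalence crosses zero; the crossing is interpolated linearly (with the
step capped at 2e-4 near the plane so the interpolation error is
negligible), the landing S–S configuration is renormalized onto the
conservation constraint, and the adapted invasion threshold is re-derived
from that configuration via the 7-dimensional eigenproblem.  The re-derived
value must agree with the branch crossing to 0.5% — a mandatory
self-consistency check.

At the default heterogeneous parameters this machinery yields
`beta_per ≈ 0.0125 < beta_inv(initial) ≈ 0.0202 < beta_inv(adapted) ≈
0.0427`; in the homogeneous limit the landing configuration is the
random-mixing one and the two invasion thresholds coincide to round-off.

## Mean-field predictions

Two per-type balance relations — rewiring balance `[I_i]/[S_i] ∝ 1/k_i`
and infection balance `[I_i]/[S_i] ∝ psi_i k_i` — combine to
`psi_a k_a^2 = psi_b k_b^2`, predicting the self-organized degree ratio
`k_b/k_a = sqrt(psi_a/psi_b)`, strictly between the bounds 1 and
`psi_a/psi_b`.  The link reproductive number is modelled as
`Z0(q) = C (p_a psi_a k_a^2 + p_b psi_b k_b^2)/<k>` with
`k_a = <k>/(p_a + p_b q)` and `C = beta/(mu + omega)`; the prefactor is a
convention (transmission relative to the rates that deactivate a link) and
every shipped conclusion — the minimizer `q* = psi_a/psi_b` and the
orderings — is invariant to it.  The minimizer is found numerically by a
log-grid scan plus bounded refinement; the analytic Lagrange condition
`psi_a k_a = psi_b k_b` serves only as the test oracle.

## What the synthetic conditions do and do not show

All inputs are generated internally (G(N, K) graphs, uniform assignments),
so the tests probe the model's own self-organization, not any empirical
contact structure.  Desk-scale runs use N = 10^3–10^4 rather than the
study-scale 10^5.  Two finite-size effects matter at desk scale and are
deliberately surfaced rather than hidden:

* The endemic prevalence at the default rates is high (I* ≈ 0.96–0.99), so
  the susceptible pool that carries the rewiring self-organization is a
  small fraction of N.  The stationary degree ratio measured in simulation
  is biased below the pair-ODE/mean-field value when that pool is only a
  few dozen nodes (e.g. ratio ≈ 2.4 at N = 5000, beta = 0.032 against an
  ODE value of 3.67), and the bias shrinks systematically with N (≈ 2.95
  at N = 10^4; ≈ 3.5 at N = 4x10^4).  Degree-ratio measurements at desk
  scale therefore anneal along the hysteresis loop: adapt at beta = 0.032,
  then continue at the lowest infectivity that sustains a metastable
  endemic state at the given N (beta = 0.016 at N = 5000; at beta = 0.015
  escape through the nearby saddle dominates), where the susceptible pool
  is largest.  Because the finite-N endemic state this close to the fold
  is metastable, the measurement uses the standard quasi-stationary
  estimator: a window that goes extinct is rerun from its starting state
  with fresh randomness (conditioning on survival), two burn-in windows of
  1e4 time units are discarded, and the degree ratio is averaged over six
  further windows.  This protocol choice is made once, on the physical
  grounds above.
* Quantities that average over the whole network (prevalence, threshold
  locations at the pair level) show no comparable bias: the annealed
  network's link-type composition yields a pair-level transcritical within
  1% of the ODE's adapted threshold, and the stationary prevalence agrees
  with the endemic fixed point to a fraction of a percent at N = 10^4.
  The *simulated* adapted-restart invasion threshold, however, sits below
  the moment-closure transcritical at desk scale: link concentration on
  the small susceptible pool makes the adapted network's degree variance
  tens of times the Poisson value, and invasions can establish through
  those hubs — a correlation the pair closure does not represent.  The
  restart-scan cross-check therefore compares through the scan's binomial
  confidence band rather than point estimates.

Passing tests therefore demonstrate internal consistency of simulator,
moment closure and mean field under the model's assumptions; they say
nothing about real contact networks, where degree heterogeneity unrelated
to the epidemic, clustering, and non-Markovian behaviour are all outside
the model class.

## Known limitations

* Only two node types; the generalization is straightforward but not
  built.
* The pair approximation inherits the known weaknesses of moment closures
  near fragmentation-type transitions; no higher-order closure is
  provided.
* No Hopf/oscillation analysis and no two-parameter bifurcation diagrams.
* The continuation assumes a single endemic branch in the scanned range,
  which holds for this model family but is not verified structurally.
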