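# hetsis

Adaptive SIS epidemics on rewiring contact networks whose agents differ in
susceptibility — stochastic simulation, pair-approximation moment-closure
ODEs, bifurcation analysis of epidemic thresholds, and mean-field
predictions of self-organized degree heterogeneity.

## The problem

A classic result of network epidemiology says heterogeneous *connectivity*
makes networks easier for a disease to invade.  This package studies the
opposite regime: agents are intrinsically heterogeneous (two types, A and
B, with susceptibilities ψ_a > ψ_b) and respond behaviourally to the
epidemic by *rewiring* — a susceptible agent cuts a link to an infected
neighbour and reconnects to another susceptible.  The feedback between node
states and topology concentrates links on the resistant type-B agents, and
the resulting degree-heterogeneous network is *more* robust to invasion
than the homogeneous random graph it started from.  What decides
invasibility is not degree heterogeneity per se but the heterogeneity of
effective infection risk, ψ_i k_i.

## Model

N agents, K undirected links, mean degree ⟨k⟩ = 2K/N.  Node types A/B with
fractions p_a, p_b are fixed; epidemic states S/I evolve by three Markov
processes:

* recovery: I → S at rate μ per infected node;
* rewiring: each S–I link is rewired at rate ω (the S end reconnects to a
  random other susceptible);
* contagion: transmission along each S–I link at rate β·ψ_type(S end).

Key quantities:

* **β_inv (invasion threshold)** — transcritical bifurcation of a
  disease-free state.  Because extinct states form a plane (any split of
  links among S–S classes is stationary), the threshold depends on the
  disease-free link configuration: the *initial* threshold belongs to the
  fresh Erdős–Rényi graph, the *adapted* threshold to the self-organized
  configuration where the unstable equilibrium branch lands, and
  β_inv(adapted) > β_inv(initial) whenever ψ_a ≠ ψ_b.
* **β_per (persistence threshold)** — fold bifurcation where the endemic
  state annihilates with a saddle; β_per < β_inv gives bistability and
  hysteresis.
* **Degree ratio q = k_b/k_a** — self-organizes to √(ψ_a/ψ_b), strictly
  between the bounds 1 and ψ_a/ψ_b.
* **Link reproductive number Z₀(q)** — expected secondary active links per
  active link; minimized (most invasion-robust network) at q* = ψ_a/ψ_b.

See `docs/methods.md` for the full equations and numerical choices.

## Worked example

```sh
python examples/01_thresholds.py
```

prints, at the default heterogeneous parameters (ψ_a = 0.65, ψ_b = 0.05,
p_a = 0.75, μ = 0.002, ω = 0.2, ⟨k⟩ = 20):

```
persistence threshold      beta_per         = 0.012501
initial invasion threshold beta_inv_initial = 0.020200
adapted invasion threshold beta_inv_adapted = 0.042742
landing configuration degree ratio k_b/k_a  = 3.600
```

Reading: between β = 0.0125 and 0.0427 an established epidemic persists
while a newly introduced one dies out; prior adaptation roughly doubles the
invasion threshold (0.0202 → 0.0427); and the self-organized network that
achieves this carries 3.6× more links per resistant node than per
susceptible node — close to the mean-field prediction √13 ≈ 3.606.

Other examples: `02_simulate.py` (stochastic run vs ODE fixed point),
`03_degree_ratio.py` (self-organized heterogeneity vs the √ rule),
`04_adapted_restart.py` (simulated invasion thresholds of adapted
networks).  There is also a CLI mirror of the protocols:

```sh
hetsis --seed 1 --out out/ threshold-report
hetsis --seed 1 --out out/ mean-field
hetsis --seed 1 --out out/ hysteresis-scan --n-nodes 2000 --n-links 20000
```

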