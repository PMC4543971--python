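"""Experiment drivers: the measurement protocols behind the main diagrams.

Each driver takes an :class:`~hetsis.io.ExperimentConfig`, runs the
corresponding protocol and writes CSV/JSON outputs stamped with the seed
and config hash.  They are thin orchestration over :mod:`hetsis.sim`,
:mod:`hetsis.thresholds` and :mod:`hetsis.mean_field`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import mean_field, sim, thresholds
from .io import ExperimentConfig, config_hash, output_header, write_network
from .moments import disease_free_state

__all__ = [
    "run_simulate",
    "run_hysteresis_scan",
    "run_threshold_scan",
    "run_threshold_report",
    "run_adapted_restart",
    "run_mean_field",
]


def _write_csv(df: pd.DataFrame, path: Path, config: ExperimentConfig) -> None:
    with open(path, "w") as fh:
        fh.write(output_header(config) + "\n")
        df.to_csv(fh, index=False)


def _fresh_network(config: ExperimentConfig, prevalence: float, seed: int):
    m = config.model
    net = sim.generate_er_network(m.n_nodes, m.n_links, seed=seed)
    return sim.assign_initial_condition(net, m.p_a, prevalence, seed=seed + 1)


def run_simulate(config: ExperimentConfig, out_dir: Path) -> pd.DataFrame:
    """One stochastic run; writes the sampled time series."""
    net = _fresh_network(config, config.initial_prevalence_high, config.seed)
    ts = sim.gillespie_run(
        net, config.model, t_max=config.t_max,
        sample_interval=max(config.t_max / 2000, 1e-3),
        seed=config.seed + 2,
    )
    df = ts.to_frame()
    _write_csv(df, out_dir / "timeseries.csv", config)
    return df


def run_hysteresis_scan(config: ExperimentConfig, out_dir: Path) -> pd.DataFrame:
    """Stationary prevalence for each (beta, initial-prevalence level).

    Low-prevalence starts probe the invasion side of the hysteresis loop,
    high-prevalence starts the persistence side.  Per-cell failures are
    recorded and the scan continues.
    """
    betas = config.beta_grid or list(np.linspace(0.005, 0.04, 8))
    rows = []
    rng = np.random.default_rng(config.seed)
    for beta in betas:
        for label, level in (
            ("low", config.initial_prevalence_low),
            ("high", config.initial_prevalence_high),
        ):
            cell_seed = int(rng.integers(2**31 - 1))
            try:
                net = _fresh_network(config, level, cell_seed)
                _, summary = sim.run_to_stationarity(
                    net, config.model.replace(beta=beta), seed=cell_seed + 1,
                    t_cap=config.t_max, window=config.window,
                )
                rows.append(
                    {
                        "beta": beta,
                        "initial": label,
                        "initial_prevalence": level,
                        "prevalence": summary.prevalence,
                        "prevalence_se": summary.prevalence_se,
                        "k_a": summary.k_a,
                        "k_b": summary.k_b,
                        "outcome": "extinct" if summary.extinct else "endemic",
                        "seed": cell_seed,
                    }
                )
            except Exception as exc:  # per-cell failure: record, continue
                rows.append(
                    {"beta": beta, "initial": label,
                     "initial_prevalence": level, "prevalence": np.nan,
                     "prevalence_se": np.nan, "k_a": np.nan, "k_b": np.nan,
                     "outcome": f"error: {exc}", "seed": cell_seed}
                )
    df = pd.DataFrame(rows)
    _write_csv(df, out_dir / "hysteresis.csv", config)
    return df


def run_threshold_scan(config: ExperimentConfig, out_dir: Path) -> dict:
    """Simulated invasion threshold from fresh (un-adapted) networks."""
    m = config.model
    betas = config.beta_grid or list(np.linspace(0.25, 2.5, 6) * 0.0202)

    def factory(seed):
        net = sim.generate_er_network(m.n_nodes, m.n_links, seed=seed)
        net = sim.assign_initial_condition(net, m.p_a, 0.0, seed=seed + 1)
        return sim.adapted_restart_state(net, config.n_restart_infected, seed + 2)

    res = sim.estimate_invasion_threshold_sim(
        factory, m, betas, n_runs=config.n_runs, seed=config.seed,
        p_cut=config.p_cut, t_max=config.t_max,
    )
    out = {
        "beta_estimate": res.beta_estimate,
        "beta_lo": res.beta_lo,
        "beta_hi": res.beta_hi,
        "grid_betas": res.grid_betas,
        "extinction_probs": res.extinction_probs,
        "p_cut": res.p_cut,
        "n_runs": res.n_runs,
        "seed": config.seed,
        "config_hash": config_hash(config),
    }
    (out_dir / "threshold_scan.json").write_text(json.dumps(out, indent=2))
    return out


def run_threshold_report(config: ExperimentConfig, out_dir: Path) -> dict:
    """ODE thresholds plus a branch dump suitable for re-plotting."""
    report = thresholds.threshold_report(config.model)
    (out_dir / "threshold_report.json").write_text(report.to_json())
    # branch dump: (beta, I*, stability) of the continued endemic branch
    beta_hi = 4.0 * report.beta_inv_initial
    try:
        branch = thresholds._downward_branch(config.model, beta_hi)
        df = pd.DataFrame(
            {
                "beta": branch.betas,
                "prevalence": branch.prevalences,
                "leading_eig": [p.leading_eig for p in branch.points],
                "stable": [p.stable for p in branch.points],
            }
        )
        _write_csv(df, out_dir / "branch.csv", config)
    except RuntimeError:
        pass
    return report.to_dict()


def run_adapted_restart(config: ExperimentConfig, out_dir: Path) -> dict:
    """Invasion threshold of the self-organized network.

    Adapts a network by running to stationarity at the configured beta,
    freezes its link pattern, and scans the restart protocol (all
    susceptible except ``n_restart_infected``) over the beta grid.
    """
    m = config.model
    net = _fresh_network(config, config.initial_prevalence_high, config.seed)
    adapted, summary = sim.run_to_stationarity(
        net, m, seed=config.seed + 1, t_cap=max(config.t_max, 2e5),
        window=config.window,
    )
    if summary.extinct:
        raise RuntimeError(
            "adaptation run went extinct; raise beta or the initial prevalence"
        )
    write_network(adapted, out_dir / "adapted_network.txt")
    betas = config.beta_grid or list(
        np.linspace(0.5, 3.0, 6)
        * thresholds.invasion_threshold_at(disease_free_state(m), m)
    )

    def factory(seed):
        return sim.adapted_restart_state(adapted, config.n_restart_infected, seed)

    res = sim.estimate_invasion_threshold_sim(
        factory, m, betas, n_runs=config.n_runs, seed=config.seed + 2,
        p_cut=config.p_cut, t_max=config.t_max,
    )
    out = {
        "beta_estimate": res.beta_estimate,
        "beta_lo": res.beta_lo,
        "beta_hi": res.beta_hi,
        "grid_betas": res.grid_betas,
        "extinction_probs": res.extinction_probs,
        "adaptation": {
            "prevalence": summary.prevalence,
            "k_a": summary.k_a,
            "k_b": summary.k_b,
            "degree_ratio": summary.degree_ratio,
        },
        "seed": config.seed,
        "config_hash": config_hash(config),
    }
    (out_dir / "adapted_restart.json").write_text(json.dumps(out, indent=2))
    return out


def run_mean_field(config: ExperimentConfig, out_dir: Path) -> dict:
    """Mean-field degree-ratio prediction, bounds, and the Z0 minimizer."""
    m = config.model
    pred = mean_field.predict_degree_ratio(m.psi_a, m.psi_b)
    curve = mean_field.percolation_curve(m)
    out = {
        "degree_ratio_predicted": pred.ratio,
        "lower_bound": pred.lower_bound,
        "upper_bound": pred.upper_bound,
        "q_optimal": curve.q_optimal,
        "config_hash": config_hash(config),
    }
    (out_dir / "mean_field.json").write_text(json.dumps(out, indent=2))
    df = pd.DataFrame({"q": curve.q, "z0": curve.z0})
    _write_csv(df, out_dir / "z0_curve.csv", config)
    return out
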