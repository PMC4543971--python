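"""Configuration, network file I/O and logging.

Networks travel as plain-text edge lists (with a comment header carrying
node types and states) or as GraphML with ``type``/``state`` node
attributes.  Experiment configuration is YAML with a flat ``model:`` block
mirroring the :class:`~hetsis.params.ModelParams` field names.  Every
output file carries a header with the seed and a hash of the generating
configuration so that published outputs can be regenerated.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import networkx as nx
import numpy as np
import yaml

from .params import ModelParams, validate_params
from .sim import NetworkState

__all__ = [
    "write_network",
    "read_network",
    "ExperimentConfig",
    "load_config",
    "config_hash",
    "configure_logging",
    "output_header",
]

_TYPE_CHARS = "AB"
_STATE_CHARS = "SI"

EXPERIMENTS = (
    "simulate",
    "hysteresis-scan",
    "threshold-scan",
    "threshold-report",
    "adapted-restart",
    "mean-field",
)


# ---------------------------------------------------------------------------
# network files
# ---------------------------------------------------------------------------

def write_network(net: NetworkState, path, fmt: str = "edge-list") -> None:
    """Write a network with its node types and epidemic states.

    ``edge-list``: '#'-comment header with compact per-node type and state
    strings, then one edge per line, smaller node id first.  ``graphml``:
    GraphML with string node attributes ``type`` in {A, B} and ``state`` in
    {S, I}.
    """
    path = Path(path)
    if fmt == "edge-list":
        lines = [
            "# hetsis network",
            f"# nodes {net.n_nodes}",
            f"# seed {net.rng_seed}",
            "# types " + "".join(_TYPE_CHARS[t] for t in net.node_type),
            "# states " + "".join(_STATE_CHARS[s] for s in net.node_state),
        ]
        for u, v in sorted(net.edge_set()):
            lines.append(f"{u} {v}")
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "graphml":
        g = nx.Graph()
        for x in range(net.n_nodes):
            g.add_node(
                x,
                type=_TYPE_CHARS[net.node_type[x]],
                state=_STATE_CHARS[net.node_state[x]],
            )
        g.add_edges_from(net.edge_set())
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format: {fmt!r}")


def read_network(path, fmt: str = "edge-list") -> NetworkState:
    """Read a network written by :func:`write_network` (lossless round trip)."""
    path = Path(path)
    if fmt == "edge-list":
        n_nodes = None
        seed = None
        types = states = None
        edges: list[tuple[int, int]] = []
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split(None, 1)
                if not parts:
                    continue
                key = parts[0]
                rest = parts[1] if len(parts) > 1 else ""
                if key == "nodes":
                    n_nodes = int(rest)
                elif key == "seed":
                    seed = None if rest == "None" else int(rest)
                elif key == "types":
                    types = np.array(
                        [_TYPE_CHARS.index(c) for c in rest.strip()], dtype=np.uint8
                    )
                elif key == "states":
                    states = np.array(
                        [_STATE_CHARS.index(c) for c in rest.strip()], dtype=np.uint8
                    )
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 'u v', got {line!r}"
                )
            try:
                u, v = int(fields[0]), int(fields[1])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer node id in {line!r}"
                ) from exc
            edges.append((u, v))
        if n_nodes is None:
            raise ValueError(f"{path}: missing '# nodes N' header")
        if types is None:
            types = np.zeros(n_nodes, dtype=np.uint8)
        if states is None:
            states = np.zeros(n_nodes, dtype=np.uint8)
        eu = np.array([e[0] for e in edges], dtype=np.int64)
        ev = np.array([e[1] for e in edges], dtype=np.int64)
        net = NetworkState(
            node_type=types, node_state=states, edge_u=eu, edge_v=ev,
            rng_seed=seed,
        )
        net.check_consistency()
        return net
    if fmt == "graphml":
        g = nx.read_graphml(path)
        nodes = sorted(g.nodes, key=lambda x: int(x))
        n = len(nodes)
        types = np.array(
            [_TYPE_CHARS.index(g.nodes[x].get("type", "A")) for x in nodes],
            dtype=np.uint8,
        )
        states = np.array(
            [_STATE_CHARS.index(g.nodes[x].get("state", "S")) for x in nodes],
            dtype=np.uint8,
        )
        edges = [(int(u), int(v)) for u, v in g.edges]
        eu = np.array([min(e) for e in edges], dtype=np.int64)
        ev = np.array([max(e) for e in edges], dtype=np.int64)
        net = NetworkState(
            node_type=types, node_state=states, edge_u=eu, edge_v=ev,
        )
        net.check_consistency()
        return net
    raise ValueError(f"unknown network format: {fmt!r}")


# ---------------------------------------------------------------------------
# experiment configuration
# ---------------------------------------------------------------------------

#: default model block (the main-figure parameter set of the study design:
#: psi_a=0.65, psi_b=0.05, p_a=0.75, omega=0.2, mu=0.002, <k>=20), at a
#: desk-scale network size
DEFAULT_MODEL = {
    "beta": 0.032,
    "psi_a": 0.65,
    "psi_b": 0.05,
    "p_a": 0.75,
    "mu": 0.002,
    "omega": 0.2,
    "n_nodes": 5000,
    "n_links": 50000,
}


@dataclass
class ExperimentConfig:
    """Validated experiment description."""

    model: ModelParams
    experiment: str = "simulate"
    beta_grid: list[float] = dc_field(default_factory=list)
    psi_a_grid: list[float] = dc_field(default_factory=list)
    n_runs: int = 100
    seed: int = 0
    out_dir: str = "hetsis-out"
    initial_prevalence_low: float = 0.004
    initial_prevalence_high: float = 0.5
    n_restart_infected: int = 20
    t_max: float = 2e4
    p_cut: float = 0.05
    window: float | None = None  # stationarity window; default 50/mu
    raw: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; "
                f"choose one of {', '.join(EXPERIMENTS)}"
            )
        for name in ("beta_grid", "psi_a_grid"):
            grid = getattr(self, name)
            if grid and sorted(grid) != list(grid):
                raise ValueError(f"{name} must be sorted ascending")


def load_config(path=None, overrides: dict | None = None) -> ExperimentConfig:
    """Load a YAML experiment config, applying CLI-style overrides.

    ``overrides`` may contain model field names (beta, psi_a, ...) and
    top-level experiment keys; None values are ignored.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    model_block = {**DEFAULT_MODEL, **(data.get("model") or {})}
    top = {k: v for k, v in data.items() if k != "model"}
    for key, val in (overrides or {}).items():
        if val is None:
            continue
        if key in model_block or key in ("beta", "psi_a", "psi_b", "p_a", "mu",
                                         "omega", "n_nodes", "n_links",
                                         "mean_psi"):
            model_block[key] = val
        else:
            top[key] = val
    if "mean_psi" in model_block and "p_a" in DEFAULT_MODEL:
        # a prescribed mean susceptibility takes precedence over the default p_a
        if "p_a" not in (data.get("model") or {}) and "p_a" not in (overrides or {}):
            model_block.pop("p_a", None)
    params = validate_params(model_block)
    known = {f for f in ExperimentConfig.__dataclass_fields__ if f not in ("model", "raw")}
    kwargs = {k: v for k, v in top.items() if k in known}
    unknown = set(top) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return ExperimentConfig(model=params, raw=data, **kwargs)


def config_hash(config: ExperimentConfig) -> str:
    """Short stable hash of a config (invariant to key order in the YAML)."""
    payload = {
        "model": config.model.as_dict(),
        "experiment": config.experiment,
        "beta_grid": config.beta_grid,
        "psi_a_grid": config.psi_a_grid,
        "n_runs": config.n_runs,
        "seed": config.seed,
        "initial_prevalence_low": config.initial_prevalence_low,
        "initial_prevalence_high": config.initial_prevalence_high,
        "n_restart_infected": config.n_restart_infected,
        "t_max": config.t_max,
        "p_cut": config.p_cut,
    }
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def output_header(config: ExperimentConfig) -> str:
    """Comment header stamped on every CSV output."""
    return (
        f"# hetsis experiment={config.experiment} seed={config.seed} "
        f"config_hash={config_hash(config)}"
    )


def configure_logging(config: ExperimentConfig, echo: bool = True) -> logging.Logger:
    """Set up a run logger writing to ``<out_dir>/hetsis.log``.

    Fails early if the output directory cannot be created or written.
    Run metadata (parameters, seed, config hash) is logged immediately.
    """
    out = Path(config.out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write-probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise RuntimeError(f"output directory {out} is not writable: {exc}") from exc
    logger = logging.getLogger("hetsis")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    fh = logging.FileHandler(out / "hetsis.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)
    if echo:
        sh = logging.StreamHandler()
        sh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        logger.addHandler(sh)
    logger.info(
        "experiment=%s seed=%s config_hash=%s model=%s",
        config.experiment, config.seed, config_hash(config),
        config.model.as_dict(),
    )
    return logger
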