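"""Model parameters for the adaptive two-type SIS model.

The model describes an SIS epidemic on a network of ``N`` agents and ``K``
undirected links in which agents come in two immutable types, A and B, that
differ only in their susceptibility to infection.  Three continuous-time
Markov processes drive the dynamics:

* recovery -- every infected node recovers at rate ``mu``;
* contact avoidance -- every link between a susceptible and an infected node
  ("active" or S-I link) is rewired at rate ``omega``: the susceptible end
  cuts the link and reconnects to a randomly chosen other susceptible node;
* contagion -- the disease is transmitted along every S-I link at rate
  ``beta * psi_i`` where ``psi_i`` is the susceptibility multiplier of the
  susceptible end's type.

All rates are continuous-time Markov rates in arbitrary time units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "ModelParams",
    "validate_params",
    "solve_pa_for_mean_susceptibility",
]


class ParameterError(ValueError):
    """A model parameter violates an invariant of the model."""


@dataclass(frozen=True)
class ModelParams:
    """Validated parameter set of the adaptive heterogeneous SIS model.

    Attributes
    ----------
    beta : float
        Base transmission rate per S-I link per unit time.
    psi_a, psi_b : float
        Dimensionless susceptibility multipliers of types A and B.  The
        convention is ``psi_a >= psi_b > 0`` (type A is more susceptible).
    p_a : float
        Fraction of nodes of type A; ``p_b = 1 - p_a``.
    mu : float
        Recovery rate per infected node per unit time.
    omega : float
        Rewiring rate per S-I link per unit time.
    n_nodes, n_links : int
        Network size N and link count K.  The link count is conserved by the
        dynamics (rewiring moves links, it never creates or destroys them).
    """

    beta: float
    psi_a: float
    psi_b: float
    p_a: float
    mu: float
    omega: float
    n_nodes: int
    n_links: int
    mean_degree: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.beta >= 0:
            raise ParameterError(f"beta must be non-negative, got {self.beta}")
        if not self.mu > 0:
            raise ParameterError(f"mu must be positive, got {self.mu}")
        if not self.omega >= 0:
            raise ParameterError(f"omega must be non-negative, got {self.omega}")
        if not self.psi_b > 0:
            raise ParameterError(f"psi_b must be positive, got {self.psi_b}")
        if not self.psi_a >= self.psi_b:
            raise ParameterError(
                f"psi_a must be >= psi_b, got psi_a={self.psi_a}, psi_b={self.psi_b}"
            )
        if not 0 < self.p_a <= 1:
            raise ParameterError(f"p_a must lie in (0, 1], got {self.p_a}")
        n, k = self.n_nodes, self.n_links
        if n < 1 or int(n) != n:
            raise ParameterError(f"n_nodes must be a positive integer, got {n}")
        if k < 0 or int(k) != k:
            raise ParameterError(f"n_links must be a non-negative integer, got {k}")
        if k > n * (n - 1) // 2:
            raise ParameterError(
                f"n_links={k} exceeds the {n * (n - 1) // 2} possible simple edges"
            )
        object.__setattr__(self, "n_nodes", int(n))
        object.__setattr__(self, "n_links", int(k))
        object.__setattr__(self, "mean_degree", 2.0 * self.n_links / self.n_nodes)

    @property
    def p_b(self) -> float:
        return 1.0 - self.p_a

    @property
    def mean_psi(self) -> float:
        """Mean susceptibility <psi> = p_a psi_a + p_b psi_b."""
        return self.p_a * self.psi_a + self.p_b * self.psi_b

    @property
    def psi(self) -> tuple[float, float]:
        """Susceptibilities indexed by type (0 = A, 1 = B)."""
        return (self.psi_a, self.psi_b)

    @property
    def p(self) -> tuple[float, float]:
        """Type fractions indexed by type (0 = A, 1 = B)."""
        return (self.p_a, self.p_b)

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        raw = {
            "beta": self.beta,
            "psi_a": self.psi_a,
            "psi_b": self.psi_b,
            "p_a": self.p_a,
            "mu": self.mu,
            "omega": self.omega,
            "n_nodes": self.n_nodes,
            "n_links": self.n_links,
        }
        raw.update(changes)
        return ModelParams(**raw)

    def as_dict(self) -> dict:
        d = {
            "beta": self.beta,
            "psi_a": self.psi_a,
            "psi_b": self.psi_b,
            "p_a": self.p_a,
            "mu": self.mu,
            "omega": self.omega,
            "n_nodes": self.n_nodes,
            "n_links": self.n_links,
            "mean_degree": self.mean_degree,
            "mean_psi": self.mean_psi,
        }
        return d


_REQUIRED = ("beta", "psi_a", "psi_b", "p_a", "mu", "omega", "n_nodes", "n_links")


def validate_params(raw: Mapping[str, float]) -> ModelParams:
    """Validate a flat mapping of parameter names into a :class:`ModelParams`.

    Either ``p_a`` or ``mean_psi`` must be supplied; if ``mean_psi`` is given
    instead of ``p_a``, the type fraction is solved from the balanced-family
    constraint ``p_a psi_a + p_b psi_b = mean_psi``.

    Raises
    ------
    ParameterError
        If a required key is missing or an invariant is violated; the message
        names the offending field.
    """
    raw = dict(raw)
    if "p_a" not in raw and "mean_psi" in raw:
        raw["p_a"] = solve_pa_for_mean_susceptibility(
            raw.get("psi_a"), raw.get("psi_b"), raw.pop("mean_psi")
        )
    raw.pop("mean_psi", None)
    raw.pop("mean_degree", None)  # derived; recomputed
    missing = [k for k in _REQUIRED if k not in raw]
    if missing:
        raise ParameterError(f"missing required parameter(s): {', '.join(missing)}")
    extra = [k for k in raw if k not in _REQUIRED]
    if extra:
        raise ParameterError(f"unknown parameter(s): {', '.join(sorted(extra))}")
    return ModelParams(**{k: raw[k] for k in _REQUIRED})


def solve_pa_for_mean_susceptibility(
    psi_a: float, psi_b: float, mean_psi: float
) -> float:
    """Solve the type fraction p_a from a prescribed mean susceptibility.

    In a "balanced family" of parameter sets the heterogeneity (psi_a, psi_b)
    is varied while the population mean <psi> = p_a psi_a + (1-p_a) psi_b is
    held fixed, which requires ``p_a = (<psi> - psi_b) / (psi_a - psi_b)``.

    Raises
    ------
    ParameterError
        If ``mean_psi`` does not lie strictly between psi_b and psi_a (no
        valid composition exists).
    """
    if psi_a is None or psi_b is None:
        raise ParameterError("psi_a and psi_b are required to solve for p_a")
    if not (psi_b < mean_psi < psi_a):
        raise ParameterError(
            f"mean_psi={mean_psi} must lie strictly between psi_b={psi_b} "
            f"and psi_a={psi_a}"
        )
    return (mean_psi - psi_b) / (psi_a - psi_b)
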