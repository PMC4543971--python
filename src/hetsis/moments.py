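"""Moment-closure state container and density conventions.

The pair-approximation description of the adaptive two-type SIS model tracks
12 quantities: the two infected node fractions [I_a], [I_b] and ten link
densities, all normalized per node.

Two bookkeeping conventions exist for link densities.  In the *unordered*
convention a symbol such as [S_aS_a] counts each undirected link once, which
forces combinatorial factors (kappa_1, the triplet delta factors) into the
evolution equations.  Internally this package uses the *ordered* convention:
every undirected link between nodes x and y contributes the two ordered pairs
(x, y) and (y, x).  S-S and I-I densities are stored as symmetric 2x2 blocks
in ordered counts (a same-class cell is twice the undirected link count); S-I
densities are stored with the S-end listed first, one entry per link, for the
four ordered type combinations.  With this convention the total ordered link
density equals the mean degree <k> = 2K/N and all symmetry factors disappear
from the equations.  :func:`to_unordered_convention` converts to the unordered
view for I/O.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .params import ModelParams

__all__ = [
    "MomentState",
    "to_unordered_convention",
    "from_unordered_convention",
    "disease_free_state",
    "random_mixing_state",
]

# Flat vector layout used throughout the ODE machinery.
FIELDS = (
    "i_a", "i_b",
    "ss_aa", "ss_ab", "ss_bb",
    "si_aa", "si_ab", "si_ba", "si_bb",
    "ii_aa", "ii_ab", "ii_bb",
)
#: index of the dependent coordinate eliminated through link conservation
DROP_INDEX = FIELDS.index("ss_bb")


@dataclass
class MomentState:
    """The 12 moment variables, link densities in the ordered convention.

    ``ss_ab`` stores the ordered (a,b) cell of the symmetric S-S block (equal
    to the (b,a) cell and to the undirected a-b link density); ``si_uv`` is
    the density of links whose S-end has type u and I-end type v, counted
    once per link.  Of the 12 stored quantities only 11 are independent:
    the ordered total ``ss_aa + 2 ss_ab + ss_bb + 2 (si_aa + si_ab + si_ba +
    si_bb) + ii_aa + 2 ii_ab + ii_bb`` is conserved and equals <k>.
    """

    i_a: float
    i_b: float
    ss_aa: float
    ss_ab: float
    ss_bb: float
    si_aa: float
    si_ab: float
    si_ba: float
    si_bb: float
    ii_aa: float
    ii_ab: float
    ii_bb: float

    # -- vector interface -------------------------------------------------
    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in FIELDS], dtype=float)

    @classmethod
    def from_vector(cls, y) -> "MomentState":
        y = np.asarray(y)
        if y.shape != (12,):
            raise ValueError(f"expected a 12-vector, got shape {y.shape}")
        return cls(*(float(v) for v in y))

    # -- derived quantities ------------------------------------------------
    @property
    def prevalence(self) -> float:
        return self.i_a + self.i_b

    def susceptible(self, params: ModelParams) -> tuple[float, float]:
        """Per-type susceptible fractions [S_u] = p_u - [I_u]."""
        return (params.p_a - self.i_a, params.p_b - self.i_b)

    def ordered_link_total(self) -> float:
        """Total ordered link density; equals <k> when conservation holds."""
        return (
            self.ss_aa + 2 * self.ss_ab + self.ss_bb
            + 2 * (self.si_aa + self.si_ab + self.si_ba + self.si_bb)
            + self.ii_aa + 2 * self.ii_ab + self.ii_bb
        )

    def degree_marginals(self, params: ModelParams) -> tuple[float, float]:
        """Per-type mean degrees (k_a, k_b) implied by the link densities.

        The ordered density of links anchored on a type-u node, divided by
        the type fraction p_u, is the mean degree of type-u nodes.
        """
        # ordered pairs whose first node has type a
        anchored_a = (
            self.ss_aa + self.ss_ab          # (S_a, S_*)
            + self.si_aa + self.si_ab        # (S_a, I_*)
            + self.si_aa + self.si_ba        # (I_a, S_*) -- reverse of si_*a
            + self.ii_aa + self.ii_ab        # (I_a, I_*)
        )
        anchored_b = (
            self.ss_bb + self.ss_ab
            + self.si_ba + self.si_bb
            + self.si_bb + self.si_ab
            + self.ii_bb + self.ii_ab
        )
        return (anchored_a / params.p_a, anchored_b / params.p_b)

    def validate(self, params: ModelParams, tol: float = 1e-8) -> None:
        """Raise if the state leaves the physical region or breaks conservation."""
        y = self.to_vector()
        if np.any(y < -tol):
            bad = FIELDS[int(np.argmin(y))]
            raise ValueError(f"negative moment density: {bad} = {y.min()}")
        if self.i_a > params.p_a + tol or self.i_b > params.p_b + tol:
            raise ValueError("per-type prevalence exceeds the type fraction")
        total = self.ordered_link_total()
        if abs(total - params.mean_degree) > tol * max(1.0, params.mean_degree):
            raise ValueError(
                f"link conservation violated: ordered total {total} != "
                f"<k> = {params.mean_degree}"
            )


_UNORDERED_KEYS = (
    "I_a", "I_b",
    "S_aS_a", "S_aS_b", "S_bS_b",
    "S_aI_a", "S_aI_b", "S_bI_a", "S_bI_b",
    "I_aI_a", "I_aI_b", "I_bI_b",
)


def to_unordered_convention(state: MomentState) -> dict:
    """Convert ordered densities to the unordered per-link convention.

    Same-class cells (both ends same state and type) are halved so that each
    undirected link is counted once; cross-class cells are reported once;
    node fractions pass through unchanged.
    """
    return {
        "I_a": state.i_a,
        "I_b": state.i_b,
        "S_aS_a": state.ss_aa / 2.0,
        "S_aS_b": state.ss_ab,
        "S_bS_b": state.ss_bb / 2.0,
        "S_aI_a": state.si_aa,
        "S_aI_b": state.si_ab,
        "S_bI_a": state.si_ba,
        "S_bI_b": state.si_bb,
        "I_aI_a": state.ii_aa / 2.0,
        "I_aI_b": state.ii_ab,
        "I_bI_b": state.ii_bb / 2.0,
    }


def from_unordered_convention(densities: Mapping[str, float]) -> MomentState:
    """Inverse of :func:`to_unordered_convention` (exact round trip)."""
    missing = [k for k in _UNORDERED_KEYS if k not in densities]
    if missing:
        raise ValueError(f"missing link-density keys: {', '.join(missing)}")
    d = densities
    return MomentState(
        i_a=d["I_a"],
        i_b=d["I_b"],
        ss_aa=2.0 * d["S_aS_a"],
        ss_ab=d["S_aS_b"],
        ss_bb=2.0 * d["S_bS_b"],
        si_aa=d["S_aI_a"],
        si_ab=d["S_aI_b"],
        si_ba=d["S_bI_a"],
        si_bb=d["S_bI_b"],
        ii_aa=2.0 * d["I_aI_a"],
        ii_ab=d["I_aI_b"],
        ii_bb=2.0 * d["I_bI_b"],
    )


def disease_free_state(
    params: ModelParams, ss_config: tuple[float, float, float] | None = None
) -> MomentState:
    """A point on the plane of extinct (disease-free) states.

    With no infected nodes the dynamics freezes, so *any* split of the link
    budget among the S-S classes is stationary: the extinct state is a
    2-parameter plane, not a point.  ``ss_config`` selects the point as the
    ordered triple (ss_aa, ss_ab, ss_bb) with ss_aa + 2 ss_ab + ss_bb = <k>.
    The default is the Erdos-Renyi random-mixing configuration
    ss[u][v] = <k> p_u p_v.
    """
    k = params.mean_degree
    if ss_config is None:
        pa, pb = params.p_a, params.p_b
        ss_config = (k * pa * pa, k * pa * pb, k * pb * pb)
    ss_aa, ss_ab, ss_bb = ss_config
    if min(ss_aa, ss_ab, ss_bb) < 0:
        raise ValueError("ss_config entries must be non-negative")
    total = ss_aa + 2 * ss_ab + ss_bb
    if abs(total - k) > 1e-8 * max(1.0, k):
        raise ValueError(
            f"ss_config ordered total {total} does not match <k> = {k}"
        )
    return MomentState(
        i_a=0.0, i_b=0.0,
        ss_aa=ss_aa, ss_ab=ss_ab, ss_bb=ss_bb,
        si_aa=0.0, si_ab=0.0, si_ba=0.0, si_bb=0.0,
        ii_aa=0.0, ii_ab=0.0, ii_bb=0.0,
    )


def random_mixing_state(params: ModelParams, prevalence: float) -> MomentState:
    """The moment state of a fresh G(N, K) network with uniform random type
    and state assignment at the given prevalence: every pair density is the
    product of its endpoint fractions times <k>.

    This is the natural initial condition matching the simulator's
    ``assign_initial_condition`` on an Erdos-Renyi graph.
    """
    if not 0 <= prevalence <= 1:
        raise ValueError(f"prevalence must lie in [0, 1], got {prevalence}")
    k = params.mean_degree
    pa, pb = params.p_a, params.p_b
    s, i = 1.0 - prevalence, prevalence
    return MomentState(
        i_a=i * pa, i_b=i * pb,
        ss_aa=k * pa * pa * s * s, ss_ab=k * pa * pb * s * s,
        ss_bb=k * pb * pb * s * s,
        si_aa=k * pa * pa * s * i, si_ab=k * pa * pb * s * i,
        si_ba=k * pb * pa * s * i, si_bb=k * pb * pb * s * i,
        ii_aa=k * pa * pa * i * i, ii_ab=k * pa * pb * i * i,
        ii_bb=k * pb * pb * i * i,
    )
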