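import numpy as np
import pytest

from hetsis.params import ModelParams


@pytest.fixture(scope="session")
def main_params() -> ModelParams:
    """The main heterogeneous parameter set (psi_a=0.65, psi_b=0.05,
    p_a=0.75 so <psi>=0.5, omega=0.2, mu=0.002, <k>=20), at desk scale."""
    return ModelParams(
        beta=0.032, psi_a=0.65, psi_b=0.05, p_a=0.75,
        mu=0.002, omega=0.2, n_nodes=10000, n_links=100000,
    )


@pytest.fixture(scope="session")
def homog_params() -> ModelParams:
    """Homogeneous limit psi_a = psi_b = 0.5 of the same parameter family."""
    return ModelParams(
        beta=0.025, psi_a=0.5, psi_b=0.5, p_a=0.75,
        mu=0.002, omega=0.2, n_nodes=10000, n_links=100000,
    )


def random_physical_state(params: ModelParams, rng: np.random.Generator):
    """A random strictly positive moment state satisfying conservation."""
    from hetsis.moments import MomentState

    i_a = rng.uniform(0.05, 0.9) * params.p_a
    i_b = rng.uniform(0.05, 0.9) * params.p_b
    weights = rng.uniform(0.1, 1.0, size=10)
    # ordered multiplicities for ss(3), si(4), ii(3) cells
    mult = np.array([1, 2, 1, 2, 2, 2, 2, 1, 2, 1], dtype=float)
    weights *= params.mean_degree / (weights @ mult)
    ss = weights[:3]
    si = weights[3:7]
    ii = weights[7:]
    return MomentState(
        i_a=i_a, i_b=i_b,
        ss_aa=ss[0], ss_ab=ss[1], ss_bb=ss[2],
        si_aa=si[0], si_ab=si[1], si_ba=si[2], si_bb=si[3],
        ii_aa=ii[0], ii_ab=ii[1], ii_bb=ii[2],
    )
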