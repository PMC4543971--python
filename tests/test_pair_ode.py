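"""Pair-approximation ODE system: conservation, symmetry, closure,
homogeneous reduction, Jacobians, integration and steady states."""

import numpy as np
import pytest

from hetsis.moments import MomentState, disease_free_state
from hetsis.pair_ode import (
    _rhs_raw,
    closure_triplet,
    find_steady_state,
    integrate,
    jacobian,
    reduce_state,
    rhs,
    rhs_vector,
)
from hetsis.params import ModelParams

from .conftest import random_physical_state
from .oracles import one_type_pair_rhs


def seeded_state(params, eps=0.05):
    """Fresh ER state with uniform random infection at prevalence eps."""
    from hetsis.moments import random_mixing_state

    return random_mixing_state(params, eps)


class TestRhs:
    def test_link_conservation_at_random_states(self, main_params):
        rng = np.random.default_rng(10)
        mult = np.array([0, 0, 1, 2, 1, 2, 2, 2, 2, 1, 2, 1], dtype=float)
        for _ in range(50):
            y = random_physical_state(main_params, rng).to_vector()
            d = rhs_vector(y, main_params)
            assert abs(d @ mult) < 1e-12 * main_params.mean_degree

    def test_disease_free_plane_is_invariant(self, main_params):
        for cfg in [None, (2.0, 4.0, 10.0), (20.0, 0.0, 0.0)]:
            df = disease_free_state(main_params, cfg)
            assert np.all(rhs_vector(df.to_vector(), main_params) == 0.0)

    def test_type_relabeling_symmetry(self, main_params):
        """Swapping the a/b labels everywhere commutes with the dynamics."""
        rng = np.random.default_rng(11)
        psi = np.array([0.65, 0.05])
        p = np.array([0.75, 0.25])
        swap = [1, 0, 4, 3, 2, 8, 7, 6, 5, 11, 10, 9]
        for _ in range(20):
            y = random_physical_state(main_params, rng).to_vector()
            d1 = _rhs_raw(y, 0.03, psi, p, 0.002, 0.2)
            d2 = _rhs_raw(y[swap], 0.03, psi[::-1], p[::-1], 0.002, 0.2)
            np.testing.assert_allclose(d1, d2[swap], rtol=1e-12, atol=1e-15)

    def test_homogeneous_reduction_to_one_type_pair_model(self, main_params):
        """For psi_a=psi_b the aggregated moments obey the classic one-type
        adaptive SIS pair equations (independent unordered-convention
        derivation).

        The exact reduction lives on the type-proportional submanifold
        (types assigned independently of everything), which is invariant
        when psi_a = psi_b; states are drawn there.
        """
        psi_bar = 0.5
        params = main_params.replace(psi_a=psi_bar, psi_b=psi_bar)
        rng = np.random.default_rng(12)
        p = np.array(params.p)
        for _ in range(100):
            # random one-type state with link conservation, split p-proportionally
            i_tot = rng.uniform(0.05, 0.9)
            w = rng.uniform(0.1, 1.0, size=3)  # ss, si, ii ordered totals
            w *= params.mean_degree / (w[0] + 2 * w[1] + w[2])
            y = np.empty(12)
            y[0], y[1] = i_tot * p
            outer = np.outer(p, p)
            y[2], y[3], y[4] = w[0] * outer[0, 0], w[0] * outer[0, 1], w[0] * outer[1, 1]
            y[5], y[6], y[7], y[8] = (w[1] * outer).ravel()
            y[9], y[10], y[11] = w[2] * outer[0, 0], w[2] * outer[0, 1], w[2] * outer[1, 1]
            d = rhs_vector(y, params)
            # aggregate: unordered [SS], [SI], [II] and [I]
            agg = np.array([
                y[0] + y[1],
                (y[2] + 2 * y[3] + y[4]) / 2,
                y[5] + y[6] + y[7] + y[8],
                (y[9] + 2 * y[10] + y[11]) / 2,
            ])
            d_agg = np.array([
                d[0] + d[1],
                (d[2] + 2 * d[3] + d[4]) / 2,
                d[5] + d[6] + d[7] + d[8],
                (d[9] + 2 * d[10] + d[11]) / 2,
            ])
            expected = one_type_pair_rhs(
                agg, params.beta * psi_bar, params.mu, params.omega,
                params.mean_degree / 2,
            )
            np.testing.assert_allclose(d_agg, expected, rtol=1e-10, atol=1e-13)


class TestClosure:
    def test_ordered_closure_value(self):
        # chains S_a-S_a-I_a from SS_aa=4, SI_aa=2, S_a=0.5: 4*2/0.5
        assert closure_triplet(4.0, 2.0, 0.5) == pytest.approx(16.0)

    def test_no_chains_without_first_link(self):
        assert closure_triplet(0.0, 3.0, 0.4) == 0.0

    def test_bilinearity(self):
        a = closure_triplet(2.0, 3.0, 0.5)
        assert closure_triplet(4.0, 3.0, 0.5) == pytest.approx(2 * a)
        assert closure_triplet(2.0, 6.0, 0.5) == pytest.approx(2 * a)

    def test_guard_at_vanishing_middle_fraction(self):
        assert closure_triplet(1e-30, 1e-30, 0.0) == 0.0

    def test_delta_factor_equivalence_non_palindromic(self):
        """Unordered closure with symmetry factors delta in {4, 2, 1} agrees
        with the ordered closure for the unambiguous chain classes.

        With [X_uY_v]_unord = [XY]_ord / kappa (kappa = 2 for identical end
        classes) the unordered pair closure [XYZ] = delta [XY][YZ]/[Y]
        reproduces the ordered chain count.
        """
        ss_aa_ord, si_ab_ord, si_aa_ord, s_a = 4.0, 1.5, 2.0, 0.5
        # chain S_a - S_a - I_b: X = Y, Y != Z -> delta = 2
        ordered = closure_triplet(ss_aa_ord, si_ab_ord, s_a)
        unordered = 2 * (ss_aa_ord / 2) * si_ab_ord / s_a
        assert ordered == pytest.approx(unordered)
        # chain I_b - S_a - I_a: all classes distinct -> delta = 1
        ordered = closure_triplet(si_ab_ord, si_aa_ord, s_a)
        unordered = 1 * si_ab_ord * si_aa_ord / s_a
        assert ordered == pytest.approx(unordered)
        # chain S_a - S_a - S_a: all identical -> delta = 4 with both pairs
        # in unordered counts
        ordered = closure_triplet(ss_aa_ord, ss_aa_ord, s_a)
        unordered = 4 * (ss_aa_ord / 2) * (ss_aa_ord / 2) / s_a
        assert ordered == pytest.approx(unordered)


class TestJacobian:
    def test_matches_central_finite_differences(self, main_params):
        rng = np.random.default_rng(13)
        from hetsis.pair_ode import _rhs_reduced

        for _ in range(5):
            s = random_physical_state(main_params, rng)
            jac = jacobian(s, main_params)
            y = reduce_state(s.to_vector())
            fd = np.empty_like(jac)
            h = 1e-6
            for j in range(11):
                yp, ym = y.copy(), y.copy()
                yp[j] += h
                ym[j] -= h
                fd[:, j] = (
                    _rhs_reduced(yp, main_params) - _rhs_reduced(ym, main_params)
                ) / (2 * h)
            scale = np.max(np.abs(jac))
            np.testing.assert_allclose(jac, fd, atol=1e-6 * scale)

    def test_stable_endemic_point_has_negative_spectrum(self, main_params):
        traj = integrate(seeded_state(main_params), main_params, 30000.0,
                         n_samples=10)
        fix = find_steady_state(traj.final_state(), main_params)
        eigs = np.linalg.eigvals(jacobian(fix, main_params))
        assert np.max(eigs.real) < 0


class TestIntegrate:
    def test_disease_free_start_stays_constant(self, main_params):
        df = disease_free_state(main_params)
        traj = integrate(df, main_params, 1000.0, n_samples=20)
        np.testing.assert_allclose(
            traj.states, np.tile(df.to_vector(), (20, 1)), atol=1e-12
        )

    def test_supercritical_seed_reaches_endemic_state(self, main_params):
        traj = integrate(seeded_state(main_params, eps=0.01), main_params,
                         30000.0, n_samples=30)
        prev = traj.prevalence()
        assert 0 < prev[-1] < 1
        assert prev[-1] > 0.5  # strongly endemic at beta=0.032

    def test_frame_export_uses_unordered_convention(self, main_params):
        traj = integrate(seeded_state(main_params), main_params, 100.0,
                         n_samples=5)
        df = traj.to_frame()
        assert list(df.columns)[:3] == ["t", "I_a", "I_b"]
        link_cols = [c for c in df.columns if len(c) > 3]
        # unordered totals sum to K/N at every sample
        np.testing.assert_allclose(
            df[link_cols].sum(axis=1),
            main_params.n_links / main_params.n_nodes,
            rtol=1e-9,
        )

    def test_conservation_drift_bounded(self, main_params):
        rtol = 1e-8
        traj = integrate(seeded_state(main_params), main_params, 20000.0,
                         rtol=rtol)
        assert traj.conservation_drift() <= 10 * rtol * main_params.mean_degree

    def test_attractor_independent_of_interior_start(self, main_params):
        """Above the invasion threshold both interior starts converge to the
        same endemic fixed point (Newton-polished to remove residual
        integrator drift)."""
        f1 = find_steady_state(
            integrate(seeded_state(main_params, eps=0.02), main_params,
                      60000.0).final_state(),
            main_params,
        )
        f2 = find_steady_state(
            integrate(seeded_state(main_params, eps=0.7), main_params,
                      60000.0).final_state(),
            main_params,
        )
        np.testing.assert_allclose(
            f1.to_vector(), f2.to_vector(), rtol=0, atol=1e-6
        )


class TestFindSteadyState:
    def test_disease_free_point_is_exact_root(self, main_params):
        df = disease_free_state(main_params)
        out = find_steady_state(df, main_params)
        np.testing.assert_allclose(out.to_vector(), df.to_vector(), atol=1e-12)

    def test_residual_below_tolerance(self, main_params):
        traj = integrate(seeded_state(main_params), main_params, 30000.0,
                         n_samples=10)
        fix = find_steady_state(traj.final_state(), main_params)
        res = np.max(np.abs(rhs_vector(fix.to_vector(), main_params)))
        assert res < 1e-10

    def test_rapid_convergence_near_endemic_point(self, main_params):
        traj = integrate(seeded_state(main_params), main_params, 60000.0,
                         n_samples=10)
        # count Newton steps via the tolerance sequence: converge with a
        # tight iteration cap
        fix = find_steady_state(traj.final_state(), main_params, max_iter=5)
        assert fix.prevalence > 0.5
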