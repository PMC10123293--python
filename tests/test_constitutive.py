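import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from poroindent.constitutive import (
    CompactionError,
    DissipationReport,
    InternalState,
    StressState,
    darcy_flux,
    dissipation,
    eq_stress,
    neq_stress,
    run_material_point,
    total_stress,
    update_internal,
    vol_stress,
    vol_stress_scalar,
)
from poroindent.kinematics import spectral_decompose
from poroindent.materials import OgdenBranch, derived_quantities

from conftest import random_deformation_gradient


def shear_F(gamma):
    F = np.eye(3)
    F[0, 1] = gamma
    return F


class TestEquilibriumStress:
    def test_zero_at_identity(self, params):
        tau = eq_stress(spectral_decompose(np.eye(3)), params)
        np.testing.assert_allclose(tau, 0.0, atol=1e-12)

    @settings(deadline=None, max_examples=40)
    @given(st.integers(0, 2**31 - 1))
    def test_trace_free_for_any_admissible_state(self, seed):
        from poroindent.materials import hydrogel_parameters
        params = hydrogel_parameters()
        rng = np.random.default_rng(seed)
        F = random_deformation_gradient(rng)
        tau = eq_stress(spectral_decompose(F), params)
        scale = max(np.abs(tau).max(), 1.0)
        assert abs(np.trace(tau)) < 1e-10 * scale
        np.testing.assert_allclose(tau, tau.T, atol=1e-10 * scale)

    def test_small_shear_recovers_consistent_modulus(self, params):
        gamma = 1e-4
        tau = eq_stress(spectral_decompose(shear_F(gamma)), params)
        assert tau[0, 1] / gamma == pytest.approx(params.eq.mu0, rel=1e-3)


class TestNonEquilibriumStress:
    def test_zero_at_identity(self, params):
        tau = neq_stress(np.eye(3), params.neq[0].branch)
        np.testing.assert_allclose(tau, 0.0, atol=1e-12)

    def test_uniaxial_isochoric_closed_form(self):
        # be = diag(l^2, 1/l, 1/l) has Je = 1; the Ogden principal stress is
        # beta_1 = (2 mu/3)(l^a - l^(-a/2)), beta_2 = beta_3 = -beta_1/2
        mu, alpha, lam = -418.0, -13.5, 1.05
        tau = neq_stress(np.diag([lam**2, 1 / lam, 1 / lam]),
                         OgdenBranch(mu, alpha))
        b1 = 2 * mu / 3 * (lam**alpha - lam ** (-alpha / 2))
        np.testing.assert_allclose(np.diag(tau), [b1, -b1 / 2, -b1 / 2],
                                   rtol=1e-12)

    def test_small_shear_modulus_limit(self, params):
        gamma = 1e-4
        F = shear_F(gamma)
        tau = neq_stress(F @ F.T, params.neq[0].branch)
        assert tau[0, 1] / gamma == pytest.approx(
            params.neq[0].branch.mu0, rel=1e-3)

    def test_non_spd_input_rejected(self, params):
        with pytest.raises(ValueError):
            neq_stress(np.diag([1.0, -1.0, 1.0]), params.neq[0].branch)


class TestVolumetricStress:
    def test_zero_at_unit_jacobian(self, params):
        np.testing.assert_allclose(vol_stress(1.0, params), 0.0, atol=1e-12)

    def test_reference_value_in_compression(self, params):
        # lambda* = 1e5 Pa, n0S = 0.032, J = 0.9
        assert vol_stress_scalar(0.9, params) == pytest.approx(-1.004e4,
                                                               rel=1e-3)

    def test_monotone_decreasing_and_divergent_toward_compaction(self, params):
        J = np.linspace(0.04, 1.0, 200)
        s = vol_stress_scalar(J, params)
        assert np.all(np.diff(s) > 0)  # s increases with J (less compression)
        # hyperbolic growth approaching the compaction point
        assert vol_stress_scalar(params.n0S + 2e-6, params) < -1e9

    def test_compaction_point_raises(self, params):
        with pytest.raises(CompactionError):
            vol_stress_scalar(params.n0S, params)


class TestTotalStress:
    def test_stress_free_reference(self, params):
        state = spectral_decompose(np.eye(3))
        st_ = total_stress(state, InternalState.reference(), 0.0, params)
        np.testing.assert_allclose(st_.tau_total, 0.0, atol=1e-12)

    def test_pore_pressure_gives_isotropic_compression(self, params):
        state = spectral_decompose(np.eye(3))
        p0 = 123.0
        st_ = total_stress(state, InternalState.reference(), p0, params)
        np.testing.assert_allclose(st_.tau_total, -p0 * np.eye(3),
                                   atol=1e-10)

    def test_decomposition_sums_to_total(self, params, rng):
        F = random_deformation_gradient(rng)
        state = spectral_decompose(F)
        internal, _ = update_internal(state, InternalState.reference(),
                                      0.01, params)
        st_ = total_stress(state, internal, 47.0, params)
        rebuilt = (st_.tau_eq + st_.tau_vol + sum(st_.tau_neq)
                   - 47.0 * state.J * np.eye(3))
        np.testing.assert_allclose(st_.tau_total, rebuilt, rtol=1e-12)


class TestInternalUpdate:
    def test_zero_dt_leaves_state_unchanged(self, params, rng):
        F = random_deformation_gradient(rng)
        state = spectral_decompose(F)
        internal, _ = update_internal(state, InternalState.reference(),
                                      0.05, params)
        again, _ = update_internal(state, internal, 0.0, params)
        for a, b in zip(internal.be, again.be):
            np.testing.assert_allclose(a, b, atol=1e-14)

    def test_reference_state_is_fixed_point(self, params):
        state = spectral_decompose(np.eye(3))
        new, tau = update_internal(state, InternalState.reference(), 5.0,
                                   params)
        for be, t in zip(new.be, tau):
            np.testing.assert_allclose(be, np.eye(3), atol=1e-12)
            np.testing.assert_allclose(t, 0.0, atol=1e-12)

    def test_trace_free_branch_stresses(self, params, rng):
        F = random_deformation_gradient(rng)
        _, tau = update_internal(spectral_decompose(F),
                                 InternalState.reference(), 0.01, params)
        for t in tau:
            assert abs(np.trace(t)) < 1e-10 * max(np.abs(t).max(), 1.0)

    def test_small_shear_relaxes_exponentially(self, params):
        """Holding a small shear step, each branch decays as
        exp(-t/(eta/mu0)); the fitted rate matches within 2% and the curve
        within 1% of the initial amplitude."""
        gamma = 1e-3
        F = shear_F(gamma)
        state = spectral_decompose(F)
        for i, vb in enumerate(params.neq):
            tau_r = vb.relaxation_time
            dt = tau_r / 100.0
            times = np.arange(0.0, 3.0 * tau_r + dt / 2, dt)
            internal = InternalState.reference()
            internal, tau0 = update_internal(state, internal, 0.0, params)
            sig = [tau0[i][0, 1]]
            for _ in times[1:]:
                internal, tau = update_internal(state, internal, dt, params)
                sig.append(tau[i][0, 1])
            sig = np.asarray(sig)
            expected = sig[0] * np.exp(-times / tau_r)
            assert np.max(np.abs(sig - expected)) < 0.01 * abs(sig[0])
            rate = -np.polyfit(times, np.log(np.abs(sig)), 1)[0]
            assert 1.0 / rate == pytest.approx(tau_r, rel=0.02)
            # stress norm is non-increasing under the hold
            assert np.all(np.diff(np.abs(sig)) <= 1e-15)

    def test_matches_dense_ode_integration(self, params):
        """Backward-Euler exponential map vs. high-accuracy integration of
        the continuous flow rule b_e' = -tau(b_e) b_e / eta under a held
        finite shear, within 1% at dt = tau/50."""
        gamma = 0.2
        F = shear_F(gamma)
        b = F @ F.T
        for i, vb in enumerate(params.neq):
            mu_b = vb.branch
            eta = vb.eta
            tau_r = vb.relaxation_time

            def rhs(t, y):
                be = y.reshape(3, 3)
                tau = neq_stress(be, mu_b)
                return (-(tau @ be) / eta).ravel()

            t_end = 1.0 * tau_r
            sol = solve_ivp(rhs, (0.0, t_end), b.ravel(), rtol=1e-10,
                            atol=1e-12, dense_output=True)
            dt = tau_r / 50.0
            times = np.arange(0.0, t_end + dt / 2, dt)
            state = spectral_decompose(F)
            internal = InternalState.reference()
            internal, tau0 = update_internal(state, internal, 0.0, params)
            scale = abs(tau0[i][0, 1])
            worst = 0.0
            for t in times[1:]:
                internal, tau = update_internal(state, internal, dt, params)
                be_exact = sol.sol(t).reshape(3, 3)
                tau_exact = neq_stress(be_exact, mu_b)
                worst = max(worst,
                            np.abs(tau[i] - tau_exact).max() / scale)
            assert worst < 0.01


class TestDarcyFlux:
    def test_zero_gradient_zero_flux(self, params):
        np.testing.assert_allclose(
            darcy_flux(np.zeros(3), 1.0, params), 0.0)

    def test_unit_jacobian_prefactor(self, params):
        g = np.array([1.0, 0.0, 0.0])
        w = darcy_flux(g, 1.0, params)
        assert w[0] == pytest.approx(-params.K0 / params.muFR, rel=1e-12)

    def test_linear_in_permeability(self, params):
        from dataclasses import replace
        g = np.array([3.0, -1.0, 0.5])
        w1 = darcy_flux(g, 0.98, params)
        w2 = darcy_flux(g, 0.98, replace(params, K0=2 * params.K0))
        np.testing.assert_allclose(w2, 2 * w1, rtol=1e-12)

    def test_compaction_guard(self, params):
        with pytest.raises(CompactionError):
            darcy_flux(np.ones(3), params.n0S, params)


class TestDissipation:
    def test_zero_state_zero_rates(self, params):
        state = spectral_decompose(np.eye(3))
        st_ = total_stress(state, InternalState.reference(), 0.0, params)
        rep = dissipation(st_, np.zeros(3), state, params)
        assert rep.Dv == pytest.approx(0.0, abs=1e-15)
        assert rep.Dp == pytest.approx(0.0, abs=1e-15)

    def test_pure_shear_branch_closed_form(self, params):
        # tau_neq = gamma (e1 x e2 + e2 x e1): Dv = gamma^2 / eta
        gamma = 7.0
        tau = gamma * (np.outer([1, 0, 0], [0, 1, 0])
                       + np.outer([0, 1, 0], [1, 0, 0]))
        state = spectral_decompose(np.eye(3))
        st_ = StressState(tau_eq=np.zeros((3, 3)), tau_vol=np.zeros((3, 3)),
                          tau_neq=(tau, np.zeros((3, 3))), p=np.array(0.0),
                          tau_total=tau)
        rep = dissipation(st_, np.zeros(3), state, params)
        assert rep.Dv == pytest.approx(gamma**2 / params.neq[0].eta,
                                       rel=1e-12)

    @settings(deadline=None, max_examples=40)
    @given(st.integers(0, 2**31 - 1))
    def test_both_rates_non_negative_on_random_states(self, seed):
        """Thermodynamic consistency: viscous and porous dissipation are
        non-negative for any admissible state and flux."""
        from poroindent.materials import hydrogel_parameters
        params = hydrogel_parameters()
        rng = np.random.default_rng(seed)
        F = random_deformation_gradient(rng)
        state = spectral_decompose(F)
        internal, _ = update_internal(state, InternalState.reference(),
                                      10 ** rng.uniform(-3, 1), params)
        st_ = total_stress(state, internal, rng.uniform(-1e3, 1e3), params)
        w = darcy_flux(rng.uniform(-100, 100, 3), state.J, params)
        rep = dissipation(st_, w, state, params)
        assert rep.Dv >= 0.0
        assert rep.Dp >= 0.0


class TestMaterialPointDriver:
    def test_identity_history_all_zero(self, params):
        times = np.linspace(0, 1, 11)
        resp = run_material_point(lambda t: np.eye(3), times, params)
        np.testing.assert_allclose(resp.tau_total, 0.0, atol=1e-12)
        np.testing.assert_allclose(resp.Dv, 0.0, atol=1e-15)

    def test_shear_step_instantaneous_and_longtime_moduli(self, params):
        """A held shear step shows the glassy modulus (sum of all branch
        moduli, ~3.295 kPa) at t=0+ and the equilibrium modulus at
        t >> tau_2."""
        gamma = 1e-3
        d = derived_quantities(params)
        times = np.concatenate([[0.0], np.geomspace(1e-4, 600.0, 400)])
        resp = run_material_point(lambda t: shear_F(gamma), times, params)
        g_inst = resp.tau_total[0, 0, 1] / gamma
        g_long = resp.tau_total[-1, 0, 1] / gamma
        assert g_inst == pytest.approx(d.mu0_instantaneous, rel=1e-3)
        assert g_long == pytest.approx(d.mu0_eq, rel=1e-3)
        assert np.all(resp.Dv >= 0.0)

    def test_time_step_self_consistency(self, params):
        """Halving dt changes the stress response by well under 0.5%
        once the fastest branch is resolved."""
        gamma = 0.05
        t_end = 0.05

        def hist(t):
            return shear_F(gamma * min(t / t_end, 1.0))

        sols = []
        for dt in (2.5e-4, 1.25e-4):
            times = np.arange(0.0, t_end + dt / 2, dt)
            resp = run_material_point(hist, times, params)
            sols.append(resp.tau_total[-1])
        scale = np.abs(sols[1]).max()
        assert np.abs(sols[0] - sols[1]).max() / scale < 0.005
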