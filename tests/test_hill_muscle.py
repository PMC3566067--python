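import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from torquesim.config import MuscleConfig
from torquesim.hill_muscle import (
    MuscleArchitecture,
    MuscleState,
    force_length,
    force_velocity,
    inverse_force_velocity,
    isometric_steady_force,
    see_force,
    step_muscle,
    total_force,
)


class TestForceLength:
    def test_unity_at_optimum(self, arch):
        assert force_length(arch.l_ce_opt, arch) == pytest.approx(1.0)

    def test_zero_at_parabola_edges(self, arch):
        for sign in (+1, -1):
            l = (1 + sign * arch.fl_width) * arch.l_ce_opt
            assert force_length(l, arch) == pytest.approx(0.0, abs=1e-12)

    def test_half_width_value(self, arch):
        l = (1 + arch.fl_width / 2) * arch.l_ce_opt
        assert force_length(l, arch) == pytest.approx(0.75)

    def test_clamped_outside(self, arch):
        assert force_length(2.5 * arch.l_ce_opt, arch) == 0.0

    def test_rejects_nonpositive_length(self, arch):
        with pytest.raises(ValueError):
            force_length(0.0, arch)

    def test_gaussian_variant(self):
        cfg = MuscleConfig(fl_shape="gaussian")
        g = MuscleArchitecture.from_config(cfg)
        assert force_length(g.l_ce_opt, g) == pytest.approx(1.0)
        assert 0 < force_length(1.3 * g.l_ce_opt, g) < 1


class TestForceVelocity:
    def test_isometric_point(self, arch):
        assert force_velocity(0.0, arch) == pytest.approx(1.0)

    def test_zero_at_max_shortening(self, arch):
        v_max = -arch.v_max_rel * arch.l_ce_opt
        assert force_velocity(v_max, arch) == pytest.approx(0.0, abs=1e-12)

    def test_eccentric_asymptote(self, arch):
        v = 1e9 * arch.l_ce_opt
        assert force_velocity(v, arch) == pytest.approx(arch.f_ecc, rel=1e-6)

    def test_monotone_increasing(self, arch):
        v = np.linspace(-arch.v_max_rel, 5.0, 400) * arch.l_ce_opt
        f = force_velocity(v, arch)
        assert np.all(np.diff(f) >= 0)

    def test_differentiable_at_zero(self, arch):
        # one-sided difference quotients agree for the default slope factor
        h = 1e-7 * arch.l_ce_opt
        left = (force_velocity(0.0, arch) - force_velocity(-h, arch)) / h
        right = (force_velocity(h, arch) - force_velocity(0.0, arch)) / h
        assert left == pytest.approx(right, rel=1e-4)

    @given(f=st.floats(min_value=0.0, max_value=1.49))
    @settings(max_examples=60, deadline=None)
    def test_inverse_roundtrip(self, arch, f):
        v = inverse_force_velocity(f, arch)
        if abs(v) < arch.v_rel_cap * arch.l_ce_opt * 0.999:
            assert force_velocity(v, arch) == pytest.approx(f, abs=1e-9)

    def test_inverse_clamps_out_of_range(self, arch):
        v = inverse_force_velocity(10.0, arch)  # far above the eccentric plateau
        assert v <= arch.v_rel_cap * arch.l_ce_opt


class TestSeeForce:
    def test_slack_is_force_free(self, arch):
        assert see_force(arch.l_see_slack, arch, 100.0) == 0.0
        assert see_force(0.5 * arch.l_see_slack, arch, 100.0) == 0.0

    def test_fmax_at_reference_strain(self, arch):
        l = arch.l_see_slack * (1 + arch.see_strain_at_fmax)
        assert see_force(l, arch, 250.0) == pytest.approx(250.0)

    def test_quadratic_at_half_strain(self, arch):
        l = arch.l_see_slack * (1 + arch.see_strain_at_fmax / 2)
        assert see_force(l, arch, 100.0) == pytest.approx(25.0)


class TestStepMuscle:
    def test_passive_stays_at_rest(self, arch):
        state = MuscleState.rest(arch, 4)
        fmax = np.array([10.0, 20.0, 30.0, 40.0])
        for _ in range(100):
            state = step_muscle(state, np.zeros(4), arch, fmax, 0.001)
        np.testing.assert_allclose(state.l_ce, arch.l_ce_opt)
        np.testing.assert_allclose(state.force_n, 0.0)

    def test_full_activation_reaches_isometric_fixed_point(self, arch):
        """Dual route: forward stepping vs 1-D root solve of the equilibrium."""
        fmax = np.array([50.0])
        state = MuscleState.rest(arch, 1)
        a = np.ones(1)
        for _ in range(2000):
            state = step_muscle(state, a, arch, fmax, 0.001)
        l_star, f_star = isometric_steady_force(1.0, arch, 50.0)
        assert state.l_ce[0] == pytest.approx(l_star, abs=1e-6)
        assert state.force_n[0] == pytest.approx(f_star, rel=1e-3)
        assert abs(state.v_ce[0]) < 1e-4

    def test_step_activation_monotone_rise(self, arch):
        state = MuscleState.rest(arch, 1)
        fmax = np.array([100.0])
        forces = []
        for _ in range(600):
            state = step_muscle(state, np.ones(1), arch, fmax, 0.001)
            forces.append(state.force_n[0])
        forces = np.array(forces)
        assert np.all(np.diff(forces) >= -1e-9)
        assert forces[-1] > 0.5 * 100.0

    def test_isometric_constraint_held(self, arch):
        state = MuscleState.rest(arch, 2)
        fmax = np.array([80.0, 120.0])
        for _ in range(500):
            state = step_muscle(state, np.array([1.0, 0.6]), arch, fmax, 0.001)
            l_see = arch.l_mtu - state.l_ce * np.cos(state.phi)
            mtu = l_see + state.l_ce * np.cos(state.phi)
            np.testing.assert_allclose(mtu, arch.l_mtu, atol=1e-9)

    def test_series_equilibrium_at_output(self, arch):
        state = MuscleState.rest(arch, 1)
        fmax = np.array([60.0])
        for _ in range(1500):
            state = step_muscle(state, np.ones(1), arch, fmax, 0.001)
        l_see = arch.l_mtu - state.l_ce * np.cos(state.phi)
        np.testing.assert_allclose(
            state.force_n, see_force(l_see, arch, fmax), atol=1e-9
        )

    def test_relaxation_after_deactivation(self, arch):
        state = MuscleState.rest(arch, 1)
        fmax = np.array([60.0])
        for _ in range(1000):
            state = step_muscle(state, np.ones(1), arch, fmax, 0.001)
        peak = state.force_n[0]
        for _ in range(2000):
            state = step_muscle(state, np.zeros(1), arch, fmax, 0.001)
        assert state.force_n[0] < 0.01 * peak
        # no parallel elastic element: the force-free configuration is only
        # determined up to the capped lengthening overshoot past SEE slack
        assert state.l_ce[0] == pytest.approx(arch.l_ce_opt, rel=5e-3)

    def test_force_bounded_by_eccentric_ceiling(self, arch):
        state = MuscleState.rest(arch, 1)
        fmax = np.array([60.0])
        for _ in range(3000):
            state = step_muscle(state, np.ones(1), arch, fmax, 0.001)
            assert 0 <= state.force_n[0] <= arch.f_ecc * 60.0 + 1e-9

    def test_constant_thickness_pennation(self, arch):
        state = MuscleState.rest(arch, 1)
        fmax = np.array([90.0])
        for _ in range(800):
            state = step_muscle(state, np.ones(1), arch, fmax, 0.001)
        w = state.l_ce * np.sin(state.phi)
        np.testing.assert_allclose(w, arch.thickness, atol=1e-12)


class TestTotalForce:
    def test_zero(self):
        assert total_force(np.zeros(5)) == 0.0

    def test_linearity(self):
        assert total_force(np.array([1.0, 2.0, 3.0])) == pytest.approx(6.0)

    def test_all_units_at_fmax(self, pool):
        assert total_force(pool.fmax_n) == pytest.approx(1433.4, abs=1e-9)

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            total_force(np.array([1.0, -0.5]))


def test_architecture_rest_configuration(arch):
    # MTU sized so the rest state (CE at optimum) leaves the SEE exactly slack
    assert arch.l_mtu == pytest.approx(
        arch.l_see_slack + arch.l_ce_opt * np.cos(arch.phi_opt)
    )
    state = MuscleState.rest(arch, 1)
    assert state.phi[0] == pytest.approx(arch.phi_opt)
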