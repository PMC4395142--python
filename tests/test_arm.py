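"""Arm kinematics and dynamics against independent oracles."""

import numpy as np
import pytest

from skyarm import (
    ArmParameters,
    ArmState,
    BaseMotionSample,
    dynamics_terms,
    forward_dynamics,
    forward_kinematics,
    gravity_torque,
    hand_jacobian,
    joint_positions,
    mechanical_energy,
)


def random_state(rng, spread=np.pi, vel=5.0):
    return ArmState(
        angles=rng.uniform(-spread, spread, 3),
        angular_velocities=rng.uniform(-vel, vel, 3),
    )


class TestForwardKinematics:
    def test_fully_extended_horizontal(self, params):
        state = ArmState(angles=np.zeros(3), angular_velocities=np.zeros(3))
        _, _, hand = forward_kinematics(params, state, BaseMotionSample())
        np.testing.assert_allclose(hand, [0.63, 0.0], atol=1e-15)

    def test_rigid_translation_of_base(self, params, rng):
        state = random_state(rng)
        still = joint_positions(params, state, BaseMotionSample())
        moved = joint_positions(
            params, state, BaseMotionSample(position=[0.03, 0.0])
        )
        np.testing.assert_allclose(moved - still, np.tile([0.03, 0.0], (4, 1)), atol=1e-15)

    def test_link_lengths_preserved(self, params, rng):
        for _ in range(20):
            pts = joint_positions(params, random_state(rng), BaseMotionSample())
            dists = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            np.testing.assert_allclose(dists, params.length, rtol=1e-12)


class TestHandJacobian:
    def test_rigid_rotation_about_base(self, params):
        state = ArmState(angles=np.zeros(3), angular_velocities=[1.0, 0.0, 0.0])
        v = hand_jacobian(params, state) @ state.angular_velocities
        np.testing.assert_allclose(v, [0.0, 0.63], atol=1e-15)

    def test_matches_finite_differences(self, params, rng):
        eps = 1e-6
        for _ in range(20):
            state = random_state(rng)
            J = hand_jacobian(params, state)
            for j in range(3):
                for sgn, store in ((1, "p"), (-1, "m")):
                    th = state.angles.copy()
                    th[j] += sgn * eps
                    s = ArmState(angles=th, angular_velocities=np.zeros(3))
                    if sgn == 1:
                        _, _, hp = forward_kinematics(params, s, BaseMotionSample())
                    else:
                        _, _, hm = forward_kinematics(params, s, BaseMotionSample())
                col = (hp - hm) / (2 * eps)
                np.testing.assert_allclose(J[:, j], col, rtol=1e-6, atol=1e-9)

    def test_zero_velocity_gives_zero_relative_hand_velocity(self, params, rng):
        state = ArmState(angles=rng.uniform(-3, 3, 3), angular_velocities=np.zeros(3))
        np.testing.assert_array_equal(
            hand_jacobian(params, state) @ state.angular_velocities, np.zeros(2)
        )


class TestDynamicsTerms:
    def test_gravity_zero_when_links_hang_straight_down(self, params):
        # every centre of mass directly below its proximal joint
        state = ArmState(angles=[-np.pi / 2, 0.0, 0.0], angular_velocities=np.zeros(3))
        terms = dynamics_terms(params, state)
        np.testing.assert_allclose(terms.gravity_torque, np.zeros(3), atol=1e-12)

    def test_coriolis_zero_at_rest(self, params, rng):
        state = ArmState(angles=rng.uniform(-3, 3, 3), angular_velocities=np.zeros(3))
        np.testing.assert_allclose(dynamics_terms(params, state).coriolis, np.zeros(3), atol=0)

    def test_inertia_symmetric_positive_definite(self, params, rng):
        for _ in range(1000):
            state = ArmState(angles=rng.uniform(-np.pi, np.pi, 3), angular_velocities=np.zeros(3))
            I_m = dynamics_terms(params, state).inertia_matrix
            np.testing.assert_allclose(I_m, I_m.T, atol=1e-12)
            assert np.all(np.linalg.eigvalsh(I_m) > 0)

    def test_agrees_with_lagrangian_oracle(self, params, rng, lagrangian_oracle):
        """Generalized forces match the symbolically derived Euler-Lagrange
        equations on random states with nonzero base acceleration."""
        for _ in range(100):
            state = random_state(rng)
            alpha = rng.uniform(-20, 20, 3)
            base_acc = rng.uniform(-5, 5, 2)
            terms = dynamics_terms(params, state)
            ours = (
                terms.inertia_matrix @ alpha
                + terms.base_coupling @ base_acc
                + terms.coriolis
                + terms.gravity_torque
            )
            ref = lagrangian_oracle(
                params, state.angles, state.angular_velocities, alpha, base_acc
            )
            np.testing.assert_allclose(ours, ref, rtol=1e-8, atol=1e-10)

    def test_oracle_holds_for_nondefault_parameters(self, rng, lagrangian_oracle):
        pars = ArmParameters(
            mass=[2.5, 1.4, 0.6],
            length=[0.3, 0.25, 0.2],
            com_offset=[0.15, 0.1, 0.1],
            inertia=[0.05, 0.02, 0.01],
            gravity=3.7,
        )
        for _ in range(20):
            state = random_state(rng)
            alpha = rng.uniform(-10, 10, 3)
            base_acc = rng.uniform(-3, 3, 2)
            terms = dynamics_terms(pars, state)
            ours = (
                terms.inertia_matrix @ alpha
                + terms.base_coupling @ base_acc
                + terms.coriolis
                + terms.gravity_torque
            )
            ref = lagrangian_oracle(pars, state.angles, state.angular_velocities, alpha, base_acc)
            np.testing.assert_allclose(ours, ref, rtol=1e-8, atol=1e-10)


class TestForwardDynamics:
    def test_static_equilibrium(self, params, rng):
        state = ArmState(angles=rng.uniform(-3, 3, 3), angular_velocities=np.zeros(3))
        tau = gravity_torque(params, state.angles)
        acc = forward_dynamics(params, state, BaseMotionSample(), np.zeros((3, 3)), tau)
        np.testing.assert_allclose(acc, np.zeros(3), atol=1e-12)

    def test_equation_of_motion_residual(self, params, rng):
        for _ in range(20):
            state = random_state(rng)
            base = BaseMotionSample(acceleration=rng.uniform(-5, 5, 2))
            D = np.diag(rng.uniform(0, 2, 3))
            tau = rng.uniform(-10, 10, 3)
            acc = forward_dynamics(params, state, base, D, tau)
            terms = dynamics_terms(params, state)
            residual = (
                terms.inertia_matrix @ acc
                + terms.base_coupling @ base.acceleration
                + terms.coriolis
                + terms.gravity_torque
                + D @ state.angular_velocities
                - tau
            )
            np.testing.assert_allclose(residual, np.zeros(3), atol=1e-10)

    def test_rejects_non_finite_torque(self, params):
        state = ArmState(angles=np.zeros(3), angular_velocities=np.zeros(3))
        with pytest.raises(ValueError, match="torque"):
            forward_dynamics(
                params, state, BaseMotionSample(), np.zeros((3, 3)), [np.nan, 0, 0]
            )

    def test_energy_conservation_without_dissipation(self, params):
        """With D = 0, no input torque and a static base, RK4 at dt = 1e-4
        conserves total mechanical energy to < 1e-6 J over 1 s."""
        dt = 1e-4
        base = BaseMotionSample()
        D = np.zeros((3, 3))
        tau = np.zeros(3)

        def acc(theta, omega):
            s = ArmState(angles=theta, angular_velocities=omega)
            return forward_dynamics(params, s, base, D, tau)

        theta = np.array([-1.0, 0.5, 0.3])
        omega = np.array([0.2, -0.1, 0.4])
        e0 = mechanical_energy(
            params, ArmState(angles=theta, angular_velocities=omega), base
        )
        for _ in range(10000):
            k1t, k1o = omega, acc(theta, omega)
            k2t, k2o = omega + dt / 2 * k1o, acc(theta + dt / 2 * k1t, omega + dt / 2 * k1o)
            k3t, k3o = omega + dt / 2 * k2o, acc(theta + dt / 2 * k2t, omega + dt / 2 * k2o)
            k4t, k4o = omega + dt * k3o, acc(theta + dt * k3t, omega + dt * k3o)
            theta = theta + dt / 6 * (k1t + 2 * k2t + 2 * k3t + k4t)
            omega = omega + dt / 6 * (k1o + 2 * k2o + 2 * k3o + k4o)
        e1 = mechanical_energy(
            params, ArmState(angles=theta, angular_velocities=omega), base
        )
        assert abs(e1 - e0) < 1e-6

    def test_translation_invariance_of_terms(self, params, rng):
        """dynamics_terms depends on the base only through the acceleration
        passed separately, never on base position."""
        state = random_state(rng)
        t1 = dynamics_terms(params, state)
        t2 = dynamics_terms(params, state)  # no base argument exists at all
        np.testing.assert_array_equal(t1.inertia_matrix, t2.inertia_matrix)


class TestParameterValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("mass", [0.0, 1.0, 1.0]),
            ("length", [0.2, -0.1, 0.2]),
            ("com_offset", [0.3, 0.09, 0.08]),  # exceeds length
            ("inertia", [-1e-3, 0.01, 0.01]),
        ],
    )
    def test_invalid_parameters_rejected(self, field, value):
        kwargs = dict(
            mass=[1.79, 1.02, 0.77],
            length=[0.24, 0.22, 0.17],
            com_offset=[0.10, 0.09, 0.08],
            inertia=[3.0e-2, 1.34e-2, 0.73e-2],
        )
        kwargs[field] = value
        with pytest.raises(ValueError):
            ArmParameters(**kwargs)
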