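"""Planar dynamics tests: assembly oracles, contact law, muscle geometry."""

import numpy as np
import pytest

import planargait as pg
from planargait.body import (ContactParams, Kinematics, SerialChain,
                             contact_forces, standing_state)
from planargait.config import load_model_config
from planargait.muscle import MuscleState


def random_state(skel, rng, spread=0.4):
    q = rng.normal(0, spread, 9)
    q[1] = abs(q[1]) + 0.8
    return pg.BodyState(q=q, qdot=rng.normal(0, 1, 9))


class TestMassMatrix:
    def test_symmetric_and_positive_definite(self, dynamics, rng):
        for _ in range(100):
            q = rng.normal(0, 0.6, 9)
            M = dynamics.mass_matrix(q)
            assert np.allclose(M, M.T, atol=1e-12)
            assert np.linalg.eigvalsh(M).min() > 0

    def test_translation_block_is_total_mass(self, dynamics):
        M = dynamics.mass_matrix(np.zeros(9))
        assert M[0, 0] == pytest.approx(dynamics.params.total_mass)
        assert M[1, 1] == pytest.approx(dynamics.params.total_mass)


class TestForwardDynamics:
    def test_rest_without_gravity_stays_at_rest(self, dynamics):
        st = standing_state(dynamics.params)
        qddot = dynamics.forward_dynamics(st, np.zeros(9), gravity=0.0)
        assert np.allclose(qddot, 0.0, atol=1e-10)

    def test_free_fall_acceleration(self, dynamics):
        st = standing_state(dynamics.params)
        qddot = dynamics.forward_dynamics(st, np.zeros(9))
        assert qddot[1] == pytest.approx(-dynamics.params.gravity)

    def test_single_pendulum_closed_form(self):
        # one pinned link: qddot = -(m g c) sin(q) / (I + m c^2)
        m, L, c, inertia = 2.0, 0.8, 0.35, 0.09
        chain = SerialChain([m], [L], [c], [inertia], gravity=9.81)
        for q0 in (0.1, 0.7, 2.0, -1.2):
            got = chain.accelerations(np.array([q0]), np.zeros(1))[0]
            expect = -(m * 9.81 * c) * np.sin(q0) / (inertia + m * c**2)
            assert got == pytest.approx(expect, rel=1e-12)

    def test_double_pendulum_energy_conserved(self):
        """< 0.1% energy drift over 5 simulated seconds."""
        chain = SerialChain([1.5, 1.0], [0.5, 0.4], [0.25, 0.2],
                            [0.03, 0.015], gravity=9.81)
        q = np.array([1.0, 0.5])
        qdot = np.zeros(2)
        e0 = chain.energy(q, qdot)
        h = 1e-4
        for _ in range(int(5.0 / h)):
            q, qdot = chain.step(q, qdot, h)
        scale = abs(e0) + chain.g * (1.5 * 0.25 + 1.0 * (0.5 + 0.2))
        assert abs(chain.energy(q, qdot) - e0) / scale < 1e-3


class TestIntegration:
    def test_ballistic_com_parabola(self, dynamics, model):
        skel, muscles, _ = model
        st = standing_state(skel)
        st.q[1] += 2.0
        st.qdot[0], st.qdot[1] = 1.2, 2.5
        ms = [MuscleState() for _ in muscles]
        masses = dynamics._masses
        def com(s):
            k = Kinematics(skel, s.q, s.qdot)
            return ((masses[:, None] * k.coms).sum(0) / masses.sum(),
                    (masses[:, None] * k.v_coms).sum(0) / masses.sum())
        c0, v0 = com(st)
        for _ in range(50):
            st, ms, _ = dynamics.integrate_step(st, ms, np.zeros(22))
        c1, _ = com(st)
        t = 0.5
        pred = c0 + v0 * t + 0.5 * np.array([0, -skel.gravity]) * t**2
        # semi-implicit Euler carries a 0.5*g*h*t bias in y
        assert abs(c1[0] - pred[0]) < 1e-9
        assert abs(c1[1] - pred[1]) < 0.5 * skel.gravity * 1e-3 * t * 1.5

    def test_zero_gravity_rest_is_invariant(self):
        cfg = load_model_config()
        cfg["gravity"] = 0.0
        skel, muscles, paths = pg.build_model(cfg)
        dyn = pg.WalkerDynamics(skel, paths, muscles)
        st = standing_state(skel)
        st.q[1] += 1.0  # airborne: no contact forces either
        ms = [MuscleState() for _ in muscles]
        st2, _, _ = dyn.integrate_step(st, ms, np.zeros(22))
        assert np.allclose(st2.q, st.q, atol=1e-12)
        assert np.allclose(st2.qdot, 0.0, atol=1e-12)

    def test_momentum_conserved_without_external_forces(self, rng):
        """dP/dt = 0 under contact-free, muscle-free, zero-gravity motion.

        Checked on the equations of motion directly (central-difference
        momentum rate along the solved acceleration), which isolates the
        conservation property of the assembly from integrator truncation.
        """
        cfg = load_model_config()
        skel, muscles, paths = pg.build_model(cfg)
        dyn = pg.WalkerDynamics(skel, paths, muscles)
        for _ in range(20):
            st = random_state(skel, rng, spread=0.3)
            st.q[1] += 3.0
            qddot = dyn.forward_dynamics(st, np.zeros(9), gravity=0.0)
            eps = 1e-6
            def P(q, qdot):
                k = Kinematics(skel, q, qdot)
                return (dyn._masses[:, None] * k.v_coms).sum(0)
            dP = (P(st.q + eps * st.qdot, st.qdot + eps * qddot)
                  - P(st.q - eps * st.qdot, st.qdot - eps * qddot)) / (2 * eps)
            scale = max(1.0, np.abs(P(st.q, st.qdot)).max(),
                        np.abs(qddot).max())
            assert np.abs(dP).max() / scale < 1e-9

    def test_determinism_bit_identical(self, dynamics, model, rng):
        skel, muscles, _ = model
        st = standing_state(skel)
        exc = rng.uniform(0, 1, 22)
        runs = []
        for _ in range(2):
            s = st.copy()
            ms = [MuscleState() for _ in muscles]
            for _ in range(20):
                s, ms, _ = dynamics.integrate_step(s, ms, exc)
            runs.append((s.q.copy(), s.qdot.copy()))
        assert np.array_equal(runs[0][0], runs[1][0])
        assert np.array_equal(runs[0][1], runs[1][1])

    def test_nonfinite_excitation_rejected(self, dynamics, model):
        skel, muscles, _ = model
        st = standing_state(skel)
        ms = [MuscleState() for _ in muscles]
        exc = np.zeros(22)
        exc[5] = np.nan
        with pytest.raises(ValueError, match="index 5"):
            dynamics.integrate_step(st, ms, exc)


class TestContact:
    CP = ContactParams()

    def test_airborne_spheres_produce_no_force(self):
        pos = np.array([[0.0, 0.5], [1.0, 0.03]])
        vel = np.zeros((2, 2))
        F = contact_forces(pos, vel, np.array([0.025, 0.025]), self.CP)
        assert np.all(F == 0.0)

    def test_static_penetration_matches_stiffness_law(self):
        d = 0.004
        pos = np.array([[0.0, 0.025 - d]])
        F = contact_forces(pos, np.zeros((1, 2)), np.array([0.025]), self.CP)
        assert F[0, 1] == pytest.approx(self.CP.stiffness * d**1.5)
        assert F[0, 0] == 0.0

    def test_friction_opposes_slip_and_saturates(self):
        d = 0.004
        pos = np.array([[0.0, 0.025 - d]])
        vel = np.array([[1.0, 0.0]])  # fast slip in +x
        F = contact_forces(pos, vel, np.array([0.025]), self.CP)
        assert F[0, 0] < 0.0
        assert abs(F[0, 0]) <= self.CP.friction_mu * F[0, 1] + 1e-12

    def test_no_adhesion_during_fast_separation(self, rng):
        for _ in range(200):
            pos = np.array([[0.0, rng.uniform(0.0, 0.05)]])
            vel = rng.normal(0, 2, (1, 2))
            F = contact_forces(pos, vel, np.array([0.025]), self.CP)
            assert F[0, 1] >= 0.0


class TestMuscleGeometry:
    def test_neutral_pose_calibration(self, model):
        skel, muscles, paths = model
        L, V, _ = paths.muscle_geometry(np.zeros(9), np.zeros(9))
        assert np.allclose(L, paths.neutral_lengths)
        assert np.allclose(V, 0.0)
        assert np.all(L > 0)

    def test_knee_flexion_lengthens_vastus(self, model):
        skel, muscles, paths = model
        names = [m.name for m in muscles]
        i_vas = names.index("VAS_R")
        q = np.zeros(9)
        q[4] = -0.3  # knee flexion
        L, V, arms = paths.muscle_geometry(q, np.zeros(9))
        dL = L[i_vas] - paths.neutral_lengths[i_vas]
        assert dL == pytest.approx(abs(arms[i_vas, 4] * 0.3))
        assert V[i_vas] == 0.0

    def test_velocity_is_time_derivative_of_length(self, model, rng):
        _, _, paths = model
        q = rng.normal(0, 0.3, 9)
        qdot = rng.normal(0, 1, 9)
        eps = 1e-7
        L0, V, _ = paths.muscle_geometry(q, qdot)
        L1, _, _ = paths.muscle_geometry(q + eps * qdot, qdot)
        assert np.allclose((L1 - L0) / eps, V, atol=1e-6)

    def test_biarticular_muscles_span_two_joints(self, model):
        _, muscles, paths = model
        names = [m.name for m in muscles]
        for nm in ("HAM_R", "RF_R", "GAS_L"):
            arms = paths.moment_arms[names.index(nm)]
            assert np.count_nonzero(arms) == 2

    def test_hip_ab_adductors_have_no_mechanical_action(self, model):
        _, muscles, paths = model
        names = [m.name for m in muscles]
        for nm in ("HAB_R", "HAD_R", "HAB_L", "HAD_L"):
            assert np.all(paths.moment_arms[names.index(nm)] == 0.0)


class TestJointLimits:
    def test_no_limit_torque_inside_range(self, dynamics):
        tau = dynamics._passive_joint_torques(np.zeros(9), np.zeros(9))
        assert np.allclose(tau, 0.0)

    def test_limit_torque_opposes_violation(self, dynamics):
        q = np.zeros(9)
        q[4] = 0.3  # knee beyond its 0.02 hyperextension stop
        tau = dynamics._passive_joint_torques(q, np.zeros(9))
        assert tau[4] < 0.0
        q[4] = -3.0  # beyond flexion stop
        tau = dynamics._passive_joint_torques(q, np.zeros(9))
        assert tau[4] > 0.0


def test_skeleton_params_validation():
    cfg = load_model_config()
    skel = pg.SkeletonParams.from_config(cfg)
    assert skel.total_mass == pytest.approx(75.05)
    assert len(skel.contact.spheres) == 3
    bad = {k: dict(v) for k, v in cfg["segments"].items()}
    bad["trunk"]["mass"] = -1.0
    cfg2 = dict(cfg)
    cfg2["segments"] = bad
    with pytest.raises(ValueError):
        pg.SkeletonParams.from_config(cfg2)
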