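"""Rigid-body engine: kinematics, dynamics, reactions and the affine maps."""

import math

import numpy as np
import pytest

import rmrsolver as rmr
from rmrsolver.multibody import (
    BodySegment,
    JointSpec,
    Model,
    ModelState,
    MuscleActuator,
    ReserveActuator,
    _muscle_geometry,
    _rot_axis,
    forward_dynamics,
    forward_kinematics,
    joint_reaction_oracle,
    linearize_accelerations,
    linearize_jrf,
    load_model,
    moment_arm_matrix,
    moment_arms,
    musculotendon_length,
    save_model,
)
from rmrsolver.muscle import MuscleParameters

from conftest import make_pendulum


def make_two_link(axis=(0.0, 1.0, 0.0)):
    """Two pin joints in series, links of 0.3 m along -z."""
    seg = lambda name: BodySegment(name=name, mass=1.0, inertia=(0.01, 0.01, 1e-4), com=(0, 0, -0.15), length=0.3)
    return Model(
        bodies=(seg("upper"), seg("lower")),
        joints=(
            JointSpec(name="j1", joint_type="pin", parent="ground", child="upper", axis=axis),
            JointSpec(
                name="j2", joint_type="pin", parent="upper", child="lower",
                translation=(0.0, 0.0, -0.3), axis=axis,
            ),
        ),
        muscles=(),
        reserves=(ReserveActuator("j1", 5.0), ReserveActuator("j2", 5.0)),
        gravity=(0.0, 0.0, -9.81),
    )


class TestForwardKinematics:
    def test_rest_pose_identity(self):
        m = make_two_link()
        frames = forward_kinematics(m, np.zeros(2))
        np.testing.assert_allclose(frames["upper"][0], np.eye(3), atol=1e-15)
        np.testing.assert_allclose(frames["lower"][1], [0, 0, -0.3], atol=1e-15)

    def test_pin_quarter_turn(self):
        m = make_two_link()
        frames = forward_kinematics(m, np.array([math.pi / 2, 0.0]))
        R, o = frames["upper"]
        np.testing.assert_allclose(R, _rot_axis(np.array([0.0, 1.0, 0.0]), math.pi / 2), atol=1e-14)
        # tip of upper link swings from -z to +x under +90 deg about +y
        np.testing.assert_allclose(frames["lower"][1], [-0.3 * 0, 0, 0] + R @ [0, 0, -0.3], atol=1e-14)

    def test_chain_matches_hand_multiplied_transforms(self, rng):
        m = make_two_link()
        for _ in range(20):
            q = rng.uniform(-2.0, 2.0, 2)
            frames = forward_kinematics(m, q)
            R1 = _rot_axis(np.array([0.0, 1.0, 0.0]), q[0])
            R2 = _rot_axis(np.array([0.0, 1.0, 0.0]), q[1])
            np.testing.assert_allclose(frames["lower"][0], R1 @ R2, atol=1e-13)
            np.testing.assert_allclose(frames["lower"][1], R1 @ [0, 0, -0.3], atol=1e-13)


def with_muscle(model, path, name="m", f_iso=100.0, l_opt=1.0):
    musc = MuscleActuator(
        name=name, parameters=MuscleParameters(f_iso_max=f_iso, l_opt=l_opt), path=path
    )
    from dataclasses import replace

    return replace(model, muscles=model.muscles + (musc,))


class TestMuscleGeometry:
    def test_same_body_length_constant(self, rng):
        m = with_muscle(
            make_two_link(),
            (("upper", (0.0, 0.0, -0.05)), ("upper", (0.02, 0.0, -0.25))),
        )
        ref = musculotendon_length(m, np.zeros(2), m.muscles[0])
        for _ in range(10):
            q = rng.uniform(-2, 2, 2)
            assert musculotendon_length(m, q, m.muscles[0]) == pytest.approx(ref, abs=1e-15)

    def test_law_of_cosines_across_pin(self):
        # straight muscle from ground (0,0,a) to a point (0,0,-b) on the upper
        # link; the two lever arms subtend angle (pi - q) at the joint
        a, b = 0.1, 0.2
        m = with_muscle(
            make_two_link(), (("ground", (0.0, 0.0, a)), ("upper", (0.0, 0.0, -b)))
        )
        for q1 in np.linspace(-1.5, 1.5, 11):
            expected = math.sqrt(a * a + b * b + 2 * a * b * math.cos(q1))
            got = musculotendon_length(m, np.array([q1, 0.0]), m.muscles[0])
            assert got == pytest.approx(expected, abs=1e-12)

    def test_length_continuity(self):
        m = with_muscle(
            make_two_link(), (("ground", (0.0, 0.0, 0.1)), ("lower", (0.0, 0.0, -0.1)))
        )
        q = np.array([0.3, -0.4])
        L0 = musculotendon_length(m, q, m.muscles[0])
        for delta in (1e-3, 1e-5, 1e-7):
            L1 = musculotendon_length(m, q + delta, m.muscles[0])
            assert abs(L1 - L0) < 2.0 * delta  # Lipschitz in q with |r| < 1 m


class TestMomentArms:
    def test_non_crossing_coordinate_has_zero_arm(self):
        m = with_muscle(
            make_two_link(), (("ground", (0.0, 0.0, 0.1)), ("upper", (0.0, 0.0, -0.2)))
        )
        r = moment_arms(m, np.array([0.4, 0.9]), m.muscles[0])
        assert abs(r[1]) < 1e-9  # muscle does not span j2

    def test_perpendicular_distance_oracle(self):
        # at q = 0 the muscle from (0, 0, +a) on ground to (d, 0, -b) on the
        # link: perpendicular distance of the line from the joint center is an
        # analytic expression checked against the tendon-excursion arm
        a, b, d = 0.15, 0.25, 0.04
        m = with_muscle(
            make_two_link(), (("ground", (0.0, 0.0, a)), ("upper", (d, 0.0, -b)))
        )
        p1, p2 = np.array([0.0, 0.0, a]), np.array([d, 0.0, -b])
        u = (p2 - p1) / np.linalg.norm(p2 - p1)
        dist = np.linalg.norm(np.cross(p1, u))
        r = moment_arms(m, np.zeros(2), m.muscles[0])
        assert abs(r[0]) == pytest.approx(dist, abs=1e-5)

    def test_sign_convention_against_forward_dynamics(self):
        """Positive moment arm means tension accelerates the coordinate positively."""
        m = with_muscle(
            make_two_link(),
            (("ground", (0.0, 0.0, 0.1)), ("upper", (0.04, 0.0, -0.2))),
            f_iso=50.0,
        )
        from dataclasses import replace

        m = replace(m, gravity=(0.0, 0.0, 0.0))
        q = np.array([0.2, 0.0])
        r = moment_arms(m, q, m.muscles[0])
        qdd = forward_dynamics(m, ModelState(q, np.zeros(2)), np.array([1.0]), np.zeros(2))
        assert math.copysign(1.0, r[0]) == math.copysign(1.0, qdd[0])

    def test_finite_difference_matches_analytic_jacobian(self, loaded_model, rng):
        for _ in range(10):
            q = rng.uniform(-0.5, 1.8, 3)
            fd = moment_arm_matrix(loaded_model, q)
            _, dldq = _muscle_geometry(loaded_model, q)
            np.testing.assert_allclose(fd, -dldq, atol=1e-8)


class TestForwardDynamics:
    def test_all_zero_input_gives_zero_acceleration(self):
        from dataclasses import replace

        m = replace(make_two_link(), gravity=(0.0, 0.0, 0.0))
        qdd = forward_dynamics(m, ModelState(np.zeros(2), np.zeros(2)), np.zeros(0), np.zeros(2))
        np.testing.assert_allclose(qdd, 0.0, atol=1e-14)

    def test_pendulum_textbook_closed_form(self, pendulum):
        # qdd = -(m g l_com / I_joint) sin(q) for a hinged rod
        mass, length = 1.5, 0.4
        l_com = length / 2
        inertia_joint = mass * length**2 / 12 + mass * l_com**2
        for q in (-1.0, -0.3, 0.5, 1.2):
            qdd = forward_dynamics(
                pendulum, ModelState(np.array([q]), np.zeros(1)), np.zeros(0), np.zeros(1)
            )
            expected = -(mass * 9.81 * l_com / inertia_joint) * math.sin(q)
            assert qdd[0] == pytest.approx(expected, rel=1e-10)

    def test_acceleration_affine_in_activation(self, loaded_model, rng):
        st = ModelState(rng.uniform(0, 1.2, 3), rng.uniform(-1, 1, 3))
        a1 = rng.uniform(0, 1, 8)
        a2 = rng.uniform(0, 1, 8)
        lam = 0.37
        c = np.zeros(3)
        mix = forward_dynamics(loaded_model, st, lam * a1 + (1 - lam) * a2, c)
        sup = lam * forward_dynamics(loaded_model, st, a1, c) + (1 - lam) * forward_dynamics(
            loaded_model, st, a2, c
        )
        np.testing.assert_allclose(mix, sup, atol=1e-10)


class TestJointReaction:
    def test_static_hanging_mass(self, toy_model):
        st = toy_model.neutral_state()
        qdd = forward_dynamics(toy_model, st, np.zeros(8), np.zeros(3))
        F = joint_reaction_oracle(toy_model, st, qdd, np.zeros(8), np.zeros(3), "gh")
        np.testing.assert_allclose(F, [0.0, 0.0, 2.0 * 9.81], atol=1e-9)

    def test_hand_load_adds_exact_weight(self, toy_model, loaded_model):
        st = toy_model.neutral_state()
        z = np.zeros(8)
        F_free = joint_reaction_oracle(toy_model, st, np.zeros(3), z, np.zeros(3), "gh")
        F_load = joint_reaction_oracle(loaded_model, st, np.zeros(3), z, np.zeros(3), "gh")
        np.testing.assert_allclose(F_load - F_free, [0.0, 0.0, 2.0 * 9.81], atol=1e-9)

    def test_unknown_joint_rejected(self, toy_model):
        with pytest.raises(KeyError):
            joint_reaction_oracle(
                toy_model, toy_model.neutral_state(), np.zeros(3), np.zeros(8), np.zeros(3), "elbow"
            )

    def test_single_muscle_through_joint_center(self):
        """Zero gravity, muscle pulling along a line through the joint: the
        reaction is antiparallel to the pull with magnitude = tendon force."""
        from dataclasses import replace

        m = make_two_link()
        m = with_muscle(m, (("ground", (0.0, 0.0, 0.25)), ("upper", (0.0, 0.0, -0.25))), f_iso=80.0, l_opt=0.5)
        m = replace(m, gravity=(0.0, 0.0, 0.0))
        st = ModelState(np.zeros(2), np.zeros(2))
        from rmrsolver.muscle import force_decomposition

        gain, passive = force_decomposition(m.muscles[0].parameters, 0.5, 0.0)
        a = np.array([0.7])
        tension = gain * 0.7 + passive
        F = joint_reaction_oracle(m, st, np.zeros(2), a, np.zeros(2), "j1")
        # pull on the upper link is +z (toward the ground anchor)
        np.testing.assert_allclose(F, [0.0, 0.0, -tension], atol=1e-10)

    def test_energy_free_statics(self):
        from dataclasses import replace

        m = replace(make_two_link(), gravity=(0.0, 0.0, 0.0))
        st = ModelState(np.array([0.7, -0.2]), np.zeros(2))
        for joint in ("j1", "j2"):
            F = joint_reaction_oracle(m, st, np.zeros(2), np.zeros(0), np.zeros(2), joint)
            np.testing.assert_allclose(F, 0.0, atol=1e-12)


class TestLinearizations:
    def test_zero_actuation_reproduces_baseline(self, loaded_model):
        st = ModelState(np.array([0.4, 0.05, -0.1]), np.array([0.5, 0.0, 0.2]))
        qdd_exp = np.array([1.0, -2.0, 0.5])
        A, q_tilde, baseline = linearize_accelerations(loaded_model, st, qdd_exp)
        x0 = np.zeros(11)
        np.testing.assert_allclose(A @ x0, 0.0)
        np.testing.assert_allclose(q_tilde, qdd_exp - baseline, atol=1e-14)
        A_F, F0 = linearize_jrf(loaded_model, st, qdd_exp, "gh")
        F_passive = joint_reaction_oracle(loaded_model, st, qdd_exp, np.zeros(8), np.zeros(3), "gh")
        np.testing.assert_allclose(F0, F_passive, atol=1e-10)

    def test_dimensions_and_locked_rows_absent(self, toy_model):
        st = toy_model.neutral_state()
        A, _, _ = linearize_accelerations(toy_model, st, np.zeros(3))
        assert A.shape == (3, 11)  # scapula lock contributes no row
        locked = toy_model.with_locks({"gh_y": 0.0, "gh_z": 0.0})
        A2, _, _ = linearize_accelerations(locked, locked.neutral_state(), np.zeros(1))
        assert A2.shape == (1, 9)  # 8 muscles + 1 remaining reserve

    def test_superposition_against_brute_force(self, loaded_model, rng):
        for _ in range(25):
            q = np.array(
                [rng.uniform(-0.3, 1.8), rng.uniform(-0.4, 0.4), rng.uniform(-0.4, 0.4)]
            )
            st = ModelState(q, rng.uniform(-2, 2, 3))
            qdd_exp = rng.uniform(-5, 5, 3)
            a = rng.uniform(0, 1, 8)
            c = rng.uniform(-1, 1, 3)
            x = np.concatenate([a, c])
            A, _, baseline = linearize_accelerations(loaded_model, st, qdd_exp)
            np.testing.assert_allclose(
                A @ x + baseline, forward_dynamics(loaded_model, st, a, c), atol=1e-10
            )
            A_F, F0 = linearize_jrf(loaded_model, st, qdd_exp, "gh")
            oracle = joint_reaction_oracle(loaded_model, st, qdd_exp, a, c, "gh")
            np.testing.assert_allclose(A_F @ x + F0, oracle, atol=1e-6)

    def test_doubling_strength_doubles_column(self, toy_model):
        from dataclasses import replace

        st = ModelState(np.array([0.6, 0.0, 0.0]), np.zeros(3))
        qdd = np.zeros(3)
        A_F, _ = linearize_jrf(toy_model, st, qdd, "gh")
        params = toy_model.muscles[0].parameters
        stronger = replace(
            toy_model,
            muscles=(replace(toy_model.muscles[0], parameters=replace(params, f_iso_max=2 * params.f_iso_max)),)
            + toy_model.muscles[1:],
        )
        A_F2, _ = linearize_jrf(stronger, st, qdd, "gh")
        np.testing.assert_allclose(A_F2[:, 0], 2.0 * A_F[:, 0], atol=1e-10)
        np.testing.assert_allclose(A_F2[:, 1:], A_F[:, 1:], atol=1e-12)


class TestModelIO:
    def test_round_trip(self, loaded_model, tmp_path):
        path = tmp_path / "model.json"
        save_model(loaded_model, path)
        back = load_model(path)
        assert back.muscle_names == loaded_model.muscle_names
        assert back.coordinate_names == loaded_model.coordinate_names
        st = ModelState(np.array([0.3, 0.1, -0.2]), np.array([1.0, 0.0, 0.5]))
        a = np.linspace(0, 1, 8)
        np.testing.assert_allclose(
            forward_dynamics(back, st, a, np.zeros(3)),
            forward_dynamics(loaded_model, st, a, np.zeros(3)),
            atol=1e-12,
        )

    def test_unsupported_schema_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"schema": "other/9"}')
        with pytest.raises(ValueError, match="schema"):
            load_model(path)

    def test_missing_reserves_rejected(self):
        with pytest.raises(ValueError, match="reserve"):
            Model(
                bodies=(BodySegment("b", 1.0, (0.01, 0.01, 0.01), (0, 0, -0.1)),),
                joints=(JointSpec(name="j", joint_type="pin", parent="ground", child="b"),),
                muscles=(),
                reserves=(),
            )
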