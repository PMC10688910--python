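"""Shared fixtures: toy models, motions and cached solver runs.

Solver runs are session-scoped because several tests interrogate the same
solution from different angles; everything is deterministic so sharing is
safe.
"""

import numpy as np
import pytest

import rmrsolver as rmr
from rmrsolver.multibody import BodySegment, JointSpec, Model, ReserveActuator


@pytest.fixture(scope="session")
def toy_model():
    return rmr.build_toy_shoulder()


@pytest.fixture(scope="session")
def loaded_model():
    return rmr.build_toy_shoulder(rmr.ToyShoulderConfig(hand_load=2.0))


@pytest.fixture(scope="session")
def elevation_tables():
    angles = rmr.generate_motion("elevation", duration=2.0, rate_hz=100.0)
    filtered = rmr.lowpass_filter(angles, cutoff_hz=3.0)
    speeds, accels = rmr.differentiate(filtered)
    return filtered, speeds, accels


@pytest.fixture(scope="session")
def solved_unconstrained(loaded_model, elevation_tables):
    filtered, speeds, accels = elevation_tables
    return rmr.solve_motion(
        loaded_model, filtered, speeds, accels, rmr.SolverSettings(enforce_gh=False)
    )


@pytest.fixture(scope="session")
def solved_constrained(loaded_model, elevation_tables):
    filtered, speeds, accels = elevation_tables
    return rmr.solve_motion(
        loaded_model, filtered, speeds, accels, rmr.SolverSettings(enforce_gh=True)
    )


def make_pendulum(mass=1.5, length=0.4, gravity=(0.0, 0.0, -9.81)):
    """Single pin-joint pendulum about +y, hanging along -z at q = 0.

    No muscles; one reserve so the Model invariant (one reserve per
    coordinate) holds.
    """
    com = length / 2.0
    inertia_com = mass * length**2 / 12.0
    return Model(
        bodies=(
            BodySegment(
                name="rod",
                mass=mass,
                inertia=(inertia_com, inertia_com, 1e-6),
                com=(0.0, 0.0, -com),
                length=length,
            ),
        ),
        joints=(
            JointSpec(
                name="hinge",
                joint_type="pin",
                parent="ground",
                child="rod",
                translation=(0.0, 0.0, 0.0),
                axis=(0.0, 1.0, 0.0),
            ),
        ),
        muscles=(),
        reserves=(ReserveActuator(coordinate="hinge", max_force=5.0),),
        gravity=gravity,
    )


@pytest.fixture
def pendulum():
    return make_pendulum()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def toy_frame_problem(A_acc, q_tilde, lower=None, upper=None, A_F=None, F0=None,
                      enforce_gh=False, glenoid=None, settings=None):
    """Hand-built frame NLP from explicit linearization matrices.

    Lets solver tests pose analytically solvable problems without a model:
    the last n_q columns of A_acc are the reserve columns.
    """
    from rmrsolver.multibody import FrameLinearization
    from rmrsolver.rmr_core import FrameProblem, SolverSettings

    A_acc = np.asarray(A_acc, float)
    n_q, n_tot = A_acc.shape
    n_m = n_tot - n_q
    lin = FrameLinearization(
        A_acc=A_acc,
        q_tilde_ddot=np.asarray(q_tilde, float),
        baseline_qddot=np.zeros(n_q),
        A_F=A_F,
        F0=F0,
    )
    return FrameProblem(
        linearization=lin,
        lower=np.zeros(n_m) if lower is None else np.asarray(lower, float),
        upper=np.ones(n_m) if upper is None else np.asarray(upper, float),
        settings=settings or SolverSettings(),
        glenoid=glenoid,
        enforce_gh=enforce_gh,
        t=0.0,
        n_m=n_m,
        n_q=n_q,
    )
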