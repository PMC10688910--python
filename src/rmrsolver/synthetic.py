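"""Toy-shoulder fixture generator.

A desk-scale stand-in for a full shoulder girdle: a ground-fixed scapula
carrying a 3-DoF gimbal "glenohumeral" joint, a humerus segment, and a
redundant set of via-point muscles in three functional groups:

* stabilizers — lines of action passing within 5 mm of the joint center
  (negligible moment arms) aimed so their tension presses the humeral head
  onto the glenoid axis: they can redirect the joint reaction force but
  barely move the arm;
* prime movers — moment arms >= 2 cm, able to drive the motion but pulling
  the reaction force off the glenoid axis as a side effect;
* antagonists — supply negative elevation torque when deceleration demands
  it.

The glenoid axis is stored as the direction a *stable* (compressive)
reaction on the humeral side points along: with the reaction force defined
on the distal subtree, that is the outward fossa normal (glenoid toward
humeral head), here -y of the scapula frame.

With the arm hanging (q = 0) the humerus points along -z; the elevation
coordinate (gh_x, the FIRST gimbal axis) swings it toward +y.  Gravity is
-z.  Elevation is deliberately the first gimbal axis: the gimbal's singular
configuration sits at +/-90 deg of the MIDDLE axis (gh_y), which all
generated motions keep near zero, so the toy never approaches gimbal lock
even though the elevation itself sweeps through 90 deg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .multibody import (
    BodySegment,
    GlenoidGeometry,
    JointSpec,
    Model,
    ModelState,
    MuscleActuator,
    ReserveActuator,
    forward_dynamics,
    musculotendon_length,
)
from .muscle import MuscleParameters
from .preprocessing import TrajectoryTable

__all__ = [
    "ToyShoulderConfig",
    "build_toy_shoulder",
    "generate_motion",
    "forward_consistency_data",
    "adversarial_gh_task",
    "shrug_locks",
]

GH_JOINT = "gh"
ELEVATION_COORD = "gh_x"
STABLE_AXIS = (0.0, -1.0, 0.0)  # scapula frame; see module docstring


@dataclass(frozen=True)
class ToyShoulderConfig:
    """Architecture and loading of the toy shoulder."""

    n_stabilizers: int = 4
    n_prime_movers: int = 3
    n_antagonists: int = 1
    humerus_mass: float = 2.0  # kg
    humerus_length: float = 0.3  # m
    hand_load: float = 0.0  # kg, point mass at the distal humerus end
    glenoid_direction: tuple[float, float, float] = STABLE_AXIS
    theta_max_deg: float = 20.0
    seed: int = 0
    f_iso_stabilizer: float = 500.0  # N
    f_iso_prime_mover: float = 1200.0
    f_iso_antagonist: float = 800.0
    reserve_max: float = 10.0  # N*m

    def __post_init__(self) -> None:
        n_total = self.n_stabilizers + self.n_prime_movers + self.n_antagonists
        if n_total < 4:  # N_q = 3 unlocked coordinates; need redundancy
            raise ValueError("toy shoulder needs at least N_q + 1 = 4 muscles")
        if self.hand_load < 0:
            raise ValueError("hand load must be non-negative")


def _muscle_param_for_path(model_lengths: np.ndarray, f_iso: float) -> MuscleParameters:
    """Size l_opt so the fiber stays at/below optimal length over the motion
    (no passive force, healthy force-length gain); rigid tendon of zero
    slack so the path length is the fiber length."""
    l_opt = 1.02 * float(np.max(model_lengths))
    return MuscleParameters(
        f_iso_max=f_iso, l_opt=l_opt, l_tendon_slack=0.0, v_max=10.0, alpha_opt=0.0
    )


def build_toy_shoulder(config: ToyShoulderConfig | None = None) -> Model:
    """Assemble the toy shoulder model.

    Muscle optimal fiber lengths are calibrated against the elevation range
    (gh_y in [0, 120 deg]) so fibers never go slack or develop passive force
    over the tasks the generator emits.  Deterministic for a given config.
    """
    config = config or ToyShoulderConfig()
    L = config.humerus_length
    bodies = (
        BodySegment(
            name="scapula",
            mass=1.0,
            inertia=(1e-3, 1e-3, 1e-3),
            com=(0.0, 0.0, 0.0),
            length=0.1,
        ),
        BodySegment(
            name="humerus",
            mass=config.humerus_mass,
            inertia=(
                config.humerus_mass * L**2 / 12.0,
                config.humerus_mass * L**2 / 12.0,
                5e-4,
            ),
            com=(0.0, 0.0, -L / 2.0),
            length=L,
        ),
    )
    joints = (
        # ground-fixed scapula via a locked pin: exercises the locking path
        JointSpec(
            name="scapula_ground",
            joint_type="pin",
            parent="ground",
            child="scapula",
            translation=(0.0, 0.0, 0.0),
            axis=(0.0, 0.0, 1.0),
            locked={"scapula_ground": 0.0},
        ),
        JointSpec(
            name=GH_JOINT,
            joint_type="gimbal3",
            parent="scapula",
            child="humerus",
            translation=(0.0, 0.0, 0.0),
        ),
    )

    muscles: list[dict] = []
    # stabilizers: humeral attachment within 5 mm of the joint center,
    # scapular anchors ringed around the +y axis so tension presses the head
    # along -y (the stable axis)
    for k in range(config.n_stabilizers):
        phi = 2.0 * math.pi * k / max(config.n_stabilizers, 1)
        cx, sz = 0.015 * math.cos(phi), 0.015 * math.sin(phi)
        muscles.append(
            dict(
                name=f"stab_{k}",
                group="stabilizer",
                f_iso=config.f_iso_stabilizer,
                path=(
                    ("humerus", (0.003 * math.cos(phi), -0.004, 0.003 * math.sin(phi))),
                    ("scapula", (cx, 0.060, sz)),
                ),
            )
        )
    # prime movers: deltoid-like elevator in the x = 0 plane plus a +/-x pair
    pm_defs = [
        (("humerus", (0.0, 0.0, -0.12)), ("scapula", (0.0, 0.030, 0.050))),
        (("humerus", (0.010, 0.0, -0.12)), ("scapula", (0.040, 0.030, 0.040))),
        (("humerus", (-0.010, 0.0, -0.12)), ("scapula", (-0.040, 0.030, 0.040))),
    ]
    for k in range(config.n_prime_movers):
        ins, org = pm_defs[k % len(pm_defs)]
        muscles.append(
            dict(name=f"pm_{k}", group="prime_mover", f_iso=config.f_iso_prime_mover,
                 path=(ins, org))
        )
    for k in range(config.n_antagonists):
        muscles.append(
            dict(
                name=f"ant_{k}",
                group="antagonist",
                f_iso=config.f_iso_antagonist,
                path=(
                    ("humerus", (0.01 * k, 0.0, -0.10)),
                    ("scapula", (0.01 * k, -0.030, -0.060)),
                ),
            )
        )

    # calibrate optimal fiber lengths over the elevation range on a probe
    # model carrying placeholder parameters
    placeholder = MuscleParameters(f_iso_max=1.0, l_opt=1.0)
    probe = Model(
        bodies=bodies,
        joints=joints,
        muscles=tuple(
            MuscleActuator(name=m["name"], parameters=placeholder, path=m["path"], group=m["group"])
            for m in muscles
        ),
        reserves=tuple(
            ReserveActuator(coordinate=c, max_force=config.reserve_max)
            for c in ("gh_x", "gh_y", "gh_z")
        ),
    )
    q_probe = np.zeros(3)
    elev_grid = np.radians(np.linspace(0.0, 120.0, 25))
    lengths = {m["name"]: [] for m in muscles}
    for elev in elev_grid:
        q_probe[:] = (elev, 0.0, 0.0)  # (gh_x, gh_y, gh_z): elevation first
        for mus in probe.muscles:
            lengths[mus.name].append(musculotendon_length(probe, q_probe, mus))

    actuators = tuple(
        MuscleActuator(
            name=m["name"],
            parameters=_muscle_param_for_path(np.array(lengths[m["name"]]), m["f_iso"]),
            path=m["path"],
            group=m["group"],
        )
        for m in muscles
    )
    direction = np.asarray(config.glenoid_direction, float)
    direction = tuple(direction / np.linalg.norm(direction))
    return Model(
        bodies=bodies,
        joints=joints,
        muscles=actuators,
        reserves=probe.reserves,
        gravity=(0.0, 0.0, -9.81),
        glenoid=GlenoidGeometry(
            joint=GH_JOINT,
            direction=direction,
            theta_max=math.radians(config.theta_max_deg),
        ),
        hand_load_mass=config.hand_load,
        hand_load_body="humerus",
        hand_load_point=(0.0, 0.0, -L),
    )


def shrug_locks() -> dict[str, float]:
    """Coordinate locks for the shrug analog (indeterminate humerus coords)."""
    return {"gh_y": 0.0, "gh_z": 0.0}


# ---------------------------------------------------------------------------
# motions
# ---------------------------------------------------------------------------


def _min_jerk(tau: np.ndarray) -> np.ndarray:
    return 10.0 * tau**3 - 15.0 * tau**4 + 6.0 * tau**5


def generate_motion(
    kind: str = "elevation", duration: float = 2.0, rate_hz: float = 100.0
) -> TrajectoryTable:
    """Smooth toy motions as angle tables.

    elevation: minimum-jerk ramp of the elevation coordinate from 10 to 110
    deg with zero end velocities/accelerations; the other gimbal coordinates
    stay at zero.  shrug_analog: minimum-jerk 10->40->10 deg elevation
    round-trip on the elevation coordinate only (for use with the humerus
    axial/plane coordinates locked).
    """
    if duration < 0.5:
        raise ValueError("duration must be at least 0.5 s")
    n = int(round(duration * rate_hz)) + 1
    t = np.arange(n) / rate_hz
    tau = t / duration
    if kind == "elevation":
        q = np.radians(10.0) + np.radians(100.0) * _min_jerk(tau)
        cols = {"gh_x": q, "gh_y": np.zeros(n), "gh_z": np.zeros(n)}
    elif kind == "shrug_analog":
        up = _min_jerk(np.clip(2.0 * tau, 0.0, 1.0))
        down = _min_jerk(np.clip(2.0 * tau - 1.0, 0.0, 1.0))
        q = np.radians(10.0) + np.radians(30.0) * (up - down)
        cols = {"gh_x": q}
    else:
        raise ValueError(f"unknown motion kind {kind!r}")
    return TrajectoryTable(time=t, columns=cols, kind="angles", name=kind)


def forward_consistency_data(
    model: Model,
    activation_script,
    rate_hz: float = 100.0,
    duration: float = 2.0,
    q0: np.ndarray | None = None,
    qd0: np.ndarray | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> tuple[TrajectoryTable, TrajectoryTable, TrajectoryTable]:
    """Dynamically consistent ground-truth data by forward integration.

    `activation_script(t)` returns per-muscle activations in [0, 1]; reserve
    controls are zero.  The returned accelerations are exactly the model's
    own at each sample, so the acceleration-matching equality is satisfiable
    with zero reserves and the generated data can serve as recovery ground
    truth.
    """
    n_q = model.n_q
    q0 = np.zeros(n_q) if q0 is None else np.asarray(q0, float)
    qd0 = np.zeros(n_q) if qd0 is None else np.asarray(qd0, float)
    zero_c = np.zeros(n_q)

    def rhs(t, y):
        state = ModelState(y[:n_q], y[n_q:])
        a = np.clip(np.asarray(activation_script(t), float), 0.0, 1.0)
        qdd = forward_dynamics(model, state, a, zero_c)
        return np.concatenate([y[n_q:], qdd])

    t_eval = np.arange(int(round(duration * rate_hz)) + 1) / rate_hz
    sol = solve_ivp(
        rhs,
        (0.0, float(t_eval[-1])),
        np.concatenate([q0, qd0]),
        method="RK45",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"forward integration failed: {sol.message}")
    Q = sol.y[:n_q].T
    Qd = sol.y[n_q:].T
    Qdd = np.empty_like(Q)
    for k, t in enumerate(t_eval):
        a = np.clip(np.asarray(activation_script(t), float), 0.0, 1.0)
        Qdd[k] = forward_dynamics(model, ModelState(Q[k], Qd[k]), a, zero_c)
    names = model.coordinate_names
    mk = lambda M, kind: TrajectoryTable(
        time=t_eval, columns={c: M[:, j] for j, c in enumerate(names)}, kind=kind
    )
    return mk(Q, "angles"), mk(Qd, "speeds"), mk(Qdd, "accelerations")


def adversarial_gh_task(
    config: ToyShoulderConfig | None = None,
    duration: float = 2.0,
    rate_hz: float = 100.0,
    min_violation_fraction: float = 0.2,
) -> tuple[Model, TrajectoryTable]:
    """Loaded elevation on which the unconstrained optimum leaves the cone.

    A 2 kg hand load plus the deltoid-like prime-mover geometry shears the
    glenoid reaction off the stable axis unless the stabilizers are
    recruited; verified at build time by running the unconstrained solver
    and checking the violation fraction, so an invalid fixture raises rather
    than silently weakening downstream comparisons.
    """
    from .preprocessing import differentiate, lowpass_filter
    from .rmr_core import SolverSettings, solve_motion
    from .stability import violation_report

    config = config or ToyShoulderConfig(hand_load=2.0)
    if config.hand_load <= 0.0:
        raise ValueError("the adversarial task needs a hand load")
    model = build_toy_shoulder(config)
    angles = generate_motion("elevation", duration=duration, rate_hz=rate_hz)
    filtered = lowpass_filter(angles, cutoff_hz=3.0)
    speeds, accels = differentiate(filtered)
    result = solve_motion(
        model, filtered, speeds, accels, SolverSettings(enforce_gh=False)
    )
    theta_deg = np.degrees(result.theta_series)
    frac, _ = violation_report(theta_deg, math.degrees(model.glenoid.theta_max))
    if frac < min_violation_fraction:
        raise RuntimeError(
            f"adversarial construction failed: unconstrained violation fraction "
            f"{frac:.2f} < {min_violation_fraction}"
        )
    return model, angles
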