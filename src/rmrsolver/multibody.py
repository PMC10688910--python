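"""Minimal rigid-body musculoskeletal engine.

A model is a tree of rigid body segments rooted at the ground, connected by
pin (1-DoF) or gimbal (3-DoF) rotational joints, actuated by via-point
muscles and by one ideal reserve actuator per coordinate.  The engine
provides:

* forward kinematics and via-point muscle path lengths / moment arms
  (tendon-excursion definition, central finite differences);
* forward dynamics via recursive Newton-Euler inverse dynamics (mass matrix
  assembled column-by-column from unit accelerations);
* a Newton-Euler joint-reaction "oracle" giving the 3-vector force
  transmitted to the distal subtree at any joint;
* exact per-frame linearizations of the coordinate accelerations and of the
  joint reaction force with respect to the stacked activation/control vector
  [a; c] — the two affine forms a per-frame redundancy solver needs.

Internally every joint is compiled to elementary revolute axes (a gimbal
becomes three axes with massless intermediate frames); locked coordinates
keep their fixed angle and contribute no column to the linearizations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .muscle import MuscleParameters, force_decomposition

__all__ = [
    "BodySegment",
    "JointSpec",
    "MuscleActuator",
    "ReserveActuator",
    "GlenoidGeometry",
    "Model",
    "ModelState",
    "FrameLinearization",
    "ConfigurationError",
    "forward_kinematics",
    "musculotendon_length",
    "moment_arms",
    "moment_arm_matrix",
    "muscle_kinematics",
    "forward_dynamics",
    "joint_reaction_oracle",
    "linearize_accelerations",
    "linearize_jrf",
    "load_model",
    "save_model",
]

MODEL_SCHEMA = "rmrsolver-model/1"
MOMENT_ARM_STEP = 1e-6  # rad, central-difference step for tendon excursion


class ConfigurationError(RuntimeError):
    """Model/state combination on which the dynamics are not solvable."""


# ---------------------------------------------------------------------------
# model description types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BodySegment:
    name: str
    mass: float
    inertia: tuple[float, float, float]  # principal moments about COM, body frame
    com: tuple[float, float, float]  # COM offset in the body (joint) frame, m
    length: float = 0.0

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise ValueError(f"body {self.name}: mass must be positive")
        if any(i <= 0 for i in self.inertia):
            raise ValueError(f"body {self.name}: inertia entries must be positive")


@dataclass(frozen=True)
class JointSpec:
    """A pin (1 coordinate, rotation about `axis`) or gimbal3 joint (3
    coordinates, intrinsic x-y-z rotations of the joint frame).

    `translation` places the joint frame in the parent body frame; the child
    body frame coincides with the rotated joint frame.  `locked` maps
    coordinate names to fixed angles (rad); locked coordinates are excluded
    from the generalized coordinates.
    """

    name: str
    joint_type: str  # "pin" | "gimbal3"
    parent: str
    child: str
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)  # pin only, joint frame
    locked: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.joint_type not in ("pin", "gimbal3"):
            raise ValueError(f"joint {self.name}: unknown type {self.joint_type!r}")
        for c in self.locked:
            if c not in self.coordinate_names():
                raise ValueError(f"joint {self.name}: cannot lock unknown coordinate {c!r}")

    def coordinate_names(self) -> list[str]:
        if self.joint_type == "pin":
            return [self.name]
        return [f"{self.name}_{ax}" for ax in ("x", "y", "z")]


@dataclass(frozen=True)
class MuscleActuator:
    """Via-point path muscle: ordered (body, local point) anchors."""

    name: str
    parameters: MuscleParameters
    path: tuple[tuple[str, tuple[float, float, float]], ...]
    group: str = "other"  # stabilizer | prime_mover | antagonist | other

    def __post_init__(self) -> None:
        if len(self.path) < 2:
            raise ValueError(f"muscle {self.name}: needs at least 2 via-points")


@dataclass(frozen=True)
class ReserveActuator:
    coordinate: str
    max_force: float = 10.0  # generalized force at |control| = 1, N*m

    def __post_init__(self) -> None:
        if not self.max_force > 0:
            raise ValueError(f"reserve {self.coordinate}: max force must be positive")


@dataclass(frozen=True)
class GlenoidGeometry:
    """Stability cone for one gimbal joint.

    `direction` is the cone axis, a unit vector fixed in the joint's parent
    body frame; a reaction force within `theta_max` of this axis is
    considered to intersect the (circular) glenoid fossa.
    """

    joint: str
    direction: tuple[float, float, float]
    theta_max: float = math.radians(20.0)

    def __post_init__(self) -> None:
        n = math.sqrt(sum(d * d for d in self.direction))
        if abs(n - 1.0) > 1e-9:
            raise ValueError("glenoid direction must be a unit vector")
        if not 0.0 < self.theta_max < math.pi / 2:
            raise ValueError("theta_max must be in (0, pi/2)")


@dataclass(frozen=True)
class ModelState:
    q: np.ndarray
    qdot: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "q", np.asarray(self.q, dtype=float))
        object.__setattr__(self, "qdot", np.asarray(self.qdot, dtype=float))
        if self.q.shape != self.qdot.shape:
            raise ValueError("q and qdot must have equal length")


@dataclass(frozen=True)
class FrameLinearization:
    """Affine maps of one frame: q̈ = A_acc@[a;c] + baseline (equivalently the
    equality residual target q_tilde_ddot = q̈_exp - baseline), and
    F = A_F@[a;c] + F0 in the glenoid parent frame."""

    A_acc: np.ndarray  # N_q x (N_m + N_q)
    q_tilde_ddot: np.ndarray  # N_q
    baseline_qddot: np.ndarray  # N_q, passive+gravity acceleration
    A_F: np.ndarray | None = None  # 3 x (N_m + N_q)
    F0: np.ndarray | None = None  # 3


# ---------------------------------------------------------------------------
# compiled elementary-joint representation
# ---------------------------------------------------------------------------


def _cross3(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """3-vector cross product; np.cross has ~30x call overhead at this size."""
    return np.array(
        [
            a[1] * b[2] - a[2] * b[1],
            a[2] * b[0] - a[0] * b[2],
            a[0] * b[1] - a[1] * b[0],
        ]
    )


def _rot_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    x, y, z = axis
    c, s = math.cos(angle), math.sin(angle)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


@dataclass
class _ENode:
    parent: int  # index into compiled nodes, -1 = ground
    p0: np.ndarray  # joint position in parent frame
    axis: np.ndarray  # rotation axis in (pre-rotation) joint frame
    locked: bool
    lock_value: float
    coord_index: int  # into unlocked q, or -1
    mass: float = 0.0
    com: np.ndarray = field(default_factory=lambda: np.zeros(3))
    inertia: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    body_name: str | None = None  # user body carried by this node


class _Compiled:
    """Elementary-revolute compilation of a Model (with hand load merged)."""

    def __init__(self, model: "Model") -> None:
        self.nodes: list[_ENode] = []
        self.body_node: dict[str, int] = {"ground": -1}
        self.coord_names: list[str] = []
        axes = {
            "x": np.array([1.0, 0.0, 0.0]),
            "y": np.array([0.0, 1.0, 0.0]),
            "z": np.array([0.0, 0.0, 1.0]),
        }
        bodies = {b.name: b for b in model.bodies}
        for joint in model.joints:
            if joint.parent not in self.body_node:
                raise ConfigurationError(
                    f"joint {joint.name}: parent body {joint.parent!r} not defined "
                    "before use (joints must be listed root-first)"
                )
            parent_idx = self.body_node[joint.parent]
            cnames = joint.coordinate_names()
            if joint.joint_type == "pin":
                elem = [(cnames[0], np.asarray(joint.axis, dtype=float))]
            else:
                elem = [(cnames[k], axes[ax]) for k, ax in enumerate(("x", "y", "z"))]
            first = True
            for cname, axis in elem:
                axis = axis / np.linalg.norm(axis)
                locked = cname in joint.locked
                node = _ENode(
                    parent=parent_idx,
                    p0=np.asarray(joint.translation, float) if first else np.zeros(3),
                    axis=axis,
                    locked=locked,
                    lock_value=joint.locked.get(cname, 0.0),
                    coord_index=-1,
                )
                if not locked:
                    node.coord_index = len(self.coord_names)
                    self.coord_names.append(cname)
                self.nodes.append(node)
                parent_idx = len(self.nodes) - 1
                first = False
            body = bodies[joint.child]
            last = self.nodes[-1]
            last.body_name = body.name
            last.mass = body.mass
            last.com = np.asarray(body.com, float)
            last.inertia = np.diag(body.inertia)
            self.body_node[body.name] = len(self.nodes) - 1
        # merge an optional hand-load point mass into its carrying body
        if model.hand_load_mass > 0.0:
            idx = self.body_node[model.hand_load_body]
            node = self.nodes[idx]
            m1, m2 = node.mass, model.hand_load_mass
            p2 = np.asarray(model.hand_load_point, float)
            com = (m1 * node.com + m2 * p2) / (m1 + m2)
            inertia = node.inertia.copy()
            for m, p in ((m1, node.com), (m2, p2)):
                d = p - com
                inertia += m * (np.dot(d, d) * np.eye(3) - np.outer(d, d))
            node.mass = m1 + m2
            node.com = com
            node.inertia = inertia
        self.n_q = len(self.coord_names)
        n = len(self.nodes)
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i, nd in enumerate(self.nodes):
            if nd.parent >= 0:
                self.children[nd.parent].append(i)
        # ancestor masks: ancestors[b][j] True if unlocked coordinate j's node
        # is on the chain from ground to node b (inclusive)
        self.ancestors = np.zeros((n, self.n_q), dtype=bool)
        for i, nd in enumerate(self.nodes):
            if nd.parent >= 0:
                self.ancestors[i] = self.ancestors[nd.parent]
            if not nd.locked:
                self.ancestors[i, nd.coord_index] = True

    # -- kinematics -----------------------------------------------------

    def angles(self, q: np.ndarray) -> np.ndarray:
        th = np.empty(len(self.nodes))
        for i, nd in enumerate(self.nodes):
            th[i] = nd.lock_value if nd.locked else q[nd.coord_index]
        return th

    def fk(self, q: np.ndarray) -> tuple[list[np.ndarray], list[np.ndarray]]:
        """World rotation and origin of every elementary node."""
        th = self.angles(q)
        Rs: list[np.ndarray] = []
        os_: list[np.ndarray] = []
        for i, nd in enumerate(self.nodes):
            if nd.parent < 0:
                Rp, op = np.eye(3), np.zeros(3)
            else:
                Rp, op = Rs[nd.parent], os_[nd.parent]
            o = op + Rp @ nd.p0
            R = Rp @ _rot_axis(nd.axis, th[i])
            Rs.append(R)
            os_.append(o)
        return Rs, os_

    def accel_pass(
        self, q: np.ndarray, qd: np.ndarray, qdd: np.ndarray
    ) -> tuple[list, list, list, list, list, list]:
        """Propagate ω, α and COM accelerations down the tree (world frame)."""
        th = self.angles(q)
        Rs, os_, om, al, acom, ao = [], [], [], [], [], []
        for i, nd in enumerate(self.nodes):
            if nd.parent < 0:
                Rp, op = np.eye(3), np.zeros(3)
                wp = np.zeros(3)
                ap = np.zeros(3)
                aop = np.zeros(3)
            else:
                j = nd.parent
                Rp, op, wp, ap, aop = Rs[j], os_[j], om[j], al[j], ao[j]
            r = Rp @ nd.p0
            o = op + r
            a_o = aop + _cross3(ap, r) + _cross3(wp, _cross3(wp, r))
            axis_w = Rp @ nd.axis
            qdi = 0.0 if nd.locked else qd[nd.coord_index]
            qddi = 0.0 if nd.locked else qdd[nd.coord_index]
            w = wp + axis_w * qdi
            a = ap + axis_w * qddi + _cross3(wp, axis_w * qdi)
            R = Rp @ _rot_axis(nd.axis, th[i])
            c = R @ nd.com
            a_c = a_o + _cross3(a, c) + _cross3(w, _cross3(w, c))
            Rs.append(R)
            os_.append(o)
            om.append(w)
            al.append(a)
            ao.append(a_o)
            acom.append(a_c)
        return Rs, os_, om, al, ao, acom

    # -- inverse dynamics ----------------------------------------------

    def inverse_dynamics(
        self, q: np.ndarray, qd: np.ndarray, qdd: np.ndarray, gravity: np.ndarray
    ) -> np.ndarray:
        """Joint torques required to realize qdd (recursive Newton-Euler)."""
        Rs, os_, om, al, _ao, acom = self.accel_pass(q, qd, qdd)
        n = len(self.nodes)
        f = [np.zeros(3) for _ in range(n)]
        nmom = [np.zeros(3) for _ in range(n)]
        tau = np.zeros(self.n_q)
        children = self.children
        for i in range(n - 1, -1, -1):
            nd = self.nodes[i]
            Iw = Rs[i] @ nd.inertia @ Rs[i].T
            c = Rs[i] @ nd.com
            fi = nd.mass * (acom[i] - gravity)
            ni = Iw @ al[i] + _cross3(om[i], Iw @ om[i]) + _cross3(c, fi)
            for ch in children[i]:
                fi = fi + f[ch]
                ni = ni + nmom[ch] + _cross3(os_[ch] - os_[i], f[ch])
            f[i] = fi
            nmom[i] = ni
            if not nd.locked:
                Rp = np.eye(3) if nd.parent < 0 else Rs[nd.parent]
                tau[nd.coord_index] = (Rp @ nd.axis) @ ni
        return tau

    def mass_matrix(self, q: np.ndarray) -> np.ndarray:
        nq = self.n_q
        M = np.empty((nq, nq))
        zero = np.zeros(nq)
        for j in range(nq):
            e = np.zeros(nq)
            e[j] = 1.0
            M[:, j] = self.inverse_dynamics(q, zero, e, np.zeros(3))
        return 0.5 * (M + M.T)

    def mass_matrix_inverse(self, q: np.ndarray) -> np.ndarray:
        """Explicit M(q)^-1 via Cholesky; raises on non-SPD configurations.

        Forward dynamics and the per-frame linearizations both go through
        this same construction so the affine map A_acc @ [a;c] + baseline
        reproduces forward_dynamics to reassociation-level rounding rather
        than solve-path-dependent rounding.
        """
        M = self.mass_matrix(q)
        try:
            Linv = np.linalg.inv(np.linalg.cholesky(M))
        except np.linalg.LinAlgError as exc:
            raise ConfigurationError(
                "mass matrix is not positive definite (singular or near-gimbal-lock configuration)"
            ) from exc
        return Linv.T @ Linv


# ---------------------------------------------------------------------------
# the Model container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Model:
    """Musculoskeletal model: body tree, joints, muscles, reserves, glenoid."""

    bodies: tuple[BodySegment, ...]
    joints: tuple[JointSpec, ...]
    muscles: tuple[MuscleActuator, ...]
    reserves: tuple[ReserveActuator, ...]
    gravity: tuple[float, float, float] = (0.0, 0.0, -9.81)
    glenoid: GlenoidGeometry | None = None
    hand_load_mass: float = 0.0
    hand_load_body: str = ""
    hand_load_point: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_compiled", _Compiled(self))
        n_q = self.n_q
        res_map = {r.coordinate: r for r in self.reserves}
        missing = [c for c in self.coordinate_names if c not in res_map]
        if missing:
            raise ValueError(f"missing reserve actuators for coordinates {missing}")
        object.__setattr__(
            self,
            "_reserve_max",
            np.array([res_map[c].max_force for c in self.coordinate_names]),
        )

    # -- basic introspection -------------------------------------------

    @property
    def compiled(self) -> _Compiled:
        return self._compiled  # type: ignore[attr-defined]

    @property
    def coordinate_names(self) -> list[str]:
        return list(self.compiled.coord_names)

    @property
    def n_q(self) -> int:
        return self.compiled.n_q

    @property
    def n_m(self) -> int:
        return len(self.muscles)

    @property
    def muscle_names(self) -> list[str]:
        return [m.name for m in self.muscles]

    @property
    def actuator_names(self) -> list[str]:
        return self.muscle_names + [f"reserve_{c}" for c in self.coordinate_names]

    @property
    def reserve_max(self) -> np.ndarray:
        return self._reserve_max  # type: ignore[attr-defined]

    def with_locks(self, locks: dict[str, float]) -> "Model":
        """Return a copy with extra coordinates locked at given values (rad)."""
        new_joints = []
        remaining = dict(locks)
        for j in self.joints:
            extra = {c: remaining.pop(c) for c in list(remaining) if c in j.coordinate_names()}
            if extra:
                j = replace(j, locked={**j.locked, **extra})
            new_joints.append(j)
        if remaining:
            raise ValueError(f"unknown coordinates to lock: {sorted(remaining)}")
        reserves = tuple(r for r in self.reserves if r.coordinate not in locks)
        return replace(self, joints=tuple(new_joints), reserves=reserves)

    def neutral_state(self) -> ModelState:
        return ModelState(np.zeros(self.n_q), np.zeros(self.n_q))


# ---------------------------------------------------------------------------
# kinematics / muscle geometry
# ---------------------------------------------------------------------------


def forward_kinematics(model: Model, q: np.ndarray) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """World (rotation, origin) of every named body; ground is the identity."""
    Rs, os_ = model.compiled.fk(np.asarray(q, float))
    frames = {"ground": (np.eye(3), np.zeros(3))}
    for name, idx in model.compiled.body_node.items():
        if idx >= 0:
            frames[name] = (Rs[idx], os_[idx])
    return frames


def _path_points_world(
    model: Model, muscle: MuscleActuator, Rs: list[np.ndarray], os_: list[np.ndarray]
) -> np.ndarray:
    pts = np.empty((len(muscle.path), 3))
    for i, (body, local) in enumerate(muscle.path):
        idx = model.compiled.body_node[body]
        if idx < 0:
            pts[i] = np.asarray(local, float)
        else:
            pts[i] = os_[idx] + Rs[idx] @ np.asarray(local, float)
    return pts


def _all_lengths(model: Model, q: np.ndarray) -> np.ndarray:
    Rs, os_ = model.compiled.fk(q)
    out = np.empty(model.n_m)
    for i, m in enumerate(model.muscles):
        pts = _path_points_world(model, m, Rs, os_)
        out[i] = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    return out


def musculotendon_length(model: Model, q: np.ndarray, muscle: MuscleActuator) -> float:
    """Total via-point path length (m) at coordinates q."""
    Rs, os_ = model.compiled.fk(np.asarray(q, float))
    pts = _path_points_world(model, muscle, Rs, os_)
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def moment_arm_matrix(model: Model, q: np.ndarray) -> np.ndarray:
    """N_m x N_q moment arms r = -dL/dq by central finite differences."""
    q = np.asarray(q, float)
    R = np.empty((model.n_m, model.n_q))
    h = MOMENT_ARM_STEP
    for j in range(model.n_q):
        qp, qm = q.copy(), q.copy()
        qp[j] += h
        qm[j] -= h
        R[:, j] = -(_all_lengths(model, qp) - _all_lengths(model, qm)) / (2.0 * h)
    return R


def moment_arms(model: Model, q: np.ndarray, muscle: MuscleActuator) -> np.ndarray:
    """Moment arms (m) of one muscle about every unlocked coordinate."""
    i = model.muscle_names.index(muscle.name)
    return moment_arm_matrix(model, q)[i]


def _muscle_geometry(model: Model, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Analytic path lengths and Jacobian dL/dq of every muscle.

    For a via point P carried by body b, dP/dq_j = w_j x (P - o_j) when
    coordinate j's axis (world direction w_j, through o_j) is an ancestor of
    b, else zero; segment length derivatives follow by projecting onto the
    segment direction.  Agrees with the tendon-excursion finite difference
    (moment_arm_matrix) to discretization error; used on hot paths.
    """
    cm = model.compiled
    Rs, os_ = cm.fk(np.asarray(q, float))
    # world axis and origin per unlocked coordinate
    axes_w = np.zeros((cm.n_q, 3))
    origins = np.zeros((cm.n_q, 3))
    for i, nd in enumerate(cm.nodes):
        if not nd.locked:
            axes_w[nd.coord_index] = Rs[i] @ nd.axis
            origins[nd.coord_index] = os_[i]
    lengths = np.zeros(model.n_m)
    dLdq = np.zeros((model.n_m, cm.n_q))
    for mi, m in enumerate(model.muscles):
        pts = _path_points_world(model, m, Rs, os_)
        node_idx = [cm.body_node[b] for b, _ in m.path]
        # dP/dq for each via point: (n_pts, n_q, 3)
        jac = np.zeros((len(pts), cm.n_q, 3))
        for p, bi in enumerate(node_idx):
            if bi < 0:
                continue
            mask = cm.ancestors[bi]
            if mask.any():
                jac[p, mask] = np.cross(axes_w[mask], pts[p] - origins[mask])
        for s in range(len(pts) - 1):
            seg = pts[s + 1] - pts[s]
            norm = float(np.linalg.norm(seg))
            lengths[mi] += norm
            if norm > 0:
                dLdq[mi] += (jac[s + 1] - jac[s]) @ (seg / norm)
    return lengths, dLdq


def muscle_kinematics(model: Model, state: ModelState) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(lengths, speeds, moment-arm matrix) of all muscles at a state.

    Moment arms are the analytic tendon-excursion derivatives r = -dL/dq;
    lengthening speed follows from the excursion identity
    v_mt = dL/dt = -sum_j r_j q̇_j.
    """
    lengths, dLdq = _muscle_geometry(model, state.q)
    R = -dLdq
    speeds = -(R @ state.qdot)
    return lengths, speeds, R


def _muscle_gains(model: Model, lengths: np.ndarray, speeds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    gains = np.empty(model.n_m)
    passives = np.empty(model.n_m)
    for i, m in enumerate(model.muscles):
        gains[i], passives[i] = force_decomposition(
            m.parameters, lengths[i], speeds[i], name=m.name
        )
    return gains, passives


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------


def _generalized_forces(
    model: Model,
    R: np.ndarray,
    gains: np.ndarray,
    passives: np.ndarray,
    activations: np.ndarray,
    controls: np.ndarray,
) -> np.ndarray:
    tensions = gains * activations + passives
    return R.T @ tensions + model.reserve_max * controls


def forward_dynamics(
    model: Model,
    state: ModelState,
    activations: np.ndarray,
    controls: np.ndarray,
) -> np.ndarray:
    """Coordinate accelerations q̈ from M(q) q̈ = τ_muscle + τ_reserve - bias."""
    activations = np.asarray(activations, float)
    controls = np.asarray(controls, float)
    lengths, speeds, R = muscle_kinematics(model, state)
    gains, passives = _muscle_gains(model, lengths, speeds)
    tau = _generalized_forces(model, R, gains, passives, activations, controls)
    cm = model.compiled
    bias = cm.inverse_dynamics(state.q, state.qdot, np.zeros(model.n_q), np.asarray(model.gravity))
    return cm.mass_matrix_inverse(state.q) @ (tau - bias)


def _subtree_nodes(model: Model, joint_name: str) -> tuple[list[int], str]:
    """Elementary nodes distal to the named joint, plus the parent body name."""
    joint = next((j for j in model.joints if j.name == joint_name), None)
    if joint is None:
        raise KeyError(f"unknown joint {joint_name!r}")
    cm = model.compiled
    child_idx = cm.body_node[joint.child]
    n_elem = 1 if joint.joint_type == "pin" else 3
    first = child_idx - n_elem + 1
    members = set(range(first, child_idx + 1))
    # descend: any node whose parent is in the set
    for i in range(child_idx + 1, len(cm.nodes)):
        if cm.nodes[i].parent in members:
            members.add(i)
    return sorted(members), joint.parent


def _crossing_unit_forces(
    model: Model, Rs: list, os_: list, members: set[int]
) -> np.ndarray:
    """Per-muscle world force on the subtree per unit tendon tension."""
    out = np.zeros((model.n_m, 3))
    for mi, m in enumerate(model.muscles):
        pts = _path_points_world(model, m, Rs, os_)
        inside = [model.compiled.body_node[b] in members for b, _ in m.path]
        for s in range(len(pts) - 1):
            if inside[s] == inside[s + 1]:
                continue
            a, b = (s, s + 1) if inside[s] else (s + 1, s)
            seg = pts[b] - pts[a]
            norm = np.linalg.norm(seg)
            if norm < 1e-12:
                raise ConfigurationError(f"muscle {m.name}: zero-length path segment")
            out[mi] += seg / norm
    return out


def joint_reaction_oracle(
    model: Model,
    state: ModelState,
    qddot: np.ndarray,
    activations: np.ndarray,
    controls: np.ndarray,
    joint_name: str,
) -> np.ndarray:
    """3-vector force (N) transmitted to the distal subtree at a joint,
    expressed in the joint's parent body frame.

    Newton balance of the subtree: F = Σ m_i (a_com,i − g) − F_muscle, where
    F_muscle sums the via-point forces that muscles crossing the cut apply to
    subtree bodies.  Reserve controls apply pure torques and do not enter the
    force balance.
    """
    del controls  # torque-only actuators: no force contribution
    activations = np.asarray(activations, float)
    members_list, parent_body = _subtree_nodes(model, joint_name)
    members = set(members_list)
    cm = model.compiled
    Rs, os_, _om, _al, _ao, acom = cm.accel_pass(state.q, state.qdot, np.asarray(qddot, float))
    g = np.asarray(model.gravity)
    F = np.zeros(3)
    for i in members_list:
        nd = cm.nodes[i]
        if nd.mass > 0.0:
            F += nd.mass * (acom[i] - g)
    lengths, speeds, _R = muscle_kinematics(model, state)
    gains, passives = _muscle_gains(model, lengths, speeds)
    tensions = gains * activations + passives
    unit_forces = _crossing_unit_forces(model, Rs, os_, members)
    F -= unit_forces.T @ tensions
    p_idx = cm.body_node[parent_body]
    R_parent = np.eye(3) if p_idx < 0 else Rs[p_idx]
    return R_parent.T @ F


# ---------------------------------------------------------------------------
# per-frame linearizations
# ---------------------------------------------------------------------------


def linearize_accelerations(
    model: Model, state: ModelState, qddot_experimental: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact affine map of q̈ in [a; c]: returns (A_acc, q_tilde_ddot, baseline).

    The baseline is the passive acceleration (all actuators off: gravity,
    velocity effects and passive muscle forces); column i of A_acc is the
    acceleration a unit activation/control of actuator i adds to it.
    Because tendon force is affine in activation and M(q)⁻¹ is linear in the
    applied generalized force, the map is exact, not a first-order expansion.
    """
    qdd_exp = np.asarray(qddot_experimental, float)
    lengths, speeds, R = muscle_kinematics(model, state)
    gains, passives = _muscle_gains(model, lengths, speeds)
    cm = model.compiled
    g = np.asarray(model.gravity)
    bias = cm.inverse_dynamics(state.q, state.qdot, np.zeros(model.n_q), g)
    Minv = cm.mass_matrix_inverse(state.q)
    baseline = Minv @ (R.T @ passives - bias)
    n_m, n_q = model.n_m, model.n_q
    A = np.empty((n_q, n_m + n_q))
    A[:, :n_m] = Minv @ (R.T * gains[None, :])
    A[:, n_m:] = Minv * model.reserve_max[None, :]
    return A, qdd_exp - baseline, baseline


def linearize_jrf(
    model: Model,
    state: ModelState,
    qddot_experimental: np.ndarray,
    joint_name: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact affine map F = A_F @ [a; c] + F0 of the joint reaction force.

    Subtree inertial terms are evaluated at the experimental q̈ (the equality
    constraint makes the solved and experimental accelerations coincide, so
    fixing them preserves exact affinity).  F0 lumps gravity, inertia and
    passive muscle force; reserve columns are zero (pure torques).
    Expressed in the joint's parent body frame.
    """
    members_list, parent_body = _subtree_nodes(model, joint_name)
    members = set(members_list)
    cm = model.compiled
    Rs, os_, _om, _al, _ao, acom = cm.accel_pass(
        state.q, state.qdot, np.asarray(qddot_experimental, float)
    )
    g = np.asarray(model.gravity)
    W = np.zeros(3)
    for i in members_list:
        nd = cm.nodes[i]
        if nd.mass > 0.0:
            W += nd.mass * (acom[i] - g)
    lengths, speeds, _R = muscle_kinematics(model, state)
    gains, passives = _muscle_gains(model, lengths, speeds)
    unit_forces = _crossing_unit_forces(model, Rs, os_, members)  # N_m x 3
    p_idx = cm.body_node[parent_body]
    R_parent = np.eye(3) if p_idx < 0 else Rs[p_idx]
    F0 = R_parent.T @ (W - unit_forces.T @ passives)
    n_m, n_q = model.n_m, model.n_q
    A_F = np.zeros((3, n_m + n_q))
    A_F[:, :n_m] = R_parent.T @ (-(unit_forces * gains[:, None]).T)
    return A_F, F0


# ---------------------------------------------------------------------------
# model file I/O (versioned JSON)
# ---------------------------------------------------------------------------


def _model_to_dict(model: Model) -> dict:
    d: dict = {
        "schema": MODEL_SCHEMA,
        "gravity": list(model.gravity),
        "bodies": [
            {
                "name": b.name,
                "mass": b.mass,
                "inertia": list(b.inertia),
                "com": list(b.com),
                "length": b.length,
            }
            for b in model.bodies
        ],
        "joints": [
            {
                "name": j.name,
                "type": j.joint_type,
                "parent": j.parent,
                "child": j.child,
                "translation": list(j.translation),
                "axis": list(j.axis),
                "locked": dict(j.locked),
            }
            for j in model.joints
        ],
        "muscles": [
            {
                "name": m.name,
                "group": m.group,
                "parameters": {
                    "f_iso_max": m.parameters.f_iso_max,
                    "l_opt": m.parameters.l_opt,
                    "l_tendon_slack": m.parameters.l_tendon_slack,
                    "v_max": m.parameters.v_max,
                    "alpha_opt": m.parameters.alpha_opt,
                },
                "path": [[body, list(point)] for body, point in m.path],
            }
            for m in model.muscles
        ],
        "reserves": [
            {"coordinate": r.coordinate, "max_force": r.max_force} for r in model.reserves
        ],
    }
    if model.glenoid is not None:
        d["glenoid"] = {
            "joint": model.glenoid.joint,
            "direction": list(model.glenoid.direction),
            "theta_max": model.glenoid.theta_max,
        }
    if model.hand_load_mass > 0:
        d["hand_load"] = {
            "mass": model.hand_load_mass,
            "body": model.hand_load_body,
            "point": list(model.hand_load_point),
        }
    return d


def _model_from_dict(d: dict) -> Model:
    if d.get("schema") != MODEL_SCHEMA:
        raise ValueError(f"unsupported model schema {d.get('schema')!r}")
    bodies = tuple(
        BodySegment(
            name=b["name"],
            mass=b["mass"],
            inertia=tuple(b["inertia"]),
            com=tuple(b["com"]),
            length=b.get("length", 0.0),
        )
        for b in d["bodies"]
    )
    joints = tuple(
        JointSpec(
            name=j["name"],
            joint_type=j["type"],
            parent=j["parent"],
            child=j["child"],
            translation=tuple(j["translation"]),
            axis=tuple(j.get("axis", (0.0, 0.0, 1.0))),
            locked=dict(j.get("locked", {})),
        )
        for j in d["joints"]
    )
    muscles = tuple(
        MuscleActuator(
            name=m["name"],
            parameters=MuscleParameters(**m["parameters"]),
            path=tuple((body, tuple(point)) for body, point in m["path"]),
            group=m.get("group", "other"),
        )
        for m in d["muscles"]
    )
    reserves = tuple(
        ReserveActuator(coordinate=r["coordinate"], max_force=r["max_force"])
        for r in d["reserves"]
    )
    glenoid = None
    if "glenoid" in d:
        glenoid = GlenoidGeometry(
            joint=d["glenoid"]["joint"],
            direction=tuple(d["glenoid"]["direction"]),
            theta_max=d["glenoid"]["theta_max"],
        )
    load = d.get("hand_load", {})
    return Model(
        bodies=bodies,
        joints=joints,
        muscles=muscles,
        reserves=reserves,
        gravity=tuple(d["gravity"]),
        glenoid=glenoid,
        hand_load_mass=load.get("mass", 0.0),
        hand_load_body=load.get("body", ""),
        hand_load_point=tuple(load.get("point", (0.0, 0.0, 0.0))),
    )


def save_model(model: Model, path) -> None:
    with open(path, "w") as fh:
        json.dump(_model_to_dict(model), fh, indent=1)
        fh.write("\n")


def load_model(path) -> Model:
    with open(path) as fh:
        return _model_from_dict(json.load(fh))
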