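"""The rapid muscle-redundancy solver.

Per input frame, a small nonlinear program chooses muscle activations a in
[0,1]^N_m and reserve controls c in [-1,1]^N_q that

    minimize      sum_i w a_i^2  +  sum_j v c_j^2
    subject to    A_acc [a; c] = q̈_exp - baseline        (track accelerations)
                  l_k <= a <= u_k                        (activation dynamics)
                  (theta/theta_max)^2 - 1 <= 0           (optional GH cone)

where A_acc and the joint-reaction affine map F = A_F [a; c] + F0 come from
the multibody linearization at the frame's kinematic state.  The activation
bounds integrate first-order activation dynamics between frames, so the
static per-frame problems are coupled into physiologically rate-limited
trajectories.  Reserve controls are weighted v/w = 10 times more heavily
than activations, so reserves act as a feasibility safety net whose usage
measures model/data inconsistency.

Frames are solved sequentially with warm starts from the previous solution
(scipy SLSQP).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .multibody import (
    FrameLinearization,
    GlenoidGeometry,
    Model,
    ModelState,
    _muscle_gains,
    linearize_accelerations,
    linearize_jrf,
    muscle_kinematics,
)
from .preprocessing import TrajectoryTable

__all__ = [
    "SolverSettings",
    "FrameProblem",
    "FrameResult",
    "SolveResult",
    "InfeasibleFrameError",
    "cost",
    "cost_gradient",
    "activation_bounds",
    "gh_constraint_value",
    "assemble_frame_problem",
    "solve_frame",
    "solve_motion",
]

ZERO_FORCE_NORM = 1e-6  # N; below this the JRF direction is treated as stable
GH_CONE_MARGIN = 1e-6  # scaled force units; see _gh_fun_and_grad
GH_SMOOTH_EPS = 0.1  # N; norm smoothing of the cone constraint


class InfeasibleFrameError(RuntimeError):
    """A frame's NLP could not be solved to feasibility."""


@dataclass(frozen=True)
class SolverSettings:
    """Weights, physiological constants and tolerances of the solver.

    Defaults follow the published formulation: muscle weight 1, reserve
    weight 10, activation/deactivation time constants 10/40 ms, stability
    cone half-angle 20 deg.
    """

    w: float = 1.0
    v: float = 10.0
    tau_act: float = 0.010
    tau_deact: float = 0.040
    theta_max: float = math.radians(20.0)
    enforce_gh: bool = False
    constraint_tol: float = 1e-8
    optimality_tol: float = 1e-6
    max_iterations: int = 300
    first_guess: float = 0.1

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.v > 0):
            raise ValueError("weights must be positive")
        if not 0 < self.tau_act <= self.tau_deact:
            raise ValueError("need 0 < tau_act <= tau_deact")
        if not 0 < self.theta_max < math.pi / 2:
            raise ValueError("theta_max must be in (0, pi/2)")


@dataclass(frozen=True)
class FrameProblem:
    linearization: FrameLinearization
    lower: np.ndarray  # per-muscle activation lower bounds
    upper: np.ndarray
    settings: SolverSettings
    glenoid: GlenoidGeometry | None  # reporting geometry (theta_max from settings)
    enforce_gh: bool
    t: float
    n_m: int
    n_q: int


@dataclass(frozen=True)
class FrameResult:
    t: float
    a: np.ndarray
    c: np.ndarray
    jrf: np.ndarray | None
    theta: float | None
    objective: float
    converged: bool
    iterations: int
    message: str = ""


@dataclass
class SolveResult:
    """Stacked per-frame solutions of one motion."""

    frames: list[FrameResult]
    coordinate_names: list[str]
    muscle_names: list[str]
    settings: SolverSettings
    reserve_share: np.ndarray  # per coordinate, fraction of |generalized force|
    meta: dict = field(default_factory=dict)

    @property
    def time(self) -> np.ndarray:
        return np.array([f.t for f in self.frames])

    @property
    def activations(self) -> np.ndarray:
        """frames x N_m activation matrix."""
        return np.array([f.a for f in self.frames])

    @property
    def controls(self) -> np.ndarray:
        return np.array([f.c for f in self.frames])

    @property
    def theta_series(self) -> np.ndarray:
        return np.array([np.nan if f.theta is None else f.theta for f in self.frames])

    @property
    def jrf_series(self) -> np.ndarray:
        return np.array(
            [np.full(3, np.nan) if f.jrf is None else f.jrf for f in self.frames]
        )

    @property
    def all_converged(self) -> bool:
        return all(f.converged for f in self.frames)

    def activation_table(self) -> TrajectoryTable:
        cols = {n: self.activations[:, i] for i, n in enumerate(self.muscle_names)}
        return TrajectoryTable(self.time, cols, kind="activations", name="activations")

    def control_table(self) -> TrajectoryTable:
        cols = {n: self.controls[:, i] for i, n in enumerate(self.coordinate_names)}
        return TrajectoryTable(self.time, cols, kind="controls", name="controls")

    def jrf_table(self) -> TrajectoryTable:
        jrf = self.jrf_series
        cols = {
            "jrf_x": jrf[:, 0],
            "jrf_y": jrf[:, 1],
            "jrf_z": jrf[:, 2],
            "theta_deg": np.degrees(self.theta_series),
        }
        return TrajectoryTable(self.time, cols, kind="jrf", name="jrf")


# ---------------------------------------------------------------------------
# NLP pieces
# ---------------------------------------------------------------------------


def cost(a: np.ndarray, c: np.ndarray, w: float = 1.0, v: float = 10.0) -> float:
    """Weighted sum of squared activations and controls (strictly convex)."""
    a = np.asarray(a, float)
    c = np.asarray(c, float)
    return float(w * np.dot(a, a) + v * np.dot(c, c))


def cost_gradient(x: np.ndarray, n_m: int, w: float, v: float) -> np.ndarray:
    g = np.empty_like(x)
    g[:n_m] = 2.0 * w * x[:n_m]
    g[n_m:] = 2.0 * v * x[n_m:]
    return g


def activation_bounds(
    a_prev: np.ndarray, dt: float, tau_act: float = 0.010, tau_deact: float = 0.040
) -> tuple[np.ndarray, np.ndarray]:
    """Box bounds on the next activation from first-order activation dynamics.

    Explicit-Euler integration of the calcium-dynamics model with the
    excitation pinned at its extremes: the effective time constant is
    tau_act*(1/2 + 3/2 a) when activating and tau_deact/(1/2 + 3/2 a) when
    deactivating.  Bounds are clipped to [0, 1] and always bracket a_prev.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    a_prev = np.asarray(a_prev, float)
    if np.any((a_prev < 0) | (a_prev > 1)):
        raise ValueError("previous activations must lie in [0, 1]")
    shape = 0.5 + 1.5 * a_prev
    lower = a_prev - a_prev * shape * (dt / tau_deact)
    upper = a_prev + (1.0 - a_prev) * dt / (shape * tau_act)
    return np.clip(lower, 0.0, 1.0), np.clip(upper, 0.0, 1.0)


def _theta_from_force(F: np.ndarray, direction: np.ndarray) -> float:
    norm = np.linalg.norm(F)
    if norm < ZERO_FORCE_NORM:
        return 0.0
    cosang = float(np.clip(np.dot(F, direction) / norm, -1.0, 1.0))
    return math.acos(cosang)


def gh_constraint_value(
    A_F: np.ndarray,
    F0: np.ndarray,
    a: np.ndarray,
    c: np.ndarray,
    glenoid: GlenoidGeometry,
) -> float:
    """(theta/theta_max)^2 - 1 of the reaction force at [a; c]; <= 0 is stable.

    Zero force is defined stable (returns -1).
    """
    x = np.concatenate([np.asarray(a, float), np.asarray(c, float)])
    F = A_F @ x + F0
    if np.linalg.norm(F) < ZERO_FORCE_NORM:
        return -1.0
    theta = _theta_from_force(F, np.asarray(glenoid.direction))
    return (theta / glenoid.theta_max) ** 2 - 1.0


def _gh_fun_and_grad(A_F: np.ndarray, F0: np.ndarray, glenoid: GlenoidGeometry):
    """Inequality handed to SLSQP: the stability cone in second-order-cone form.

    theta <= theta_max is equivalent (for theta_max < pi/2) to

        g(x) = F . d - cos(theta_max) ||F|| >= 0,

    which is concave in F (hence defines the same convex feasible set as the
    (theta/theta_max)^2 - 1 form) and smooth everywhere except F = 0, where
    both forms declare stability.  The angle form uses arccos, whose
    curvature explodes near the axis and near anti-alignment and stalls the
    SQP line search; the cone form has bounded derivatives and identical
    solutions.  Scaled by a force magnitude so tolerances are units-robust.

    Two regularizations keep the SQP iteration honest without changing the
    physics: the norm is smoothed to sqrt(||F||^2 + eps^2) with eps = 0.1 N,
    which makes the constraint differentiable at F = 0 and keeps any
    feasible reaction force above ~eps/tan(theta_max) in magnitude (a
    minimum-effort solution otherwise parks F at the cone apex, where its
    direction — hence theta — is numerical noise); and a small absolute
    margin is subtracted so the returned iterate sits strictly inside the
    true cone by far more than the SQP's own constraint residual.  Both are
    orders of magnitude below physiological force resolution.
    """
    d = np.asarray(glenoid.direction, float)
    cos_max = math.cos(glenoid.theta_max)
    scale = max(1.0, float(np.linalg.norm(F0)))
    eps2 = GH_SMOOTH_EPS**2

    def fun(x: np.ndarray) -> float:
        F = A_F @ x + F0
        n_s = math.sqrt(float(F @ F) + eps2)
        return (float(np.dot(F, d)) - cos_max * n_s) / scale - GH_CONE_MARGIN

    def grad(x: np.ndarray) -> np.ndarray:
        F = A_F @ x + F0
        n_s = math.sqrt(float(F @ F) + eps2)
        return A_F.T @ (d - cos_max * F / n_s) / scale

    return fun, grad


def assemble_frame_problem(
    model: Model,
    state: ModelState,
    qddot_experimental: np.ndarray,
    a_prev: np.ndarray | None,
    settings: SolverSettings,
    t: float = 0.0,
    dt: float | None = None,
) -> FrameProblem:
    """Linearize the dynamics at the frame state and collect bounds.

    First frame (a_prev None): bounds are the full [0, 1] box.  The GH
    linearization is carried whenever the model has glenoid geometry so the
    reaction force can be reported even when the cone is not enforced.
    """
    A_acc, q_tilde, baseline = linearize_accelerations(model, state, qddot_experimental)
    A_F = F0 = None
    if model.glenoid is not None:
        A_F, F0 = linearize_jrf(model, state, qddot_experimental, model.glenoid.joint)
    lin = FrameLinearization(
        A_acc=A_acc, q_tilde_ddot=q_tilde, baseline_qddot=baseline, A_F=A_F, F0=F0
    )
    n_m = model.n_m
    if a_prev is None:
        lower = np.zeros(n_m)
        upper = np.ones(n_m)
    else:
        if dt is None or dt <= 0:
            raise ValueError("dt is required when a_prev is given")
        lower, upper = activation_bounds(a_prev, dt, settings.tau_act, settings.tau_deact)
    if settings.enforce_gh and model.glenoid is None:
        raise ValueError("enforce_gh requested but the model has no glenoid geometry")
    glenoid = None
    if model.glenoid is not None:
        glenoid = replace(model.glenoid, theta_max=settings.theta_max)
    return FrameProblem(
        linearization=lin,
        lower=lower,
        upper=upper,
        settings=settings,
        glenoid=glenoid,
        enforce_gh=settings.enforce_gh,
        t=t,
        n_m=n_m,
        n_q=model.n_q,
    )


def solve_frame(problem: FrameProblem, initial_guess: np.ndarray | None = None) -> FrameResult:
    """Solve one frame's NLP with SLSQP.

    The equality rows are scaled by max(1, per-row magnitude of A_acc) so the
    stopping tolerance is units-robust.  Returns a flagged (non-converged)
    FrameResult rather than raising when SLSQP reports failure but the
    iterate is usable; raises InfeasibleFrameError when the returned iterate
    violates the constraints grossly.
    """
    st = problem.settings
    lin = problem.linearization
    n_m, n_q = problem.n_m, problem.n_q
    n_x = n_m + n_q
    if initial_guess is None:
        x0 = np.concatenate([np.full(n_m, st.first_guess), np.zeros(n_q)])
    else:
        x0 = np.asarray(initial_guess, float).copy()
    lower = np.concatenate([problem.lower, -np.ones(n_q)])
    upper = np.concatenate([problem.upper, np.ones(n_q)])
    x0 = np.clip(x0, lower, upper)

    row_scale = np.maximum(1.0, np.max(np.abs(lin.A_acc), axis=1))
    A_eq = lin.A_acc / row_scale[:, None]
    b_eq = lin.q_tilde_ddot / row_scale

    def obj(x: np.ndarray) -> float:
        return cost(x[:n_m], x[n_m:], st.w, st.v)

    def obj_grad(x: np.ndarray) -> np.ndarray:
        return cost_gradient(x, n_m, st.w, st.v)

    constraints = [
        {
            "type": "eq",
            "fun": lambda x: A_eq @ x - b_eq,
            "jac": lambda x: A_eq,
        }
    ]
    if problem.enforce_gh:
        if lin.A_F is None or lin.F0 is None or problem.glenoid is None:
            raise ValueError("GH constraint requested without a JRF linearization")
        fun, grad = _gh_fun_and_grad(lin.A_F, lin.F0, problem.glenoid)
        constraints.append({"type": "ineq", "fun": fun, "jac": grad})

    def attempt(x_start: np.ndarray, maxiter: int):
        return optimize.minimize(
            obj,
            x_start,
            jac=obj_grad,
            bounds=list(zip(lower, upper)),
            constraints=constraints,
            method="SLSQP",
            options={"maxiter": maxiter, "ftol": 1e-10},
        )

    def feasible(x: np.ndarray) -> bool:
        if np.max(np.abs(A_eq @ x - b_eq)) > 10.0 * st.constraint_tol:
            return False
        if problem.enforce_gh:
            g = gh_constraint_value(
                lin.A_F, lin.F0, x[:n_m], x[n_m:], problem.glenoid
            )
            if g > 10.0 * st.constraint_tol:
                return False
        return True

    res = attempt(x0, st.max_iterations)
    if not (res.success and feasible(np.clip(res.x, lower, upper))):
        # retry from the cold start; warm starts occasionally stall the
        # line search when the active set flips between frames
        x_cold = np.clip(
            np.concatenate([np.full(n_m, st.first_guess), np.zeros(n_q)]), lower, upper
        )
        res2 = attempt(x_cold, 2 * st.max_iterations)
        better = res2.success and feasible(np.clip(res2.x, lower, upper))
        if better and not (res.success and feasible(np.clip(res.x, lower, upper))):
            res = res2
        elif better and res2.fun < res.fun:
            res = res2
    x = np.clip(res.x, lower, upper)
    eq_resid = float(np.max(np.abs(A_eq @ x - b_eq))) if n_q else 0.0
    gh_violation = 0.0
    theta = None
    jrf = None
    if lin.A_F is not None and lin.F0 is not None:
        F = lin.A_F @ x + lin.F0
        jrf = F
        if problem.glenoid is not None:
            theta = _theta_from_force(F, np.asarray(problem.glenoid.direction))
            if problem.enforce_gh:
                gh_violation = max(0.0, (theta / problem.glenoid.theta_max) ** 2 - 1.0)
    converged = bool(res.success) and eq_resid <= 10.0 * st.constraint_tol and (
        gh_violation <= 10.0 * st.constraint_tol
    )
    if eq_resid > 1e-3:
        raise InfeasibleFrameError(
            f"frame t={problem.t:.4f}: equality residual {eq_resid:.3g} "
            f"(solver message: {res.message})"
        )
    return FrameResult(
        t=problem.t,
        a=x[:n_m],
        c=x[n_m:],
        jrf=jrf,
        theta=theta,
        objective=float(res.fun),
        converged=converged,
        iterations=int(res.get("nit", 0)),
        message=str(res.message),
    )


def solve_motion(
    model: Model,
    angles: TrajectoryTable,
    speeds: TrajectoryTable,
    accelerations: TrajectoryTable,
    settings: SolverSettings | None = None,
    keep_going: bool = False,
) -> SolveResult:
    """Run the per-frame solver over aligned angle/speed/acceleration tables.

    Frame k takes its activation-rate bounds from frame k-1's solution and
    warm-starts SLSQP there.  Deterministic given inputs and settings.
    """
    settings = settings or SolverSettings()
    if not (
        np.array_equal(angles.time, speeds.time)
        and np.array_equal(angles.time, accelerations.time)
    ):
        raise ValueError("angle, speed and acceleration tables must share one time grid")
    coords = model.coordinate_names
    for tbl, kind in ((angles, "angles"), (speeds, "speeds"), (accelerations, "accelerations")):
        missing = [c for c in coords if c not in tbl.columns]
        if missing:
            raise ValueError(f"{kind} table lacks coordinates {missing}")
    Q = angles.as_matrix(coords)
    Qd = speeds.as_matrix(coords)
    Qdd = accelerations.as_matrix(coords)
    time = angles.time
    frames: list[FrameResult] = []
    a_prev: np.ndarray | None = None
    x_warm: np.ndarray | None = None
    # accumulated |generalized force| per coordinate for the reserve share
    musc_abs = np.zeros(model.n_q)
    res_abs = np.zeros(model.n_q)
    for k in range(time.size):
        state = ModelState(Q[k], Qd[k])
        dt = None if k == 0 else float(time[k] - time[k - 1])
        problem = assemble_frame_problem(
            model, state, Qdd[k], a_prev, settings, t=float(time[k]), dt=dt
        )
        try:
            fr = solve_frame(problem, x_warm)
        except InfeasibleFrameError:
            if not keep_going:
                raise
            fr = FrameResult(
                t=float(time[k]),
                a=a_prev if a_prev is not None else np.zeros(model.n_m),
                c=np.zeros(model.n_q),
                jrf=None,
                theta=None,
                objective=math.nan,
                converged=False,
                iterations=0,
                message="infeasible frame (kept)",
            )
        frames.append(fr)
        a_prev = fr.a
        x_warm = np.concatenate([fr.a, fr.c])
        lengths, spds, Rma = muscle_kinematics(model, state)
        gains, passives = _muscle_gains(model, lengths, spds)
        tensions = gains * fr.a + passives
        musc_abs += np.abs(Rma * tensions[:, None]).sum(axis=0)
        res_abs += np.abs(model.reserve_max * fr.c)
    total = musc_abs + res_abs
    share = np.divide(res_abs, total, out=np.zeros_like(total), where=total > 0)
    return SolveResult(
        frames=frames,
        coordinate_names=coords,
        muscle_names=model.muscle_names,
        settings=settings,
        reserve_share=share,
        meta={"n_frames": len(frames)},
    )
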