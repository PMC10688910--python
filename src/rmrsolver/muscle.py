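"""Hill-type muscle mechanics with a rigid tendon.

The actuator model is the standard Hill arrangement: an active contractile
element in parallel with a passive elastic element, both inside a fiber that
sits at a pennation angle to a tendon of fixed length (rigid-tendon
assumption).  Because the tendon is rigid, the fiber kinematics follow
directly from the musculotendon length and speed, and the tendon force is
*affine* in the activation:

    F_tendon(a) = active_gain * a + passive_force

with ``active_gain = F_iso_max * fL(l~) * fV(v~) * cos(alpha)`` and
``passive_force = F_iso_max * fPE(l~) * cos(alpha)``.  That affinity is what
lets a per-frame redundancy solver express joint accelerations and joint
reaction forces as linear functions of the activations.

Curve shapes (Gaussian active force-length, exponential passive
force-length, hyperbolic/saturating force-velocity) are the conventional
smooth parameterizations; the solver's correctness does not depend on the
exact shape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "MuscleParameters",
    "MuscleState",
    "DegenerateFiberError",
    "fiber_geometry",
    "active_force_length",
    "passive_force_length",
    "force_velocity",
    "force_decomposition",
    "tendon_force",
]

# Curve constants (dimensionless).  gamma: width of the Gaussian active
# force-length curve; KPE/EPS0: shape/strain scale of the passive exponential
# (passive multiplier reaches 1 at 60% fiber strain); FV_ECC_MAX: eccentric
# force plateau.
GAMMA = 0.45
KPE = 4.0
EPS0 = 0.6
FV_ECC_MAX = 1.4


class DegenerateFiberError(ValueError):
    """Raised when the musculotendon is shorter than the rigid tendon."""


@dataclass(frozen=True)
class MuscleParameters:
    """Constant architectural parameters of one musculotendon actuator.

    Parameters
    ----------
    f_iso_max : float
        Maximal isometric fiber force, N.
    l_opt : float
        Optimal fiber length, m.
    l_tendon_slack : float
        Tendon slack length, m; the tendon is rigid so this is the fixed
        tendon length.
    v_max : float
        Maximal shortening velocity, optimal fiber lengths per second.
    alpha_opt : float
        Pennation angle at optimal fiber length, rad.
    """

    f_iso_max: float
    l_opt: float
    l_tendon_slack: float = 0.0
    v_max: float = 10.0
    alpha_opt: float = 0.0

    def __post_init__(self) -> None:
        if not self.f_iso_max > 0:
            raise ValueError("f_iso_max must be positive")
        if not self.l_opt > 0:
            raise ValueError("l_opt must be positive")
        if self.l_tendon_slack < 0:
            raise ValueError("l_tendon_slack must be non-negative")
        if not self.v_max > 0:
            raise ValueError("v_max must be positive")
        if not 0.0 <= self.alpha_opt < math.pi / 2:
            raise ValueError("alpha_opt must be in [0, pi/2)")


@dataclass(frozen=True)
class MuscleState:
    """Instantaneous kinematic + activation state of a muscle.

    l_mt (m) and v_mt (m/s, positive = lengthening) are set by the skeleton
    state; activation a in [0, 1] is the optimization variable.
    """

    l_mt: float
    v_mt: float = 0.0
    a: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.a <= 1.0:
            raise ValueError("activation must be in [0, 1]")


def fiber_geometry(
    params: MuscleParameters, l_mt: float, name: str = "muscle"
) -> tuple[float, float]:
    """Normalized fiber length and pennation cosine at musculotendon length l_mt.

    Uses the constant-thickness pennation model: the fiber height
    ``l_opt * sin(alpha_opt)`` is invariant, so

        l_fiber = sqrt((l_mt - l_ts)^2 + (l_opt sin(alpha_opt))^2).

    Returns ``(l_fiber / l_opt, cos(alpha))``.
    """
    span = l_mt - params.l_tendon_slack
    if span <= 0:
        raise DegenerateFiberError(
            f"{name}: musculotendon length {l_mt:.6g} m does not exceed the "
            f"rigid tendon length {params.l_tendon_slack:.6g} m"
        )
    height = params.l_opt * math.sin(params.alpha_opt)
    l_fiber = math.hypot(span, height)
    return l_fiber / params.l_opt, span / l_fiber


def active_force_length(l_fiber_norm: float) -> float:
    """Active force-length multiplier: Gaussian peaked at optimal length."""
    if not l_fiber_norm > 0:
        raise ValueError("normalized fiber length must be positive")
    d = l_fiber_norm - 1.0
    return math.exp(-d * d / GAMMA)


def passive_force_length(l_fiber_norm: float) -> float:
    """Passive force-length multiplier: zero at/below optimum, exponential above.

    Normalized so the multiplier is exactly 1 at fiber strain EPS0.
    """
    if not l_fiber_norm > 0:
        raise ValueError("normalized fiber length must be positive")
    if l_fiber_norm <= 1.0:
        return 0.0
    return math.expm1(KPE * (l_fiber_norm - 1.0) / EPS0) / math.expm1(KPE)


def force_velocity(v_fiber_norm: float) -> float:
    """Force-velocity multiplier of normalized fiber velocity v/(v_max l_opt).

    Hyperbolic (Hill) shortening branch with f(-1) = 0 and f(0) = 1, and a
    saturating lengthening branch capped at FV_ECC_MAX; continuous with a
    matched slope at v = 0 and monotone non-decreasing.
    """
    a_hill = 0.25  # Hill shape parameter a/F0 of the shortening hyperbola
    if v_fiber_norm <= -1.0:
        return 0.0
    if v_fiber_norm <= 0.0:
        # f = (1 + v) / (1 - v / a_hill)
        return (1.0 + v_fiber_norm) / (1.0 - v_fiber_norm / a_hill)
    # slope at 0- is (1 + 1/a_hill); the eccentric branch saturates at
    # FV_ECC_MAX with the same initial slope
    slope0 = 1.0 + 1.0 / a_hill
    excess = FV_ECC_MAX - 1.0
    return FV_ECC_MAX - excess * math.exp(-slope0 * v_fiber_norm / excess)


def force_decomposition(
    params: MuscleParameters,
    l_mt: float,
    v_mt: float,
    name: str = "muscle",
) -> tuple[float, float]:
    """Split the tendon force into an activation gain and a passive offset.

    Returns ``(active_gain, passive_force)`` in N such that the tendon force
    at activation ``a`` is exactly ``active_gain * a + passive_force``.
    """
    l_norm, cos_a = fiber_geometry(params, l_mt, name)
    # rigid tendon: fiber lengthening speed = projection of v_mt on the fiber
    v_fiber = v_mt * cos_a
    v_norm = v_fiber / (params.v_max * params.l_opt)
    gain = params.f_iso_max * active_force_length(l_norm) * force_velocity(v_norm) * cos_a
    passive = params.f_iso_max * passive_force_length(l_norm) * cos_a
    return gain, passive


def tendon_force(params: MuscleParameters, state: MuscleState, name: str = "muscle") -> float:
    """Full Hill-model tendon force at the given state (N)."""
    gain, passive = force_decomposition(params, state.l_mt, state.v_mt, name)
    return gain * state.a + passive
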