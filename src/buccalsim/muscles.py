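"""Muscle/tissue tension laws and conversion of tensions to force vectors.

Each muscle carries a double-first-order activation filter
``dA/dt = (N - A)/tau_A``, ``dT~/dt = (A - T~)/tau_T`` driven by a Boolean
neural input ``N``; active tension is ``T_max * T~``.  Passive tension is a
piecewise-linear spring (zero below rest length) except for the I1
elements, whose linear law extends below rest length to model the bulk
elasticity of the I1/I3 complex in compression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

from buccalsim.geometry import Point2

__all__ = [
    "MuscleSpec",
    "MuscleState",
    "passive_tension",
    "activation_derivatives",
    "total_tension",
    "line_force",
    "i2_wrap_force",
    "hinge_mechanical_advantage",
    "i3_mechanical_advantage",
]

PASSIVE_LAWS = ("piecewise", "linear", "none")


@dataclass
class MuscleSpec:
    """Parameters of one muscle/tissue element.

    ``tau_act``/``tau_relax`` are used for I2, which activates faster than
    it relaxes; all other muscles use the single ``tau``.
    """

    id: str
    T_max: float
    tau: float = 1.0
    L_0: Optional[float] = None
    L_max: Optional[float] = None
    passive_law: str = "none"
    tau_act: Optional[float] = None
    tau_relax: Optional[float] = None

    def __post_init__(self) -> None:
        if self.T_max < 0:
            raise ValueError(f"{self.id}: T_max must be >= 0")
        if self.tau <= 0:
            raise ValueError(f"{self.id}: tau must be > 0")
        if self.passive_law not in PASSIVE_LAWS:
            raise ValueError(f"{self.id}: unknown passive law {self.passive_law!r}")
        if self.passive_law != "none":
            if self.L_0 is None or self.L_max is None:
                raise ValueError(f"{self.id}: passive law requires L_0 and L_max")
            if not (0 < self.L_0 < self.L_max):
                raise ValueError(f"{self.id}: need 0 < L_0 < L_max")

    def tau_activation(self, N: float) -> float:
        """Activation-filter time constant; I2 switches on the sign of N."""
        if self.tau_act is not None and self.tau_relax is not None:
            return self.tau_act if N >= 0.5 else self.tau_relax
        return self.tau


@dataclass
class MuscleState:
    """Filter states of one muscle: activation A and normalized tension T~."""

    A: float = 0.0
    T_tilde: float = 0.0


def passive_tension(spec: MuscleSpec, L: float) -> float:
    """Passive spring tension at length ``L``.

    The piecewise law is zero below rest length and ramps linearly to
    ``T_max`` at ``L_max``; the linear (I1) law extends the same line below
    rest length, giving negative (compressive) reactions.
    """
    if spec.passive_law == "none":
        raise ValueError(f"{spec.id} has no passive law")
    slope = spec.T_max / (spec.L_max - spec.L_0)
    t = slope * (L - spec.L_0)
    if spec.passive_law == "piecewise" and L < spec.L_0:
        return 0.0
    return t


def activation_derivatives(
    state: MuscleState, N: float, tau_A: float, tau_T: float
) -> Tuple[float, float]:
    """Time derivatives ``(dA/dt, dT~/dt)`` of the double-first-order filter."""
    dA = (N - state.A) / tau_A
    dT = (state.A - state.T_tilde) / tau_T
    return dA, dT


def total_tension(spec: MuscleSpec, state: MuscleState, L: Optional[float] = None) -> float:
    """Active plus passive tension.

    Elements without a passive law (bulk/anterior I3, I4) produce only the
    active component and need no length.
    """
    T = spec.T_max * state.T_tilde
    if spec.passive_law != "none":
        if L is None:
            raise ValueError(f"{spec.id}: length required for passive tension")
        T += passive_tension(spec, L)
    return T


def line_force(T: float, attachment: Point2, anchor: Point2) -> Tuple[float, float]:
    """Force vector of magnitude ``T`` directed attachment -> anchor."""
    dx = anchor.x - attachment.x
    dy = anchor.y - attachment.y
    d = math.hypot(dx, dy)
    if d == 0.0:
        raise ValueError("line element has coincident attachment and anchor")
    return T * dx / d, T * dy / d


def i2_wrap_force(T: float, alpha_d: float, alpha_v: float) -> Tuple[float, float]:
    """Net force of the wrapped I2 on the odontophore.

    Integral of the inward radial pressure between the tangency angles;
    equals the vector sum of the two end-tension tangent directions.
    """
    return (
        T * (math.sin(alpha_d) - math.sin(alpha_v)),
        T * (math.cos(alpha_v) - math.cos(alpha_d)),
    )


def hinge_mechanical_advantage(
    x_v: float, x_hinge: float, L_hinge: float, L_0: float, L_max: float
) -> float:
    """Signed mechanical advantage of the hinge, in [-1, 1].

    The magnitude ramps linearly with stretch, saturating at 1 once the
    hinge passes 50% of its maximum stretch; the sign points the force
    from the hinge point toward the ventral groove.
    """
    stretch = (L_hinge - L_0) / (L_max - L_0)
    mag = min(2.0 * stretch, 1.0)
    mag = max(mag, 0.0)
    if x_v == x_hinge:
        return 0.0
    return math.copysign(mag, x_v - x_hinge)


def i3_mechanical_advantage(delta: float, R: float) -> float:
    """Mechanical advantage of the bulk I3 on the odontophore, in [-1, 0].

    Full (retracting) force when the odontophore is fully inside the lumen
    (``delta > 2R``), zero when fully outside (``delta < 0``), linear in
    between.  The I3 force vector is ``MA * T * (1, 0)`` applied along the
    horizontal lumen midline.
    """
    if delta > 2.0 * R:
        return -1.0
    if delta < 0.0:
        return 0.0
    return -delta / (2.0 * R)
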