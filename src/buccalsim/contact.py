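"""Pin-slot constraint handling and penalty contact laws.

The pin-slot equality constraint is eliminated analytically: the vertical
reaction (Lagrange multiplier) follows from the y-balance, and the
rotation rate absorbs the constraint coupling.  Two inequality penalties
prevent interpenetration: a rotational stop on the odontophore and a
ventral-wall contact force.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

from buccalsim.geometry import AnatomyParams, GeneralizedState, hinge_point_x

__all__ = [
    "PenaltyParams",
    "pin_slot_lambda",
    "theta_g_rate",
    "penalty_torque",
    "wall_penalty_force",
]


@dataclass
class PenaltyParams:
    k_pen: float = 5.0  # rotational penalty stiffness (torque/rad)
    k_W: float = 5.0  # ventral-wall penalty stiffness (force/length)

    def __post_init__(self) -> None:
        if self.k_pen < 0 or self.k_W < 0:
            raise ValueError("penalty stiffnesses must be >= 0")


def pin_slot_lambda(Q_yg: float, c_yg: float, ydot_g: float) -> float:
    """Vertical reaction force from the slot: ``lambda = Q_yg - c_yg*ydot_g``."""
    return Q_yg - c_yg * ydot_g


def theta_g_rate(
    Q_theta: float,
    Q_yg: float,
    theta_g: float,
    anat: AnatomyParams,
    c_theta: float,
    c_yg: float,
) -> Tuple[float, float]:
    """Rotation rate of the odontophore and the slaved vertical rate.

    Returns ``(thetadot_g, ydot_g)``.  The y equation is eliminated through
    the pin-slot constraint, which folds the vertical generalized force and
    damping into the rotational balance.
    """
    if c_theta <= 0:
        raise ValueError("c_theta must be positive")
    g = anat.R * math.cos(theta_g + anat.theta_H)
    thetadot = (Q_theta - Q_yg * g) / (c_theta + c_yg * g * g)
    ydot = -g * thetadot
    return thetadot, ydot


def penalty_torque(theta_g: float, anat: AnatomyParams, k_pen: float) -> float:
    """Rotational stop: restoring torque when the odontophore over-rotates
    past ``theta_g + theta_H = 3*pi/2`` (no reaction on the lumen)."""
    dtheta = 1.5 * math.pi - (theta_g + anat.theta_H)
    if dtheta >= 0.0:
        return k_pen * dtheta
    return 0.0


def wall_penalty_force(
    state: GeneralizedState, anat: AnatomyParams, k_W: float
) -> Tuple[float, float]:
    """Ventral-wall contact force on the odontophore.

    Active only when the odontophore is outside the I3 lumen
    (``x_g < x_hinge``) and the ventral groove point has entered the
    odontophore circle; the force pushes the odontophore away along the
    point-to-center direction, with magnitude growing with penetration
    depth.  An equal-and-opposite x reaction acts on ``x_v``.
    """
    x_hinge = hinge_point_x(state, anat)
    lx = state.x_g - state.x_v
    ly = state.y_g
    l = math.hypot(lx, ly)
    if not (state.x_g < x_hinge and l < anat.R):
        return 0.0, 0.0
    mag = k_W * math.sqrt(max(anat.R * anat.R - l * l, 0.0))
    if l == 0.0:
        # degenerate direction: push anteriorly
        return mag, 0.0
    return mag * lx / l, mag * ly / l
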