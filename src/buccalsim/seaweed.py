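"""Stick-slip frictional coupling between seaweed and the grasper/jaws.

Friction is memoryless: stick/slip is re-evaluated from the instantaneous
force balance on each body at every right-hand-side call.  Seaweed can be
detached (no friction), fixed (rigidly tethered), or of finite breaking
strength, in which case it becomes detached once the applied force exceeds
the strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

__all__ = [
    "SeaweedState",
    "FrictionParams",
    "body_force_sums",
    "friction_force",
    "grasp_indicator",
    "update_seaweed",
]

SEAWEED_MODES = ("detached", "fixed", "finite_strength")


@dataclass
class FrictionParams:
    mu_s_g: float = 2.0  # static coefficient, grasper
    mu_k_g: float = 1.6  # kinetic coefficient, grasper
    mu_s_j: float = 2.0  # static coefficient, jaws
    mu_k_j: float = 1.6  # kinetic coefficient, jaws


@dataclass
class SeaweedState:
    """Boundary-condition state of the seaweed."""

    mode: str = "detached"
    breaking_strength: float = float("inf")
    broken: bool = False
    slip_g: bool = True
    slip_j: bool = True
    delta_ingest: int = 0

    def __post_init__(self) -> None:
        if self.mode not in SEAWEED_MODES:
            raise ValueError(f"unknown seaweed mode {self.mode!r}")

    @property
    def effectively_fixed(self) -> bool:
        return self.mode in ("fixed", "finite_strength") and not self.broken


def body_force_sums(forces: Dict[str, float]) -> tuple[float, float]:
    """Net non-friction horizontal force on the grasper and on the jaws.

    ``forces`` maps element ids to their x force components as applied to
    the odontophore (grasper sums) or as defined on the head (jaw sums);
    the wall penalty is excluded by construction.
    """
    sum_g = (
        forces.get("I2", 0.0)
        + forces.get("I3", 0.0)
        + forces.get("hinge", 0.0)
        + forces.get("E1", 0.0)
        + forces.get("E2", 0.0)
    )
    sum_j = (
        forces.get("sp_h", 0.0)
        - forces.get("I1v", 0.0)
        - forces.get("I1d", 0.0)
        - forces.get("I3", 0.0)
        - forces.get("E1", 0.0)
        - forces.get("E2", 0.0)
        - forces.get("E6", 0.0)
    )
    return sum_g, sum_j


def friction_force(sum_F: float, P: float, mu_s: float, mu_k: float) -> float:
    """Frictional force on a body gripping fixed seaweed.

    Zero when the body is being pushed anteriorly (seaweed supports no
    compression); exactly cancels the applied force while stuck; kinetic
    ``mu_k * P`` once slipping.  Always non-negative.
    """
    if P < 0:
        raise ValueError("grip force P must be >= 0")
    if sum_F > 0.0:
        return 0.0
    slipping = abs(sum_F) >= mu_s * P
    if slipping:
        return mu_k * P
    return -sum_F


def grasp_indicator(P_g: float, T_max_I4: float) -> int:
    """1 iff the grasper pressure exceeds half the maximal I4 tension."""
    return 1 if P_g > 0.5 * T_max_I4 else 0


def update_seaweed(seaweed: SeaweedState, F_on_seaweed: float) -> SeaweedState:
    """Break finite-strength seaweed when the applied force reaches its
    breaking strength.  Returns the (mutated) state."""
    if (
        seaweed.mode == "finite_strength"
        and not seaweed.broken
        and F_on_seaweed >= seaweed.breaking_strength
    ):
        seaweed.broken = True
    return seaweed
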