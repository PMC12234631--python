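"""Geometric primitives of the planar buccal-mass model.

Coordinate conventions
----------------------
Global ``x`` is positive toward the jaws (anterior).  ``y = 0`` is the
ventral wall of the I3 lumen, which is also the pin-slot line of the
odontophore: the ventral lateral-groove attachment sits at ``(x_v, 0)``,
the dorsal attachment at ``(x_d, H_lumen)``, and the lumen midline at
``y = H_lumen/2``.  With the pin at the bottom of the odontophore
(``theta_H = 3*pi/2`` nominal), the center rides at ``y_g = R*cos(theta_g)``,
so the dorsal groove point can never enter the odontophore circle and the
ventral one is kept out by the wall penalty.  All lengths are in model
units where the odontophore radius ``R = 1`` by convention; a single
scalar ``mm_per_unit`` converts outputs to mm.

The vertical position of the odontophore center is slaved to its rotation
by the pin-slot constraint ``y_g = -R*sin(theta_g + theta_H)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

__all__ = [
    "Point2",
    "AnatomyParams",
    "GeneralizedState",
    "tangent_point",
    "safe_tangent_point",
    "i2_tangency_angles",
    "element_length",
    "overlap_delta",
    "radular_cusp",
    "hinge_point_x",
    "GeometryError",
]


class GeometryError(ValueError):
    """Raised when a muscle-path construction is geometrically impossible,
    e.g. a wrap anchor strictly inside the odontophore circle."""


@dataclass(frozen=True)
class Point2:
    """A planar point in model units."""

    x: float
    y: float

    def __iter__(self):
        yield self.x
        yield self.y

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass
class AnatomyParams:
    """Fixed geometry of the model.

    ``L_0``/``L_max`` for the passive elements live with the muscle specs;
    this class holds only the rigid geometry and anchor points.  Anchors
    whose names end in ``_rel_head`` ride with the head (their global x is
    ``x_h + anchor.x``); the esophagus anchor is fixed in the global frame.
    """

    R: float = 1.0
    theta_H: float = 4.71238898038469  # rad, midline -> pin (3*pi/2 nominal)
    theta_f: float = 0.60  # rad, odontophore midline -> radular cusp
    H_lumen: float = 2.00  # I3 lumen height
    L_head: float = 3.00  # rigid head length (x_h -> jaw line)
    mm_per_unit: float = 6.00  # mm per model length unit
    # anchor points (y is global; x relative to head where noted)
    eso_anchor: Point2 = field(default_factory=lambda: Point2(-2.5, 2.0))
    e6_anchor_rel_head: Point2 = field(default_factory=lambda: Point2(-1.0, 2.0))

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError("odontophore radius R must be positive")
        if self.H_lumen <= 0:
            raise ValueError("H_lumen must be positive")

    # jaw-line anchor points --------------------------------------------
    def jaw_x(self, x_h: float) -> float:
        """Global x of the jaw line (anterior edge of the lumen)."""
        return x_h + self.L_head

    def jaw_anchor(self, x_h: float, dorsal: bool) -> Point2:
        """Jaw anchor at the dorsal/ventral lumen corner (I1, E1, E2)."""
        y = self.H_lumen if dorsal else 0.0
        return Point2(self.jaw_x(x_h), y)


@dataclass
class GeneralizedState:
    """The six generalized coordinates.

    ``y_g`` is not independent: it is reconstructed from the pin-slot
    constraint each time the state is built (eliminating drift).
    """

    x_h: float
    x_d: float
    x_v: float
    x_g: float
    theta_g: float
    y_g: float = 0.0

    @classmethod
    def from_coords(
        cls, x_h: float, x_d: float, x_v: float, x_g: float, theta_g: float, anat: AnatomyParams
    ) -> "GeneralizedState":
        y_g = -anat.R * math.sin(theta_g + anat.theta_H)
        return cls(x_h, x_d, x_v, x_g, theta_g, y_g)

    def center(self) -> Point2:
        return Point2(self.x_g, self.y_g)

    def groove_point(self, anat: AnatomyParams, dorsal: bool) -> Point2:
        """Dorsal/ventral lateral-groove attachment point."""
        if dorsal:
            return Point2(self.x_d, anat.H_lumen)
        return Point2(self.x_v, 0.0)

    def constraint_residual(self, anat: AnatomyParams) -> float:
        return self.y_g + anat.R * math.sin(self.theta_g + anat.theta_H)


def tangent_point(center: Point2, R: float, anchor: Point2, tol: float = 1e-12) -> Point2:
    """Posterior tangency point of the line from ``anchor`` to the circle.

    Of the two tangent points from an external anchor, the one with the
    smaller x coordinate (posterior edge of the odontophore) is returned.
    Ties are broken toward the smaller y.  An anchor exactly on the circle
    is its own tangency point.

    Raises
    ------
    GeometryError
        If the anchor lies strictly inside the circle.
    """
    tx = anchor.x - center.x
    ty = anchor.y - center.y
    d2 = tx * tx + ty * ty
    disc = d2 - R * R
    if disc < -tol * max(1.0, R * R):
        raise GeometryError(
            f"wrap anchor ({anchor.x:.4f},{anchor.y:.4f}) lies inside the "
            f"odontophore circle (center ({center.x:.4f},{center.y:.4f}), R={R})"
        )
    disc = max(disc, 0.0)
    root = math.sqrt(disc)

    if abs(ty) < 1e-9:
        # removable singularity of the y-recovery formula: solve in a frame
        # rotated by 90 degrees and rotate back.
        rot_center = Point2(-center.y, center.x)
        rot_anchor = Point2(-anchor.y, anchor.x)
        p = _tangent_candidates(rot_center, R, rot_anchor, root, d2)
        cands = [Point2(q.y, -q.x) for q in p]
    else:
        cands = _tangent_candidates(center, R, anchor, root, d2)

    # posterior (min-x) selection; tie -> smaller y
    cands.sort(key=lambda p: (p.x, p.y))
    return cands[0]


def _tangent_candidates(center: Point2, R: float, anchor: Point2, root: float, d2: float):
    tx = anchor.x - center.x
    ty = anchor.y - center.y
    pts = []
    for s in (+1.0, -1.0):
        x = center.x + (tx * R * R + s * ty * R * root) / d2
        y = center.y + (R * R - tx * (x - center.x)) / ty
        pts.append(Point2(x, y))
    return pts


def safe_tangent_point(
    center: Point2, R: float, anchor: Point2, max_penetration: float = 0.15
) -> Point2:
    """Tangency point tolerant of small penalty-regulated penetrations.

    Contact between the odontophore and the ventral wall is only weakly
    enforced (penalty method), so a wrap anchor may transiently sit a
    little inside the circle.  Anchors penetrating by less than
    ``max_penetration * R`` are projected radially onto the circle;
    deeper penetrations still raise :class:`GeometryError`.
    """
    tx = anchor.x - center.x
    ty = anchor.y - center.y
    d = math.hypot(tx, ty)
    if d < R:
        if d < (1.0 - max_penetration) * R or d == 0.0:
            raise GeometryError(
                f"wrap anchor ({anchor.x:.4f},{anchor.y:.4f}) penetrates the "
                f"odontophore circle too deeply (|d|={d:.4f}, R={R})"
            )
        anchor = Point2(center.x + tx * R / d, center.y + ty * R / d)
    return tangent_point(center, R, anchor)


def i2_tangency_angles(
    state: GeneralizedState, anat: AnatomyParams
) -> Tuple[float, float]:
    """Polar angles (about the odontophore center) of the dorsal and
    ventral I2 tangency points.

    Returns ``(alpha_d, alpha_v)`` in radians, measured from the
    horizontal.  Both tangency points lie on the posterior arc.
    """
    c = state.center()
    pd = safe_tangent_point(c, anat.R, state.groove_point(anat, dorsal=True))
    pv = safe_tangent_point(c, anat.R, state.groove_point(anat, dorsal=False))
    alpha_d = math.atan2(pd.y - c.y, pd.x - c.x)
    alpha_v = math.atan2(pv.y - c.y, pv.x - c.x)
    return alpha_d, alpha_v


def hinge_point_x(state: GeneralizedState, anat: AnatomyParams) -> float:
    """Global x of the hinge/pin point on the odontophore rim."""
    return state.x_g + anat.R * math.cos(state.theta_g + anat.theta_H)


def radular_cusp(state: GeneralizedState, anat: AnatomyParams) -> Point2:
    """Location of the radular cusp, the point where food is held."""
    a = state.theta_g - anat.theta_f
    return Point2(
        state.x_g + anat.R * math.cos(a),
        state.y_g + anat.R * math.sin(a),
    )


def overlap_delta(state: GeneralizedState, anat: AnatomyParams) -> float:
    """Overlap between the odontophore and the I3 lumen.

    ``delta = x_g + R - 0.5*(x_d + x_v)``; may be negative when the
    odontophore is entirely posterior to the lateral groove.
    """
    return state.x_g + anat.R - 0.5 * (state.x_d + state.x_v)


def _dist(a: Point2, b: Point2) -> float:
    return math.hypot(a.x - b.x, a.y - b.y)


def i2_path_length(state: GeneralizedState, anat: AnatomyParams) -> float:
    """Wrapped I2 path: dorsal tangent segment + posterior arc + ventral
    tangent segment.  The arc is traversed dorsal -> ventral the long way
    around the posterior of the odontophore."""
    c = state.center()
    gd = state.groove_point(anat, dorsal=True)
    gv = state.groove_point(anat, dorsal=False)
    pd = safe_tangent_point(c, anat.R, gd)
    pv = safe_tangent_point(c, anat.R, gv)
    alpha_d = math.atan2(pd.y - c.y, pd.x - c.x)
    alpha_v = math.atan2(pv.y - c.y, pv.x - c.x)
    # going dorsal -> ventral with increasing angle passes through the
    # posterior direction (pi): wrap angle in [0, 2*pi)
    sweep = (alpha_v - alpha_d) % (2.0 * math.pi)
    return _dist(gd, pd) + anat.R * sweep + _dist(gv, pv)


def element_length(element: str, state: GeneralizedState, anat: AnatomyParams) -> float:
    """Current path length of a named muscle/tissue element.

    E1/E2/E6/esophagus are Euclidean attachment-to-anchor distances;
    I1d/I1v are the horizontal jaw-to-groove distances; the hinge is the
    horizontal ventral-groove-to-hinge-point distance; I2 is the full
    wrapped path length.
    """
    if element == "I2":
        return i2_path_length(state, anat)
    if element == "I1d":
        return anat.jaw_x(state.x_h) - state.x_d
    if element == "I1v":
        return anat.jaw_x(state.x_h) - state.x_v
    if element == "hinge":
        return abs(state.x_v - hinge_point_x(state, anat))
    if element == "E1":
        c = state.center()
        p = safe_tangent_point(c, anat.R, state.groove_point(anat, dorsal=True))
        return _dist(p, anat.jaw_anchor(state.x_h, dorsal=True))
    if element == "E2":
        c = state.center()
        p = safe_tangent_point(c, anat.R, state.groove_point(anat, dorsal=False))
        return _dist(p, anat.jaw_anchor(state.x_h, dorsal=False))
    if element == "E6":
        mid = Point2(0.5 * (state.x_d + state.x_v), 0.5 * anat.H_lumen)
        anchor = Point2(
            state.x_h + anat.e6_anchor_rel_head.x, anat.e6_anchor_rel_head.y
        )
        return _dist(mid, anchor)
    if element == "esophagus":
        gd = state.groove_point(anat, dorsal=True)
        return _dist(gd, anat.eso_anchor)
    raise KeyError(f"unknown element id: {element!r}")


#: elements whose length is defined by :func:`element_length`
LENGTH_ELEMENTS = ("I2", "I1d", "I1v", "hinge", "E1", "E2", "E6", "esophagus")
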