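"""Parameter configuration: loading, validation, and the cue protocol.

Parameters are stored in a flat-ish YAML document (see
``buccalsim/data/default_params.yaml``).  All lengths are in model units
(odontophore radius = 1); all times in the muscle tables are in model time
units (the I2 activation time constant = 1), converted to seconds through
the single ``time_scale`` factor.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional

import yaml

from buccalsim.contact import PenaltyParams
from buccalsim.controller import BooleanNetwork, FeedingCues, load_default_rules
from buccalsim.geometry import AnatomyParams, Point2
from buccalsim.muscles import MuscleSpec
from buccalsim.seaweed import FrictionParams

__all__ = [
    "DampingParams",
    "HeadSpring",
    "ModelParams",
    "CueSegment",
    "CueProtocol",
    "load_params",
    "default_params",
]

COORDS = ("x_h", "x_d", "x_v", "x_g", "y_g", "theta_g")
MUSCLE_ORDER = ("I2", "I3", "I3a", "I4", "hinge", "I1d", "I1v", "E1", "E2", "E6")


@dataclass
class DampingParams:
    """Per-coordinate damping ``c_i = scale * rel_i`` (model units)."""

    scale: float = 0.02
    rel: Dict[str, float] = field(
        default_factory=lambda: {c: 1.0 for c in COORDS}
    )

    def c(self, coord: str) -> float:
        v = self.scale * self.rel[coord]
        if v <= 0:
            raise ValueError(f"damping for {coord} must be positive")
        return v


@dataclass
class HeadSpring:
    """Linear body-wall spring anchoring the head to the global frame."""

    k: float = 1.0
    x_rest: float = 0.0

    def force(self, x_h: float) -> float:
        return -self.k * (x_h - self.x_rest)


@dataclass
class CueSegment:
    """One time segment of the feeding-cue protocol."""

    t_start: float
    t_end: float
    chem_lips: bool = False
    mech_lips: bool = False
    mech_grasper: bool = False
    seaweed_mode: str = "detached"
    strength: float = math.inf

    def cues(self) -> FeedingCues:
        return FeedingCues(self.chem_lips, self.mech_lips, self.mech_grasper)


class CueProtocol:
    """Ordered, non-overlapping cue segments; last segment extends forever."""

    def __init__(self, segments: List[CueSegment]):
        if not segments:
            raise ValueError("protocol needs at least one segment")
        segs = sorted(segments, key=lambda s: s.t_start)
        for a, b in zip(segs, segs[1:]):
            if b.t_start < a.t_end - 1e-12:
                raise ValueError("protocol segments overlap")
        self.segments = segs

    def at(self, t: float) -> CueSegment:
        current = self.segments[0]
        for seg in self.segments:
            if t >= seg.t_start - 1e-12:
                current = seg
        return current

    @classmethod
    def constant(
        cls,
        duration: float,
        chem_lips: bool = False,
        mech_lips: bool = False,
        mech_grasper: bool = False,
        seaweed_mode: str = "detached",
        strength: float = math.inf,
    ) -> "CueProtocol":
        return cls(
            [
                CueSegment(
                    0.0, duration, chem_lips, mech_lips, mech_grasper,
                    seaweed_mode, strength,
                )
            ]
        )

    @classmethod
    def from_dicts(cls, records: List[dict]) -> "CueProtocol":
        return cls([CueSegment(**r) for r in records])


@dataclass
class ModelParams:
    """Complete parameter set of the neuromechanical model."""

    anatomy: AnatomyParams
    muscles: Dict[str, MuscleSpec]
    esophagus: MuscleSpec
    damping: DampingParams
    penalty: PenaltyParams
    friction: FrictionParams
    head_spring: HeadSpring
    network: BooleanNetwork
    time_scale: float = 1.1  # seconds per model time unit
    control_dt: float = 0.01  # s, Boolean-controller update period
    initial_coords: Dict[str, float] = field(default_factory=dict)
    raw: dict = field(default_factory=dict, repr=False)

    def copy(self) -> "ModelParams":
        p = copy.deepcopy(self)
        return p

    @property
    def L0_I1_mean(self) -> float:
        return 0.5 * (self.muscles["I1v"].L_0 + self.muscles["I1d"].L_0)


def _point(v) -> Point2:
    return Point2(float(v[0]), float(v[1]))


def _build(doc: dict) -> ModelParams:
    a = doc["anatomy"]
    anat = AnatomyParams(
        R=a["R"],
        theta_H=a["theta_H"],
        theta_f=a["theta_f"],
        H_lumen=a["H_lumen"],
        L_head=a["L_head"],
        mm_per_unit=a["mm_per_unit"],
        eso_anchor=_point(a["eso_anchor"]),
        e6_anchor_rel_head=_point(a["e6_anchor_rel_head"]),
    )
    muscles = {}
    for mid in MUSCLE_ORDER:
        rec = dict(doc["muscles"][mid])
        muscles[mid] = MuscleSpec(id=mid, **rec)
    eso = MuscleSpec(id="esophagus", **doc["muscles"]["esophagus"])
    damping = DampingParams(
        scale=doc["damping"]["scale"],
        rel={c: float(doc["damping"]["rel"].get(c, 1.0)) for c in COORDS},
    )
    rules = doc.get("rules") or load_default_rules()
    return ModelParams(
        anatomy=anat,
        muscles=muscles,
        esophagus=eso,
        damping=damping,
        penalty=PenaltyParams(**doc["penalty"]),
        friction=FrictionParams(**doc["friction"]),
        head_spring=HeadSpring(**doc["head_spring"]),
        network=BooleanNetwork(rules),
        time_scale=doc["time_scale"],
        control_dt=doc["control_dt"],
        initial_coords=dict(doc["initial_state"]),
        raw=doc,
    )


def default_params() -> ModelParams:
    """The packaged default (hand-tuned) parameter set."""
    text = (
        resources.files("buccalsim").joinpath("data/default_params.yaml").read_text()
    )
    return _build(yaml.safe_load(text))


def load_params(path: Optional[str] = None, overrides: Optional[dict] = None) -> ModelParams:
    """Load parameters from a YAML file (defaults if ``path`` is None).

    ``overrides`` is a nested dict merged on top of the document.
    """
    if path is None:
        text = (
            resources.files("buccalsim")
            .joinpath("data/default_params.yaml")
            .read_text()
        )
        doc = yaml.safe_load(text)
    else:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    if overrides:
        doc = _merge(doc, overrides)
    return _build(doc)


def _merge(base: dict, over: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in over.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out
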