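"""Three-layer Boolean neural controller with proprioceptive feedback.

Cerebral neurons select the behavior from chemical/mechanical feeding
cues; buccal interneurons set cycle phasing from thresholded
proprioception; motor neurons drive the Boolean inputs of the nine muscle
groups.  All neurons update synchronously: each expression reads the
states of presynaptic neurons from the previous control tick, so the
network acts as a finite state machine clocked by the control grid.

The update logic is declarative: a rules document (YAML) lists sensory
threshold channels, derived cue combinations, one Boolean expression per
neuron, and the motor map from muscles to neurons.  Corrections to the
wiring therefore require no code change.
"""

from __future__ import annotations

import ast
import math
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Mapping, Optional, Tuple

import yaml

from buccalsim.geometry import AnatomyParams, GeneralizedState

__all__ = [
    "FeedingCues",
    "SensoryThreshold",
    "BooleanNetwork",
    "proprioception",
    "sensory_encode",
    "load_default_rules",
]


@dataclass
class FeedingCues:
    """Externally scripted sensory cues."""

    chem_lips: bool = False
    mech_lips: bool = False
    mech_grasper: bool = False

    def as_namespace(self) -> Dict[str, int]:
        return {
            "chem_lips": int(self.chem_lips),
            "mech_lips": int(self.mech_lips),
            "mech_grasper": int(self.mech_grasper),
        }


@dataclass
class SensoryThreshold:
    """One proprioceptive threshold channel.

    ``signal`` names a continuous proprioceptive quantity (``xhat`` or
    ``Pg_norm``); the channel emits 1 when the signal is strictly on the
    ``direction`` side of the threshold.
    """

    name: str
    signal: str
    threshold: float
    direction: str  # "greater" | "less"
    target: Optional[str] = None

    def __post_init__(self) -> None:
        if self.direction not in ("greater", "less"):
            raise ValueError(f"{self.name}: direction must be 'greater' or 'less'")
        if not math.isfinite(self.threshold):
            raise ValueError(f"{self.name}: threshold must be finite")


def sensory_encode(signal: float, threshold: float, direction: str) -> int:
    """Threshold a continuous signal to a Boolean sensory bit (strict)."""
    if direction == "greater":
        return 1 if signal > threshold else 0
    if direction == "less":
        return 1 if signal < threshold else 0
    raise ValueError(f"unknown direction {direction!r}")


def proprioception(
    state: GeneralizedState,
    anat: AnatomyParams,
    T_tilde_I4: float,
    L0_I1v: float,
    L0_I1d: float,
) -> Tuple[float, float]:
    """Continuous proprioceptive signals ``(xhat, Pg_norm)``.

    ``xhat`` is the relative odontophore position: 0 with the odontophore
    front a rest-lumen-length behind the jaw line (full retraction), 1
    with the front at the jaw line.  ``Pg_norm`` is the grasper pressure
    normalized by the maximal I4 tension.
    """
    L_bar = 0.5 * (L0_I1v + L0_I1d)
    xhat = ((state.x_g + anat.R) - (anat.L_head + state.x_h) + L_bar) / L_bar
    Pg = min(max(T_tilde_I4, 0.0), 1.0)
    return xhat, Pg


# expression safety: only these node types may appear in a rules file
_ALLOWED_NODES = (
    ast.Expression,
    ast.BoolOp,
    ast.And,
    ast.Or,
    ast.UnaryOp,
    ast.Not,
    ast.Name,
    ast.Load,
    ast.Constant,
    ast.Compare,
    ast.Eq,
    ast.NotEq,
    ast.Gt,
    ast.GtE,
    ast.Lt,
    ast.LtE,
    ast.IfExp,
    ast.BinOp,
    ast.Add,
    ast.Sub,
    ast.Mult,
)


def _compile_rule(name: str, expr: str):
    tree = ast.parse(expr, mode="eval")
    for node in ast.walk(tree):
        if not isinstance(node, _ALLOWED_NODES):
            raise ValueError(
                f"rule {name!r}: disallowed syntax {type(node).__name__} in {expr!r}"
            )
    return compile(tree, filename=f"<rule:{name}>", mode="eval")


class BooleanNetwork:
    """Synchronous Boolean network built from a declarative rules document.

    The document has four sections: ``sensory`` (threshold channels),
    ``derived`` (named cue/state combinations, evaluated before the neuron
    updates), ``neurons`` (one expression per neuron, reading
    previous-step states), and ``motor_map`` (muscle id -> neuron name).
    """

    def __init__(self, rules: Mapping):
        self.thresholds = [
            SensoryThreshold(name=k, **v) for k, v in rules.get("sensory", {}).items()
        ]
        self.derived = {
            k: _compile_rule(k, v) for k, v in rules.get("derived", {}).items()
        }
        self.neuron_exprs = {
            k: _compile_rule(k, v) for k, v in rules["neurons"].items()
        }
        self.motor_map: Dict[str, str] = dict(rules["motor_map"])
        self.neuron_names = list(self.neuron_exprs)
        for muscle, neuron in self.motor_map.items():
            if neuron not in self.neuron_exprs:
                raise ValueError(f"motor map: {muscle} -> unknown neuron {neuron}")

    def initial_state(self) -> Dict[str, int]:
        return {name: 0 for name in self.neuron_names}

    def sensory_bits(self, signals: Mapping[str, float]) -> Dict[str, int]:
        bits = {}
        for ch in self.thresholds:
            bits[ch.name] = sensory_encode(
                signals[ch.signal], ch.threshold, ch.direction
            )
        return bits

    def step(
        self,
        prev: Mapping[str, int],
        cues: FeedingCues,
        sensory_bits: Mapping[str, int],
        extra: Optional[Mapping[str, int]] = None,
    ) -> Dict[str, int]:
        """One synchronous update; every neuron reads previous-step states."""
        ns: Dict[str, int] = {}
        ns.update(prev)
        ns.update(cues.as_namespace())
        ns.update(sensory_bits)
        if extra:
            ns.update(extra)
        for name, code in self.derived.items():
            ns[name] = int(eval(code, {"__builtins__": {}}, ns))
        new = {}
        for name, code in self.neuron_exprs.items():
            new[name] = int(eval(code, {"__builtins__": {}}, ns))
        return new

    def motor_inputs(self, states: Mapping[str, int]) -> Dict[str, int]:
        """Boolean drive ``N`` per muscle id (ternary neurons clip to 1)."""
        return {
            muscle: 1 if states[neuron] >= 1 else 0
            for muscle, neuron in self.motor_map.items()
        }


def load_default_rules() -> dict:
    """Load the packaged default rules document."""
    text = (
        resources.files("buccalsim").joinpath("data/default_rules.yaml").read_text()
    )
    return yaml.safe_load(text)
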