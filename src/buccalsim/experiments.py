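"""Scripted computational experiments.

Behavior cue mapping: biting = chemical + mechanical stimulus at the lips
only; swallowing adds mechanical stimulus at the grasper (seaweed
detached for unloaded, fixed for loaded); rejection = mechanical stimulus
at the grasper without the chemical cue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from buccalsim.dynamics import Trajectory, simulate
from buccalsim.observables import CycleMetrics, detect_cycles, scalar_metrics
from buccalsim.params import CueProtocol, CueSegment, ModelParams, default_params

__all__ = [
    "ExperimentSpec",
    "BEHAVIOR_CUES",
    "behavior_protocol",
    "run_behavior",
    "run_switching",
    "run_seaweed_strength_sweep",
    "run_damping_sweep",
    "classify_behavior",
    "ANIMAL_BITE_TIME_S",
]

#: mean animal bite cycle time used to convert model time units to seconds
ANIMAL_BITE_TIME_S = 4.36

BEHAVIOR_CUES: Dict[str, dict] = {
    "bite": dict(chem_lips=True, mech_lips=True, mech_grasper=False,
                 seaweed_mode="detached"),
    "swallow_unloaded": dict(chem_lips=True, mech_lips=True, mech_grasper=True,
                             seaweed_mode="detached"),
    "swallow_loaded": dict(chem_lips=True, mech_lips=True, mech_grasper=True,
                           seaweed_mode="fixed"),
    "reject": dict(chem_lips=False, mech_lips=False, mech_grasper=True,
                   seaweed_mode="detached"),
}


@dataclass
class ExperimentSpec:
    """A named experiment: parameter overrides plus a cue schedule."""

    name: str
    protocol: CueProtocol
    duration: float = 20.0
    overrides: dict = field(default_factory=dict)


def behavior_protocol(behavior: str, duration: float = 20.0) -> CueProtocol:
    if behavior not in BEHAVIOR_CUES:
        raise KeyError(f"unknown behavior {behavior!r}")
    return CueProtocol.constant(duration, **BEHAVIOR_CUES[behavior])


def run_behavior(
    behavior: str,
    params: Optional[ModelParams] = None,
    duration: float = 20.0,
) -> Tuple[Trajectory, CycleMetrics]:
    """Simulate one steady behavior and compute steady-cycle metrics."""
    params = params or default_params()
    traj = simulate(params, behavior_protocol(behavior, duration), duration)
    return traj, scalar_metrics(traj)


def classify_behavior(
    traj: Trajectory, t0: float, t1: float
) -> str:
    """Classify the behavior expressed in a time window.

    Swallow: radular closure overlapping retraction with net ingestion;
    rejection: closure overlapping protraction with net egestion;
    bite: ingestion-neutral cycling with closure in retraction.
    """
    sel = (traj.t >= t0) & (traj.t < t1)
    if np.mean(np.asarray(traj.neurons["CBI4"])[sel]) < 0.5:
        return "bite"  # no mechanical cue at the grasper
    closed = np.asarray(traj.neurons["B8ab"])[sel] >= 1
    protraction = np.asarray(traj.neurons["B31B32"])[sel] >= 1
    retraction = ~protraction
    closure_in_prot = np.sum(closed & protraction)
    closure_in_ret = np.sum(closed & retraction)
    ling = traj.L_ingested[sel]
    net = ling[-1] - ling[0] if ling.size else 0.0
    pulls_on_food = ling.size and traj.F_seaweed[sel].max() > 0.25
    if closure_in_prot > closure_in_ret and net < 0:
        return "reject"
    if closure_in_ret >= closure_in_prot and (net > 1e-6 or pulls_on_food):
        return "swallow"
    return "bite"


def run_switching(
    params: Optional[ModelParams] = None,
    phase_duration: float = 20.0,
    order: Sequence[str] = ("bite", "swallow_unloaded", "swallow_loaded", "reject"),
) -> Tuple[Trajectory, List[str]]:
    """Single continuous simulation through four cue phases; returns the
    trajectory and the classification of each phase."""
    params = params or default_params()
    segments = []
    for i, b in enumerate(order):
        segments.append(
            CueSegment(i * phase_duration, (i + 1) * phase_duration,
                       **BEHAVIOR_CUES[b])
        )
    protocol = CueProtocol(segments)
    duration = phase_duration * len(order)
    traj = simulate(params, protocol, duration)
    labels = []
    for i in range(len(order)):
        t0 = i * phase_duration
        # classify on the back half of the phase (post-transient)
        labels.append(classify_behavior(traj, t0 + 0.5 * phase_duration,
                                        t0 + phase_duration))
    return traj, labels


def run_seaweed_strength_sweep(
    strengths: Sequence[float],
    params: Optional[ModelParams] = None,
    duration: float = 20.0,
    fixation_time: float = 2.0,
) -> List[dict]:
    """Swallowing on seaweed that becomes fixed at ``fixation_time`` with
    finite breaking strength; records break events and cycle lengths."""
    params = params or default_params()
    out = []
    for s in strengths:
        if s < 0:
            raise ValueError("seaweed strength must be >= 0")
        protocol = CueProtocol(
            [
                CueSegment(0.0, fixation_time, chem_lips=True, mech_lips=True,
                           mech_grasper=True, seaweed_mode="detached"),
                CueSegment(fixation_time, duration, chem_lips=True,
                           mech_lips=True, mech_grasper=True,
                           seaweed_mode="finite_strength", strength=float(s)),
            ]
        )
        traj = simulate(params, protocol, duration)
        fixed = traj.seaweed_fixed
        after = traj.t >= fixation_time
        broke = bool(np.any(after & ~fixed & (traj.t >= fixation_time)))
        t_break = None
        if broke:
            idx = np.flatnonzero(after & ~fixed)
            t_break = float(traj.t[idx[0]])
        metrics = scalar_metrics(traj)
        out.append(
            {
                "strength": float(s),
                "broke": broke,
                "t_break": t_break,
                "cycle_time": metrics.cycle_time,
                "metrics": metrics.as_dict(),
                "trajectory": traj,
            }
        )
    return out


def run_damping_sweep(
    c_values: Sequence[float],
    params: Optional[ModelParams] = None,
    duration_model_units: float = 25.0,
) -> List[dict]:
    """Bite simulations across damping values with tau_I2 = 1 model unit.

    For each damping scale the bite cycle time is measured in model time
    units and converted to a predicted I2 activation time constant as
    (mean animal bite time) / (model cycle time).  The low-damping limit
    of this prediction is the quantity that plateaus as damping -> 0.
    """
    params = params or default_params()
    out = []
    for c in c_values:
        if c <= 0:
            raise ValueError("damping values must be positive")
        p = params.copy()
        p.damping.scale = float(c)
        p.time_scale = 1.0  # run in model time units (tau_I2 = 1)
        traj = simulate(p, behavior_protocol("bite", duration_model_units),
                        duration_model_units)
        m = scalar_metrics(traj)
        out.append(
            {
                "damping": float(c),
                "cycle_time_model_units": m.cycle_time,
                "predicted_tau_I2_s": ANIMAL_BITE_TIME_S / m.cycle_time,
            }
        )
    return out


def plateau_value(pairs: List[dict]) -> float:
    """Predicted tau_I2 at the smallest damping of a sweep."""
    best = min(pairs, key=lambda r: r["damping"])
    return best["predicted_tau_I2_s"]
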