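"""Cycle detection and kinematic observables.

Cycle starts are OFF->ON transitions of the B31/B32 protraction motor
neuron; the first (start-up) cycle is excluded from scalar metrics.
Translation is reported in mm relative to the jaw line (more caudal more
negative), rotation in degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Dict, List, Tuple

import numpy as np

from buccalsim.dynamics import Trajectory

__all__ = [
    "CycleMetrics",
    "detect_cycles",
    "continuous_observables",
    "scalar_metrics",
]


@dataclass
class CycleMetrics:
    """Mean per-cycle scalar metrics over the steady-state cycles."""

    n_cycles: int
    cycle_time: float  # s
    time_in_protraction: float  # s
    percent_protraction: float  # %
    translation_ROM_mm: float
    rotation_ROM_deg: float

    def as_dict(self) -> dict:
        return asdict(self)


def detect_cycles(trajectory: Trajectory, neuron: str = "B31B32") -> List[Tuple[float, float]]:
    """Half-open cycle intervals ``[t_start, t_end)`` between successive
    OFF->ON transitions of the protraction motor neuron."""
    trace = np.asarray(trajectory.neurons[neuron])
    t = trajectory.t
    on = (trace >= 1).astype(int)
    starts = np.flatnonzero(np.diff(on) == 1) + 1
    times = t[starts]
    return [(times[i], times[i + 1]) for i in range(len(times) - 1)]


def continuous_observables(trajectory: Trajectory) -> Dict[str, np.ndarray]:
    """Continuous observable traces in physical units."""
    p = trajectory.params
    anat = p.anatomy
    dx_model = (
        trajectory.coords["x_g"] + anat.R
        - (anat.L_head + trajectory.coords["x_h"])
    )
    theta_obs = (180.0 / math.pi) * (
        0.5 * math.pi - (trajectory.coords["theta_g"] - anat.theta_f)
    )
    return {
        "t": trajectory.t,
        "translation_mm": anat.mm_per_unit * dx_model,
        "rotation_deg": theta_obs,
        "F_seaweed": trajectory.F_seaweed,
        "L_ingested_mm": anat.mm_per_unit * trajectory.L_ingested,
    }


def scalar_metrics(
    trajectory: Trajectory,
    cycles: List[Tuple[float, float]] | None = None,
    drop_startup: bool = True,
) -> CycleMetrics:
    """Per-cycle scalar metrics averaged over the steady-state cycles.

    Time in protraction is the total B31/B32 ON time within the cycle
    (contiguity not assumed).
    """
    if cycles is None:
        cycles = detect_cycles(trajectory)
    if drop_startup and len(cycles) > 1:
        cycles = cycles[1:]
    if not cycles:
        raise ValueError("no complete steady-state cycle in trajectory")

    obs = continuous_observables(trajectory)
    t = trajectory.t
    on = (np.asarray(trajectory.neurons["B31B32"]) >= 1)
    dt = float(np.median(np.diff(t)))

    ct, tp, trom, rrom = [], [], [], []
    for t0, t1 in cycles:
        sel = (t >= t0 - 1e-9) & (t < t1 - 1e-9)
        ct.append(t1 - t0)
        tp.append(float(np.sum(on[sel])) * dt)
        trom.append(float(np.ptp(obs["translation_mm"][sel])))
        rrom.append(float(np.ptp(obs["rotation_deg"][sel])))

    cycle_time = float(np.mean(ct))
    time_prot = float(np.mean(tp))
    return CycleMetrics(
        n_cycles=len(cycles),
        cycle_time=cycle_time,
        time_in_protraction=time_prot,
        percent_protraction=100.0 * time_prot / cycle_time,
        translation_ROM_mm=float(np.mean(trom)),
        rotation_ROM_deg=float(np.mean(rrom)),
    )
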