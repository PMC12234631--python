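"""Generalized-force assembly and the quasi-static hybrid integrator.

Because inertia is negligible, the mechanics reduce to first-order
equations ``qdot = Q/c`` per coordinate, with the odontophore rotation
rate absorbing the pin-slot constraint.  The Boolean controller is
evaluated on a fixed control grid (``control_dt``); between ticks the
continuous mechanics and muscle activation filters are integrated with an
adaptive embedded low-order pair (max step 0.1 s, rtol 1e-5, atol 1e-4,
no event detection).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, TYPE_CHECKING

import numpy as np
from scipy.integrate import solve_ivp

from buccalsim.contact import penalty_torque, pin_slot_lambda, theta_g_rate, wall_penalty_force
from buccalsim.controller import FeedingCues, proprioception
from buccalsim.geometry import (
    GeneralizedState,
    Point2,
    hinge_point_x,
    overlap_delta,
    radular_cusp,
    safe_tangent_point,
)
from buccalsim.muscles import (
    MuscleState,
    activation_derivatives,
    hinge_mechanical_advantage,
    i2_wrap_force,
    i3_mechanical_advantage,
    line_force,
    passive_tension,
    total_tension,
)
from buccalsim.seaweed import (
    SeaweedState,
    body_force_sums,
    friction_force,
    grasp_indicator,
    update_seaweed,
)

if TYPE_CHECKING:  # pragma: no cover
    from buccalsim.params import CueProtocol, ModelParams

__all__ = ["DampingParams", "Trajectory", "ForceReport", "generalized_forces",
           "state_derivative", "simulate"]

# re-exported here because damping belongs to the dynamics contract
from buccalsim.params import DampingParams, MUSCLE_ORDER, COORDS  # noqa: E402

N_COORDS = 5  # x_h, x_d, x_v, x_g, theta_g (y_g is algebraic)


@dataclass
class ForceReport:
    """All force components at one instant (model force units).

    x/y components are as applied to the odontophore for grasper-side
    elements; scalar reactions follow the sign conventions of the
    generalized-force sums.
    """

    Q: Dict[str, float]
    element_x: Dict[str, float]
    F_friction_g: float
    F_friction_j: float
    F_seaweed: float
    delta_ingest: int
    jaw_hold: int
    lam: float
    delta: float
    cusp: Point2
    tensions: Dict[str, float]


def _muscle_states(y: np.ndarray) -> Dict[str, MuscleState]:
    out = {}
    for i, mid in enumerate(MUSCLE_ORDER):
        out[mid] = MuscleState(A=y[N_COORDS + 2 * i], T_tilde=y[N_COORDS + 2 * i + 1])
    return out


def generalized_forces(
    gs: GeneralizedState,
    mstates: Mapping[str, MuscleState],
    params: "ModelParams",
    seaweed: SeaweedState,
) -> ForceReport:
    """Assemble the generalized forces Q for every coordinate.

    Raises a diagnostic error naming the offending element if any force
    is non-finite.
    """
    anat = params.anatomy
    mus = params.muscles

    # --- geometry -----------------------------------------------------
    center = gs.center()
    gd = gs.groove_point(anat, dorsal=True)
    gv = gs.groove_point(anat, dorsal=False)
    pd = safe_tangent_point(center, anat.R, gd)
    pv = safe_tangent_point(center, anat.R, gv)
    alpha_d = math.atan2(pd.y - center.y, pd.x - center.x)
    alpha_v = math.atan2(pv.y - center.y, pv.x - center.x)
    x_hinge = hinge_point_x(gs, anat)
    delta = overlap_delta(gs, anat)
    cusp = radular_cusp(gs, anat)
    jaw_d = anat.jaw_anchor(gs.x_h, dorsal=True)
    jaw_v = anat.jaw_anchor(gs.x_h, dorsal=False)

    # element lengths, reusing the tangency points already computed
    sweep = (alpha_v - alpha_d) % (2.0 * math.pi)
    e6_mid = Point2(0.5 * (gs.x_d + gs.x_v), 0.5 * anat.H_lumen)
    e6_anchor = Point2(
        gs.x_h + anat.e6_anchor_rel_head.x, anat.e6_anchor_rel_head.y
    )
    lengths = {
        "I2": (
            math.hypot(pd.x - gd.x, pd.y - gd.y)
            + anat.R * sweep
            + math.hypot(pv.x - gv.x, pv.y - gv.y)
        ),
        "I1d": anat.jaw_x(gs.x_h) - gs.x_d,
        "I1v": anat.jaw_x(gs.x_h) - gs.x_v,
        "hinge": abs(gs.x_v - x_hinge),
        "E1": math.hypot(pd.x - jaw_d.x, pd.y - jaw_d.y),
        "E2": math.hypot(pv.x - jaw_v.x, pv.y - jaw_v.y),
        "E6": math.hypot(e6_mid.x - e6_anchor.x, e6_mid.y - e6_anchor.y),
        "esophagus": math.hypot(gd.x - anat.eso_anchor.x, gd.y - anat.eso_anchor.y),
    }

    # --- tensions -----------------------------------------------------
    T = {}
    for mid in MUSCLE_ORDER:
        spec = mus[mid]
        L = lengths.get(mid)
        T[mid] = total_tension(spec, mstates[mid], L)
    T_eso = passive_tension(params.esophagus, lengths["esophagus"])

    # --- forces on the odontophore ------------------------------------
    # I2 wrap, split into dorsal/ventral end-tension parts
    F_i2d = (T["I2"] * math.sin(alpha_d), -T["I2"] * math.cos(alpha_d))
    F_i2v = (-T["I2"] * math.sin(alpha_v), T["I2"] * math.cos(alpha_v))
    F_i2 = (F_i2d[0] + F_i2v[0], F_i2d[1] + F_i2v[1])

    MA_i3 = i3_mechanical_advantage(delta, anat.R)
    F_i3x = MA_i3 * T["I3"]

    F_e1 = line_force(T["E1"], pd, jaw_d)
    F_e2 = line_force(T["E2"], pv, jaw_v)

    MA_h = hinge_mechanical_advantage(
        gs.x_v, x_hinge, lengths["hinge"], mus["hinge"].L_0, mus["hinge"].L_max
    )
    F_hx = MA_h * T["hinge"]

    FW = wall_penalty_force(gs, anat, params.penalty.k_W)

    # --- friction -----------------------------------------------------
    F_i1d = T["I1d"]
    F_i1v = T["I1v"]
    F_e6 = line_force(T["E6"], e6_mid, e6_anchor)
    F_sp_h = params.head_spring.force(gs.x_h)

    elem_x = {
        "I2": F_i2[0],
        "I3": F_i3x,
        "hinge": F_hx,
        "E1": F_e1[0],
        "E2": F_e2[0],
        "E6": F_e6[0],
        "I1d": F_i1d,
        "I1v": F_i1v,
        "sp_h": F_sp_h,
    }
    sum_g, sum_j = body_force_sums(elem_x)

    P_g = mus["I4"].T_max * max(mstates["I4"].T_tilde, 0.0)
    P_j = mus["I3a"].T_max * max(mstates["I3a"].T_tilde, 0.0)
    if seaweed.effectively_fixed:
        fric = params.friction
        F_fg = friction_force(sum_g, P_g, fric.mu_s_g, fric.mu_k_g)
        F_fj = friction_force(sum_j, P_j, fric.mu_s_j, fric.mu_k_j)
    else:
        F_fg = 0.0
        F_fj = 0.0
    d_ing = grasp_indicator(P_g, mus["I4"].T_max)
    # jaws pinching food (anterior I3) anchor it against transport
    jaw_hold = 1 if P_j > 0.5 * mus["I3a"].T_max else 0

    # --- generalized forces -------------------------------------------
    Q_xg = F_i2[0] + F_i3x + F_e1[0] + F_e2[0] + F_hx + F_fg + FW[0]
    Q_yg = F_i2[1] + F_e1[1] + F_e2[1] + FW[1]

    # torques about the odontophore center (application points: tangency
    # points for I2/E1/E2, hinge point, cusp for grasper friction, the
    # lumen midline for I3; the wall force passes through the center)
    def torque(r: Point2, Fx: float, Fy: float) -> float:
        return (r.x - center.x) * Fy - (r.y - center.y) * Fx

    M_pen = penalty_torque(gs.theta_g, anat, params.penalty.k_pen)
    Q_th = (
        torque(pd, *F_i2d)
        + torque(pv, *F_i2v)
        + torque(pd, *F_e1)
        + torque(pv, *F_e2)
        - (0.5 * anat.H_lumen - gs.y_g) * F_i3x  # applied along the lumen midline
        + gs.y_g * F_hx  # hinge point lies on the slot line y=0
        + -(cusp.y - center.y) * F_fg
        + M_pen
    )

    Q_xd = F_i1d - F_i2d[0] + line_force(T_eso, gd, anat.eso_anchor)[0] + 0.5 * F_e6[0]
    Q_xv = F_i1v - F_i2v[0] - F_hx + 0.5 * F_e6[0] - FW[0]
    Q_xh = (
        F_sp_h + F_fj - F_i1v - F_i1d - F_i3x - F_e1[0] - F_e2[0] - F_e6[0]
    )

    Q = {"x_h": Q_xh, "x_d": Q_xd, "x_v": Q_xv, "x_g": Q_xg,
         "y_g": Q_yg, "theta_g": Q_th}
    for k, v in Q.items():
        if not math.isfinite(v):
            bad = [e for e, f in elem_x.items() if not math.isfinite(f)]
            raise FloatingPointError(
                f"non-finite generalized force Q_{k}"
                + (f" (offending elements: {bad})" if bad else "")
            )

    c_yg = params.damping.c("y_g") * params.time_scale
    thetadot, ydot = theta_g_rate(
        Q_th, Q_yg, gs.theta_g, anat,
        params.damping.c("theta_g") * params.time_scale, c_yg,
    )
    lam = pin_slot_lambda(Q_yg, c_yg, ydot)

    return ForceReport(
        Q=Q,
        element_x=elem_x,
        F_friction_g=F_fg,
        F_friction_j=F_fj,
        F_seaweed=F_fg + F_fj,
        delta_ingest=d_ing,
        jaw_hold=jaw_hold,
        lam=lam,
        delta=delta,
        cusp=cusp,
        tensions=dict(T, esophagus=T_eso),
    )


def state_derivative(
    t: float,
    y: np.ndarray,
    params: "ModelParams",
    N: Mapping[str, int],
    seaweed: SeaweedState,
) -> np.ndarray:
    """Right-hand side of the continuous subsystem (time in seconds)."""
    anat = params.anatomy
    gs = GeneralizedState.from_coords(y[0], y[1], y[2], y[3], y[4], anat)
    mstates = _muscle_states(y)
    rep = generalized_forces(gs, mstates, params, seaweed)

    ts = params.time_scale
    dy = np.empty_like(y)
    dy[0] = rep.Q["x_h"] / (params.damping.c("x_h") * ts)
    dy[1] = rep.Q["x_d"] / (params.damping.c("x_d") * ts)
    dy[2] = rep.Q["x_v"] / (params.damping.c("x_v") * ts)
    dy[3] = rep.Q["x_g"] / (params.damping.c("x_g") * ts)
    thetadot, _ = theta_g_rate(
        rep.Q["theta_g"], rep.Q["y_g"], gs.theta_g, anat,
        params.damping.c("theta_g") * ts, params.damping.c("y_g") * ts,
    )
    dy[4] = thetadot
    for i, mid in enumerate(MUSCLE_ORDER):
        spec = params.muscles[mid]
        n = float(N.get(mid, 0))
        tau_A = spec.tau_activation(n) * ts
        tau_T = spec.tau * ts
        dA, dT = activation_derivatives(mstates[mid], n, tau_A, tau_T)
        dy[N_COORDS + 2 * i] = dA
        dy[N_COORDS + 2 * i + 1] = dT
    return dy


@dataclass
class Trajectory:
    """Densely sampled simulation output (one row per control tick)."""

    t: np.ndarray
    coords: Dict[str, np.ndarray]  # x_h, x_d, x_v, x_g, y_g, theta_g
    muscle_A: Dict[str, np.ndarray]
    muscle_T: Dict[str, np.ndarray]
    neurons: Dict[str, np.ndarray]
    xhat: np.ndarray
    Pg_norm: np.ndarray
    F_seaweed: np.ndarray
    L_ingested: np.ndarray  # model units, ingestion positive
    delta_ingest: np.ndarray
    seaweed_fixed: np.ndarray
    lam: np.ndarray
    params: "ModelParams" = field(repr=False, default=None)

    def constraint_residual(self) -> np.ndarray:
        anat = self.params.anatomy
        return self.coords["y_g"] + anat.R * np.sin(
            self.coords["theta_g"] + anat.theta_H
        )

    def to_dataframe(self):
        import pandas as pd

        data = {"t": self.t}
        data.update({k: v for k, v in self.coords.items()})
        for mid in self.muscle_A:
            data[f"A_{mid}"] = self.muscle_A[mid]
            data[f"T_{mid}"] = self.muscle_T[mid]
        for name, trace in self.neurons.items():
            data[name] = trace
        data["xhat"] = self.xhat
        data["Pg_norm"] = self.Pg_norm
        data["F_seaweed"] = self.F_seaweed
        data["L_ingested"] = self.L_ingested
        data["delta_ingest"] = self.delta_ingest
        data["seaweed_fixed"] = self.seaweed_fixed
        return pd.DataFrame(data)


def _initial_vector(params: "ModelParams") -> np.ndarray:
    y0 = np.zeros(N_COORDS + 2 * len(MUSCLE_ORDER))
    ic = params.initial_coords
    y0[0] = ic.get("x_h", 0.0)
    y0[1] = ic.get("x_d", 0.0)
    y0[2] = ic.get("x_v", 0.0)
    y0[3] = ic.get("x_g", 0.0)
    y0[4] = ic.get("theta_g", 0.0)
    return y0


def simulate(
    params: "ModelParams",
    protocol: "CueProtocol",
    duration: float,
    control_dt: Optional[float] = None,
    rtol: float = 1e-5,
    atol: float = 1e-4,
    max_step: float = 0.1,
) -> Trajectory:
    """Run the closed-loop hybrid simulation for ``duration`` seconds.

    The Boolean network and seaweed boundary state update on the control
    grid; mechanics and activation filters are integrated continuously in
    between.  Fully deterministic.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    dt = control_dt if control_dt is not None else params.control_dt
    n_ticks = int(round(duration / dt))
    anat = params.anatomy
    net = params.network

    y = _initial_vector(params)
    neuron_state = net.initial_state()
    seaweed = SeaweedState()
    current_seg = None
    L_ing = 0.0

    n_rows = n_ticks + 1
    rec_t = np.empty(n_rows)
    rec_y = np.empty((n_rows, y.size))
    rec_neu = {name: np.zeros(n_rows, dtype=int) for name in net.neuron_names}
    rec_xhat = np.empty(n_rows)
    rec_pg = np.empty(n_rows)
    rec_fsw = np.empty(n_rows)
    rec_ling = np.empty(n_rows)
    rec_ding = np.zeros(n_rows, dtype=int)
    rec_fixed = np.zeros(n_rows, dtype=bool)
    rec_lam = np.empty(n_rows)

    prev_cusp_x = None
    for k in range(n_rows):
        t = k * dt
        seg = protocol.at(t)
        if seg is not current_seg:
            # boundary-condition change: reinitialize the seaweed state
            # (a broken strip stays broken only within its own segment)
            seaweed = SeaweedState(
                mode=seg.seaweed_mode,
                breaking_strength=seg.strength,
            )
            current_seg = seg
        cues = seg.cues()

        gs = GeneralizedState.from_coords(y[0], y[1], y[2], y[3], y[4], anat)
        mstates = _muscle_states(y)
        xhat, pg = proprioception(
            gs, anat, mstates["I4"].T_tilde,
            params.muscles["I1v"].L_0, params.muscles["I1d"].L_0,
        )
        bits = net.sensory_bits({"xhat": xhat, "Pg_norm": pg})
        neuron_state = net.step(
            neuron_state, cues, bits,
            extra={"seaweed_fixed": int(seaweed.effectively_fixed)},
        )
        N = net.motor_inputs(neuron_state)

        rep = generalized_forces(gs, mstates, params, seaweed)
        update_seaweed(seaweed, rep.F_seaweed)

        # ingestion bookkeeping: grasped food moves with the radular cusp
        # (ingestion positive as the cusp moves caudally) unless the jaws
        # are pinching it in place or the seaweed is tethered
        if (
            prev_cusp_x is not None
            and rec_ding[k - 1]
            and not rep.jaw_hold
            and not seaweed.effectively_fixed
        ):
            L_ing += -(rep.cusp.x - prev_cusp_x)
        prev_cusp_x = rep.cusp.x

        rec_t[k] = t
        rec_y[k] = y
        for name in net.neuron_names:
            rec_neu[name][k] = neuron_state[name]
        rec_xhat[k] = xhat
        rec_pg[k] = pg
        rec_fsw[k] = rep.F_seaweed
        rec_ding[k] = rep.delta_ingest
        rec_ling[k] = L_ing
        rec_fixed[k] = seaweed.effectively_fixed
        rec_lam[k] = rep.lam

        if k == n_ticks:
            break

        sol = solve_ivp(
            state_derivative,
            (t, t + dt),
            y,
            method="RK23",
            args=(params, N, seaweed),
            rtol=rtol,
            atol=atol,
            max_step=min(max_step, dt),
            dense_output=False,
        )
        if not sol.success:
            raise RuntimeError(
                f"integrator failed at t={t:.3f}s: {sol.message}; "
                f"last state {y}"
            )
        y = sol.y[:, -1]

    coords = {
        "x_h": rec_y[:, 0],
        "x_d": rec_y[:, 1],
        "x_v": rec_y[:, 2],
        "x_g": rec_y[:, 3],
        "theta_g": rec_y[:, 4],
    }
    coords["y_g"] = -anat.R * np.sin(coords["theta_g"] + anat.theta_H)
    muscle_A = {
        mid: rec_y[:, N_COORDS + 2 * i] for i, mid in enumerate(MUSCLE_ORDER)
    }
    muscle_T = {
        mid: rec_y[:, N_COORDS + 2 * i + 1] for i, mid in enumerate(MUSCLE_ORDER)
    }
    return Trajectory(
        t=rec_t,
        coords=coords,
        muscle_A=muscle_A,
        muscle_T=muscle_T,
        neurons=rec_neu,
        xhat=rec_xhat,
        Pg_norm=rec_pg,
        F_seaweed=rec_fsw,
        L_ingested=rec_ling,
        delta_ingest=rec_ding,
        seaweed_fixed=rec_fixed,
        lam=rec_lam,
        params=params,
    )
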