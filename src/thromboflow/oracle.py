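"""Independent well-mixed (0D) integration of the reaction network.

This module is a verification oracle: it re-states the platelet/CF/clot
source network from scratch and integrates it with a stiff-capable adaptive
solver (`scipy.integrate.solve_ivp`, Radau), restarting cleanly at every
threshold-cutoff crossing located by event detection.  It shares nothing
with the PDE transport path except the parameter containers, so agreement
between the two is a genuine cross-check of the reaction implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .closures import CONC_UNIT, ModelParameters, Thresholds
from .errors import InvalidInputError, ThromboflowError

__all__ = ["OracleResult", "ode_oracle"]


@dataclass
class OracleResult:
    """Time series of the well-mixed reaction network."""

    t: np.ndarray
    RPs: np.ndarray
    APs: np.ndarray
    CFs: np.ndarray
    TCs: np.ndarray

    def final(self):
        return self.RPs[-1], self.APs[-1], self.CFs[-1], self.TCs[-1]


def ode_oracle(
    params: ModelParameters | None = None,
    thresholds: Thresholds | None = None,
    *,
    phi_npss: float = 0.0,
    rt_mode: str = "growing",
    rt_value: float = 0.0,
    rps0: float = 475e12,
    aps0: float = 25e12,
    cfs0: float = 0.0,
    tcs0: float = 0.0,
    horizon: float = 10.0,
    rtol: float = 1e-10,
    t_eval: np.ndarray | None = None,
    tc_gate: str = "tcs",
    ap_frac0: float = 1.0,
    cf_release: str = "activation",
) -> OracleResult:
    """Integrate the 0D reaction network under fixed forcings.

    ``phi_npss`` is the (held) shear gating factor; the residence-time
    forcing either grows as RT(t) = rt_value + t (a sealed parcel aging in
    place, ``rt_mode="growing"``) or is held fixed (``rt_mode="fixed"``).

    Gating factors are discontinuous at ``cutoff_fraction`` times each
    threshold, so integration proceeds piecewise between crossings found by
    event detection; each segment restarts the stiff solver.
    """
    params = params or ModelParameters()
    th = thresholds or Thresholds()
    if rtol <= 0:
        raise InvalidInputError("rtol must be > 0")
    if rt_mode not in ("growing", "fixed"):
        raise InvalidInputError(f"unknown rt_mode {rt_mode!r}")
    if tc_gate not in ("tcs", "unity", "ap_fraction"):
        raise InvalidInputError(f"unknown tc_gate {tc_gate!r}")
    if cf_release not in ("activation", "aps_rate"):
        raise InvalidInputError(f"unknown cf_release {cf_release!r}")
    cut = th.cutoff_fraction

    def rt_at(t):
        return rt_value + t if rt_mode == "growing" else rt_value

    def gate(value, threshold):
        return value / threshold if value >= cut * threshold else 0.0

    def rhs(t, y):
        rp, ap, cf, tc = y
        phi_c = gate(cf, th.CF0)
        rp_pos = max(rp, 0.0)
        # RPs >= 0 is an absorbing floor: conversion stops once RPs is spent
        r12 = params.k1 * phi_npss * rp_pos + (
            params.k2 * phi_c * ap if rp > 0.0 else 0.0
        )
        tot = ap + rp_pos
        frac = ap / tot if tot > 0 else 0.0
        if tc_gate == "tcs":
            phi1 = gate(tc, th.TC0)
        elif tc_gate == "unity":
            phi1 = 1.0
        else:
            phi1 = gate(frac, ap_frac0)
        dtc = params.k_TCs * (phi1 * frac + gate(rt_at(t), th.RT0))
        dcf = (params.k_CFs / CONC_UNIT) * (
            r12 if cf_release == "activation" else ap
        )
        return [-r12, r12, dcf, dtc]

    # events: upward crossings of each gate's cutoff
    def ev_cf(t, y):
        return y[2] - cut * th.CF0

    def ev_tc(t, y):
        return y[3] - cut * th.TC0

    def ev_rt(t, y):
        return rt_at(t) - cut * th.RT0

    def ev_rp(t, y):
        return y[0]

    events = [ev_cf]
    if tc_gate == "tcs":
        events.append(ev_tc)
    if rt_mode == "growing":
        events.append(ev_rt)
    for ev in events:
        ev.terminal = True
        ev.direction = 1.0
    ev_rp.terminal = True
    ev_rp.direction = -1.0
    events.append(ev_rp)

    scale = np.array([rps0 + aps0, rps0 + aps0, th.CF0, th.TC0], dtype=float)
    atol = rtol * np.maximum(scale, 1e-30)

    if t_eval is None:
        t_eval = np.linspace(0.0, horizon, 201)
    t_eval = np.asarray(t_eval, dtype=float)

    t0 = 0.0
    y0 = np.array([rps0, aps0, cfs0, tcs0], dtype=float)
    ts = [np.array([0.0])]
    ys = [y0[:, None]]
    restarts = 0
    while t0 < horizon and restarts <= 100:
        seg_eval = t_eval[(t_eval > t0) & (t_eval <= horizon)]
        sol = solve_ivp(
            rhs,
            (t0, horizon),
            y0,
            method="Radau",
            rtol=rtol,
            atol=atol,
            events=events,
            t_eval=seg_eval if len(seg_eval) else None,
            dense_output=True,
        )
        if not sol.success:
            raise ThromboflowError(f"oracle integration failed: {sol.message}")
        if len(sol.t):
            ts.append(sol.t)
            ys.append(sol.y)
        if sol.status == 1:  # a cutoff crossing: restart just past it
            t_ev = min(t[0] for t in sol.t_events if len(t))
            y0 = sol.sol(t_ev)
            # plant the crossed quantity firmly on the active side of its
            # cutoff so the gate is on and the event cannot re-fire
            for y_idx, cutoff in ((2, cut * th.CF0), (3, cut * th.TC0)):
                if abs(y0[y_idx] - cutoff) <= 1e-9 * cutoff:
                    y0[y_idx] = cutoff * (1.0 + 1e-12)
            if abs(y0[0]) <= 1e-9 * (rps0 + aps0):
                y0[1] += y0[0]  # hand the residue to APs, conserving the sum
                # park RPs infinitesimally below zero so the exhaustion
                # event cannot re-fire from an identically-zero signal
                y0[0] = -1e-30 * (rps0 + aps0)
            t0 = t_ev + 1e-12 * max(horizon, 1.0)
            restarts += 1
        else:
            break
    if restarts > 100:
        raise ThromboflowError("oracle exceeded 100 event restarts")

    t_all = np.concatenate(ts)
    y_all = np.concatenate(ys, axis=1)
    order = np.argsort(t_all, kind="stable")
    t_all = t_all[order]
    y_all = y_all[:, order]
    y_all[0] = np.maximum(y_all[0], 0.0)  # report the floored RPs
    return OracleResult(
        t=t_all, RPs=y_all[0], APs=y_all[1], CFs=y_all[2], TCs=y_all[3]
    )
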