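"""Coupled transport of the five thrombosis-model scalars.

The model advects and diffuses residence time (RT), resting and activated
platelets (RPs, APs) and coagulation factors (CFs) over a frozen (or
feedback-coupled) steady flow field, and grows a local clot field (TCs) that
has no transport of its own.  Reaction network, per cell:

    dRPs/dt = -(k1 phi_NPSS RPs + k2 phi_CFs APs)   [while RPs > 0]
    dAPs/dt = +(k1 phi_NPSS RPs + k2 phi_CFs APs)
    dCFs/dt = k_CFs * (RPs -> APs conversion rate)  (agonist release on
              activation; the literal standing-concentration source
              k_CFs * APs is available as ``cf_release="aps_rate"``)
    dTCs/dt = k_TCs phi_TCs APs/(APs+RPs) + k_TCs phi_RT
    dRT/dt  = 1                    (fluid ages at one second per second)

with phi_x the threshold gating factors.  The RPs -> APs transfer shuts off
at RPs = 0 (an absorbing floor): the second exchange term is proportional
to APs, not RPs, so without the floor the network would push RPs negative
and, with release coupled to conversion, diverge.  Transport uses conservative
finite-volume upwind advection and central diffusion; time stepping is
backward-Euler for transport (unconditionally stable; steady states are
dt-independent) with the nonlinear reactions advanced by classical RK4
sub-steps that bisect down onto threshold-cutoff crossings, so the single
well-mixed cell limit reproduces an independent ODE integration to
high accuracy.  An explicit scheme with CFL/Fourier step-size checking is
available via ``scheme="explicit"``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .closures import (
    CONC_UNIT,
    ModelParameters,
    Thresholds,
    cf_effective_diffusivity,
    platelet_diffusivity,
    scalar_shear_stress,
    threshold_factor,
    thrombus_viscosity,
)
from .errors import InvalidInputError, StabilityError
from .flow_fields import FlowField, solve_steady_flow
from .grid import CellKind, StructuredGrid2D

logger = logging.getLogger(__name__)

__all__ = [
    "SpeciesState",
    "SpeciesBCs",
    "TransportControls",
    "TransportStepper",
    "advance_rt",
    "advance_platelets",
    "advance_cfs",
    "advance_tcs",
    "run_to_steady",
]


@dataclass
class SpeciesState:
    """Per-cell fields of the five transported scalars.

    RT in seconds, platelets in 1/m^3, CFs and TCs in nmol/L.
    """

    RT: np.ndarray
    RPs: np.ndarray
    APs: np.ndarray
    CFs: np.ndarray
    TCs: np.ndarray
    t: float = 0.0

    @classmethod
    def fresh(cls, grid: StructuredGrid2D, bcs: "SpeciesBCs") -> "SpeciesState":
        """Domain primed with inlet blood: the natural start of a pump run."""
        shape = (grid.ny, grid.nx)
        open_cells = ~grid.wall

        def fill(v):
            a = np.zeros(shape)
            a[open_cells] = v
            return a

        return cls(
            RT=fill(bcs.inlet_RT),
            RPs=fill(bcs.inlet_RPs),
            APs=fill(bcs.inlet_APs),
            CFs=fill(bcs.inlet_CFs),
            TCs=fill(bcs.inlet_TCs),
        )

    def copy(self) -> "SpeciesState":
        return SpeciesState(
            self.RT.copy(),
            self.RPs.copy(),
            self.APs.copy(),
            self.CFs.copy(),
            self.TCs.copy(),
            self.t,
        )

    def ap_fraction(self) -> np.ndarray:
        tot = self.APs + self.RPs
        return np.divide(self.APs, tot, out=np.zeros_like(tot), where=tot > 0)


@dataclass(frozen=True)
class SpeciesBCs:
    """Inlet values and wall treatment for the transported scalars.

    Defaults are the physiological inlet state: fresh blood of age zero with
    a 5% activated-platelet background (25e12 of 500e12 platelets/m^3), no
    free coagulation factors and no clots.  Outlets and walls are zero-flux,
    except the CFs wall boundary which releases ``k_ceff`` wherever the wall
    shear stress is below 0.2 Pa and the local clot level has not yet reached
    TC0 (low-shear agonist release from the artificial surface).
    """

    inlet_RT: float = 0.0
    inlet_APs: float = 25e12
    inlet_RPs: float = 475e12
    inlet_CFs: float = 0.0
    inlet_TCs: float = 0.0
    cf_wall_flux: bool = True
    cf_wall_sss_max: float = 0.2


@dataclass
class TransportControls:
    """Numerical controls for :func:`run_to_steady`."""

    dt: float | None = None
    horizon: float = 10.0
    steady_tol: float = 1e-4
    feedback: bool = False
    feedback_interval: int = 100
    scheme: str = "implicit"
    cfs_advection: bool = True
    cf_release: str = "activation"  # "activation" | "aps_rate"
    tc_gate: str = "tcs"  # "tcs" | "unity" | "ap_fraction"
    ap_frac0: float = 1.0
    crossing_depth: int = 3
    flow_tol: float = 1e-6
    flow_max_iter: int = 200
    sink_form: str = "brinkman"
    check_every: int = 5


# ---------------------------------------------------------------------------
class _Operator:
    """Conservative advection-diffusion operator on the fluid cells.

    Encodes dc/dt = -A c + r_in with upwind advection from the face fluxes
    and central diffusion; inflow Dirichlet values enter through ``r_in``.
    """

    def __init__(self, grid, flux_x, flux_y, D_cells, inlet_value, advect=True):
        ny, nx = grid.ny, grid.nx
        kind = grid.cell_kind
        fluid = grid.fluid
        self.cells = np.argwhere(fluid)
        self.n = len(self.cells)
        self.Cidx = np.full((ny, nx), -1, dtype=np.int64)
        self.Cidx[fluid] = np.arange(self.n)
        V = grid.cell_volume
        jj, ii = self.cells[:, 0], self.cells[:, 1]

        rows, cols, data = [], [], []
        diag = np.zeros(self.n)
        rin = np.zeros(self.n)

        # outflow-signed flux through each of the four faces of every cell
        face_defs = (
            (+1, 0, flux_x[jj, ii + 1], grid.dy, grid.dx, 0, 1),   # E
            (-1, 0, flux_x[jj, ii], grid.dy, grid.dx, 0, -1),      # W
            (+1, 1, flux_y[jj + 1, ii], grid.dx, grid.dy, 1, 0),   # N
            (-1, 1, flux_y[jj, ii], grid.dx, grid.dy, -1, 0),      # S
        )
        for sgn, _ax, raw_q, area, dist, dj, di in face_defs:
            Q = sgn * raw_q  # > 0 means outflow through this face
            jn = jj + dj
            inn = ii + di
            inside = (jn >= 0) & (jn < ny) & (inn >= 0) & (inn < nx)
            nkind = np.full(self.n, int(CellKind.WALL), dtype=np.int8)
            nkind[inside] = kind[jn[inside], inn[inside]]
            is_fluid = nkind == CellKind.FLUID
            is_inlet = nkind == CellKind.INLET
            is_outlet = nkind == CellKind.OUTLET

            if advect:
                out = (Q > 0) & (is_fluid | is_inlet | is_outlet)
                diag[out] += Q[out] / V
                infl_f = (Q < 0) & is_fluid
                rows.append(np.nonzero(infl_f)[0])
                cols.append(self.Cidx[jn[infl_f], inn[infl_f]])
                data.append(Q[infl_f] / V)
                infl_i = (Q < 0) & is_inlet
                rin[infl_i] += (-Q[infl_i]) * inlet_value / V
                # outlet backflow re-enters at the cell's own value
                back = (Q < 0) & is_outlet
                diag[back] += Q[back] / V

            if D_cells is not None:
                D_P = D_cells[jj, ii]
                coeff = np.zeros(self.n)
                D_N = np.zeros(self.n)
                D_N[is_fluid] = D_cells[jn[is_fluid], inn[is_fluid]]
                cf = 0.5 * (D_P + D_N) * area / (dist * V)
                coeff[is_fluid] = cf[is_fluid]
                diag += np.where(is_fluid, coeff, 0.0)
                rows.append(np.nonzero(is_fluid)[0])
                cols.append(self.Cidx[jn[is_fluid], inn[is_fluid]])
                data.append(-coeff[is_fluid])
                # Dirichlet half-cell exchange with inlet cells
                ci = D_P * area / (0.5 * dist * V)
                diag[is_inlet] += ci[is_inlet]
                rin[is_inlet] += ci[is_inlet] * inlet_value

        rows.append(np.arange(self.n))
        cols.append(np.arange(self.n))
        data.append(diag)
        self.A = sp.coo_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n, self.n),
        ).tocsc()
        self.r_in = rin
        self.diag = diag
        self._lu = {}

    def lu(self, dt):
        key = float(dt)
        if key not in self._lu:
            eye = sp.identity(self.n, format="csc")
            self._lu[key] = spla.splu(eye + dt * self.A)
        return self._lu[key]

    def implicit_step(self, c_cells, dt, source=None):
        rhs = c_cells + dt * self.r_in
        if source is not None:
            rhs = rhs + dt * source
        return self.lu(dt).solve(rhs)

    def explicit_step(self, c_cells, dt, source=None):
        dt_max = self.explicit_dt_max()
        if dt > dt_max:
            raise StabilityError(
                f"explicit step dt={dt:g} exceeds stability bound {dt_max:g}",
                dt=dt,
                dt_max=dt_max,
            )
        out = c_cells + dt * (self.r_in - self.A @ c_cells)
        if source is not None:
            out = out + dt * source
        return out

    def explicit_dt_max(self) -> float:
        """0.8-safety CFL/Fourier bound of the combined upwind operator."""
        m = float(np.max(self.diag, initial=0.0))
        return np.inf if m == 0 else 0.8 / m


# ---------------------------------------------------------------------------
class TransportStepper:
    """One coupled pseudo-time step: implicit transport + RK4 reactions.

    Built for one frozen flow field; rebuilt by :func:`run_to_steady` when
    thrombus feedback re-solves the flow.
    """

    def __init__(
        self,
        grid: StructuredGrid2D,
        flow: FlowField,
        bcs: SpeciesBCs,
        params: ModelParameters,
        thresholds: Thresholds,
        *,
        scheme: str = "implicit",
        cfs_advection: bool = True,
        cf_release: str = "activation",
        tc_gate: str = "tcs",
        ap_frac0: float = 1.0,
        crossing_depth: int = 3,
    ):
        if scheme not in ("implicit", "explicit"):
            raise InvalidInputError(f"unknown scheme {scheme!r}")
        if tc_gate not in ("tcs", "unity", "ap_fraction"):
            raise InvalidInputError(f"unknown tc_gate {tc_gate!r}")
        if cf_release not in ("activation", "aps_rate"):
            raise InvalidInputError(f"unknown cf_release {cf_release!r}")
        self.cf_release = cf_release
        self.grid = grid
        self.flow = flow
        self.bcs = bcs
        self.params = params
        self.th = thresholds
        self.scheme = scheme
        self.tc_gate = tc_gate
        self.ap_frac0 = ap_frac0
        self.crossing_depth = crossing_depth
        self.clip_count = 0
        self._warned_zero_platelets = False

        self.sss = scalar_shear_stress(flow.grad_v, flow.mu_eff)
        self.sss[~grid.fluid] = 0.0
        self.gamma = self.sss / flow.mu_eff
        self.phi_npss = threshold_factor(
            self.sss, thresholds.NPSS0, thresholds.cutoff_fraction
        )
        D_rt = np.full((grid.ny, grid.nx), params.D_RT)
        D_p = platelet_diffusivity(self.sss, flow.mu_eff, params)
        D_c = cf_effective_diffusivity(self.gamma, thresholds, params)
        fx, fy = flow.flux_x, flow.flux_y
        self.op_rt = _Operator(grid, fx, fy, D_rt, bcs.inlet_RT)
        self.op_rp = _Operator(grid, fx, fy, D_p, bcs.inlet_RPs)
        self.op_ap = _Operator(grid, fx, fy, D_p, bcs.inlet_APs)
        self.op_cf = _Operator(
            grid, fx, fy, D_c, bcs.inlet_CFs, advect=cfs_advection
        )
        self.cells = self.op_rt.cells
        self._jj, self._ii = self.cells[:, 0], self.cells[:, 1]
        self._phiN = self.phi_npss[self._jj, self._ii]
        self._wall_cf_base = self._cf_wall_source()

    # -- boundary CF release ------------------------------------------
    def _cf_wall_source(self) -> np.ndarray:
        """Per-cell base wall CF source (nmol/L per s), before the TC gate."""
        if not self.bcs.cf_wall_flux or self.params.k_ceff == 0.0:
            return np.zeros(len(self.cells))
        grid, k = self.grid, self.grid.cell_kind
        ny, nx = grid.ny, grid.nx
        src = np.zeros(len(self.cells))
        sss_c = self.sss[self._jj, self._ii]
        for dj, di, area in (
            (0, 1, grid.dy),
            (0, -1, grid.dy),
            (1, 0, grid.dx),
            (-1, 0, grid.dx),
        ):
            jn = self._jj + dj
            inn = self._ii + di
            inside = (jn >= 0) & (jn < ny) & (inn >= 0) & (inn < nx)
            is_wall = np.where(
                inside, k[np.clip(jn, 0, ny - 1), np.clip(inn, 0, nx - 1)], 1
            ) == int(CellKind.WALL)
            eligible = is_wall & (sss_c < self.bcs.cf_wall_sss_max)
            src[eligible] += self.params.k_ceff * area / grid.cell_volume
        return src

    # -- reaction network ---------------------------------------------
    @staticmethod
    def _gate(value, threshold, cut):
        # unchecked threshold_factor for the hot RK4 path
        return np.where(value >= cut * threshold, value / threshold, 0.0)

    def _rhs(self, y, phiN):
        rt, rp, ap, cf, tc = y
        th, p = self.th, self.params
        cut = th.cutoff_fraction
        cf_gate = self._gate(np.maximum(cf, 0.0), th.CF0, cut)
        rp_pos = np.maximum(rp, 0.0)
        active = rp > 0.0  # absorbing floor: conversion stops when RPs spent
        r12 = p.k1 * phiN * rp_pos + p.k2 * cf_gate * ap * active
        tot = ap + rp_pos
        frac = np.divide(ap, tot, out=np.zeros_like(tot), where=tot > 0)
        if self.tc_gate == "tcs":
            phi1 = self._gate(tc, th.TC0, cut)
        elif self.tc_gate == "unity":
            phi1 = 1.0
        else:
            phi1 = self._gate(frac, self.ap_frac0, cut)
        phi_rt = self._gate(rt, th.RT0, cut)
        dtc = p.k_TCs * (phi1 * frac + phi_rt)
        if self.cf_release == "activation":
            dcf = (p.k_CFs / CONC_UNIT) * r12
        else:
            dcf = (p.k_CFs / CONC_UNIT) * ap
        return np.ones_like(rt), -r12, r12, dcf, dtc

    def _rk4(self, y, phiN, h):
        k1 = self._rhs(y, phiN)
        y2 = tuple(a + 0.5 * h * b for a, b in zip(y, k1))
        k2 = self._rhs(y2, phiN)
        y3 = tuple(a + 0.5 * h * b for a, b in zip(y, k2))
        k3 = self._rhs(y3, phiN)
        y4 = tuple(a + h * b for a, b in zip(y, k3))
        k4 = self._rhs(y4, phiN)
        return tuple(
            a + (h / 6.0) * (b1 + 2 * b2 + 2 * b3 + b4)
            for a, b1, b2, b3, b4 in zip(y, k1, k2, k3, k4)
        )

    def _gate_signature(self, y):
        rt, rp, ap, cf, tc = y
        th = self.th
        cut = th.cutoff_fraction
        sig = [rt >= cut * th.RT0, cf >= cut * th.CF0, rp > 0.0]
        if self.tc_gate == "tcs":
            sig.append(tc >= cut * th.TC0)
        elif self.tc_gate == "ap_fraction":
            tot = ap + rp
            frac = np.divide(ap, tot, out=np.zeros_like(tot), where=tot > 0)
            sig.append(frac >= cut * self.ap_frac0)
        return sig

    def _react(self, y, phiN, h, depth):
        """RK4 step that bisects onto threshold-cutoff crossings, per cell.

        The gating functions are discontinuous at their cutoffs; integrating
        across a crossing with a full step loses accuracy.  The whole field
        is advanced with one RK4 step, then only the cells whose gate
        signature changed are re-integrated recursively over the two half
        steps (down to ``2**-depth`` of the base step), so the cost of sharp
        crossing resolution scales with the number of crossing cells, not
        with the grid.
        """
        y_new = self._rk4(y, phiN, h)
        if depth <= 0:
            return y_new
        sig0 = self._gate_signature(y)
        sig1 = self._gate_signature(y_new)
        changed = np.zeros(np.shape(y[0]), dtype=bool)
        for a, b in zip(sig0, sig1):
            changed |= a != b
        if not np.any(changed):
            return y_new
        y_sub = tuple(np.atleast_1d(a[changed]) for a in y)
        phi_sub = np.atleast_1d(phiN[changed])
        y_half = self._react(y_sub, phi_sub, 0.5 * h, depth - 1)
        y_done = self._react(y_half, phi_sub, 0.5 * h, depth - 1)
        out = tuple(a.copy() for a in y_new)
        for a, b in zip(out, y_done):
            a[changed] = b
        return out

    def _reaction_subcycles(self, y, dt) -> int:
        """Number of RK4 sub-steps keeping max local rate * h <= 1."""
        _rt, rp, ap, cf, _tc = y
        th, p = self.th, self.params
        live = rp > 0
        lam = float(np.max(p.k1 * self._phiN * live, initial=0.0))
        if np.any(live):
            cf_gate = threshold_factor(
                np.maximum(cf, 0.0), th.CF0, th.cutoff_fraction
            )
            lam_k2 = p.k2 * cf_gate * live
            lam_cf = (
                (p.k_CFs / CONC_UNIT) * p.k2 * ap / th.CF0 * (cf_gate > 0) * live
                if self.cf_release == "activation"
                else 0.0
            )
            lam = max(lam, float(np.max(lam_k2 + lam_cf, initial=0.0)))
        return int(np.clip(np.ceil(lam * dt), 1, 400))

    def _clip(self, rp, ap):
        """Repair negative platelet counts while conserving their sum."""
        neg = rp < 0
        if np.any(neg):
            self.clip_count += int(np.count_nonzero(neg))
            ap[neg] += rp[neg]
            rp[neg] = 0.0
        neg = ap < 0
        if np.any(neg):
            self.clip_count += int(np.count_nonzero(neg))
            rp[neg] += ap[neg]
            ap[neg] = 0.0
            np.maximum(rp, 0.0, out=rp)
        return rp, ap

    # -- one full step -------------------------------------------------
    def step(self, state: SpeciesState, dt: float) -> SpeciesState:
        if dt <= 0:
            raise InvalidInputError("dt must be > 0")
        jj, ii = self._jj, self._ii
        y = (
            state.RT[jj, ii],
            state.RPs[jj, ii],
            state.APs[jj, ii],
            state.CFs[jj, ii],
            state.TCs[jj, ii],
        )
        # reactions first (Lie splitting), then transport; the reaction is
        # sub-cycled so the fastest local rate stays well inside the RK4
        # stability region (the CF-activation loop can reach O(100)/s)
        m = self._reaction_subcycles(y, dt)
        h = dt / m
        for _ in range(m):
            y = self._react(y, self._phiN, h, self.crossing_depth)
        rt, rp, ap, cf, tc = y
        rp, ap = self._clip(rp, ap)
        if not self._warned_zero_platelets and np.any((rp + ap) <= 0):
            logger.warning("cells with zero total platelets encountered")
            self._warned_zero_platelets = True

        if self.scheme == "implicit":
            rt = self.op_rt.implicit_step(rt, dt)
            rp = self.op_rp.implicit_step(rp, dt)
            ap = self.op_ap.implicit_step(ap, dt)
            cf = self.op_cf.implicit_step(cf, dt, source=self._cf_source(tc))
        else:
            rt = self.op_rt.explicit_step(rt, dt)
            rp = self.op_rp.explicit_step(rp, dt)
            ap = self.op_ap.explicit_step(ap, dt)
            cf = self.op_cf.explicit_step(cf, dt, source=self._cf_source(tc))
        cf = np.maximum(cf, 0.0)

        out = state.copy()
        out.RT[jj, ii] = np.maximum(rt, 0.0)
        out.RPs[jj, ii] = rp
        out.APs[jj, ii] = ap
        out.CFs[jj, ii] = cf
        out.TCs[jj, ii] = tc
        out.t = state.t + dt
        return out

    def _cf_source(self, tc_cells) -> np.ndarray | None:
        """Wall CF release gated per cell by the local clot level."""
        if not np.any(self._wall_cf_base):
            return None
        return self._wall_cf_base * (tc_cells <= self.th.TC0)


# ---------------------------------------------------------------------------
# Spec-level single-species advance operations (thin wrappers).
def _stepper_for(grid, flow, params, thresholds, scheme, bcs=None):
    return TransportStepper(
        grid,
        flow,
        bcs or SpeciesBCs(),
        params,
        thresholds or Thresholds(),
        scheme=scheme,
    )


def advance_rt(state, flow, grid, params, dt, *, bcs=None, scheme="implicit"):
    """Advance the residence-time field one step (unit source, inlet age 0)."""
    st = _stepper_for(grid, flow, params, Thresholds(), scheme, bcs)
    jj, ii = st._jj, st._ii
    rt = state.RT[jj, ii] + dt  # unit source: fluid ages by dt
    if scheme == "implicit":
        rt = st.op_rt.implicit_step(rt, dt)
    else:
        rt = st.op_rt.explicit_step(rt, dt)
    out = state.copy()
    out.RT[jj, ii] = np.maximum(rt, 0.0)
    out.t = state.t + dt
    return out


def advance_platelets(
    state, flow, sss_field, grid, params, thresholds, dt, *, bcs=None,
    scheme="implicit",
):
    """Advance RPs/APs one step: shear + CF activation transfer, shared D_p."""
    st = _stepper_for(grid, flow, params, thresholds, scheme, bcs)
    if sss_field is not None:
        st.sss = np.asarray(sss_field, float)
        st._phiN = threshold_factor(
            st.sss, thresholds.NPSS0, thresholds.cutoff_fraction
        )[st._jj, st._ii]
    jj, ii = st._jj, st._ii
    rp = state.RPs[jj, ii]
    ap = state.APs[jj, ii]
    cf_gate = threshold_factor(
        state.CFs[jj, ii], thresholds.CF0, thresholds.cutoff_fraction
    )
    rate = params.k1 * st._phiN * rp + params.k2 * cf_gate * ap
    # limit the transfer so RPs cannot cross zero within the step
    transfer = np.minimum(rate * dt, rp)
    st.clip_count += int(np.count_nonzero(rate * dt > rp))
    rp = rp - transfer
    ap = ap + transfer
    if scheme == "implicit":
        rp = st.op_rp.implicit_step(rp, dt)
        ap = st.op_ap.implicit_step(ap, dt)
    else:
        rp = st.op_rp.explicit_step(rp, dt)
        ap = st.op_ap.explicit_step(ap, dt)
    out = state.copy()
    out.RPs[jj, ii] = rp
    out.APs[jj, ii] = ap
    out.t = state.t + dt
    return out


def advance_cfs(
    state, flow, gamma_field, grid, params, thresholds, dt, *, bcs=None,
    scheme="implicit", cfs_advection=True, cf_release="activation",
):
    """Advance CFs one step: release by activation, gated diffusion, wall flux.

    ``cf_release="activation"`` (default) releases k_CFs per converted
    platelet; ``"aps_rate"`` is the literal standing-concentration source
    k_CFs * APs per second.
    """
    st = TransportStepper(
        grid,
        flow,
        bcs or SpeciesBCs(),
        params,
        thresholds,
        scheme=scheme,
        cfs_advection=cfs_advection,
        cf_release=cf_release,
    )
    jj, ii = st._jj, st._ii
    if cf_release == "aps_rate":
        release = (params.k_CFs / CONC_UNIT) * state.APs[jj, ii]
    else:
        rp = state.RPs[jj, ii]
        cf_gate = threshold_factor(
            np.maximum(state.CFs[jj, ii], 0.0),
            thresholds.CF0,
            thresholds.cutoff_fraction,
        )
        r12 = params.k1 * st._phiN * np.maximum(rp, 0.0) + (
            params.k2 * cf_gate * state.APs[jj, ii] * (rp > 0)
        )
        release = (params.k_CFs / CONC_UNIT) * r12
    cf = state.CFs[jj, ii] + dt * release
    src = st._cf_source(state.TCs[jj, ii])
    if scheme == "implicit":
        cf = st.op_cf.implicit_step(cf, dt, source=src)
    else:
        cf = st.op_cf.explicit_step(cf, dt, source=src)
    out = state.copy()
    out.CFs[jj, ii] = np.maximum(cf, 0.0)
    out.t = state.t + dt
    return out


def advance_tcs(
    state, rt_field, grid, params, thresholds, dt, *, tc_gate="tcs",
    ap_frac0=1.0,
):
    """Advance the clot field one local (no-transport) step.

    The clot source is nonnegative, so TCs is monotone nondecreasing.
    """
    if dt <= 0:
        raise InvalidInputError("dt must be > 0")
    fluid = grid.fluid
    rt = np.asarray(rt_field, float)[fluid]
    rp = state.RPs[fluid]
    ap = state.APs[fluid]
    tc = state.TCs[fluid]
    tot = ap + rp
    frac = np.divide(ap, tot, out=np.zeros_like(tot), where=tot > 0)
    if np.any(tot <= 0):
        logger.warning("zero-platelet cells contribute no AP-fraction source")
    if tc_gate == "tcs":
        phi1 = threshold_factor(tc, thresholds.TC0, thresholds.cutoff_fraction)
    elif tc_gate == "unity":
        phi1 = 1.0
    else:
        phi1 = threshold_factor(frac, ap_frac0, thresholds.cutoff_fraction)
    phi_rt = threshold_factor(rt, thresholds.RT0, thresholds.cutoff_fraction)
    out = state.copy()
    out.TCs[fluid] = tc + dt * params.k_TCs * (phi1 * frac + phi_rt)
    out.t = state.t + dt
    return out


# ---------------------------------------------------------------------------
def run_to_steady(
    grid: StructuredGrid2D,
    flow: FlowField,
    bcs: SpeciesBCs | None = None,
    params: ModelParameters | None = None,
    thresholds: Thresholds | None = None,
    controls: TransportControls | None = None,
    state: SpeciesState | None = None,
    inflow=None,
    on_step=None,
):
    """Pseudo-time march all species to steady state (or the horizon).

    RT, RPs, APs and CFs are declared steady when their relative change per
    unit time falls below ``controls.steady_tol``; TCs grows without bound by
    construction, so its growth *rate* must stabilize instead.  With
    ``controls.feedback`` enabled the flow is re-solved every
    ``feedback_interval`` steps using the clot-amplified viscosity and the
    Brinkman sink, rebuilding the transport operators.

    Returns ``(state, report, flow)`` where ``flow`` is the final
    (possibly re-solved) flow field; if the horizon is reached without
    steadiness a warning is issued and the partial state is still returned.
    ``inflow`` (an :class:`InletBC`) is only needed for feedback re-solves.
    """
    bcs = bcs or SpeciesBCs()
    params = params or ModelParameters()
    thresholds = thresholds or Thresholds()
    controls = controls or TransportControls()
    dt = controls.dt if controls.dt is not None else min(0.05, controls.horizon / 200)
    if dt <= 0 or controls.horizon <= 0:
        raise InvalidInputError("dt and horizon must be > 0")
    state = state.copy() if state is not None else SpeciesState.fresh(grid, bcs)

    current_flow = flow
    stepper = TransportStepper(
        grid,
        current_flow,
        bcs,
        params,
        thresholds,
        scheme=controls.scheme,
        cfs_advection=controls.cfs_advection,
        cf_release=controls.cf_release,
        tc_gate=controls.tc_gate,
        ap_frac0=controls.ap_frac0,
        crossing_depth=controls.crossing_depth,
    )
    n_steps = int(np.ceil(controls.horizon / dt))
    prev_tc_rate = None
    steady = False
    history = []
    flow_resolves = 0
    residual = np.inf

    for k in range(1, n_steps + 1):
        new = stepper.step(state, dt)
        if on_step is not None:
            on_step(new, k)
        if controls.feedback and k % controls.feedback_interval == 0:
            phi = threshold_factor(new.TCs, thresholds.TC0, thresholds.cutoff_fraction)
            if np.any(phi > 0):
                mu_eff = thrombus_viscosity(phi, params.mu0)
                current_flow = solve_steady_flow(
                    grid,
                    inflow,
                    mu=mu_eff,
                    phi_tc=phi,
                    params=params,
                    tol=controls.flow_tol,
                    max_iter=controls.flow_max_iter,
                    sink_form=controls.sink_form,
                    warm_start=current_flow,
                )
                flow_resolves += 1
                logger.info(
                    "feedback: flow re-solved at t=%.4g s "
                    "(max phi_TC=%.3f, %d iterations)",
                    new.t,
                    float(np.max(phi)),
                    len(current_flow.residuals),
                )
                stepper = TransportStepper(
                    grid,
                    current_flow,
                    bcs,
                    params,
                    thresholds,
                    scheme=controls.scheme,
                    cfs_advection=controls.cfs_advection,
                    cf_release=controls.cf_release,
                    tc_gate=controls.tc_gate,
                    ap_frac0=controls.ap_frac0,
                    crossing_depth=controls.crossing_depth,
                )
        if k % controls.check_every == 0 or k == n_steps:
            tc_rate = (new.TCs - state.TCs) / dt
            resid = 0.0
            for a_new, a_old in (
                (new.RT, state.RT),
                (new.RPs, state.RPs),
                (new.APs, state.APs),
                (new.CFs, state.CFs),
            ):
                scale = max(float(np.max(np.abs(a_new))), 1e-300)
                resid = max(
                    resid, float(np.max(np.abs(a_new - a_old))) / (dt * scale)
                )
            if prev_tc_rate is not None:
                rate_scale = max(float(np.max(np.abs(tc_rate))), 1e-300)
                resid = max(
                    resid,
                    float(np.max(np.abs(tc_rate - prev_tc_rate))) / (dt * rate_scale)
                    if np.any(tc_rate != 0.0)
                    else 0.0,
                )
            prev_tc_rate = tc_rate
            residual = resid
            history.append((new.t, resid))
            logger.info(
                "t=%.4g s  steady-residual=%.3e  clips=%d",
                new.t,
                resid,
                stepper.clip_count,
            )
            if resid < controls.steady_tol:
                state = new
                steady = True
                break
        state = new

    if not steady:
        warnings.warn(
            f"species march reached horizon t={state.t:g}s without steadiness "
            f"(last residual {residual:.3e}); returning partial state",
            stacklevel=2,
        )
    report = {
        "steady": steady,
        "t_final": state.t,
        "steps": k,
        "dt": dt,
        "residual": residual,
        "residual_history": history,
        "clip_count": stepper.clip_count,
        "flow_resolves": flow_resolves,
    }
    return state, report, current_flow
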