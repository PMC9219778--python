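"""Deterministic surrogate geometries for rotary-blood-pump flow features.

Real centrifugal and axial pumps concentrate their thrombosis risk in a few
recurring flow features: narrow leakage clearances carrying fast shear-laden
secondary flow, recirculation pockets behind steps and vanes, and long
near-wall residence in inlet ducting.  The fixtures here reproduce those
features in desk-scale 2D geometries:

``channel``
    A plane channel whose wall shear stays below the reaction cutoff — the
    null model (no activation, no clots).
``step_recirculation``
    A backward-facing step: near-wall shear in the inlet duct sits between
    the cutoff and the activation threshold (mild activation) and the
    recirculation bubble behind the step retains old blood (long residence).
``gap_jet``
    A pressure-driven clearance: a narrow gap (0.25 mm, the published
    clearance scale) opening into a wider in-plate relief section, giving a
    high-shear jet plus recirculation inside the passage itself.
``combined_surrogate``
    The gap-jet passage followed by a backward-facing expansion, combining
    every modelled mechanism in one domain.

Everything is a deterministic function of the spec: no randomness anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .closures import ModelParameters
from .errors import InvalidInputError
from .flow_fields import (
    FlowField,
    InletBC,
    make_channel_flow,
    solve_steady_flow,
)
from .grid import CellKind, StructuredGrid2D

__all__ = ["FixtureSpec", "Fixture", "generate_fixture"]

_KINDS = ("channel", "step_recirculation", "gap_jet", "combined_surrogate")


@dataclass(frozen=True)
class FixtureSpec:
    """Severity knobs of the surrogate geometries (SI units).

    Only the knobs relevant to ``kind`` are used.  The defaults are the
    shipped study conditions: channel wall shear 2.1 Pa (null), step inlet
    wall shear ~18 Pa (above the 14 Pa cutoff, below the 35 Pa threshold:
    mild activation without igniting the coagulation-factor feedback loop),
    gap driven to a ~2 m/s jet through a 0.25 mm clearance (shear well above
    threshold).
    """

    kind: str = "channel"
    # channel
    channel_height: float = 5e-3
    channel_length: float = 1e-2
    mean_velocity: float = 0.5
    # backward-facing step
    step_inlet_height: float = 5e-4
    step_expansion_ratio: float = 3.0
    step_upstream: float = 1e-3
    step_downstream: float = 7e-3
    step_velocity: float = 0.45
    # gap jet
    gap_width: float = 2.5e-4
    gap_drive_pressure: float = 4000.0
    gap_channel_height: float = 2e-3
    gap_length: float = 8e-3
    gap_plate_start: float = 2e-3
    gap_narrow_length: float = 5e-4
    gap_relief_length: float = 1e-3
    gap_relief_mult: float = 3.0
    # resolution
    dx: float = 1e-4
    dy: float = 5e-5

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise InvalidInputError(
                f"unknown fixture kind {self.kind!r}; choose from {_KINDS}"
            )
        checks = {
            "channel_height": (1e-4, 2e-2),
            "channel_length": (1e-3, 1e-1),
            "mean_velocity": (0.0, 3.0),
            "step_inlet_height": (2e-4, 5e-3),
            "step_expansion_ratio": (1.2, 5.0),
            "step_velocity": (0.0, 2.0),
            "gap_width": (1e-4, 1e-3),
            # down to creeping-flow drives: a pump near standstill is the
            # canonical low-flow thrombosis operating point
            "gap_drive_pressure": (0.1, 2e4),
            "gap_relief_mult": (1.5, 6.0),
            "dx": (1e-5, 1e-3),
            "dy": (1e-5, 1e-3),
        }
        for name, (lo, hi) in checks.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise InvalidInputError(
                    f"{name}={v!r} outside the supported range [{lo}, {hi}]"
                )


@dataclass
class Fixture:
    """A materialized surrogate case: grid, boundary condition, solved flow."""

    spec: FixtureSpec
    grid: StructuredGrid2D
    inflow: InletBC | None
    flow: FlowField
    gap_span: tuple | None = None  # (i0, i2) column span of the clearance
    notes: dict = field(default_factory=dict)

    def through_gap_flux(self, flow: FlowField | None = None) -> float:
        """Volumetric flux (per unit depth) through the clearance throat."""
        if self.gap_span is None:
            raise InvalidInputError("fixture has no gap")
        fl = flow if flow is not None else self.flow
        return float(fl.flux_x[:, self.gap_span[0]].sum())

    def gap_mask(self) -> np.ndarray:
        """Fluid cells of the clearance region (throat, relief and the
        plate-face entry/exit corners where leakage flow stagnates)."""
        if self.gap_span is None:
            raise InvalidInputError("fixture has no gap")
        if self.grid.region_label is not None:
            return (self.grid.region_label == 1) & self.grid.fluid
        m = np.zeros_like(self.grid.fluid)
        m[:, self.gap_span[0] : self.gap_span[1]] = True
        return m & self.grid.fluid


def _channel(spec, params):
    # the null surrogate uses a moderate wall-normal resolution: the age of
    # the discrete wall layer is set by the half-cell sampled velocity
    # (6 U dy / 2h), and the feature-free reference is meaningful only while
    # that layer stays below the residence-time reaction cutoff
    dy = max(spec.dy, 2e-4)
    dx = max(spec.dx, 2e-4)
    ny_fluid = int(round(spec.channel_height / dy))
    nx = int(round(spec.channel_length / dx))
    kind = np.full((ny_fluid + 2, nx), CellKind.FLUID, dtype=np.int8)
    kind[0, :] = CellKind.WALL
    kind[-1, :] = CellKind.WALL
    kind[1:-1, 0] = CellKind.INLET
    kind[1:-1, -1] = CellKind.OUTLET
    grid = StructuredGrid2D(nx, ny_fluid + 2, dx, dy, kind)
    grid.region_label = np.where(grid.fluid, 0, -1)
    flow = make_channel_flow(grid, spec.mean_velocity, params.mu0)
    bc = InletBC(mode="velocity", mean_velocity=spec.mean_velocity)
    return Fixture(spec, grid, bc, flow)


def _step(spec, params, flow_tol, flow_max_iter):
    H = spec.step_inlet_height * spec.step_expansion_ratio
    ny = int(round(H / spec.dy)) + 2
    nx = int(round((spec.step_upstream + spec.step_downstream) / spec.dx))
    kind = np.full((ny, nx), CellKind.FLUID, dtype=np.int8)
    kind[0, :] = CellKind.WALL
    kind[-1, :] = CellKind.WALL
    n_in = int(round(spec.step_inlet_height / spec.dy))
    n_step = ny - 2 - n_in
    i_step = int(round(spec.step_upstream / spec.dx))
    kind[1 : 1 + n_step, :i_step] = CellKind.WALL  # the step block
    kind[1 + n_step : -1, 0] = CellKind.INLET
    kind[1:-1, -1] = CellKind.OUTLET
    grid = StructuredGrid2D(nx, ny, spec.dx, spec.dy, kind)
    labels = np.full((ny, nx), -1, dtype=np.int64)
    labels[:, :i_step] = 0  # inlet duct
    labels[:, i_step : i_step + 3 * n_step] = 1  # recirculation zone
    labels[:, i_step + 3 * n_step :] = 2  # recovery/outlet duct
    grid.region_label = np.where(grid.fluid, labels, -1)
    bc = InletBC(mode="velocity", mean_velocity=spec.step_velocity)
    flow = solve_steady_flow(
        grid, bc, params=params, tol=flow_tol, max_iter=flow_max_iter
    )
    return Fixture(spec, grid, bc, flow)


def _gap_kind(spec):
    """Cell kinds and landmark columns of the gap-jet passage."""
    ny = int(round(spec.gap_channel_height / spec.dy)) + 2
    nx = int(round(spec.gap_length / spec.dx))
    kind = np.full((ny, nx), CellKind.FLUID, dtype=np.int8)
    kind[0, :] = CellKind.WALL
    kind[-1, :] = CellKind.WALL
    i0 = int(round(spec.gap_plate_start / spec.dx))
    i1 = i0 + int(round(spec.gap_narrow_length / spec.dx))
    i2 = i1 + int(round(spec.gap_relief_length / spec.dx))
    jc = ny // 2
    for a, b, width in (
        (i0, i1, spec.gap_width),
        (i1, i2, spec.gap_relief_mult * spec.gap_width),
    ):
        ncell = int(round(width / spec.dy))
        j_lo = jc - ncell // 2
        kind[1:j_lo, a:b] = CellKind.WALL
        kind[j_lo + ncell : -1, a:b] = CellKind.WALL
    return kind, ny, nx, i0, i1, i2


def _gap(spec, params, flow_tol, flow_max_iter):
    kind, ny, nx, i0, i1, i2 = _gap_kind(spec)
    kind[1:-1, 0] = CellKind.INLET
    kind[1:-1, -1] = CellKind.OUTLET
    grid = StructuredGrid2D(nx, ny, spec.dx, spec.dy, kind)
    # the clearance region includes the plate-face corners: the stagnant
    # pockets where leakage flow turns into and out of the throat
    ia, ib = max(i0 - 3, 0), min(i2 + 3, nx)
    labels = np.full((ny, nx), -1, dtype=np.int64)
    labels[:, :ia] = 0  # upstream plenum
    labels[:, ia:ib] = 1  # the clearance passage
    labels[:, ib:] = 2  # downstream expansion
    grid.region_label = np.where(grid.fluid, labels, -1)
    bc = InletBC(mode="pressure", pressure=spec.gap_drive_pressure)
    flow = solve_steady_flow(
        grid, bc, params=params, tol=flow_tol, max_iter=flow_max_iter
    )
    return Fixture(spec, grid, bc, flow, gap_span=(i0, i2))


def _combined(spec, params, flow_tol, flow_max_iter):
    """Gap passage discharging over a backward-facing expansion."""
    kind, ny, nx, i0, i1, i2 = _gap_kind(spec)
    # drop the floor downstream of the plate: extra expansion + pocket
    n_drop = int(round(0.25 * (ny - 2)))
    i3 = i2 + int(round(1e-3 / spec.dx))
    grow = np.zeros((n_drop, nx), dtype=np.int8)
    grow[:, :] = CellKind.WALL
    grow[:, i3:] = CellKind.FLUID
    kind = np.vstack(
        [np.full((1, nx), CellKind.WALL, dtype=np.int8), grow, kind[1:, :]]
    )
    ny = kind.shape[0]
    kind[1:-1, 0] = np.where(
        kind[1:-1, 0] == CellKind.FLUID, CellKind.INLET, kind[1:-1, 0]
    )
    kind[1:-1, -1] = np.where(
        kind[1:-1, -1] == CellKind.FLUID, CellKind.OUTLET, kind[1:-1, -1]
    )
    grid = StructuredGrid2D(nx, ny, spec.dx, spec.dy, kind)
    ia, ib = max(i0 - 3, 0), min(i2 + 3, nx)
    labels = np.full((ny, nx), -1, dtype=np.int64)
    labels[:, :ia] = 0
    labels[:, ia:ib] = 1
    labels[:, ib:] = 2
    grid.region_label = np.where(grid.fluid, labels, -1)
    bc = InletBC(mode="pressure", pressure=spec.gap_drive_pressure)
    flow = solve_steady_flow(
        grid, bc, params=params, tol=flow_tol, max_iter=flow_max_iter
    )
    return Fixture(spec, grid, bc, flow, gap_span=(i0, i2))


def generate_fixture(
    spec: FixtureSpec,
    params: ModelParameters | None = None,
    *,
    flow_tol: float = 1e-6,
    flow_max_iter: int = 200,
) -> Fixture:
    """Materialize a surrogate case: grid + boundary condition + steady flow.

    The channel is analytic (plane Poiseuille); the other kinds are solved.
    The same spec always produces bit-identical output (no randomness).
    """
    params = params or ModelParameters()
    if spec.kind == "channel":
        return _channel(spec, params)
    if spec.kind == "step_recirculation":
        return _step(spec, params, flow_tol, flow_max_iter)
    if spec.kind == "gap_jet":
        return _gap(spec, params, flow_tol, flow_max_iter)
    return _combined(spec, params, flow_tol, flow_max_iter)
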