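"""Steady incompressible 2D flow fields: analytic, solved, or imported.

The flow stage provides the frozen velocity/pressure/viscosity fields on
which the species transport runs, and re-solves them under thrombus feedback
(clot-amplified viscosity plus a Brinkman momentum sink).  Geometries are
desk-scale canonical surrogates — plane channel, orifice gap jet,
backward-facing step, lid-driven cavity — standing in for the narrow
clearances and recirculation pockets of rotary blood pumps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse.linalg as spla

from . import vtk_io
from ._mac import MacSystem
from .closures import ModelParameters
from .errors import ConvergenceError, FormatError, GeometryError, InvalidInputError
from .grid import CellKind, StructuredGrid2D

__all__ = [
    "FlowField",
    "InletBC",
    "make_channel_flow",
    "make_uniform_flow",
    "solve_steady_flow",
    "import_flow_field",
    "export_flow_field",
]


@dataclass
class InletBC:
    """Inflow boundary condition on the inlet cells (column 0).

    mode "velocity": plug or parabolic profile with the given mean velocity.
    mode "pressure": fixed inlet pressure (Pa); the flow rate is then set by
    the resistance of the geometry, so a growing clot can throttle it.
    """

    mode: str = "velocity"
    mean_velocity: float = 0.0
    profile: str = "parabolic"
    pressure: float = 0.0

    def face_values(self, grid: StructuredGrid2D) -> np.ndarray:
        """Inlet-face u per row; parabolae span each contiguous inlet run."""
        uin = np.zeros(grid.ny)
        rows = np.nonzero(grid.cell_kind[:, 0] == CellKind.INLET)[0]
        if len(rows) == 0:
            return uin
        if self.profile == "plug":
            uin[rows] = self.mean_velocity
            return uin
        if self.profile != "parabolic":
            raise InvalidInputError(f"unknown inlet profile {self.profile!r}")
        runs = np.split(rows, np.nonzero(np.diff(rows) > 1)[0] + 1)
        for run in runs:
            h = len(run) * grid.dy
            y0 = run[0] * grid.dy
            y = (run + 0.5) * grid.dy
            s = (y - y0) / h
            uin[run] = 6.0 * self.mean_velocity * s * (1.0 - s)
        return uin


@dataclass
class FlowField:
    """Cell-centered flow state plus face-centered volumetric fluxes.

    ``flux_x[j, i]`` is the volumetric flux (m^3/s per metre of depth)
    through the vertical face left of cell ``(j, i)``; ``flux_y`` likewise
    for horizontal faces.  ``grad_v[j, i]`` is the 2x2 velocity-gradient
    tensor d v_i / d x_j at the cell center.
    """

    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    mu_eff: np.ndarray
    grad_v: np.ndarray
    flux_x: np.ndarray
    flux_y: np.ndarray
    face_u: np.ndarray = field(default=None, repr=False)
    face_v: np.ndarray = field(default=None, repr=False)
    residuals: list = field(default_factory=list, repr=False)
    converged: bool = True

    @property
    def mass_flux(self):
        return self.flux_x, self.flux_y

    def speed(self) -> np.ndarray:
        return np.hypot(self.u, self.v)

    def kinetic_energy(self, grid: StructuredGrid2D, rho: float) -> float:
        """Total kinetic energy per unit depth over fluid cells, J/m."""
        ke = 0.5 * rho * (self.u**2 + self.v**2)
        return float(np.sum(ke[grid.fluid]) * grid.cell_volume)


# ---------------------------------------------------------------------------
def _centered_from_faces(grid, U, V):
    u_c = 0.5 * (U[:, :-1] + U[:, 1:])
    v_c = 0.5 * (V[:-1, :] + V[1:, :])
    open_mask = ~grid.wall
    u_c = np.where(open_mask, u_c, np.where(grid.wall, grid.wall_u, 0.0))
    v_c = np.where(open_mask, v_c, 0.0)
    return u_c, v_c


def _tangential_derivative(fld, wall, wall_value, axis, spacing):
    """Two-point derivative of a cell field along ``axis``.

    Fluid/wall interfaces use the wall value at half a cell (no-slip ghost);
    domain edges along y are treated as walls, edges along x are one-sided.
    """
    ny, nx = fld.shape
    h = spacing

    def _shift(arr, step, fill):
        out = np.full_like(np.asarray(arr, float), fill)
        if axis == 0:
            if step > 0:
                out[:-1] = arr[1:]
            else:
                out[1:] = arr[:-1]
        else:
            if step > 0:
                out[:, :-1] = arr[:, 1:]
            else:
                out[:, 1:] = arr[:, :-1]
        return out

    edge_is_wall = axis == 0
    val_p = _shift(fld, +1, 0.0)
    val_m = _shift(fld, -1, 0.0)
    wall_p = _shift(wall, +1, edge_is_wall).astype(bool)
    wall_m = _shift(wall, -1, edge_is_wall).astype(bool)
    wv_p = _shift(wall_value, +1, 0.0)
    wv_m = _shift(wall_value, -1, 0.0)
    d_p = np.where(wall_p, 0.5 * h, h)
    d_m = np.where(wall_m, 0.5 * h, h)
    val_p = np.where(wall_p, wv_p, val_p)
    val_m = np.where(wall_m, wv_m, val_m)
    if not edge_is_wall:  # one-sided at open x edges
        val_p[:, -1] = fld[:, -1]
        d_p[:, -1] = 0.0
        val_m[:, 0] = fld[:, 0]
        d_m[:, 0] = 0.0
        # avoid 0/0 on single-column grids
        d_p[:, -1] = np.where(d_m[:, -1] == 0.0, h, d_p[:, -1])
        d_m[:, 0] = np.where(d_p[:, 0] == 0.0, h, d_m[:, 0])
    return (val_p - val_m) / (d_p + d_m)


def _gradients(grid, U, V, u_c, v_c):
    """Cell-centered velocity-gradient tensors from MAC faces.

    Normal derivatives come exactly from the face differences; tangential
    derivatives are two-point formulas that honour no-slip at fluid/wall
    interfaces (value ``wall_u`` at half a cell).
    """
    ny, nx = grid.ny, grid.nx
    wall = grid.wall
    g = np.zeros((ny, nx, 2, 2))
    g[:, :, 0, 0] = (U[:, 1:] - U[:, :-1]) / grid.dx  # du/dx
    g[:, :, 1, 1] = (V[1:, :] - V[:-1, :]) / grid.dy  # dv/dy
    wall_u_val = np.where(wall, grid.wall_u, 0.0)
    zeros = np.zeros((ny, nx))
    g[:, :, 0, 1] = _tangential_derivative(u_c, wall, wall_u_val, 0, grid.dy)
    g[:, :, 1, 0] = _tangential_derivative(v_c, wall, zeros, 1, grid.dx)
    g[wall] = 0.0
    return g


def _field_from_faces(grid, U, V, p, mu_c) -> FlowField:
    u_c, v_c = _centered_from_faces(grid, U, V)
    grad = _gradients(grid, U, V, u_c, v_c)
    return FlowField(
        u=u_c,
        v=v_c,
        p=p,
        mu_eff=mu_c.copy(),
        grad_v=grad,
        flux_x=U * grid.dy,
        flux_y=V * grid.dx,
        face_u=U,
        face_v=V,
    )


# ---------------------------------------------------------------------------
def _channel_rows(grid: StructuredGrid2D):
    """Fluid row span of a straight channel; raises if not a channel."""
    kind = grid.cell_kind
    fluid_rows = np.nonzero(np.any(kind == CellKind.FLUID, axis=1))[0]
    if len(fluid_rows) == 0:
        raise GeometryError("no fluid rows")
    j0, j1 = fluid_rows[0], fluid_rows[-1]
    if j0 == 0 or j1 == grid.ny - 1:
        raise GeometryError("channel requires wall rows at top and bottom")
    span = np.arange(j0, j1 + 1)
    interior = kind[j0 : j1 + 1, 1:-1]
    if not np.all(interior == CellKind.FLUID):
        raise GeometryError("channel interior must be all fluid")
    if not (
        np.all(kind[:j0] == CellKind.WALL) and np.all(kind[j1 + 1 :] == CellKind.WALL)
    ):
        raise GeometryError("cells outside the channel span must be walls")
    if not (
        np.all(kind[j0 : j1 + 1, 0] == CellKind.INLET)
        and np.all(kind[j0 : j1 + 1, -1] == CellKind.OUTLET)
    ):
        raise GeometryError(
            "channel requires an inlet column on the left and an outlet "
            "column on the right"
        )
    return span


def make_channel_flow(
    grid: StructuredGrid2D, mean_velocity: float, mu: float
) -> FlowField:
    """Analytic plane-Poiseuille flow through a straight channel grid.

    The parabolic profile with the requested mean velocity is imposed at
    every x-face (hence exactly divergence-free); the wall shear rate is
    ``6 U_mean / h`` for channel height ``h`` and the pressure falls linearly
    at ``dp/dx = -12 mu U_mean / h^2``.
    """
    if mu <= 0:
        raise InvalidInputError("mu must be > 0")
    span = _channel_rows(grid)
    ny, nx = grid.ny, grid.nx
    dy = grid.dy
    h = len(span) * dy
    y0 = span[0] * dy
    y = (np.arange(ny) + 0.5) * dy
    s = np.clip((y - y0) / h, 0.0, 1.0)
    u_profile = 6.0 * mean_velocity * s * (1.0 - s)
    u_profile[: span[0]] = 0.0
    u_profile[span[-1] + 1 :] = 0.0

    U = np.repeat(u_profile[:, None], nx + 1, axis=1)
    V = np.zeros((ny + 1, nx))
    dpdx = -12.0 * mu * mean_velocity / h**2
    x = grid.x_centers()
    p = np.repeat((dpdx * (x - nx * grid.dx))[None, :], ny, axis=0)
    p[~grid.fluid] = 0.0
    mu_c = np.full((ny, nx), mu)

    fieldout = _field_from_faces(grid, U, V, p, mu_c)
    # exact analytic gradient du/dy at cell centers
    dudy = 6.0 * mean_velocity * (1.0 - 2.0 * s) / h
    g = np.zeros((ny, nx, 2, 2))
    g[:, :, 0, 1] = dudy[:, None]
    g[grid.wall] = 0.0
    fieldout.grad_v = g
    return fieldout


def make_uniform_flow(grid: StructuredGrid2D, u0: float) -> FlowField:
    """Synthetic plug flow: uniform x-velocity on every open cell.

    A test/verification surrogate (e.g. the plug-flow residence-time limit);
    gradients are identically zero and walls carry no flux.
    """
    ny, nx = grid.ny, grid.nx
    open_cell = ~grid.wall
    U = np.zeros((ny, nx + 1))
    left_open = np.pad(open_cell, ((0, 0), (1, 0)), constant_values=True)
    right_open = np.pad(open_cell, ((0, 0), (0, 1)), constant_values=True)
    U[left_open & right_open] = u0
    V = np.zeros((ny + 1, nx))
    p = np.zeros((ny, nx))
    mu_c = np.full((ny, nx), ModelParameters().mu0)
    f = _field_from_faces(grid, U, V, p, mu_c)
    f.grad_v = np.zeros((ny, nx, 2, 2))
    return f


# ---------------------------------------------------------------------------
def solve_steady_flow(
    grid: StructuredGrid2D,
    inflow: InletBC | None = None,
    *,
    mu=None,
    phi_tc=None,
    params: ModelParameters | None = None,
    rho: float | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
    relax: float = 0.9,
    sink_form: str = "brinkman",
    warm_start: FlowField | None = None,
) -> FlowField:
    """Steady laminar incompressible flow with optional clot feedback terms.

    Solves the coupled momentum/continuity system by Picard (Oseen)
    iteration with sparse direct inner solves; iterates until the normalized
    nonlinear momentum residual falls below ``tol``.  ``mu`` may be a scalar
    or per-cell effective-viscosity field; ``phi_tc`` is the clot threshold
    factor driving the Brinkman sink ``-k_M phi v``.

    Raises
    ------
    ConvergenceError
        If ``max_iter`` Picard iterations do not reach ``tol``; carries the
        residual history.
    """
    params = params or ModelParameters()
    rho = params.rho if rho is None else float(rho)
    if tol <= 0:
        raise InvalidInputError("tol must be > 0")
    if sink_form not in ("brinkman", "constant"):
        raise InvalidInputError(f"unknown sink_form {sink_form!r}")
    ny, nx = grid.ny, grid.nx
    if mu is None:
        mu_c = np.full((ny, nx), params.mu0)
    elif np.ndim(mu) == 0:
        mu_c = np.full((ny, nx), float(mu))
    else:
        mu_c = np.array(mu, dtype=float)
        if mu_c.shape != (ny, nx):
            raise InvalidInputError("mu field shape must be (ny, nx)")
    if np.any(mu_c[grid.fluid] <= 0):
        raise InvalidInputError("mu must be > 0")
    phi_c = np.zeros((ny, nx)) if phi_tc is None else np.asarray(phi_tc, float).copy()
    phi_c[~grid.fluid] = 0.0

    mode = None
    uin = None
    p_in = 0.0
    if np.any(grid.inlet):
        if inflow is None:
            raise GeometryError("grid has an inlet; an InletBC is required")
        mode = inflow.mode
        if mode == "velocity":
            uin = inflow.face_values(grid)
        elif mode == "pressure":
            p_in = inflow.pressure
        else:
            raise InvalidInputError(f"unknown inflow mode {inflow.mode!r}")

    sys_ = MacSystem(grid, inlet_mode=mode, uin=uin, p_in=p_in)
    U = np.zeros((ny, nx + 1))
    V = np.zeros((ny + 1, nx))
    p = np.zeros((ny, nx))
    if warm_start is not None and warm_start.face_u is not None:
        U[:] = warm_start.face_u
        V[:] = warm_start.face_v
        p[:] = warm_start.p
    sys_.fill_faces(U, V)

    residuals = []
    omega = 1.0
    for it in range(max_iter):
        A, b, _ = sys_.assemble(U, V, mu_c, phi_c, rho, params.k_M, sink_form)
        x_old = sys_.pack(U, V, p)
        r = A @ x_old - b
        nm = sys_.nU + sys_.nV
        diag = A.diagonal()
        denom = float(np.sum(np.abs(diag[:nm] * x_old[:nm])))
        res_m = float(np.sum(np.abs(r[:nm]))) / max(denom, 1e-300)
        res_c = float(np.max(np.abs(r[nm:]), initial=0.0))
        flux_scale = max(float(np.max(np.abs(U))) * grid.dy, 1e-300)
        res = max(res_m if denom > 0 else 0.0, res_c / flux_scale)
        residuals.append(res)
        if it > 0 and res < tol:
            break
        x_new = spla.spsolve(A.tocsc(), b)
        x = omega * x_new + (1.0 - omega) * x_old if it > 0 else x_new
        sys_.unpack(x, U, V, p)
        omega = relax
        if len(residuals) > 3 and residuals[-1] > 4.0 * residuals[-2]:
            omega = max(0.4, omega * 0.6)
    else:
        raise ConvergenceError(
            f"steady flow did not reach tol={tol:g} in {max_iter} iterations "
            f"(last residual {residuals[-1]:.3e})",
            residual_history=residuals,
        )

    out = _field_from_faces(grid, U, V, p, mu_c)
    out.residuals = residuals
    out.converged = True
    return out


# ---------------------------------------------------------------------------
def export_flow_field(path, grid: StructuredGrid2D, flow: FlowField) -> None:
    """Write grid + flow to a legacy-VTK structured-points ASCII file."""
    fields = {
        "velocity": np.stack([flow.u, flow.v], axis=-1),
        "pressure": flow.p,
        "viscosity": flow.mu_eff,
        "cell_kind": grid.cell_kind.astype(float),
    }
    vtk_io.write_structured_points(path, grid.dx, grid.dy, fields)


def import_flow_field(path, grid_spec: StructuredGrid2D | None = None):
    """Read a steady flow field from legacy VTK structured points or CSV.

    Wall cells are taken from a ``cell_kind`` array when present, otherwise
    inferred from exact zero-velocity cells; remaining cells are fluid.
    Velocity gradients are recomputed by central differences, so an exported
    field round-trips to writer precision.
    """
    path = str(path)
    if path.endswith(".csv"):
        dx, dy, fields = vtk_io.read_csv_field(path)
    else:
        dx, dy, fields = vtk_io.read_structured_points(path)
    if "velocity" not in fields:
        raise FormatError(f"{path}: missing 'velocity' array")
    vel = fields["velocity"]
    u_c = vel[..., 0]
    v_c = vel[..., 1]
    ny, nx = u_c.shape
    if grid_spec is not None:
        grid = grid_spec
        if (grid.ny, grid.nx) != (ny, nx):
            raise FormatError(
                f"{path}: grid_spec is {grid.ny}x{grid.nx} cells but file has "
                f"{ny}x{nx}"
            )
    else:
        if "cell_kind" in fields:
            kind = np.rint(fields["cell_kind"]).astype(np.int8)
        else:
            kind = np.where(
                (u_c == 0.0) & (v_c == 0.0), CellKind.WALL, CellKind.FLUID
            ).astype(np.int8)
            if not np.any(kind == CellKind.FLUID):
                raise FormatError(f"{path}: all-zero velocity field")
        grid = StructuredGrid2D(nx, ny, dx, dy, kind)

    # faces by averaging cell-centered values; one-sided at boundaries
    U = np.zeros((ny, nx + 1))
    U[:, 1:-1] = 0.5 * (u_c[:, :-1] + u_c[:, 1:])
    U[:, 0] = u_c[:, 0]
    U[:, -1] = u_c[:, -1]
    V = np.zeros((ny + 1, nx))
    V[1:-1, :] = 0.5 * (v_c[:-1, :] + v_c[1:, :])
    p = fields.get("pressure", np.zeros((ny, nx)))
    mu_c = fields.get("viscosity", np.full((ny, nx), ModelParameters().mu0))

    flow = _field_from_faces(grid, U, V, p, np.asarray(mu_c, float))
    flow.u = u_c
    flow.v = v_c
    # central-difference gradients of the imported centered field
    g = np.zeros((ny, nx, 2, 2))
    g[:, :, 0, 0] = np.gradient(u_c, grid.dx, axis=1)
    g[:, :, 0, 1] = np.gradient(u_c, grid.dy, axis=0)
    g[:, :, 1, 0] = np.gradient(v_c, grid.dx, axis=1)
    g[:, :, 1, 1] = np.gradient(v_c, grid.dy, axis=0)
    g[grid.wall] = 0.0
    flow.grad_v = g
    return grid, flow
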