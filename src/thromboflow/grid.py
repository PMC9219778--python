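"""Rectilinear cell-centered 2D grids with fluid/wall/inlet/outlet labels.

Convention: arrays are indexed ``[j, i]`` with ``j`` the y (row) index
increasing upward and ``i`` the x (column) index; cell centers sit at
``((i + 0.5) dx, (j + 0.5) dy)``, 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .errors import GeometryError, InvalidInputError

__all__ = ["CellKind", "StructuredGrid2D"]


class CellKind(IntEnum):
    FLUID = 0
    WALL = 1
    INLET = 2
    OUTLET = 3


@dataclass
class StructuredGrid2D:
    """Structured cell-centered grid with per-cell type labels.

    Parameters
    ----------
    nx, ny : int
        Cell counts in x and y (each >= 3).
    dx, dy : float
        Cell sizes in metres.
    cell_kind : ndarray of int, shape (ny, nx)
        Per-cell label from :class:`CellKind`.
    region_label : ndarray of int, shape (ny, nx), optional
        Integer region ids for reporting; -1 marks unassigned cells.
    wall_u : ndarray, shape (ny, nx), optional
        Tangential velocity of wall cells (m/s) for moving-wall boundaries
        (e.g. a lid-driven cavity); zero by default.
    """

    nx: int
    ny: int
    dx: float
    dy: float
    cell_kind: np.ndarray
    region_label: np.ndarray | None = None
    wall_u: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.nx < 3 or self.ny < 3:
            raise InvalidInputError("nx and ny must each be >= 3")
        if not (self.dx > 0 and self.dy > 0):
            raise InvalidInputError("dx and dy must be > 0")
        self.cell_kind = np.asarray(self.cell_kind, dtype=np.int8)
        if self.cell_kind.shape != (self.ny, self.nx):
            raise InvalidInputError(
                f"cell_kind shape {self.cell_kind.shape} != (ny, nx) = "
                f"({self.ny}, {self.nx})"
            )
        if not np.any(self.cell_kind == CellKind.FLUID):
            raise GeometryError("grid has no fluid cells")
        if self.wall_u is None:
            self.wall_u = np.zeros((self.ny, self.nx))
        self._check_open_cells_on_boundary()

    def _check_open_cells_on_boundary(self):
        """Inlet/outlet cells must touch the domain boundary or a wall cell."""
        kind = self.cell_kind
        wall = kind == CellKind.WALL
        for label in (CellKind.INLET, CellKind.OUTLET):
            jj, ii = np.nonzero(kind == label)
            for j, i in zip(jj, ii):
                if j in (0, self.ny - 1) or i in (0, self.nx - 1):
                    continue
                neigh = wall[j - 1 : j + 2, i - 1 : i + 2]
                if not neigh.any():
                    raise GeometryError(
                        f"{CellKind(label).name.lower()} cell ({j}, {i}) is "
                        "interior and not adjacent to any wall cell"
                    )

    # -- convenience masks ------------------------------------------------
    @property
    def fluid(self) -> np.ndarray:
        return self.cell_kind == CellKind.FLUID

    @property
    def wall(self) -> np.ndarray:
        return self.cell_kind == CellKind.WALL

    @property
    def inlet(self) -> np.ndarray:
        return self.cell_kind == CellKind.INLET

    @property
    def outlet(self) -> np.ndarray:
        return self.cell_kind == CellKind.OUTLET

    @property
    def cell_volume(self) -> float:
        """Cell volume per unit depth, m^3/m."""
        return self.dx * self.dy

    def x_centers(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.dx

    def y_centers(self) -> np.ndarray:
        return (np.arange(self.ny) + 0.5) * self.dy

    def copy(self) -> "StructuredGrid2D":
        return StructuredGrid2D(
            self.nx,
            self.ny,
            self.dx,
            self.dy,
            self.cell_kind.copy(),
            None if self.region_label is None else self.region_label.copy(),
            self.wall_u.copy(),
        )


def channel_grid(
    nx: int,
    ny_fluid: int,
    dx: float,
    dy: float,
    n_wall: int = 1,
) -> StructuredGrid2D:
    """A straight channel: wall rows top and bottom, inlet left, outlet right."""
    ny = ny_fluid + 2 * n_wall
    kind = np.full((ny, nx), CellKind.FLUID, dtype=np.int8)
    kind[:n_wall, :] = CellKind.WALL
    kind[-n_wall:, :] = CellKind.WALL
    kind[n_wall:-n_wall, 0] = CellKind.INLET
    kind[n_wall:-n_wall, -1] = CellKind.OUTLET
    return StructuredGrid2D(nx, ny, dx, dy, kind)
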