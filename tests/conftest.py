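import numpy as np
import pytest

from thromboflow import (
    CellKind,
    ModelParameters,
    StructuredGrid2D,
    Thresholds,
    channel_grid,
    make_channel_flow,
    make_uniform_flow,
)


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def thresholds():
    return Thresholds()


@pytest.fixture()
def sealed_cell_grid():
    """A single fluid cell surrounded by walls: the 0D well-mixed limit."""
    kind = np.full((3, 3), CellKind.WALL, dtype=np.int8)
    kind[1, 1] = CellKind.FLUID
    return StructuredGrid2D(3, 3, 1e-3, 1e-3, kind)


@pytest.fixture()
def sealed_cell_case(sealed_cell_grid, params):
    """Sealed cell with a forced 35 Pa simple-shear field (phi_NPSS = 1)."""
    flow = make_uniform_flow(sealed_cell_grid, 0.0)
    grad = np.zeros((3, 3, 2, 2))
    grad[1, 1, 0, 1] = 35.0 / params.mu0  # 10,000/s simple shear
    flow.grad_v = grad
    return sealed_cell_grid, flow


def make_cavity(n, lid_speed=1.0):
    """Lid-driven cavity grid: sealed square, moving top wall."""
    kind = np.full((n + 2, n + 2), CellKind.FLUID, dtype=np.int8)
    kind[0, :] = CellKind.WALL
    kind[-1, :] = CellKind.WALL
    kind[:, 0] = CellKind.WALL
    kind[:, -1] = CellKind.WALL
    grid = StructuredGrid2D(n + 2, n + 2, 1.0 / n, 1.0 / n, kind)
    grid.wall_u[-1, :] = lid_speed
    return grid


def make_plug_case(ncells, length=0.1, speed=0.1):
    """1D plug-flow lane (inlet left, outlet right, zero-flux sides)."""
    kind = np.full((3, ncells), CellKind.FLUID, dtype=np.int8)
    kind[:, 0] = CellKind.INLET
    kind[:, -1] = CellKind.OUTLET
    grid = StructuredGrid2D(ncells, 3, length / ncells, 1e-3, kind)
    flow = make_uniform_flow(grid, speed)
    return grid, flow


@pytest.fixture(scope="session")
def null_channel(params):
    """Sub-threshold channel (wall SSS 2.1 Pa): the null model."""
    grid = channel_grid(nx=50, ny_fluid=24, dx=2e-4, dy=5e-3 / 24)
    flow = make_channel_flow(grid, 0.5, params.mu0)
    return grid, flow
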