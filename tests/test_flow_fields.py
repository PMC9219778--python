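"""Flow fields: analytic channel, coupled steady solver, import/export."""

import numpy as np
import pytest

from thromboflow import (
    CellKind,
    InletBC,
    ModelParameters,
    StructuredGrid2D,
    channel_grid,
    export_flow_field,
    import_flow_field,
    make_channel_flow,
    make_uniform_flow,
    scalar_shear_stress,
    solve_steady_flow,
)
from thromboflow.errors import (
    ConvergenceError,
    FormatError,
    GeometryError,
    InvalidInputError,
)

from conftest import make_cavity


def divergence(grid, flow):
    div = (flow.flux_x[:, 1:] - flow.flux_x[:, :-1]) + (
        flow.flux_y[1:, :] - flow.flux_y[:-1, :]
    )
    return np.abs(div[grid.fluid]).max()


class TestChannelFlow:
    def test_poiseuille_profile(self):
        """Wall shear rate 6U/h, centerline 1.5U, linear pressure drop."""
        h, U = 5e-3, 0.5
        grid = channel_grid(nx=40, ny_fluid=32, dx=2.5e-4, dy=h / 32)
        flow = make_channel_flow(grid, U, 0.0035)
        # closed form: wall shear rate 600/s -> wall SSS 2.1 Pa
        assert 6 * U / h == pytest.approx(600.0)
        assert 0.0035 * 6 * U / h == pytest.approx(2.1)
        # the discrete profile approaches those values at half a cell off
        sss = scalar_shear_stress(flow.grad_v, flow.mu_eff)
        assert sss[grid.fluid].max() == pytest.approx(
            2.1 * (1 - grid.dy / h), rel=1e-12
        )
        assert flow.u.max() == pytest.approx(1.5 * U, rel=2e-3)
        assert np.abs(flow.v).max() == 0.0
        assert divergence(grid, flow) < 1e-18
        # mean over a cross-section equals the requested mean velocity
        assert flow.u[grid.fluid].mean() == pytest.approx(U, rel=1e-3)

    def test_zero_velocity_gives_zero_field(self):
        grid = channel_grid(nx=10, ny_fluid=8, dx=1e-4, dy=1e-4)
        flow = make_channel_flow(grid, 0.0, 0.0035)
        assert np.all(flow.u == 0) and np.all(flow.v == 0)

    def test_non_channel_grid_rejected(self):
        grid = make_cavity(8)
        with pytest.raises(GeometryError):
            make_channel_flow(grid, 0.5, 0.0035)


class TestSteadySolver:
    def test_channel_matches_analytic(self, params):
        """Solved channel within 2% of plane Poiseuille at 64x32 cells."""
        grid = channel_grid(nx=64, ny_fluid=32, dx=3.125e-4, dy=5e-3 / 32)
        ana = make_channel_flow(grid, 0.5, params.mu0)
        bc = InletBC(mode="velocity", mean_velocity=0.5, profile="parabolic")
        sol = solve_steady_flow(grid, bc, params=params, tol=1e-6)
        err = np.abs(sol.u - ana.u)[grid.fluid].max() / ana.u.max()
        assert err < 0.02
        assert divergence(grid, sol) < 1e-12
        assert sol.converged

    def test_refinement_reduces_channel_error(self, params):
        """First-order-or-better convergence over three refinements."""
        errs = []
        for ny in (8, 16, 32):
            grid = channel_grid(nx=24, ny_fluid=ny, dx=2e-4, dy=5e-3 / ny)
            ana = make_channel_flow(grid, 0.3, params.mu0)
            bc = InletBC(mode="velocity", mean_velocity=0.3)
            sol = solve_steady_flow(grid, bc, params=params, tol=1e-8)
            errs.append(np.abs(sol.u - ana.u)[grid.fluid].max() / ana.u.max())
        assert errs[0] > 2 * errs[1] > 4 * errs[2]

    def test_cavity_profiles_converge_with_grid(self):
        """Lid cavity at Re=100: coarse vs fine centerline within 3%."""
        pars = ModelParameters(mu0=0.01, rho=1.0)  # Re = U L rho / mu = 100
        profiles = {}
        for n in (32, 64):
            grid = make_cavity(n)
            sol = solve_steady_flow(grid, None, params=pars, tol=1e-6)
            mid = n // 2 + 1
            # u along the vertical centerline; the thin boundary layer at the
            # moving lid is excluded (not resolved at the coarse grid)
            profiles[n] = np.interp(
                np.linspace(0.05, 0.75, 8), grid.y_centers(), sol.u[:, mid]
            )
        assert np.abs(profiles[32] - profiles[64]).max() < 0.03  # of lid speed

    def test_brinkman_sink_slows_flow(self, params):
        """Clot drag in a subregion strictly lowers the local peak velocity.

        A 1 Pa drive keeps the channel genuinely laminar (Re ~ 90) so the
        comparison measures the sink physics, not convection residuals.
        """
        grid = channel_grid(nx=40, ny_fluid=16, dx=2.5e-4, dy=5e-3 / 16)
        bc = InletBC(mode="pressure", pressure=1.0)
        base = solve_steady_flow(grid, bc, params=params, tol=1e-8)
        phi = np.zeros((grid.ny, grid.nx))
        phi[:, 18:22] = 1.0
        clogged = solve_steady_flow(
            grid, bc, params=params, tol=1e-8, phi_tc=phi
        )
        sub = np.zeros_like(grid.fluid)
        sub[:, 18:22] = True
        sub &= grid.fluid
        assert clogged.speed()[sub].max() < base.speed()[sub].max()
        assert clogged.kinetic_energy(grid, params.rho) < base.kinetic_energy(
            grid, params.rho
        )
        # the constant-force (dry-friction-like) sink form also opposes the
        # flow; it is only well-posed while weaker than the pressure driving
        const = solve_steady_flow(
            grid, bc, params=params, tol=1e-8, phi_tc=1e-6 * phi,
            sink_form="constant",
        )
        assert const.kinetic_energy(grid, params.rho) < base.kinetic_energy(
            grid, params.rho
        )

    def test_sink_monotonicity_on_cavity(self):
        """Increasing phi_TC pointwise never increases kinetic energy."""
        pars = ModelParameters(mu0=0.01, rho=1.0)
        grid = make_cavity(16)
        kes = []
        for level in (0.0, 0.5, 1.0):
            phi = np.full((grid.ny, grid.nx), level)
            sol = solve_steady_flow(grid, None, params=pars, tol=1e-6, phi_tc=phi)
            kes.append(sol.kinetic_energy(grid, pars.rho))
        assert kes[0] > kes[1] > kes[2]

    def test_pressure_driven_flow_direction(self, params):
        grid = channel_grid(nx=30, ny_fluid=10, dx=2e-4, dy=2e-4)
        sol = solve_steady_flow(
            grid, InletBC(mode="pressure", pressure=100.0), params=params
        )
        assert sol.flux_x[:, 10].sum() > 0  # flows inlet -> outlet

    def test_nonconvergence_raises_with_history(self, params):
        grid = channel_grid(nx=24, ny_fluid=8, dx=2e-4, dy=2e-4)
        bc = InletBC(mode="velocity", mean_velocity=0.5)
        with pytest.raises(ConvergenceError) as exc:
            solve_steady_flow(grid, bc, params=params, tol=1e-14, max_iter=2)
        assert len(exc.value.residual_history) == 2

    def test_mass_conservation_at_boundaries(self, params):
        grid = channel_grid(nx=32, ny_fluid=12, dx=2e-4, dy=3e-4)
        bc = InletBC(mode="velocity", mean_velocity=0.4)
        sol = solve_steady_flow(grid, bc, params=params, tol=1e-6)
        q_in = sol.flux_x[:, 1].sum()
        q_out = sol.flux_x[:, -2].sum()
        assert q_out == pytest.approx(q_in, rel=1e-9)


class TestImportExport:
    def test_vtk_round_trip(self, tmp_path, params):
        grid = channel_grid(nx=16, ny_fluid=8, dx=2e-4, dy=2e-4)
        flow = make_channel_flow(grid, 0.4, params.mu0)
        path = tmp_path / "field.vtk"
        export_flow_field(path, grid, flow)
        grid2, flow2 = import_flow_field(path)
        assert (grid2.nx, grid2.ny) == (grid.nx, grid.ny)
        np.testing.assert_array_equal(grid2.cell_kind, grid.cell_kind)
        np.testing.assert_allclose(flow2.u, flow.u, rtol=0, atol=1e-16)
        np.testing.assert_allclose(flow2.p, flow.p, rtol=0, atol=1e-12)

    def test_csv_round_trip_and_errors(self, tmp_path):
        import pandas as pd

        # uniform flow: interior gradients must vanish
        x, y = np.meshgrid(np.arange(6) * 1e-3 + 5e-4, np.arange(5) * 1e-3 + 5e-4)
        df = pd.DataFrame(
            {
                "x": x.ravel(),
                "y": y.ravel(),
                "u": np.full(30, 0.25),
                "v": np.zeros(30),
            }
        )
        path = tmp_path / "flow.csv"
        df.to_csv(path, index=False)
        grid, flow = import_flow_field(path)
        assert np.abs(flow.grad_v).max() == 0.0
        df.drop(columns=["v"]).to_csv(path, index=False)
        with pytest.raises(FormatError, match="'v'"):
            import_flow_field(path)

    def test_missing_velocity_named(self, tmp_path):
        from thromboflow import vtk_io

        path = tmp_path / "bad.vtk"
        vtk_io.write_structured_points(path, 1e-4, 1e-4, {"pressure": np.zeros((4, 4))})
        with pytest.raises(FormatError, match="velocity"):
            import_flow_field(path)


class TestGridValidation:
    def test_grid_invariants(self):
        with pytest.raises(InvalidInputError):
            StructuredGrid2D(2, 5, 1e-4, 1e-4, np.zeros((5, 2), dtype=np.int8))
        kind = np.full((5, 5), CellKind.WALL, dtype=np.int8)
        with pytest.raises(GeometryError):
            StructuredGrid2D(5, 5, 1e-4, 1e-4, kind)  # no fluid
        # interior inlet not touching a wall is rejected
        kind = np.full((5, 5), CellKind.FLUID, dtype=np.int8)
        kind[2, 2] = CellKind.INLET
        with pytest.raises(GeometryError):
            StructuredGrid2D(5, 5, 1e-4, 1e-4, kind)
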