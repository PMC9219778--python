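"""Species transport: single-operation contracts, conservation, 0D limit."""

import warnings

import numpy as np
import pytest

from thromboflow import (
    ModelParameters,
    Thresholds,
    channel_grid,
    make_channel_flow,
    make_uniform_flow,
)
from thromboflow.errors import InvalidInputError, StabilityError
from thromboflow.oracle import ode_oracle
from thromboflow.species_transport import (
    SpeciesBCs,
    SpeciesState,
    TransportControls,
    TransportStepper,
    advance_cfs,
    advance_platelets,
    advance_rt,
    advance_tcs,
    run_to_steady,
)

from conftest import make_plug_case


def quiet_run(*args, **kwargs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_to_steady(*args, **kwargs)


class TestResidenceTime:
    def test_sealed_domain_ages_like_clock(self, sealed_cell_case, params):
        """Zero flow, sealed: RT(t) = t everywhere (pure unit source)."""
        grid, flow = sealed_cell_case
        state = SpeciesState.fresh(grid, SpeciesBCs())
        for _ in range(20):
            state = advance_rt(state, flow, grid, params, dt=0.1)
        assert state.RT[1, 1] == pytest.approx(2.0, rel=1e-12)

    def test_plug_flow_outlet_age(self, params, thresholds):
        """Steady outlet RT approaches L/U; upwind error is O(dx)."""
        grid, flow = make_plug_case(64)
        st, rep, _ = quiet_run(
            grid,
            flow,
            SpeciesBCs(),
            params,
            thresholds,
            TransportControls(dt=0.05, horizon=6.0, steady_tol=1e-8, check_every=20),
        )
        assert st.RT[1, -2] == pytest.approx(1.0, abs=2.5 / 64)

    def test_doubling_speed_halves_outlet_age(self, params, thresholds):
        ages = []
        for speed in (0.1, 0.2):
            grid, flow = make_plug_case(48, speed=speed)
            st, _, _ = quiet_run(
                grid,
                flow,
                SpeciesBCs(),
                params,
                thresholds,
                TransportControls(
                    dt=0.05, horizon=6.0, steady_tol=1e-8, check_every=20
                ),
            )
            ages.append(st.RT[1, -2])
        assert ages[0] == pytest.approx(2 * ages[1], rel=0.02)

    def test_explicit_scheme_enforces_stability_bound(self, params):
        grid, flow = make_plug_case(32)
        state = SpeciesState.fresh(grid, SpeciesBCs())
        with pytest.raises(StabilityError):
            advance_rt(state, flow, grid, params, dt=10.0, scheme="explicit")
        # a small explicit step is accepted
        dx_over_u = (0.1 / 32) / 0.1
        advance_rt(state, flow, grid, params, dt=0.1 * dx_over_u, scheme="explicit")


class TestPlatelets:
    def test_exponential_decay_under_threshold_shear(self, sealed_cell_case):
        """phi_NPSS = 1, k2 off: RPs decays as exp(-k1 t)."""
        grid, flow = sealed_cell_case
        params = ModelParameters(k2=1e-30)
        state = SpeciesState.fresh(grid, SpeciesBCs())
        dt = 1e-3
        for _ in range(1000):
            state = advance_platelets(
                state, flow, None, grid, params, Thresholds(), dt
            )
        expected = 475e12 * np.exp(-0.3)
        assert state.RPs[1, 1] == pytest.approx(expected, rel=1e-3)

    def test_no_sources_below_cutoff(self, null_channel, params, thresholds):
        """Sub-threshold shear and CFs: platelet composition unchanged."""
        grid, flow = null_channel
        state = SpeciesState.fresh(grid, SpeciesBCs())
        out = advance_platelets(state, flow, None, grid, params, thresholds, 0.05)
        np.testing.assert_allclose(out.APs[grid.fluid], 25e12, rtol=1e-12)

    def test_total_platelets_conserved_in_sealed_domain(
        self, sealed_cell_case, params, thresholds
    ):
        grid, flow = sealed_cell_case
        state = SpeciesState.fresh(grid, SpeciesBCs())
        stepper = TransportStepper(grid, flow, SpeciesBCs(), params, thresholds)
        total0 = (state.RPs + state.APs)[grid.fluid].sum()
        for _ in range(50):
            state = stepper.step(state, 0.05)
            total = (state.RPs + state.APs)[grid.fluid].sum()
            assert total == pytest.approx(total0, rel=1e-12)


class TestCoagulationFactors:
    def test_no_release_without_activation(self, null_channel, params, thresholds):
        grid, flow = null_channel
        state = SpeciesState.fresh(grid, SpeciesBCs(cf_wall_flux=False))
        out = advance_cfs(state, flow, None, grid, params, thresholds, 0.1,
                          bcs=SpeciesBCs(cf_wall_flux=False))
        assert np.all(out.CFs == 0.0)

    def test_literal_source_grows_linearly(self, sealed_cell_case, thresholds):
        """cf_release='aps_rate': dCFs/dt = k_CFs * APs (per second)."""
        grid, flow = sealed_cell_case
        params = ModelParameters(k1=1e-30, k2=1e-30)  # freeze composition
        bcs = SpeciesBCs(cf_wall_flux=False)
        state = SpeciesState.fresh(grid, bcs)
        ctrl = TransportControls(
            dt=0.01, horizon=1.0, steady_tol=0.0, cf_release="aps_rate",
            check_every=10**9,
        )
        st, _, _ = quiet_run(grid, flow, bcs, params, thresholds, ctrl)
        expected = (params.k_CFs / 1e-6) * 25e12 * 1.0  # nmol/L after 1 s
        assert st.CFs[1, 1] == pytest.approx(expected, rel=1e-6)

    def test_wall_flux_gated_by_shear_and_clots(self, params, thresholds):
        """Walls release k_ceff only below 0.2 Pa and below TC0."""
        from thromboflow import CellKind, StructuredGrid2D

        kind = np.full((3, 3), CellKind.WALL, dtype=np.int8)
        kind[1, 1] = CellKind.FLUID
        grid = StructuredGrid2D(3, 3, 1e-3, 1e-3, kind)
        flow = make_uniform_flow(grid, 0.0)

        def stepper_with_sss(sss_pa):
            grad = np.zeros((3, 3, 2, 2))
            grad[1, 1, 0, 1] = sss_pa / params.mu0
            flow.grad_v = grad
            return TransportStepper(grid, flow, SpeciesBCs(), params, thresholds)

        area_over_v = 4 * 1e-3 / (1e-3 * 1e-3)  # four eligible wall faces
        low = stepper_with_sss(0.1)
        assert low._wall_cf_base[0] == pytest.approx(params.k_ceff * area_over_v)
        high = stepper_with_sss(0.3)
        assert high._wall_cf_base[0] == 0.0
        # the TC <= TC0 gate switches the source off per cell
        assert low._cf_source(np.array([250.0]))[0] == 0.0
        assert low._cf_source(np.array([50.0]))[0] > 0.0


class TestThromboticClots:
    def test_stays_zero_without_seeds(self, null_channel, params, thresholds):
        grid, flow = null_channel
        state = SpeciesState.fresh(grid, SpeciesBCs())
        out = advance_tcs(state, state.RT, grid, params, thresholds, dt=1.0)
        assert np.all(out.TCs == 0.0)

    def test_linear_growth_at_unity_gates(self, sealed_cell_case, params,
                                          thresholds):
        """phi terms pinned at 1: TCs = 2 k_TCs t."""
        grid, _ = sealed_cell_case
        state = SpeciesState.fresh(grid, SpeciesBCs())
        state.APs[1, 1] = 500e12
        state.RPs[1, 1] = 0.0  # AP fraction = 1
        rt = np.full((3, 3), 1.0)  # phi_RT = 1
        for _ in range(10):
            state = advance_tcs(state, rt, grid, params, thresholds, dt=0.1,
                                tc_gate="unity")
        assert state.TCs[1, 1] == pytest.approx(2 * params.k_TCs * 1.0, rel=1e-12)

    def test_monotone_nondecreasing(self, sealed_cell_case, params, thresholds):
        grid, flow = sealed_cell_case
        st, _, _ = quiet_run(
            grid, flow, SpeciesBCs(cf_wall_flux=False), params, thresholds,
            TransportControls(dt=0.05, horizon=3.0, steady_tol=0.0,
                              check_every=10**9),
        )
        prev = st.TCs[1, 1]
        stepper = TransportStepper(
            grid, flow, SpeciesBCs(cf_wall_flux=False), params, thresholds
        )
        for _ in range(20):
            st = stepper.step(st, 0.05)
            assert st.TCs[1, 1] >= prev
            prev = st.TCs[1, 1]


class TestRunToSteady:
    def test_null_channel_steady_state(self, null_channel, params, thresholds):
        """Sub-threshold channel: uniform inlet composition, no CFs, no TCs."""
        grid, flow = null_channel
        st, rep, _ = quiet_run(
            grid, flow, SpeciesBCs(), params, thresholds,
            TransportControls(dt=0.02, horizon=5.0, steady_tol=1e-6,
                              check_every=10),
        )
        assert rep["steady"]
        frac = st.ap_fraction()[grid.fluid]
        np.testing.assert_allclose(frac, 0.05, rtol=1e-9)
        assert np.all(st.TCs == 0.0)
        assert st.CFs.max() < 0.04 * thresholds.CF0  # 10% of the cutoff

    def test_infinite_thresholds_freeze_reactions(self, params):
        """All thresholds huge: the final state is inlet advection only."""
        grid = channel_grid(nx=30, ny_fluid=10, dx=2e-4, dy=5e-5)
        flow = make_channel_flow(grid, 1.0, params.mu0)  # wall SSS 42 Pa
        frozen = Thresholds(RT0=1e12, NPSS0=1e12, gamma0=1e12, CF0=1e12,
                            TC0=1e12)
        st, _, _ = quiet_run(
            grid, flow, SpeciesBCs(), params, frozen,
            TransportControls(dt=0.01, horizon=2.0, steady_tol=1e-6,
                              check_every=10),
        )
        np.testing.assert_allclose(st.ap_fraction()[grid.fluid], 0.05, rtol=1e-9)
        assert np.all(st.TCs == 0.0)
        assert np.all(st.CFs == 0.0)

    def test_zero_d_limit_matches_ode_oracle(self, sealed_cell_case, params,
                                             thresholds):
        """Single-cell PDE run == independent stiff ODE network (2 s)."""
        grid, flow = sealed_cell_case
        bcs = SpeciesBCs(cf_wall_flux=False)
        ctrl = TransportControls(dt=1e-3, horizon=2.0, steady_tol=0.0,
                                 crossing_depth=40, check_every=10**9)
        st, _, _ = quiet_run(grid, flow, bcs, params, thresholds, ctrl)
        orc = ode_oracle(params, thresholds, phi_npss=1.0, rt_mode="growing",
                         horizon=2.0, rtol=1e-11, t_eval=[2.0])
        rp, ap, cf, tc = orc.final()
        scale = 500e12
        assert abs(st.RPs[1, 1] - rp) / scale < 1e-6
        assert abs(st.APs[1, 1] - ap) / scale < 1e-6
        assert abs(st.CFs[1, 1] - cf) / max(abs(cf), 1e-12) < 1e-6
        assert abs(st.TCs[1, 1] - tc) / max(abs(tc), 1e-12) < 1e-6

    def test_horizon_without_steadiness_warns(self, sealed_cell_case, params,
                                              thresholds):
        grid, flow = sealed_cell_case
        with pytest.warns(UserWarning, match="without steadiness"):
            st, rep, _ = run_to_steady(
                grid, flow, SpeciesBCs(), params, thresholds,
                TransportControls(dt=0.1, horizon=0.5, steady_tol=1e-12,
                                  check_every=1),
            )
        assert not rep["steady"]
        assert st.t == pytest.approx(0.5)

    def test_invalid_controls(self, sealed_cell_case, params, thresholds):
        grid, flow = sealed_cell_case
        with pytest.raises(InvalidInputError):
            run_to_steady(grid, flow, controls=TransportControls(dt=-1.0))


class TestOracle:
    def test_closed_form_decay(self, params, thresholds):
        orc = ode_oracle(params, thresholds, phi_npss=1.0, rt_mode="fixed",
                         horizon=1.0, t_eval=[1.0], cf_release="aps_rate")
        # with k2 engaged the decay is faster than pure exp(-k1 t); disable
        p = ModelParameters(k2=1e-30)
        orc = ode_oracle(p, thresholds, phi_npss=1.0, rt_mode="fixed",
                         horizon=1.0, t_eval=[1.0])
        assert orc.RPs[-1] / 475e12 == pytest.approx(np.exp(-0.3), rel=1e-9)

    def test_constant_below_cutoffs(self, params, thresholds):
        orc = ode_oracle(params, thresholds, phi_npss=0.0, rt_mode="fixed",
                         rt_value=0.1, horizon=5.0)
        assert orc.RPs[-1] == pytest.approx(475e12, rel=1e-12)
        assert orc.CFs[-1] == 0.0 and orc.TCs[-1] == 0.0

    def test_full_activation_asymptote(self, params, thresholds):
        """Held shear forcing drives the AP fraction to 1."""
        orc = ode_oracle(params, thresholds, phi_npss=1.0, rt_mode="fixed",
                         horizon=60.0, t_eval=[60.0])
        frac = orc.APs[-1] / (orc.APs[-1] + orc.RPs[-1])
        assert frac > 0.999
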