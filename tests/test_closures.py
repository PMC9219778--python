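"""Algebraic closures: printed calibration points, invariances, validation."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thromboflow import (
    ModelParameters,
    Thresholds,
    cf_effective_diffusivity,
    momentum_sink,
    platelet_diffusivity,
    scalar_shear_stress,
    threshold_factor,
    thrombus_viscosity,
)
from thromboflow.errors import InvalidInputError

MU = 0.0035


def simple_shear(rate):
    g = np.zeros((2, 2))
    g[0, 1] = rate  # du/dy
    return g


class TestScalarShearStress:
    @pytest.mark.parametrize(
        "grad, mu, expected",
        [
            # 10,000/s simple shear <-> 35 Pa calibration point
            (simple_shear(1e4), MU, 35.0),
            (np.zeros((2, 2)), MU, 0.0),
            # planar extension at 1000/s: sigma = 2 mu e = 7 Pa
            (np.diag([1000.0, -1000.0]), MU, 7.0),
            (np.diag([1000.0, -1000.0, 0.0]), MU, 7.0),
        ],
    )
    def test_reference_values(self, grad, mu, expected):
        assert scalar_shear_stress(grad, mu) == pytest.approx(expected, abs=1e-12)

    def test_simple_shear_equals_mu_gamma(self):
        for rate in (1.0, 600.0, 48000.0):
            assert scalar_shear_stress(simple_shear(rate), MU) == pytest.approx(
                MU * rate, rel=1e-14
            )

    @given(
        angle=st.floats(0.0, 2 * np.pi),
        a=st.floats(-1e4, 1e4),
        b=st.floats(-1e4, 1e4),
        c=st.floats(-1e4, 1e4),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_rotation_invariance(self, angle, a, b, c):
        """SSS is a tensor invariant: unchanged by rotating the frame."""
        grad = np.array([[a, b], [c, -a]])  # traceless: incompressible planar
        R = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        rotated = R @ grad @ R.T
        s0 = scalar_shear_stress(grad, MU)
        s1 = scalar_shear_stress(rotated, MU)
        assert s1 == pytest.approx(s0, rel=1e-10, abs=1e-12)

    @given(
        scale=st.floats(1e-3, 1e3),
        rate=st.floats(-1e4, 1e4),
        shear=st.floats(-1e4, 1e4),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_linearity_in_mu_and_gradient(self, scale, rate, shear):
        grad = np.array([[rate, shear], [0.0, -rate]])
        s = scalar_shear_stress(grad, MU)
        assert scalar_shear_stress(grad * scale, MU) == pytest.approx(
            s * scale, rel=1e-10, abs=1e-300
        )
        assert scalar_shear_stress(grad, MU * scale) == pytest.approx(
            s * scale, rel=1e-10, abs=1e-300
        )

    def test_vectorized_over_fields(self):
        grads = np.stack([simple_shear(1e4), np.zeros((2, 2))])
        out = scalar_shear_stress(grads, MU)
        np.testing.assert_allclose(out, [35.0, 0.0], atol=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            scalar_shear_stress(np.full((2, 2), np.nan), MU)
        with pytest.raises(InvalidInputError):
            scalar_shear_stress(np.zeros((2, 2)), 0.0)
        with pytest.raises(InvalidInputError):
            scalar_shear_stress(np.zeros((2, 3)), MU)


class TestThresholdFactor:
    @pytest.mark.parametrize(
        "value, threshold, expected",
        [
            (35.0, 35.0, 1.0),
            (0.0, 35.0, 0.0),
            (10.0, 35.0, 0.0),  # 10 < 0.4 * 35 = 14: reaction stopped
            (14.0, 35.0, 0.4),  # exactly at the cutoff: gate is on
            (70.0, 35.0, 2.0),  # linear above the threshold
        ],
    )
    def test_values(self, value, threshold, expected):
        assert threshold_factor(value, threshold, 0.4) == pytest.approx(expected)

    @given(
        value=st.floats(0.0, 1e6),
        threshold=st.floats(1e-6, 1e6),
        c=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_homogeneity(self, value, threshold, c):
        """phi(c*x, c*x0) == phi(x, x0)."""
        assert threshold_factor(c * value, c * threshold, 0.4) == pytest.approx(
            threshold_factor(value, threshold, 0.4), rel=1e-12, abs=0
        )

    def test_negative_value_rejected(self):
        with pytest.raises(InvalidInputError):
            threshold_factor(-1.0, 35.0, 0.4)
        with pytest.raises(InvalidInputError):
            threshold_factor(1.0, 0.0, 0.4)


class TestDiffusivities:
    def test_platelet_diffusivity(self, params):
        assert platelet_diffusivity(0.0, MU, params) == pytest.approx(1.6e-13)
        # at the 35 Pa threshold the shear enhancement dominates: ~7.0e-9
        assert platelet_diffusivity(35.0, MU, params) == pytest.approx(
            1.6e-13 + 7e-13 * 1e4, rel=1e-12
        )
        p0 = ModelParameters(alpha=1e-300)
        assert p0.D_pt == pytest.approx(
            platelet_diffusivity(100.0, MU, p0), rel=1e-6
        )
        # monotone nondecreasing in shear stress
        vals = platelet_diffusivity(np.linspace(0, 100, 11), MU, params)
        assert np.all(np.diff(vals) >= 0)
        with pytest.raises(InvalidInputError):
            platelet_diffusivity(1.0, 0.0, params)

    def test_cf_effective_diffusivity(self, params, thresholds):
        assert cf_effective_diffusivity(100.0, thresholds, params) == pytest.approx(
            1e-8
        )
        assert cf_effective_diffusivity(0.0, thresholds, params) == 0.0
        assert cf_effective_diffusivity(200.0, thresholds, params) == pytest.approx(
            2e-8
        )
        assert cf_effective_diffusivity(10.0, thresholds, params) == 0.0  # < cutoff


class TestThrombusViscosityAndSink:
    @pytest.mark.parametrize(
        "phi, expected", [(0.0, 0.0035), (1.0, 0.3535), (0.1, 0.0385)]
    )
    def test_viscosity(self, phi, expected):
        assert thrombus_viscosity(phi, MU) == pytest.approx(expected)

    def test_sink(self):
        np.testing.assert_array_equal(
            momentum_sink(0.0, np.array([3.0, -2.0]), 1e7), [0.0, 0.0]
        )
        np.testing.assert_allclose(
            momentum_sink(1.0, np.array([1.0, 0.0]), 1e7), [-1e7, 0.0]
        )
        one = momentum_sink(0.5, np.array([1.0, 2.0]), 1e7)
        two = momentum_sink(0.5, np.array([2.0, 4.0]), 1e7)
        np.testing.assert_allclose(two, 2 * one)
        # always anti-parallel to the velocity
        v = np.array([3.0, -4.0])
        f = momentum_sink(0.7, v, 1e7)
        assert float(np.dot(f, v)) < 0


class TestParameterContainers:
    def test_defaults_are_published_values(self, params, thresholds):
        assert (params.k1, params.k2) == (0.3, 0.1)
        assert params.k_CFs == 3e-17
        assert params.D_RT == 1.14e-11
        assert (params.mu0, params.rho) == (0.0035, 1055.0)
        assert (thresholds.RT0, thresholds.NPSS0) == (1.0, 35.0)
        assert (thresholds.gamma0, thresholds.CF0, thresholds.TC0) == (
            100.0,
            10.0,
            200.0,
        )

    def test_json_round_trip_exact(self, params, thresholds):
        for model in (params, thresholds):
            clone = type(model).model_validate(
                json.loads(model.model_dump_json())
            )
            assert clone == model

    def test_validation(self):
        with pytest.raises(ValueError):
            ModelParameters(k1=-0.1)
        with pytest.raises(ValueError):
            ModelParameters(unknown_rate=1.0)
        with pytest.raises(ValueError):
            Thresholds(cutoff_fraction=1.5)
        ModelParameters(k_ceff=0.0)  # zero wall flux is allowed

    def test_closures_are_pure(self, params, thresholds):
        g = simple_shear(1234.5)
        a = scalar_shear_stress(g, MU)
        b = scalar_shear_stress(g, MU)
        assert a == b  # bit-identical
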