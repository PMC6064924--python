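"""Closed-form flow oracles: dimensionless groups, Poiseuille and Womersley."""

import numpy as np
import pytest

from aortashear.oracles import (
    FluidProperties,
    HarmonicPressureGradient,
    OracleError,
    channel_gradient_for_mean_velocity,
    channel_womersley_velocity,
    channel_womersley_wss_series,
    plane_poiseuille_wss,
    poiseuille_tube_wss,
    reynolds_number,
    tube_gradient_for_mean_velocity,
    waveform_harmonics,
    womersley_number,
    womersley_velocity_profile,
    womersley_wss_series,
)

R = 0.79e-3
D = 1.58e-3
T = 0.1


class TestDimensionlessGroups:
    def test_blood_model_reynolds_number(self, props):
        re = reynolds_number(props, 1.0, D)
        assert re == pytest.approx(487.825, abs=1e-3)
        assert round(re) == 488

    def test_reynolds_zero_flow_and_linearity(self, props):
        assert reynolds_number(props, 0.0, D) == 0.0
        assert reynolds_number(props, 1.0, 2 * D) == pytest.approx(
            2 * reynolds_number(props, 1.0, D)
        )

    def test_womersley_number_default_cycle(self, props):
        alpha = womersley_number(R, 2 * np.pi / T, props)
        assert alpha == pytest.approx(3.48, abs=0.01)

    def test_womersley_steady_limit_and_linearity(self, props):
        assert womersley_number(R, 0.0, props) == 0.0
        assert womersley_number(2 * R, 10.0, props) == pytest.approx(
            2 * womersley_number(R, 10.0, props)
        )

    def test_cgs_units_give_identical_dimensionless_values(self, props):
        cgs = FluidProperties(density_rho=1.235, dynamic_viscosity_eta=0.04)
        assert reynolds_number(cgs, 100.0, 0.158) == pytest.approx(
            reynolds_number(props, 1.0, D), rel=1e-12
        )
        assert womersley_number(0.079, 2 * np.pi / T, cgs) == pytest.approx(
            womersley_number(R, 2 * np.pi / T, props), rel=1e-12
        )

    def test_invalid_parameters_rejected(self, props):
        with pytest.raises(OracleError):
            reynolds_number(props, 1.0, -1.0)
        with pytest.raises(OracleError):
            womersley_number(-R, 1.0, props)
        with pytest.raises(OracleError):
            FluidProperties(density_rho=-1.0)


class TestSteadyWss:
    def test_tube_value_and_linearity(self, props):
        assert poiseuille_tube_wss(props, 0.1, R) == pytest.approx(2.025, abs=1e-3)
        assert poiseuille_tube_wss(props, 0.0, R) == 0.0
        assert poiseuille_tube_wss(props, 0.2, R) == pytest.approx(
            2 * poiseuille_tube_wss(props, 0.1, R)
        )

    def test_plane_value_and_inverse_height(self, props):
        assert plane_poiseuille_wss(props, 0.1, D) == pytest.approx(1.519, abs=1e-3)
        assert plane_poiseuille_wss(props, 0.0, D) == 0.0
        assert plane_poiseuille_wss(props, 0.1, D / 2) == pytest.approx(
            2 * plane_poiseuille_wss(props, 0.1, D)
        )

    def test_invalid_geometry_rejected(self, props):
        with pytest.raises(OracleError):
            poiseuille_tube_wss(props, 0.1, 0.0)
        with pytest.raises(OracleError):
            plane_poiseuille_wss(props, 0.1, -1.0)


class TestWomersleySeries:
    def test_steady_gradient_gives_constant_poiseuille_shear(self, props):
        grad = HarmonicPressureGradient(1000.0, (), T)
        _, tau = womersley_wss_series(grad, R, props, 64)
        assert np.allclose(tau, 1000.0 * R / 2)
        _, tau_ch = channel_womersley_wss_series(grad, D, props, 64)
        assert np.allclose(tau_ch, 1000.0 * D / 2)

    def test_low_alpha_quasi_steady_limit(self, props):
        # alpha <= 0.3: inertia negligible, tau(t) tracks G(t)*R/2
        omega = (0.3 / R) ** 2 * props.kinematic_viscosity
        period = 2 * np.pi / omega
        grad = HarmonicPressureGradient(100.0, [(30.0, 0.7)], period)
        t, tau = womersley_wss_series(grad, R, props, 128)
        quasi = grad(t) * R / 2
        assert np.max(np.abs(tau - quasi) / np.abs(quasi)) < 0.02

    @pytest.mark.parametrize("harmonics", [
        [(3000.0, 0.3)],
        [(3000.0, 0.3), (1000.0, -1.0), (500.0, 2.2)],
    ])
    def test_tube_shear_matches_profile_differentiation(self, props, harmonics):
        grad = HarmonicPressureGradient(2000.0, harmonics, T)
        t, tau = womersley_wss_series(grad, R, props, 64)
        scale = np.max(np.abs(tau))
        h = R * 1e-6
        for k in range(0, 64, 7):
            r = np.array([R - 2 * h, R - h, R])
            u = womersley_velocity_profile(grad, R, props, r, t[k])
            dudr = (3 * u[2] - 4 * u[1] + u[0]) / (2 * h)
            assert abs(-props.dynamic_viscosity_eta * dudr - tau[k]) < 1e-3 * scale

    def test_channel_shear_matches_profile_differentiation(self, props):
        grad = HarmonicPressureGradient(2000.0, [(3000.0, 0.3), (800.0, 1.1)], T)
        t, tau = channel_womersley_wss_series(grad, D, props, 64)
        scale = np.max(np.abs(tau))
        d = D * 1e-6
        for k in range(0, 64, 7):
            y = np.array([-D / 2, -D / 2 + d, -D / 2 + 2 * d])
            u = channel_womersley_velocity(grad, D, props, y, t[k])
            dudy = (-3 * u[0] + 4 * u[1] - u[2]) / (2 * d)
            assert abs(props.dynamic_viscosity_eta * dudy - tau[k]) < 1e-3 * scale

    def test_time_mean_equals_steady_component(self, props):
        grad = HarmonicPressureGradient(1500.0, [(4000.0, 0.4), (2000.0, -0.9)], T)
        _, tau = womersley_wss_series(grad, R, props, 512)
        assert abs(tau.mean() - 1500.0 * R / 2) < 1e-3 * abs(1500.0 * R / 2)

    def test_linearity_in_driving_amplitude(self, props):
        g1 = HarmonicPressureGradient(1000.0, [(2000.0, 0.5)], T)
        g2 = HarmonicPressureGradient(3000.0, [(6000.0, 0.5)], T)
        _, t1 = womersley_wss_series(g1, R, props, 64)
        _, t2 = womersley_wss_series(g2, R, props, 64)
        assert np.allclose(t2, 3.0 * t1, rtol=1e-12)

    def test_extreme_alpha_rejected(self, props):
        grad = HarmonicPressureGradient(0.0, [(1000.0, 0.0)], 1e-9)
        with pytest.raises(OracleError, match="out of supported range"):
            womersley_wss_series(grad, R, props, 64)


class TestGradientConversion:
    """Velocity-waveform -> pressure-gradient transfer functions."""

    @pytest.mark.parametrize("convert,geom", [
        (channel_gradient_for_mean_velocity, "channel"),
        (tube_gradient_for_mean_velocity, "tube"),
    ])
    def test_roundtrip_recovers_mean_velocity_waveform(self, props, convert, geom):
        target_mean, target_harms = 0.1, [(0.03, 0.4), (0.01, -1.2)]
        size = D if geom == "channel" else R
        grad = convert(target_mean, target_harms, size, props, T)
        # reconstruct the cross-sectional mean velocity numerically
        n = 512
        t = np.arange(n) * (T / n)
        if geom == "channel":
            y = np.linspace(-D / 2, D / 2, 4001)
            ubar = np.array(
                [np.trapezoid(channel_womersley_velocity(grad, D, props, y, tt), y) / D
                 for tt in t]
            )
        else:
            r = np.linspace(0, R, 4001)
            ubar = np.array(
                [2 * np.trapezoid(womersley_velocity_profile(grad, R, props, r, tt) * r, r) / R**2
                 for tt in t]
            )
        mean, harms = waveform_harmonics(ubar, 2)
        assert mean == pytest.approx(target_mean, rel=1e-4)
        for (amp, ph), (ta, tp) in zip(harms, target_harms):
            assert amp == pytest.approx(ta, rel=1e-3)
            assert (ph - tp + np.pi) % (2 * np.pi) - np.pi == pytest.approx(0.0, abs=1e-3)
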