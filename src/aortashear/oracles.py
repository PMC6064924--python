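"""Closed-form laminar flow solutions used to validate the solver and metrics.

All solutions assume an incompressible Newtonian fluid in a rigid conduit —
the same model the unsteady solver discretizes — so they serve as exact
oracles for the solver's wall shear stress.  Covered are steady Poiseuille
flow in a tube and a plane channel, and the pulsatile Womersley solution for
both geometries, driven by a harmonic decomposition of the axial pressure
gradient.

Conventions
-----------
The driving gradient is expressed as ``P(t) = -dp/dx`` with

    P(t) = G0 + sum_n A_n * cos(n*omega*t + phi_n),   omega = 2*pi/T,

and wall shear stress is the flow-direction viscous traction on the wall
(positive when the near-wall fluid moves in +x).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import jv


class OracleError(ValueError):
    """Invalid physical parameter or out-of-range oracle request."""


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid constants of the blood model.

    Defaults are the murine blood model used throughout: density
    ``rho = 1235 kg/m^3`` and dynamic viscosity ``eta = 0.004 Pa*s``.
    """

    density_rho: float = 1235.0
    dynamic_viscosity_eta: float = 0.004

    def __post_init__(self) -> None:
        if self.density_rho <= 0 or self.dynamic_viscosity_eta <= 0:
            raise OracleError("density and viscosity must be positive")

    @property
    def kinematic_viscosity(self) -> float:
        return self.dynamic_viscosity_eta / self.density_rho


@dataclass(frozen=True)
class HarmonicPressureGradient:
    """Harmonic decomposition of the negative axial pressure gradient.

    ``harmonics[n-1] = (amplitude_Pa_per_m, phase_rad)`` for the n-th
    multiple of the fundamental angular frequency ``2*pi/period_T``.
    """

    mean_component: float
    harmonics: tuple = field(default_factory=tuple)
    period_T: float = 0.1

    def __post_init__(self) -> None:
        if self.period_T <= 0:
            raise OracleError("period_T must be positive")
        h = tuple((float(a), float(p)) for a, p in self.harmonics)
        object.__setattr__(self, "harmonics", h)
        if not all(np.isfinite(a) and np.isfinite(p) for a, p in h):
            raise OracleError("harmonic amplitudes/phases must be finite")

    @property
    def omega(self) -> float:
        return 2.0 * np.pi / self.period_T

    def complex_amplitudes(self) -> np.ndarray:
        """Complex amplitude C_n with P(t) = G0 + sum Re[C_n e^{i n w t}]."""
        return np.array([a * np.exp(1j * p) for a, p in self.harmonics], dtype=complex)

    def __call__(self, t) -> np.ndarray:
        """Evaluate P(t)."""
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, self.mean_component)
        for n, (a, p) in enumerate(self.harmonics, start=1):
            out = out + a * np.cos(n * self.omega * t + p)
        return out


def reynolds_number(props: FluidProperties, speed_V: float, diameter_D: float) -> float:
    """Re = rho*V*D/eta.  ``speed_V`` may be zero (quiescent limit)."""
    if speed_V < 0 or diameter_D <= 0:
        raise OracleError("speed must be >= 0 and diameter positive")
    return props.density_rho * speed_V * diameter_D / props.dynamic_viscosity_eta


def womersley_number(radius_R: float, angular_freq_omega: float, props: FluidProperties) -> float:
    """alpha = R * sqrt(omega * rho / eta)."""
    if radius_R <= 0 or angular_freq_omega < 0:
        raise OracleError("radius must be positive and omega >= 0")
    return radius_R * np.sqrt(angular_freq_omega * props.density_rho / props.dynamic_viscosity_eta)


def poiseuille_tube_wss(props: FluidProperties, mean_velocity_U: float, radius_R: float) -> float:
    """Wall shear magnitude 4*eta*U/R of fully developed tube flow."""
    if radius_R <= 0:
        raise OracleError("radius must be positive")
    return 4.0 * props.dynamic_viscosity_eta * mean_velocity_U / radius_R


def plane_poiseuille_wss(props: FluidProperties, mean_velocity_U: float, height_h: float) -> float:
    """Wall shear magnitude 6*eta*U/h of fully developed plane-channel flow."""
    if height_h <= 0:
        raise OracleError("height must be positive")
    return 6.0 * props.dynamic_viscosity_eta * mean_velocity_U / height_h


_ALPHA_MAX = 500.0  # complex Bessel/cosh arguments overflow beyond this


def _tube_beta(n: int, omega: float, nu: float) -> complex:
    # beta^2 = -i n omega / nu  (J0(beta r) satisfies the unsteady Stokes operator)
    return np.sqrt(-1j * n * omega / nu)


def womersley_wss_series(
    grad: HarmonicPressureGradient,
    radius_R: float,
    props: FluidProperties,
    n_times: int = 256,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact wall-shear time series of pulsatile tube (Womersley) flow.

    Returns ``(times, tau)`` at ``n_times`` uniform points spanning one
    period (endpoint-exclusive).  Each pressure-gradient harmonic
    contributes the classical Womersley profile; the mean component
    contributes the steady Poiseuille shear ``G0*R/2``.
    """
    if n_times < 8:
        raise OracleError("n_times must be >= 8")
    if radius_R <= 0:
        raise OracleError("radius must be positive")
    nu = props.kinematic_viscosity
    omega = grad.omega
    t = np.arange(n_times) * (grad.period_T / n_times)
    tau = np.full(n_times, grad.mean_component * radius_R / 2.0)
    for n, C in enumerate(grad.complex_amplitudes(), start=1):
        alpha_n = womersley_number(radius_R, n * omega, props)
        if alpha_n > _ALPHA_MAX:
            raise OracleError(f"Womersley number {alpha_n:.1f} out of supported range")
        beta = _tube_beta(n, omega, nu)
        z = beta * radius_R
        # tau_hat = -eta * d(u_hat)/dr at r=R
        tau_hat = (
            -props.dynamic_viscosity_eta
            * (C / (1j * props.density_rho * n * omega))
            * beta
            * jv(1, z)
            / jv(0, z)
        )
        tau = tau + np.real(tau_hat * np.exp(1j * n * omega * t))
    return t, tau


def womersley_velocity_profile(
    grad: HarmonicPressureGradient,
    radius_R: float,
    props: FluidProperties,
    r: np.ndarray,
    t: float,
) -> np.ndarray:
    """Axial velocity u(r, t) of pulsatile tube flow (for differentiation checks)."""
    r = np.asarray(r, dtype=float)
    nu = props.kinematic_viscosity
    omega = grad.omega
    u = grad.mean_component * (radius_R**2 - r**2) / (4.0 * props.dynamic_viscosity_eta)
    for n, C in enumerate(grad.complex_amplitudes(), start=1):
        beta = _tube_beta(n, omega, nu)
        u_hat = (C / (1j * props.density_rho * n * omega)) * (
            1.0 - jv(0, beta * r) / jv(0, beta * radius_R)
        )
        u = u + np.real(u_hat * np.exp(1j * n * omega * t))
    return u


def channel_womersley_wss_series(
    grad: HarmonicPressureGradient,
    height_h: float,
    props: FluidProperties,
    n_times: int = 256,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact wall-shear series of pulsatile plane-channel flow.

    The plane-channel analogue of the Womersley solution: per harmonic the
    profile is ``(C/(i rho n w)) * (1 - cosh(g y)/cosh(g a))`` with
    ``g = sqrt(i n w / nu)`` and half-height ``a = h/2``.  Returns the
    flow-direction shear at the wall, ``(times, tau)``.
    """
    if n_times < 8:
        raise OracleError("n_times must be >= 8")
    if height_h <= 0:
        raise OracleError("height must be positive")
    a = height_h / 2.0
    nu = props.kinematic_viscosity
    omega = grad.omega
    t = np.arange(n_times) * (grad.period_T / n_times)
    tau = np.full(n_times, grad.mean_component * a)
    for n, C in enumerate(grad.complex_amplitudes(), start=1):
        alpha_n = womersley_number(a, n * omega, props)
        if alpha_n > _ALPHA_MAX:
            raise OracleError(f"Womersley number {alpha_n:.1f} out of supported range")
        g = np.sqrt(1j * n * omega / nu)
        tau_hat = (
            props.dynamic_viscosity_eta
            * (C / (1j * props.density_rho * n * omega))
            * g
            * np.tanh(g * a)
        )
        tau = tau + np.real(tau_hat * np.exp(1j * n * omega * t))
    return t, tau


def channel_womersley_velocity(
    grad: HarmonicPressureGradient,
    height_h: float,
    props: FluidProperties,
    y: np.ndarray,
    t: float,
) -> np.ndarray:
    """Axial velocity u(y, t), with ``y`` measured from the channel centerline."""
    y = np.asarray(y, dtype=float)
    a = height_h / 2.0
    nu = props.kinematic_viscosity
    omega = grad.omega
    u = grad.mean_component * (a**2 - y**2) / (2.0 * props.dynamic_viscosity_eta)
    for n, C in enumerate(grad.complex_amplitudes(), start=1):
        g = np.sqrt(1j * n * omega / nu)
        u_hat = (C / (1j * props.density_rho * n * omega)) * (
            1.0 - np.cosh(g * y) / np.cosh(g * a)
        )
        u = u + np.real(u_hat * np.exp(1j * n * omega * t))
    return u


def channel_gradient_for_mean_velocity(
    mean_U: float,
    velocity_harmonics,
    height_h: float,
    props: FluidProperties,
    period_T: float,
) -> HarmonicPressureGradient:
    """Pressure-gradient harmonics producing a target mean-velocity waveform.

    ``velocity_harmonics`` are ``(amplitude m/s, phase rad)`` pairs of the
    cross-sectionally averaged velocity; each is converted through the exact
    per-harmonic transfer function ``u_bar_n = (C_n/(i rho n w)) *
    (1 - tanh(g a)/(g a))`` of plane-channel pulsatile flow.
    """
    if height_h <= 0:
        raise OracleError("height must be positive")
    a = height_h / 2.0
    nu = props.kinematic_viscosity
    omega = 2.0 * np.pi / period_T
    G0 = 3.0 * props.dynamic_viscosity_eta * mean_U / a**2
    harms = []
    for n, (amp, phase) in enumerate(velocity_harmonics, start=1):
        g = np.sqrt(1j * n * omega / nu)
        transfer = (1.0 - np.tanh(g * a) / (g * a)) / (1j * props.density_rho * n * omega)
        C = (amp * np.exp(1j * phase)) / transfer
        harms.append((abs(C), float(np.angle(C))))
    return HarmonicPressureGradient(G0, tuple(harms), period_T)


def tube_gradient_for_mean_velocity(
    mean_U: float,
    velocity_harmonics,
    radius_R: float,
    props: FluidProperties,
    period_T: float,
) -> HarmonicPressureGradient:
    """Tube analogue of :func:`channel_gradient_for_mean_velocity`."""
    if radius_R <= 0:
        raise OracleError("radius must be positive")
    nu = props.kinematic_viscosity
    omega = 2.0 * np.pi / period_T
    G0 = 8.0 * props.dynamic_viscosity_eta * mean_U / radius_R**2
    harms = []
    for n, (amp, phase) in enumerate(velocity_harmonics, start=1):
        beta = _tube_beta(n, omega, nu)
        z = beta * radius_R
        transfer = (1.0 - 2.0 * jv(1, z) / (z * jv(0, z))) / (
            1j * props.density_rho * n * omega
        )
        C = (amp * np.exp(1j * phase)) / transfer
        harms.append((abs(C), float(np.angle(C))))
    return HarmonicPressureGradient(G0, tuple(harms), period_T)


def waveform_harmonics(values: np.ndarray, n_harmonics: int) -> tuple[float, list]:
    """Harmonic decomposition of a uniformly sampled periodic signal.

    Returns ``(mean, [(amplitude, phase), ...])`` such that
    ``v(t) ~= mean + sum_n amp_n cos(n w t + phi_n)`` where the samples are
    assumed to span exactly one period, endpoint-exclusive.
    """
    values = np.asarray(values, dtype=float)
    N = values.size
    if n_harmonics >= N // 2:
        raise OracleError("n_harmonics must be < n_samples/2")
    spec = np.fft.rfft(values) / N
    mean = float(np.real(spec[0]))
    harms = [(2.0 * abs(spec[n]), float(np.angle(spec[n]))) for n in range(1, n_harmonics + 1)]
    return mean, harms
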