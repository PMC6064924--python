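"""Periodic inlet velocity waveforms and cubic Bezier spline fits.

The inlet boundary condition of the flow solver is a periodic velocity
waveform v(t) with cardiac-cycle period ``T``.  Measured waveforms arrive as
sampled time/velocity tables; for use in the solver they are approximated by
a composite third-order (cubic) Bezier spline with C0 continuity at segment
joins and periodic closure v(0) = v(T).

Within each segment the control-point *times* sit at the uniform thirds of
the segment, so the time component of the Bezier curve is linear in the
Bernstein parameter ``u`` and the spline is an explicit function of time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np


class WaveformError(ValueError):
    """Invalid waveform data or fit request."""


@dataclass(frozen=True)
class SampledWaveform:
    """A periodic velocity waveform sampled within one cycle.

    Parameters
    ----------
    times : array of float
        Sample times in seconds, strictly increasing, all in ``[0, period_T)``.
    velocities : array of float
        Velocities in m/s at the sample times.
    period_T : float
        Cycle time T in seconds.  The waveform is treated as T-periodic.
    """

    times: np.ndarray
    velocities: np.ndarray
    period_T: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.velocities, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "velocities", v)
        if self.period_T <= 0:
            raise WaveformError("period_T must be positive")
        if t.ndim != 1 or v.shape != t.shape:
            raise WaveformError("times and velocities must be 1-D arrays of equal length")
        if t.size < 4:
            raise WaveformError("need at least 4 samples")
        if not np.all(np.diff(t) > 0):
            raise WaveformError("sample times must be strictly increasing")
        if t[0] < 0 or t[-1] >= self.period_T:
            raise WaveformError("sample times must lie in [0, period_T)")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise WaveformError("samples must be finite")

    @classmethod
    def from_csv(cls, path, period_T: float) -> "SampledWaveform":
        """Read a 2-column CSV (``time_s``, ``velocity_m_s``) with a header row."""
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), period_T)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"time_s": self.times, "velocity_m_s": self.velocities}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class BezierWaveform:
    """Composite periodic cubic Bezier spline v(t).

    ``segments`` is an array of shape ``(n_segments, 4, 2)``; each segment
    holds 4 control points ``(time, velocity)``.  Segment k spans
    ``[k*T/n, (k+1)*T/n]`` with control times at the uniform thirds, segment
    endpoints chain continuously and the last endpoint equals the first
    (periodic closure).
    """

    segments: np.ndarray
    period_T: float
    fit_residual_rms: float = field(default=float("nan"), compare=False)

    def __post_init__(self) -> None:
        seg = np.asarray(self.segments, dtype=float)
        object.__setattr__(self, "segments", seg)
        if self.period_T <= 0:
            raise WaveformError("period_T must be positive")
        if seg.ndim != 3 or seg.shape[1:] != (4, 2):
            raise WaveformError("segments must have shape (n_segments, 4, 2)")
        n = seg.shape[0]
        dt = self.period_T / n
        tol = 1e-9 * self.period_T
        for k in range(n):
            t0 = k * dt
            expect = t0 + dt * np.arange(4) / 3.0
            if np.max(np.abs(seg[k, :, 0] - expect)) > max(tol, 1e-12):
                raise WaveformError("control-point times must sit at uniform segment thirds")
        # C0 chaining and periodic closure on the velocity component
        v_end = seg[:, 3, 1]
        v_start = np.roll(seg[:, 0, 1], -1)
        scale = max(np.max(np.abs(seg[:, :, 1])), 1.0)
        if np.max(np.abs(v_end - v_start)) > 1e-9 * scale:
            raise WaveformError("segments must chain continuously and close periodically")
        if not np.all(np.isfinite(seg)):
            raise WaveformError("control points must be finite")

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]

    def __call__(self, t):
        return evaluate_waveform(self, t)

    def to_json(self) -> str:
        return json.dumps(
            {
                "period_T": self.period_T,
                "segments": self.segments.tolist(),
                "fit_residual_rms": None
                if np.isnan(self.fit_residual_rms)
                else self.fit_residual_rms,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "BezierWaveform":
        d = json.loads(text)
        res = d.get("fit_residual_rms")
        return cls(
            np.asarray(d["segments"]),
            d["period_T"],
            float("nan") if res is None else res,
        )


def _bernstein3(u: np.ndarray) -> np.ndarray:
    """Cubic Bernstein basis, shape (..., 4)."""
    u = np.asarray(u, dtype=float)
    w = 1.0 - u
    return np.stack([w**3, 3 * w**2 * u, 3 * w * u**2, u**3], axis=-1)


def fit_bezier_waveform(samples: SampledWaveform, n_segments: int) -> BezierWaveform:
    """Least-squares fit of a periodic composite cubic Bezier spline.

    The spline has ``n_segments`` cubic segments on uniform knots.  Free
    parameters are the join velocities and the two inner control velocities
    of each segment (3*n_segments unknowns); C0 continuity and periodic
    closure are built into the parameterization, so they hold exactly.

    Returns a :class:`BezierWaveform` whose ``fit_residual_rms`` attribute
    holds the root-mean-square residual to the samples.
    """
    if n_segments < 1:
        raise WaveformError("n_segments must be >= 1")
    t = samples.times
    v = samples.velocities
    if t.size < 3 * n_segments:
        raise WaveformError(
            f"under-determined fit: {t.size} samples for {3 * n_segments} parameters "
            f"({n_segments} segments); supply >= {4 * n_segments} samples"
        )
    T = samples.period_T
    dt = T / n_segments
    seg_idx = np.minimum((t // dt).astype(int), n_segments - 1)
    u = (t - seg_idx * dt) / dt
    B = _bernstein3(u)

    # Parameter vector: [v_0..v_{n-1} (join values), c1_0, c2_0, ..., c1_{n-1}, c2_{n-1}]
    n_par = 3 * n_segments
    A = np.zeros((t.size, n_par))
    rows = np.arange(t.size)
    A[rows, seg_idx] += B[:, 0]  # P0 = join k
    A[rows, (seg_idx + 1) % n_segments] += B[:, 3]  # P3 = join k+1 (periodic)
    A[rows, n_segments + 2 * seg_idx] += B[:, 1]
    A[rows, n_segments + 2 * seg_idx + 1] += B[:, 2]

    coef, *_ = np.linalg.lstsq(A, v, rcond=None)
    resid = A @ coef - v
    rms = float(np.sqrt(np.mean(resid**2)))

    joins = coef[:n_segments]
    inner = coef[n_segments:].reshape(n_segments, 2)
    segs = np.zeros((n_segments, 4, 2))
    for k in range(n_segments):
        t0 = k * dt
        segs[k, :, 0] = t0 + dt * np.arange(4) / 3.0
        segs[k, 0, 1] = joins[k]
        segs[k, 1, 1] = inner[k, 0]
        segs[k, 2, 1] = inner[k, 1]
        segs[k, 3, 1] = joins[(k + 1) % n_segments]
    return BezierWaveform(segs, T, fit_residual_rms=rms)


def evaluate_waveform(w: BezierWaveform, t) -> np.ndarray | float:
    """Evaluate the spline at time ``t`` (scalar or array), T-periodically."""
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    tm = np.mod(t_arr, w.period_T)
    n = w.n_segments
    dt = w.period_T / n
    k = np.minimum((tm // dt).astype(int), n - 1)
    u = (tm - k * dt) / dt
    B = _bernstein3(u)
    vals = np.einsum("...j,...j->...", B, w.segments[k, :, 1])
    return float(vals) if scalar else vals


def scale_waveform(w: BezierWaveform, factor: float) -> BezierWaveform:
    """Scale all control-point velocities by ``factor`` (> 0); times unchanged."""
    if factor <= 0:
        raise WaveformError("scale factor must be positive")
    seg = w.segments.copy()
    seg[:, :, 1] *= factor
    return BezierWaveform(seg, w.period_T, fit_residual_rms=w.fit_residual_rms)


def waveform_mean(w: BezierWaveform, n: int = 4096) -> float:
    """Cycle-mean velocity by uniform quadrature (periodic trapezoid)."""
    tt = np.arange(n) * (w.period_T / n)
    return float(np.mean(evaluate_waveform(w, tt)))
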