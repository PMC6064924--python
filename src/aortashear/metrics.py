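"""Wall-shear-stress metrics: TAWSS, OSI and transWSS.

Each metric is a cycle integral of the instantaneous wall shear stress
vector tau(t) at one surface point:

* ``TAWSS = (1/T) int_0^T |tau| dt`` — time-averaged shear magnitude (Pa);
* ``OSI = 0.5 * (1 - |tau_mean| / TAWSS)`` with
  ``tau_mean = (1/T) int_0^T tau dt`` — 0 for unidirectional shear, 0.5 for
  pure zero-mean oscillation;
* ``transWSS = (1/T) int_0^T |tau . (n x tau_mean/|tau_mean|)| dt`` — mean
  absolute shear component perpendicular to the mean shear direction within
  the wall tangent plane (Pa); requires 3-D vectors and the outward wall
  normal ``n``.

Integrals are evaluated by periodic trapezoidal quadrature on the uniform
time grid, which reduces to the arithmetic mean of the samples and is
spectrally accurate for smooth periodic signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EPS_TAWSS = 1e-12  # Pa; below this the shear is treated as zero
EPS_MEAN = 1e-12  # Pa; below this the mean-shear direction is degenerate


class RecordError(ValueError):
    """Invalid wall-shear record."""


class MetricUndefinedError(ValueError):
    """Metric not defined for this record (e.g. transWSS on 2-D vectors)."""


@dataclass(frozen=True)
class WallShearRecord:
    """One surface point's WSS vector time series over one cycle.

    ``times`` must be a uniform grid spanning one period, endpoint-exclusive
    (``times[k] = t0 + k*T/n``); ``tau_vectors`` has shape ``(n_times, d)``
    with d = 2 or 3.  For 3-D records the vectors must lie in the wall
    tangent plane of the unit ``outward_normal``.
    """

    point_id: int
    position: np.ndarray
    outward_normal: np.ndarray
    region_label: str
    times: np.ndarray
    tau_vectors: np.ndarray
    period_T: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        tau = np.asarray(self.tau_vectors, dtype=float)
        n = np.asarray(self.outward_normal, dtype=float)
        pos = np.asarray(self.position, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "tau_vectors", tau)
        object.__setattr__(self, "outward_normal", n)
        object.__setattr__(self, "position", pos)
        if t.ndim != 1 or t.size < 8:
            raise RecordError("need at least 8 uniform time samples")
        if self.period_T <= 0:
            raise RecordError("period_T must be positive")
        dt = self.period_T / t.size
        if np.max(np.abs(np.diff(t) - dt)) > 1e-9 * self.period_T:
            raise RecordError("times must be uniform spanning one period, endpoint-exclusive")
        if tau.shape != (t.size, n.size) or n.size not in (2, 3):
            raise RecordError("tau_vectors must be (n_times, d) with d = normal dimension in {2,3}")
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise RecordError("outward_normal must have unit length")
        if not (np.all(np.isfinite(tau)) and np.all(np.isfinite(t))):
            raise RecordError("record values must be finite")
        if n.size == 3:
            mags = np.linalg.norm(tau, axis=1)
            dots = np.abs(tau @ n)
            bad = dots > 1e-6 * np.maximum(mags, EPS_TAWSS)
            if np.any(bad & (mags > EPS_TAWSS)):
                raise RecordError("3-D tau vectors must be tangential to the wall")

    @property
    def n_times(self) -> int:
        return self.times.size

    @property
    def is_3d(self) -> bool:
        return self.outward_normal.size == 3


def mean_wss_vector(rec: WallShearRecord) -> np.ndarray:
    """Component-wise cycle mean of the WSS vector (periodic trapezoid)."""
    if rec.tau_vectors.size == 0:
        raise RecordError("empty record")
    return rec.tau_vectors.mean(axis=0)


def tawss(rec: WallShearRecord) -> float:
    """Time-averaged WSS magnitude, (1/T) int |tau| dt, in Pa."""
    return float(np.linalg.norm(rec.tau_vectors, axis=1).mean())


def osi(rec: WallShearRecord) -> float:
    """Oscillatory shear index, 0.5*(1 - |tau_mean|/TAWSS), in [0, 0.5]."""
    ta = tawss(rec)
    if ta < EPS_TAWSS:
        return 0.0
    val = 0.5 * (1.0 - float(np.linalg.norm(mean_wss_vector(rec))) / ta)
    return float(np.clip(val, 0.0, 0.5))


def transwss(rec: WallShearRecord) -> tuple[float, bool]:
    """Transverse WSS in Pa, plus a direction-degeneracy flag.

    Returns ``(value, degenerate)``.  When the cycle-mean vector vanishes
    the transverse direction is undefined; by convention the value is 0 and
    ``degenerate`` is True.  Raises :class:`MetricUndefinedError` for 2-D
    records, where the in-plane cross product leaves no tangential
    transverse direction.
    """
    if not rec.is_3d:
        raise MetricUndefinedError(
            "transWSS requires 3-D WSS vectors and a wall normal; "
            "2-D records have no in-plane transverse direction"
        )
    tm = mean_wss_vector(rec)
    norm_tm = np.linalg.norm(tm)
    if norm_tm < EPS_MEAN:
        return 0.0, True
    transverse_dir = np.cross(rec.outward_normal, tm / norm_tm)
    return float(np.abs(rec.tau_vectors @ transverse_dir).mean()), False


@dataclass(frozen=True)
class HemodynamicMetrics:
    """Per-point metric table plus per-region mean/SEM summaries."""

    per_point: pd.DataFrame = field(compare=False)
    per_region: pd.DataFrame = field(compare=False)

    @classmethod
    def from_records(cls, records) -> "HemodynamicMetrics":
        per_point = compute_metrics(records)
        return cls(per_point=per_point, per_region=summarize_regions(per_point))


def compute_metrics(records) -> pd.DataFrame:
    """Per-point TAWSS/OSI/transWSS table for a collection of records.

    transWSS is NaN for 2-D records (undefined) and 0 with
    ``degenerate_flag`` set where the mean-shear direction vanishes.
    """
    rows = []
    for rec in records:
        row = {
            "point_id": rec.point_id,
            "region": rec.region_label,
            "tawss_pa": tawss(rec),
            "osi": osi(rec),
        }
        if rec.is_3d:
            tw, degen = transwss(rec)
            row["transwss_pa"] = tw
            row["degenerate_flag"] = degen
        else:
            row["transwss_pa"] = np.nan
            row["degenerate_flag"] = False
        rows.append(row)
    if not rows:
        raise RecordError("no records supplied")
    return pd.DataFrame(rows)


def summarize_regions(per_point: pd.DataFrame, include_pooled: bool = True) -> pd.DataFrame:
    """Mean, SEM and n per region for each metric column.

    SEM = sd/sqrt(n) with ddof=1; reported as NaN when n = 1.  With
    ``include_pooled``, rows labelled ``"all_ostial"`` (every region except
    ``"non-ostial"``) and ``"all"`` summarize the pooled points, covering
    both interpretations of a single per-group number.
    """
    metric_cols = [c for c in ("tawss_pa", "osi", "transwss_pa") if c in per_point.columns]
    groups: list[tuple[str, pd.DataFrame]] = [
        (str(name), g) for name, g in per_point.groupby("region", sort=True)
    ]
    if include_pooled:
        ostial = per_point[per_point["region"] != "non-ostial"]
        if len(ostial):
            groups.append(("all_ostial", ostial))
        groups.append(("all", per_point))
    rows = []
    for name, g in groups:
        row: dict = {"region": name, "n": len(g)}
        for c in metric_cols:
            vals = g[c].dropna().to_numpy()
            row[f"{c}_mean"] = vals.mean() if vals.size else np.nan
            row[f"{c}_sem"] = (
                vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def records_to_dataframe(records) -> pd.DataFrame:
    """Long-format table (point_id, region, x, y[, z], normal, time_s, tau_*)."""
    frames = []
    for rec in records:
        d = rec.outward_normal.size
        cols = {
            "point_id": rec.point_id,
            "region": rec.region_label,
            "time_s": rec.times,
        }
        for k, ax in enumerate("xyz"[:d]):
            cols[ax] = rec.position[k]
            cols[f"n{ax}"] = rec.outward_normal[k]
            cols[f"tau_{ax}"] = rec.tau_vectors[:, k]
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)


def records_from_dataframe(df: pd.DataFrame, period_T: float) -> list:
    """Inverse of :func:`records_to_dataframe`."""
    dims = [ax for ax in "xyz" if f"tau_{ax}" in df.columns]
    recs = []
    for pid, g in df.groupby("point_id", sort=True):
        g = g.sort_values("time_s")
        recs.append(
            WallShearRecord(
                point_id=int(pid),
                position=g.iloc[0][dims].to_numpy(dtype=float),
                outward_normal=g.iloc[0][[f"n{ax}" for ax in dims]].to_numpy(dtype=float),
                region_label=str(g.iloc[0]["region"]),
                times=g["time_s"].to_numpy(dtype=float),
                tau_vectors=g[[f"tau_{ax}" for ax in dims]].to_numpy(dtype=float),
                period_T=period_T,
            )
        )
    return recs
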