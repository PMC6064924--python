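"""End-to-end orchestration and the two-group statistics.

A run is described by a validated :class:`RunConfig` (YAML/JSON-friendly)
and executes one of two modes:

* ``synthetic`` — generate a two-group cohort of WSS fields, compute the
  per-point metrics, summarize per subject and region, and compare groups;
* ``solver`` — run the unsteady channel simulation for the configured
  cycles, record final-cycle wall shear and compute the metrics.

Group comparisons use Welch's two-sample t test on subject-level region
means (the subject, not the wall point, is the unit of analysis), with
Holm correction across regions within each metric.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field
from scipy import stats

from .metrics import compute_metrics, records_to_dataframe, summarize_regions
from .oracles import FluidProperties
from .solver import OutletSplit, build_channel, run_cycles
from .synthetic import (
    DEFAULT_GROUP_ADJUSTMENTS,
    CohortSpec,
    SyntheticFieldSpec,
    generate_cohort,
    quadrant_of_region,
)
from .waveform import fit_bezier_waveform, scale_waveform
from .synthetic import default_mouse_waveform

_CSV_FLOAT = "%.12g"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is stage-tagged."""


# ---- configuration ---------------------------------------------------------


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class WaveformConfig(_Strict):
    period_T: float = 0.1
    peak_velocity: float = 1.0
    n_segments: int = 8
    scale: float = 1.0  # applied after fitting (group contrast on the inlet)
    kind: str = "pulse"  # "pulse" (systolic raised cosine) | "constant"


class FluidConfig(_Strict):
    density_rho: float = 1235.0
    dynamic_viscosity_eta: float = 0.004


class GeometryConfig(_Strict):
    length_L: float = 12 * 1.58e-3
    height_h: float = 1.58e-3
    grid_nx: int = 128
    grid_ny: int = 32
    ostia: str | list = "default"
    branch_length: float = 0.0


class SolverConfig(_Strict):
    n_cycles: int = 3
    steps_per_cycle: int = 1000
    inlet_profile: str = "parabolic"
    region_width_factor: float = 1.5


class FieldConfig(_Strict):
    n_points_per_region: int = 5
    n_nonostial_points: int = 20
    period_T: float = 0.1
    n_times: int = 64
    oscillatory_fraction: float = 0.25
    transverse_fraction: float = 0.10
    noise_sd_pa: float = 0.05
    between_point_cv: float = 0.10


class CohortConfig(_Strict):
    field: FieldConfig = Field(default_factory=FieldConfig)
    group_adjustments: dict = Field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_GROUP_ADJUSTMENTS.items()}
    )
    n_subjects: int = 12
    between_subject_cv: float = 0.05


class RunConfig(_Strict):
    """Validated run configuration; unknown keys are rejected."""

    mode: str  # "solver" | "synthetic"
    seed: int = 0
    waveform: WaveformConfig = Field(default_factory=WaveformConfig)
    fluid: FluidConfig = Field(default_factory=FluidConfig)
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    solver: SolverConfig = Field(default_factory=SolverConfig)
    cohort: CohortConfig = Field(default_factory=CohortConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))


# ---- group comparison ------------------------------------------------------


@dataclass(frozen=True)
class GroupComparison:
    """Welch t comparison of one metric in one region."""

    metric: str
    region: str
    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int
    t_statistic: float
    df: float
    p_value: float
    available: bool = True


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else float("nan")


def compare_groups(values_a, values_b, metric: str = "", region: str = "") -> GroupComparison:
    """Welch two-sample t test on subject-level values.

    Groups with fewer than 2 subjects yield an ``available=False``
    comparison with NaN statistics.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    base = dict(
        metric=metric,
        region=region,
        mean_a=float(a.mean()) if a.size else float("nan"),
        sem_a=_sem(a),
        n_a=a.size,
        mean_b=float(b.mean()) if b.size else float("nan"),
        sem_b=_sem(b),
        n_b=b.size,
    )
    if a.size < 2 or b.size < 2:
        return GroupComparison(
            t_statistic=float("nan"), df=float("nan"), p_value=float("nan"),
            available=False, **base
        )
    res = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        t_statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        **base,
    )


def subject_region_means(subject, pool_quadrants: bool = True) -> pd.DataFrame:
    """Subject-level metric means per region (plus pooled ostial points).

    With ``pool_quadrants`` the 12 ostium regions are pooled into their 4
    quadrants before averaging.
    """
    per_point = compute_metrics(subject.records)
    if pool_quadrants:
        per_point = per_point.assign(region=per_point["region"].map(quadrant_of_region))
    metric_cols = ["tawss_pa", "osi", "transwss_pa"]
    out = per_point.groupby("region", sort=True)[metric_cols].mean().reset_index()
    ostial = per_point[per_point["region"] != "non-ostial"]
    if len(ostial):
        pooled = ostial[metric_cols].mean().to_frame().T
        pooled.insert(0, "region", "all_ostial")
        out = pd.concat([out, pooled], ignore_index=True)
    out.insert(0, "subject_id", subject.subject_id)
    out.insert(0, "group", subject.group)
    return out


def holm_adjust(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def compare_cohort(
    summaries: pd.DataFrame,
    metrics=("tawss_pa", "osi", "transwss_pa"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All metric-by-region Welch comparisons with Holm correction.

    ``summaries`` is the concatenation of :func:`subject_region_means` over
    all subjects of both groups; group A is the alphabetically first label.
    """
    groups = sorted(summaries["group"].unique())
    if len(groups) != 2:
        raise PipelineError(f"comparison stage: need exactly 2 groups, got {groups}")
    ga, gb = groups
    rows = []
    for metric in metrics:
        for region in sorted(summaries["region"].unique()):
            sub = summaries[summaries["region"] == region]
            a = sub.loc[sub["group"] == ga, metric].dropna().to_numpy()
            b = sub.loc[sub["group"] == gb, metric].dropna().to_numpy()
            cmp_ = compare_groups(a, b, metric=metric, region=region)
            rows.append(cmp_.__dict__ | {"group_a": ga, "group_b": gb})
        block = [r for r in rows if r["metric"] == metric]
        avail = [r for r in block if r["available"]]
        if avail:
            adj = holm_adjust(np.array([r["p_value"] for r in avail]))
            for r, pa in zip(avail, adj):
                r["p_holm"] = pa
                r["significant"] = bool(pa < alpha)
        for r in block:
            r.setdefault("p_holm", float("nan"))
            r.setdefault("significant", False)
    return pd.DataFrame(rows)


# ---- pipeline --------------------------------------------------------------


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_CSV_FLOAT)


def run_pipeline(config: RunConfig | dict, out_dir) -> dict:
    """Execute the configured mode and write the report bundle.

    Writes metric tables, summaries, (synthetic mode) group comparisons and
    a run manifest to ``out_dir``.  Deterministic given config + seed.
    Returns a dict of result tables and output paths.
    """
    if isinstance(config, dict):
        config = RunConfig.model_validate(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    if config.mode == "synthetic":
        try:
            fs = SyntheticFieldSpec(
                seed=config.seed, **config.cohort.field.model_dump()
            )
            cohort = CohortSpec(
                field_spec=fs,
                group_adjustments=config.cohort.group_adjustments,
                n_subjects=config.cohort.n_subjects,
                between_subject_cv=config.cohort.between_subject_cv,
                base_seed=config.seed,
            )
            subjects = generate_cohort(cohort)
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"generation stage: {e}") from e
        try:
            summaries = pd.concat(
                [subject_region_means(s) for s in subjects], ignore_index=True
            )
            comparisons = compare_cohort(summaries)
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"comparison stage: {e}") from e
        _write_csv(summaries, out / "subject_summaries.csv")
        _write_csv(comparisons, out / "group_comparisons.csv")
        results["subject_summaries"] = summaries
        results["group_comparisons"] = comparisons

    elif config.mode == "solver":
        try:
            if config.waveform.kind == "constant":
                t = np.arange(128) * (config.waveform.period_T / 128)
                from .waveform import SampledWaveform

                samples = SampledWaveform(
                    t, np.full(128, config.waveform.peak_velocity), config.waveform.period_T
                )
            elif config.waveform.kind == "pulse":
                samples = default_mouse_waveform(
                    period_T=config.waveform.period_T, peak=config.waveform.peak_velocity
                )
            else:
                raise ValueError(f"unknown waveform kind {config.waveform.kind!r}")
            spline = fit_bezier_waveform(samples, config.waveform.n_segments)
            if config.waveform.scale != 1.0:
                spline = scale_waveform(spline, config.waveform.scale)
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"waveform stage: {e}") from e
        try:
            geometry = build_channel(config.geometry.model_dump())
            props = FluidProperties(**config.fluid.model_dump())
            splits = OutletSplit.paper_default(n_ostia=len(geometry.ostia))
            records, diagnostics = run_cycles(
                geometry,
                props,
                spline,
                splits,
                n_cycles=config.solver.n_cycles,
                steps_per_cycle=config.solver.steps_per_cycle,
                inlet_profile=config.solver.inlet_profile,
                region_width_factor=config.solver.region_width_factor,
            )
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"solver stage: {e}") from e
        try:
            per_point = compute_metrics(records)
            per_region = summarize_regions(per_point)
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"metrics stage: {e}") from e
        _write_csv(records_to_dataframe(records), out / "wall_shear_series.csv")
        _write_csv(per_point, out / "point_metrics.csv")
        _write_csv(per_region, out / "region_summaries.csv")
        results["point_metrics"] = per_point
        results["region_summaries"] = per_region
        results["diagnostics"] = {
            k: v for k, v in diagnostics.items() if k != "final_state"
        }
        with open(out / "solver_diagnostics.json", "w") as fh:
            json.dump(results["diagnostics"], fh, indent=2, sort_keys=True)
    else:
        raise PipelineError(f"config stage: unknown mode {config.mode!r}")

    from importlib.metadata import version

    manifest = {
        "mode": config.mode,
        "seed": config.seed,
        "config_sha256": _config_hash(config),
        "config": config.model_dump(),
        "package_version": version("aortashear"),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    results["out_dir"] = str(out)
    return results
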