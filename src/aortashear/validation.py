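"""End-to-end validation studies: solver-vs-oracle and cohort statistics.

Each function runs one self-contained study at desk scale and returns the
measured figures of merit.  They are the computations behind the
verification scripts and the acceptance checks:

* steady straight-channel wall shear vs the plane-Poiseuille closed form;
* pulsatile straight-channel wall shear vs the plane-channel Womersley
  solution, including a grid-convergence study (time step refined with the
  grid, since space and time discretizations are both second order);
* cycle-to-cycle periodicity under the 3-cycle, 1000-steps-per-cycle
  protocol, and outflow-split conservation in the 12-ostia channel;
* shear-metric equivalence against dense quadrature on random band-limited
  WSS records, and the closed-form sinusoid values;
* two-group recovery power and null calibration of the cohort comparison.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import WallShearRecord, compute_metrics, osi, tawss, transwss
from .oracles import (
    FluidProperties,
    HarmonicPressureGradient,
    channel_womersley_wss_series,
    plane_poiseuille_wss,
)
from .solver import OutletSplit, build_channel, extract_wall_shear, run_cycles, run_to_steady
from .synthetic import CohortSpec, SyntheticFieldSpec, default_mouse_waveform, generate_cohort
from .waveform import fit_bezier_waveform, scale_waveform

H = 1.58e-3  # channel height = aortic-root hydraulic diameter (m)
T = 0.1  # cardiac cycle time (s), ~600 bpm


def _straight_channel(ny: int, nx: int = 24, n_heights: float = 4.0):
    return build_channel(
        {"length_L": n_heights * H, "height_h": H, "grid_nx": nx, "grid_ny": ny, "ostia": []}
    )


def steady_poiseuille_validation(
    ny: int = 64, mean_U: float = 0.1, props: FluidProperties | None = None
) -> dict:
    """Steady straight-channel run vs the 6*eta*U/h closed form.

    Wall shear is measured on the central band of an 8h-long channel, away
    from the inlet and outlet adjustment regions.  Returns the maximum
    relative wall-shear error plus conservation diagnostics.
    """
    props = props or FluidProperties()
    geo = build_channel(
        {"length_L": 8 * H, "height_h": H, "grid_nx": 48, "grid_ny": ny, "ostia": []}
    )
    state, _ = run_to_steady(geo, props, mean_U, OutletSplit({"main": 1.0}), tol=1e-10)
    wss = extract_wall_shear(state, geo, props)
    band = wss[(wss.x > 2 * H) & (wss.x < 5 * H)]
    exact = plane_poiseuille_wss(props, mean_U, H)
    return {
        "rel_error": float(np.max(np.abs(band.tau_x - exact)) / exact),
        "max_divergence": state.max_divergence,
        "mass_error": state.mass_error,
        "n_wall_points": len(band),
    }


def _validation_gradient(props: FluidProperties) -> HarmonicPressureGradient:
    """Single-harmonic gradient with alpha = 3.48 (<= 4) and mean U = 0.1 m/s."""
    a = H / 2
    G0 = 3.0 * props.dynamic_viscosity_eta * 0.1 / a**2
    return HarmonicPressureGradient(G0, [(2.0 * G0, 0.0)], T)


def womersley_channel_validation(
    ny: int = 64,
    steps_per_cycle: int = 1000,
    n_cycles: int = 3,
    props: FluidProperties | None = None,
) -> dict:
    """Pulsatile straight-channel run vs the plane-channel Womersley oracle.

    The inlet imposes the exact Womersley profile, so the whole channel
    carries the analytic solution; wall shear of the final cycle is compared
    point-by-point in time on the central band.  Also reports the RMS
    change between the last two cycles (periodicity of the 3-cycle
    protocol) and the conservation diagnostics.
    """
    props = props or FluidProperties()
    grad = _validation_gradient(props)
    geo = _straight_channel(ny)
    records, diag = run_cycles(
        geo,
        props,
        None,
        OutletSplit({"main": 1.0}),
        n_cycles=n_cycles,
        steps_per_cycle=steps_per_cycle,
        period_T=T,
        inlet_profile="womersley",
        gradient=grad,
    )
    _, tau_exact = channel_womersley_wss_series(grad, H, props, n_times=steps_per_cycle)
    rms_exact = float(np.sqrt(np.mean(tau_exact**2)))
    band = [r for r in records if H < r.position[0] < 3 * H]
    rms_err = max(
        float(np.sqrt(np.mean((r.tau_vectors[:, 0] - tau_exact) ** 2))) for r in band
    )
    return {
        "rms_rel_error": rms_err / rms_exact,
        "cycle_rms_change": diag["cycle_rms_change"],
        "max_divergence": diag["max_divergence"],
        "max_mass_error": diag["max_mass_error"],
        "alpha": float(np.sqrt(2 * np.pi / T / props.kinematic_viscosity)) * H / 2,
        "n_band_points": len(band),
    }


def grid_convergence_study(
    nys=(32, 64, 128), base_steps: int = 1000, props: FluidProperties | None = None
) -> dict:
    """Observed convergence order of the pulsatile wall shear.

    Refines the transverse grid together with the time step (both
    discretizations are second order) and fits the least-squares slope of
    log2(error) against log2(resolution).
    """
    errors = {}
    for ny in nys:
        spc = int(base_steps * ny // nys[0])
        res = womersley_channel_validation(ny=ny, steps_per_cycle=spc)
        errors[ny] = res["rms_rel_error"]
    x = np.log2(np.array(list(errors), dtype=float))
    y = np.log2(np.array(list(errors.values())))
    order = float(-np.polyfit(x, y, 1)[0])
    return {"errors": errors, "observed_order": order}


def branched_channel_study(
    grid_nx: int = 128,
    grid_ny: int = 32,
    steps_per_cycle: int = 1000,
    n_cycles: int = 3,
    peak_mean_velocity: float = 0.4,
    inlet_scale: float = 1.0,
    props: FluidProperties | None = None,
) -> dict:
    """Full 12-ostia channel run under the cardiac-cycle protocol.

    The inlet is the fitted murine waveform scaled so its peak mean velocity
    is ``peak_mean_velocity * inlet_scale``; splits follow the branched
    protocol (main outlet 69.8%, 0.14% per ostium, renormalized).  Returns
    per-point metrics, region summaries and conservation diagnostics.
    """
    props = props or FluidProperties()
    geo = build_channel(
        {"length_L": 12 * H, "height_h": H, "grid_nx": grid_nx, "grid_ny": grid_ny,
         "ostia": "default"}
    )
    spline = fit_bezier_waveform(default_mouse_waveform(period_T=T, peak=1.0), 8)
    spline = scale_waveform(spline, peak_mean_velocity * inlet_scale)
    splits = OutletSplit.paper_default(n_ostia=len(geo.ostia))
    records, diag = run_cycles(
        geo, props, spline, splits, n_cycles=n_cycles, steps_per_cycle=steps_per_cycle
    )
    per_point = compute_metrics(records)
    return {
        "per_point": per_point,
        "records": records,
        "max_ostium_flux_error": diag["max_ostium_flux_error"],
        "cycle_rms_change": diag["cycle_rms_change"],
        "max_divergence": diag["max_divergence"],
        "max_mass_error": diag["max_mass_error"],
        "n_wall_points": diag["n_wall_points"],
    }


# ---- metric oracles --------------------------------------------------------


def metric_closed_forms(n_times: int = 1024) -> dict:
    """The three closed-form sinusoid values.

    A zero-mean sinusoid has OSI exactly 0.5; an axial or transverse
    sinusoid of amplitude pi/2 has TAWSS resp. transWSS exactly 1 Pa, since
    the cycle mean of |sin| is 2/pi.
    """
    t = np.arange(n_times) * (T / n_times)
    s = np.sin(2 * np.pi * t / T)
    normal = np.array([0.0, 0.0, 1.0])

    def rec(tau):
        return WallShearRecord(0, np.zeros(3), normal, "r", t, tau, T)

    tau_osc = np.stack([s, np.zeros_like(s), np.zeros_like(s)], axis=1)
    tau_ax = (np.pi / 2) * tau_osc
    tau_tr = np.stack([np.ones_like(s), (np.pi / 2) * s, np.zeros_like(s)], axis=1)
    return {
        "osi_pure_oscillation": osi(rec(tau_osc)),
        "tawss_half_pi_sinusoid_pa": tawss(rec(tau_ax)),
        "transwss_half_pi_sinusoid_pa": transwss(rec(tau_tr))[0],
    }


def metric_oracle_sweep(
    n_records: int = 1000, n_times: int = 8192, dense_factor: int = 4, seed: int = 12345
) -> dict:
    """Random band-limited WSS records vs dense quadrature of the formulas.

    Each record is a random trigonometric polynomial pair (axial and
    transverse components in a random tangent frame).  The oracle evaluates
    the same continuous signal on a ``dense_factor`` finer grid and
    integrates the metric definitions directly; the bounds
    0 <= OSI <= 0.5 and 0 <= transWSS <= TAWSS are checked on every record.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n_times) * (T / n_times)
    td = np.arange(n_times * dense_factor) * (T / (n_times * dense_factor))
    w = 2 * np.pi / T
    n_harm = 6
    max_err = {"tawss": 0.0, "osi": 0.0, "transwss": 0.0}
    bounds_violations = 0
    for _ in range(n_records):
        coef = rng.normal(0, 0.5, (2, n_harm, 2))
        means = np.array([rng.uniform(-1.0, 3.0), rng.uniform(-0.5, 0.5)])

        def signal(x):
            out = np.tile(means[:, None], (1, x.size))
            for n in range(1, n_harm + 1):
                out += coef[:, n - 1, 0, None] * np.cos(n * w * x)
                out += coef[:, n - 1, 1, None] * np.sin(n * w * x)
            return out

        # random tangent frame
        nvec = rng.normal(size=3)
        nvec /= np.linalg.norm(nvec)
        helper = np.array([1.0, 0.0, 0.0])
        if abs(nvec @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        e1 = helper - (helper @ nvec) * nvec
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(nvec, e1)

        comp = signal(t)
        tau = comp[0][:, None] * e1 + comp[1][:, None] * e2
        rec = WallShearRecord(0, np.zeros(3), nvec, "r", t, tau, T)
        ta, o = tawss(rec), osi(rec)
        tw, _ = transwss(rec)
        if not (0.0 <= o <= 0.5 and -1e-9 <= tw <= ta + 1e-9):
            bounds_violations += 1

        dx, dy = signal(td)
        mag = np.hypot(dx, dy)
        ta_o = float(mag.mean())
        mean_vec = np.array([dx.mean(), dy.mean()])
        o_o = 0.5 * (1 - np.linalg.norm(mean_vec) / ta_o)
        tdir = np.array([-mean_vec[1], mean_vec[0]]) / np.linalg.norm(mean_vec)
        tw_o = float(np.abs(dx * tdir[0] + dy * tdir[1]).mean())

        max_err["tawss"] = max(max_err["tawss"], abs(ta - ta_o) / ta_o)
        max_err["osi"] = max(max_err["osi"], abs(o - o_o) / max(o_o, 1e-3))
        max_err["transwss"] = max(max_err["transwss"], abs(tw - tw_o) / max(tw_o, 1e-3))
    return {"max_rel_error": max_err, "bounds_violations": bounds_violations,
            "n_records": n_records}


# ---- cohort statistics -----------------------------------------------------


def _subject_tawss(subject) -> float:
    pp = compute_metrics(subject.records)
    return float(pp.loc[pp.region != "non-ostial", "tawss_pa"].mean())


def cohort_power_study(n_replicates: int = 200, n_subjects: int = 12, seed: int = 0) -> dict:
    """Fraction of replicates where all three metrics are significantly lower
    in the reduced-amplitude group (Welch t on pooled-ostial subject means)."""
    from .pipeline import compare_cohort, subject_region_means

    hits = 0
    ratios = []
    for r in range(n_replicates):
        spec = CohortSpec(n_subjects=n_subjects, base_seed=(seed * 1_000_003 + r) % (2**31))
        subs = generate_cohort(spec)
        summ = pd.concat([subject_region_means(s) for s in subs], ignore_index=True)
        comp = compare_cohort(summ)
        ao = comp[comp.region == "all_ostial"].set_index("metric")
        ok = all(
            ao.loc[m, "p_value"] < 0.05 and ao.loc[m, "mean_b"] < ao.loc[m, "mean_a"]
            for m in ("tawss_pa", "osi", "transwss_pa")
        )
        hits += ok
        ratios.append(ao.loc["tawss_pa", "mean_b"] / ao.loc["tawss_pa", "mean_a"])
    return {
        "power": hits / n_replicates,
        "mean_tawss_ratio": float(np.mean(ratios)),
        "n_replicates": n_replicates,
    }


def null_calibration_study(
    n_replicates: int = 1000, n_subjects: int = 10, seed: int = 0
) -> dict:
    """Type-I error of the TAWSS comparison under identical groups.

    Replicate cohorts use a reduced field size (the p-value distribution
    under the null does not depend on the per-subject field resolution).
    """
    small = SyntheticFieldSpec(n_points_per_region=2, n_nonostial_points=4, n_times=32)
    rejections = 0
    for r in range(n_replicates):
        spec = CohortSpec(
            field_spec=small,
            group_adjustments={"control": {}, "dha": {}},
            n_subjects=n_subjects,
            base_seed=(seed * 1_000_003 + r) % (2**31),
        )
        subs = generate_cohort(spec)
        a = [_subject_tawss(s) for s in subs if s.group == "control"]
        b = [_subject_tawss(s) for s in subs if s.group == "dha"]
        p = stats.ttest_ind(a, b, equal_var=False).pvalue
        rejections += p < 0.05
    return {"rejection_rate": rejections / n_replicates, "n_replicates": n_replicates}
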