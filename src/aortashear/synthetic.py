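"""Synthetic inputs for the pipeline: waveforms, WSS fields and cohorts.

Real inputs to this analysis — a Doppler-derived inlet waveform and
surface wall-shear vector time series from a subject-specific 3-D
simulation — are replaced by parametric generators with controlled
statistical structure:

* a murine-like inlet waveform (systolic raised-cosine pulse, ~600 bpm,
  peak anchored at 1 m/s);
* per-surface-point 3-D WSS vector series combining an axial mean
  component, a zero-mean oscillatory axial sinusoid, a phase-shifted
  transverse sinusoid and Gaussian noise, tangent to a random unit normal;
* two-group cohorts ("control" vs a reduced-amplitude "dha" group) for the
  downstream metric comparison, with per-subject seeds derived
  deterministically from one base seed.

The default group contrast emulates the direction and ratio of the
reference comparison (treated/control TAWSS ratio ~0.78), not absolute Pa
levels, which depend on subject-specific 3-D geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .metrics import WallShearRecord
from .waveform import SampledWaveform

QUADRANTS = ("left_upper", "right_upper", "left_lower", "right_lower")

#: 12 ostium regions (4 quadrants x 3 ostia each) plus the non-ostial wall.
OSTIUM_REGIONS = tuple(f"{q}_{k}" for q in QUADRANTS for k in (1, 2, 3))


def quadrant_of_region(region: str) -> str:
    """Map an ostium region label to its quadrant (``non-ostial`` unchanged)."""
    for q in QUADRANTS:
        if region.startswith(q):
            return q
    return region


class SpecError(ValueError):
    """Invalid synthetic-data specification."""


def default_mouse_waveform(
    period_T: float = 0.1, peak: float = 1.0, n_samples: int = 128
) -> SampledWaveform:
    """Murine-like inlet velocity waveform.

    A raised-cosine systolic pulse over roughly a third of the cycle on a
    low diastolic plateau (5% of peak).  The cycle time default 0.1 s
    corresponds to a 600 bpm mouse heart rate; the peak default 1.0 m/s is
    the typical murine aortic-root maximum.  The systolic peak is placed on
    a sample, so ``max(velocities) == peak`` exactly.
    """
    if period_T <= 0 or peak <= 0:
        raise SpecError("period and peak must be positive")
    t = np.arange(n_samples) * (period_T / n_samples)
    k_half = max(1, round(n_samples / 6))  # peak sample index
    t_sys = 2 * k_half * period_T / n_samples  # systolic duration ~ T/3
    dia = 0.05 * peak
    v = np.full(n_samples, dia)
    sys_mask = t < t_sys
    v[sys_mask] = dia + (peak - dia) * 0.5 * (1.0 - np.cos(2.0 * np.pi * t[sys_mask] / t_sys))
    return SampledWaveform(t, v, period_T)


def _default_region_means() -> dict:
    means = {r: 20.0 for r in OSTIUM_REGIONS}
    means["non-ostial"] = 10.0
    return means


@dataclass(frozen=True)
class SyntheticFieldSpec:
    """Parameters of one synthetic WSS vector field.

    ``region_mean_pa`` maps region labels to the mean shear magnitude;
    ``oscillatory_fraction`` and ``transverse_fraction`` are sinusoid
    amplitudes as fractions of each point's mean magnitude;
    ``between_point_cv`` is the coefficient of variation of per-point mean
    magnitudes around the regional mean.
    """

    n_points_per_region: int = 5
    n_nonostial_points: int = 20
    period_T: float = 0.1
    n_times: int = 64
    region_mean_pa: dict = field(default_factory=_default_region_means)
    oscillatory_fraction: float = 0.25
    transverse_fraction: float = 0.10
    transverse_phase: float = np.pi / 2.0
    noise_sd_pa: float = 0.05
    between_point_cv: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_times < 8:
            raise SpecError("n_times must be >= 8")
        if self.period_T <= 0:
            raise SpecError("period_T must be positive")
        if min(self.oscillatory_fraction, self.transverse_fraction) < 0:
            raise SpecError("amplitude fractions must be >= 0")
        if self.noise_sd_pa < 0 or self.between_point_cv < 0:
            raise SpecError("noise and dispersion parameters must be >= 0")
        if any(v <= 0 for v in self.region_mean_pa.values()):
            raise SpecError("regional mean shear magnitudes must be positive")

    def scaled(
        self,
        mean_scale: float = 1.0,
        oscillatory_scale: float = 1.0,
        transverse_scale: float = 1.0,
        noise_scale: float = 1.0,
        seed: int = None,
    ) -> "SyntheticFieldSpec":
        """Multiplicatively adjusted copy (used for group contrasts)."""
        if min(mean_scale, oscillatory_scale, transverse_scale, noise_scale) <= 0:
            raise SpecError("scales must be positive")
        return replace(
            self,
            region_mean_pa={k: v * mean_scale for k, v in self.region_mean_pa.items()},
            oscillatory_fraction=self.oscillatory_fraction * oscillatory_scale,
            transverse_fraction=self.transverse_fraction * transverse_scale,
            noise_sd_pa=self.noise_sd_pa * noise_scale,
            seed=self.seed if seed is None else seed,
        )


def _random_tangent_frame(rng: np.random.Generator):
    """Random unit normal with an orthonormal tangent basis (e1, e2)."""
    n = rng.normal(size=3)
    n /= np.linalg.norm(n)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(n @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = helper - (helper @ n) * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    # random in-plane rotation of the axial direction
    ang = rng.uniform(0.0, 2.0 * np.pi)
    a1 = np.cos(ang) * e1 + np.sin(ang) * e2
    a2 = np.cross(n, a1)
    return n, a1, a2


def generate_wss_field(spec: SyntheticFieldSpec) -> list:
    """Draw one WSS vector field as a list of :class:`WallShearRecord`.

    Per point: tau(t) = a1*(m + f_osc*m*sin(w t)) + a2*(f_trans*m*
    sin(w t + phase)) + tangential Gaussian noise, with m drawn around the
    regional mean.  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    t = np.arange(spec.n_times) * (spec.period_T / spec.n_times)
    w = 2.0 * np.pi / spec.period_T
    s_ax = np.sin(w * t)
    s_tr = np.sin(w * t + spec.transverse_phase)

    layout: list[tuple[str, int]] = []
    for r in sorted(spec.region_mean_pa):
        n_pts = spec.n_nonostial_points if r == "non-ostial" else spec.n_points_per_region
        layout.extend((r, i) for i in range(n_pts))

    records = []
    for pid, (region, _) in enumerate(layout):
        n, a1, a2 = _random_tangent_frame(rng)
        m = spec.region_mean_pa[region] * max(
            0.05, 1.0 + spec.between_point_cv * rng.standard_normal()
        )
        ax = m + spec.oscillatory_fraction * m * s_ax
        tr = spec.transverse_fraction * m * s_tr
        if spec.noise_sd_pa > 0:
            ax = ax + spec.noise_sd_pa * rng.standard_normal(spec.n_times)
            tr = tr + spec.noise_sd_pa * rng.standard_normal(spec.n_times)
        tau = ax[:, None] * a1[None, :] + tr[:, None] * a2[None, :]
        records.append(
            WallShearRecord(
                point_id=pid,
                position=rng.uniform(-1.0, 1.0, size=3),
                outward_normal=n,
                region_label=region,
                times=t,
                tau_vectors=tau,
                period_T=spec.period_T,
            )
        )
    return records


#: Default group adjustments emulating the reference contrast: the treated
#: ("dha") group has lower shear amplitude (TAWSS ratio ~0.8) and lower
#: oscillatory content, so all three metrics fall.
DEFAULT_GROUP_ADJUSTMENTS = {
    "control": {},
    "dha": {"mean_scale": 0.8, "oscillatory_scale": 0.8, "transverse_scale": 0.8},
}


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort: per-group field adjustments and subject counts.

    ``between_subject_cv`` scales each subject's mean shear level by a
    lognormal-free multiplicative Gaussian factor around 1; per-subject
    seeds are spawned deterministically from ``base_seed``.
    """

    field_spec: SyntheticFieldSpec = field(default_factory=SyntheticFieldSpec)
    group_adjustments: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_GROUP_ADJUSTMENTS.items()}
    )
    n_subjects: int = 12
    between_subject_cv: float = 0.05
    base_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.group_adjustments) != 2:
            raise SpecError("exactly 2 groups are required")
        if self.n_subjects < 1:
            raise SpecError("n_subjects must be >= 1")
        if self.between_subject_cv < 0:
            raise SpecError("between_subject_cv must be >= 0")


@dataclass(frozen=True)
class Subject:
    group: str
    subject_id: int
    records: list = field(compare=False)


def generate_cohort(spec: CohortSpec) -> list:
    """Generate all subjects of a two-group cohort.

    Returns a flat list of :class:`Subject`; each subject's field is an
    independent :func:`generate_wss_field` draw whose parameters carry the
    group adjustment and a subject-level mean-scale factor.
    """
    ss = np.random.SeedSequence(spec.base_seed)
    groups = sorted(spec.group_adjustments)
    children = ss.spawn(len(groups) * spec.n_subjects + 1)
    level_rng = np.random.default_rng(children[0])
    subjects = []
    idx = 1
    for g in groups:
        adj = dict(spec.group_adjustments[g])
        for s in range(spec.n_subjects):
            subj_scale = max(0.05, 1.0 + spec.between_subject_cv * level_rng.standard_normal())
            seed = int(children[idx].generate_state(1)[0] % (2**31))
            idx += 1
            fs = spec.field_spec.scaled(
                mean_scale=adj.get("mean_scale", 1.0) * subj_scale,
                oscillatory_scale=adj.get("oscillatory_scale", 1.0),
                transverse_scale=adj.get("transverse_scale", 1.0),
                noise_scale=adj.get("noise_scale", 1.0),
                seed=seed,
            )
            subjects.append(Subject(group=g, subject_id=s, records=generate_wss_field(fs)))
    return subjects
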