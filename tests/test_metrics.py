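"""TAWSS, OSI and transWSS against closed forms and quadrature oracles."""

import numpy as np
import pytest
from scipy.interpolate import CubicSpline

from aortashear.metrics import (
    MetricUndefinedError,
    RecordError,
    WallShearRecord,
    compute_metrics,
    mean_wss_vector,
    osi,
    summarize_regions,
    tawss,
    transwss,
)
from conftest import make_record, random_trig_record

T = 0.1


def sin_axis(amplitude, axis=0, offset=0.0):
    def f(t):
        tau = np.zeros((t.size, 3))
        tau[:, axis] = offset + amplitude * np.sin(2 * np.pi * t / T)
        return tau

    return f


class TestMeanVector:
    def test_constant_vector(self):
        rec = make_record(lambda t: np.tile([2.0, 0.0, 0.0], (t.size, 1)))
        assert np.allclose(mean_wss_vector(rec), [2.0, 0.0, 0.0])

    def test_zero_mean_sinusoid(self):
        rec = make_record(sin_axis(1.0))
        assert np.linalg.norm(mean_wss_vector(rec)) < 1e-12

    def test_matches_periodic_cubic_spline_quadrature(self):
        rng = np.random.default_rng(7)
        t = np.arange(256) * (T / 256)
        tau = rng.normal(0, 1, (256, 3))
        tau[:, 2] = 0.0
        rec = WallShearRecord(0, np.zeros(3), np.array([0.0, 0.0, 1.0]),
                              "non-ostial", t, tau, T)
        mean = mean_wss_vector(rec)
        for k in range(2):
            ts = np.append(t, T)
            ys = np.append(tau[:, k], tau[0, k])
            spline = CubicSpline(ts, ys, bc_type="periodic")
            oracle = spline.integrate(0, T) / T
            assert mean[k] == pytest.approx(oracle, rel=1e-6, abs=1e-9)


class TestTawss:
    def test_constant_magnitude(self):
        rec = make_record(lambda t: np.tile([0.0, 2.0, 0.0], (t.size, 1)))
        assert tawss(rec) == pytest.approx(2.0)

    def test_half_pi_sinusoid_gives_unity(self):
        # mean of |A sin| = 2A/pi = 1 for A = pi/2
        rec = make_record(sin_axis(np.pi / 2), n_times=1024)
        assert tawss(rec) == pytest.approx(1.0, abs=1e-3)

    def test_dominates_mean_vector_norm(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            rec, _ = random_trig_record(rng)
            assert tawss(rec) >= np.linalg.norm(mean_wss_vector(rec)) - 1e-12


class TestOsi:
    def test_unidirectional_steady_is_zero(self):
        rec = make_record(lambda t: np.tile([1.5, 0.3, 0.0], (t.size, 1)))
        assert osi(rec) == pytest.approx(0.0, abs=1e-14)

    def test_pure_reversal_is_half(self):
        rec = make_record(sin_axis(1.0), n_times=1024)
        assert osi(rec) == pytest.approx(0.5, abs=1e-12)

    def test_offset_sinusoid_without_reversal_is_zero(self):
        # tau_x = 1 + 0.5 sin never changes sign: |mean| equals mean of |tau|
        rec = make_record(sin_axis(0.5, offset=1.0), n_times=1024)
        assert osi(rec) == pytest.approx(0.0, abs=1e-12)

    def test_zero_field_returns_zero(self):
        rec = make_record(lambda t: np.zeros((t.size, 3)))
        assert osi(rec) == 0.0


class TestTranswss:
    def test_parallel_field_is_zero(self):
        d = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
        rec = make_record(lambda t: (1 + 0.5 * np.sin(2 * np.pi * t / T))[:, None] * d)
        val, degen = transwss(rec)
        assert val == pytest.approx(0.0, abs=1e-12) and not degen

    def test_half_pi_transverse_sinusoid_gives_unity(self):
        def f(t):
            tau = np.zeros((t.size, 3))
            tau[:, 0] = 1.0
            tau[:, 1] = (np.pi / 2) * np.sin(2 * np.pi * t / T)
            return tau

        rec = make_record(f, n_times=1024)
        val, degen = transwss(rec)
        assert val == pytest.approx(1.0, abs=1e-3) and not degen

    def test_rotating_vector_is_direction_degenerate(self):
        def f(t):
            th = 2 * np.pi * t / T
            return np.stack([3.0 * np.cos(th), 3.0 * np.sin(th), np.zeros_like(t)], axis=1)

        val, degen = transwss(make_record(f, n_times=256))
        assert val == 0.0 and degen

    def test_two_dimensional_record_rejected(self):
        t = np.arange(64) * (T / 64)
        tau = np.stack([np.ones(64), np.zeros(64)], axis=1)
        rec = WallShearRecord(0, np.zeros(2), np.array([0.0, 1.0]), "r", t,
                              np.stack([np.zeros(64), np.zeros(64)], axis=1), T)
        rec2 = WallShearRecord(0, np.zeros(2), np.array([0.0, 1.0]), "r", t,
                               tau * 0, T)
        with pytest.raises(MetricUndefinedError):
            transwss(rec)
        with pytest.raises(MetricUndefinedError):
            transwss(rec2)


class TestRecordValidation:
    def test_nontangential_3d_vectors_rejected(self):
        t = np.arange(64) * (T / 64)
        tau = np.tile([0.0, 0.0, 1.0], (64, 1))  # along the normal
        with pytest.raises(RecordError, match="tangential"):
            WallShearRecord(0, np.zeros(3), np.array([0.0, 0.0, 1.0]), "r", t, tau, T)

    def test_duplicated_endpoint_grid_rejected(self):
        t = np.linspace(0.0, T, 65)  # includes t = T: wrong spacing for n=65
        tau = np.zeros((65, 3))
        with pytest.raises(RecordError):
            WallShearRecord(0, np.zeros(3), np.array([0.0, 0.0, 1.0]), "r", t, tau, T)

    def test_non_unit_normal_rejected(self):
        t = np.arange(64) * (T / 64)
        with pytest.raises(RecordError, match="unit"):
            WallShearRecord(0, np.zeros(3), np.array([0.0, 0.0, 2.0]), "r", t,
                            np.zeros((64, 3)), T)


class TestProperties:
    def test_bounds_and_quadrature_oracle_on_random_records(self):
        """Random band-limited records: bounds hold and node quadrature
        matches dense quadrature of the same continuous signal."""
        rng = np.random.default_rng(12345)
        dense = 16384
        td = np.arange(dense) * (T / dense)
        for _ in range(60):
            rec, (fx, fy) = random_trig_record(rng, n_times=2048)
            ta, o = tawss(rec), osi(rec)
            tw, _ = transwss(rec)
            assert 0.0 <= o <= 0.5
            assert 0.0 <= tw <= ta + 1e-9
            # dense oracle on the underlying trigonometric signal
            tx, ty = fx(td), fy(td)
            mag = np.hypot(tx, ty)
            ta_o = mag.mean()
            mean_vec = np.array([tx.mean(), ty.mean(), 0.0])
            o_o = 0.5 * (1 - np.linalg.norm(mean_vec) / ta_o)
            trans_dir = np.cross(rec.outward_normal, mean_vec / np.linalg.norm(mean_vec))
            tw_o = np.abs(tx * trans_dir[0] + ty * trans_dir[1]).mean()
            assert ta == pytest.approx(ta_o, rel=1e-6)
            assert o == pytest.approx(o_o, rel=1e-6, abs=1e-9)
            assert tw == pytest.approx(tw_o, rel=2e-5, abs=1e-8)

    def test_quadrature_refinement_stability(self):
        def f(t):
            th = 2 * np.pi * t / T
            return np.stack(
                [1.0 + 0.8 * np.sin(th), 0.4 * np.sin(th + 1.0), np.zeros_like(t)], axis=1
            )

        r1, r2 = make_record(f, n_times=256), make_record(f, n_times=2048)
        assert tawss(r1) == pytest.approx(tawss(r2), rel=1e-4)
        assert osi(r1) == pytest.approx(osi(r2), rel=1e-4, abs=1e-8)
        assert transwss(r1)[0] == pytest.approx(transwss(r2)[0], rel=1e-4)

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(99)
        rec, _ = random_trig_record(rng)
        from scipy.spatial.transform import Rotation

        Q = Rotation.random(random_state=5).as_matrix()
        rot = WallShearRecord(
            rec.point_id, rec.position, Q @ rec.outward_normal, rec.region_label,
            rec.times, rec.tau_vectors @ Q.T, rec.period_T
        )
        assert tawss(rot) == pytest.approx(tawss(rec), abs=1e-9)
        assert osi(rot) == pytest.approx(osi(rec), abs=1e-9)
        assert transwss(rot)[0] == pytest.approx(transwss(rec)[0], abs=1e-9)


class TestSummaries:
    def _pp(self, values, region="left_upper"):
        import pandas as pd

        return pd.DataFrame(
            {
                "point_id": range(len(values)),
                "region": region,
                "tawss_pa": values,
                "osi": 0.1,
                "transwss_pa": 0.0,
            }
        )

    def test_identical_values_have_zero_sem(self):
        s = summarize_regions(self._pp([2.0, 2.0, 2.0]), include_pooled=False)
        assert s["tawss_pa_mean"].iloc[0] == 2.0
        assert s["tawss_pa_sem"].iloc[0] == 0.0

    def test_hand_computed_sem(self):
        s = summarize_regions(self._pp([1.0, 2.0, 3.0]), include_pooled=False)
        assert s["tawss_pa_mean"].iloc[0] == pytest.approx(2.0)
        assert s["tawss_pa_sem"].iloc[0] == pytest.approx(1.0 / np.sqrt(3), abs=1e-12)

    def test_single_point_region_sem_unavailable(self):
        s = summarize_regions(self._pp([5.0]), include_pooled=False)
        assert np.isnan(s["tawss_pa_sem"].iloc[0])

    def test_global_mean_is_weighted_average_of_regions(self):
        import pandas as pd

        pp = pd.concat(
            [self._pp([1.0, 2.0], "left_upper"), self._pp([4.0, 5.0, 6.0], "right_lower")],
            ignore_index=True,
        )
        s = summarize_regions(pp, include_pooled=True).set_index("region")
        w = (s.loc["left_upper", "n"] * s.loc["left_upper", "tawss_pa_mean"]
             + s.loc["right_lower", "n"] * s.loc["right_lower", "tawss_pa_mean"])
        assert s.loc["all", "tawss_pa_mean"] == pytest.approx(w / s.loc["all", "n"])

    def test_compute_metrics_roundtrip_dataframe(self):
        from aortashear.metrics import records_from_dataframe, records_to_dataframe

        rng = np.random.default_rng(5)
        recs = [random_trig_record(rng)[0] for _ in range(3)]
        for i, r in enumerate(recs):
            object.__setattr__(r, "point_id", i)
        df = records_to_dataframe(recs)
        back = records_from_dataframe(df, T)
        assert len(back) == 3
        for a, b in zip(recs, back):
            assert np.allclose(a.tau_vectors, b.tau_vectors)
            assert np.allclose(a.outward_normal, b.outward_normal)
        pp = compute_metrics(recs)
        assert set(pp.columns) >= {"point_id", "region", "tawss_pa", "osi", "transwss_pa"}
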