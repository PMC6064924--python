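"""Projection solver: geometry, conservation, and analytic-flow validation."""

import collections

import numpy as np
import pytest

from aortashear.oracles import FluidProperties, plane_poiseuille_wss
from aortashear.solver import (
    GeometryError,
    Ostium,
    OutletSplit,
    SolverError,
    build_channel,
    extract_wall_shear,
    make_solver,
    run_cycles,
    run_to_steady,
)
from aortashear.waveform import fit_bezier_waveform, scale_waveform
from aortashear.synthetic import default_mouse_waveform

H = 1.58e-3
T = 0.1


def small_ostia_geometry(nx=64, ny=16, n_pairs=2):
    width = 0.18 * H
    xs = np.linspace(0.3, 0.7, n_pairs) * 6 * H
    ostia = []
    for x in xs:
        ostia.append(Ostium("lower", float(x), width))
        ostia.append(Ostium("upper", float(x), width))
    return build_channel(
        {"length_L": 6 * H, "height_h": H, "grid_nx": nx, "grid_ny": ny, "ostia": ostia}
    )


@pytest.fixture(scope="module")
def mouse_spline():
    return fit_bezier_waveform(default_mouse_waveform(), 8)


class TestGeometry:
    def test_plain_channel_has_two_openings(self):
        geo = build_channel({"length_L": 6 * H, "height_h": H, "grid_nx": 32,
                             "grid_ny": 16, "ostia": []})
        labels = geo.boundary_face_labels()
        assert set(labels["left"]) == {"inlet"} and set(labels["right"]) == {"outlet"}
        assert set(labels["lower"]) == {"wall"} and set(labels["upper"]) == {"wall"}

    def test_default_layout_counts_twelve_ostia(self):
        geo = build_channel({"length_L": 12 * H, "height_h": H, "grid_nx": 128,
                             "grid_ny": 32, "ostia": "default"})
        labels = geo.boundary_face_labels()
        openings = set()
        for side in ("lower", "upper"):
            openings |= {l for l in labels[side] if l.startswith("ostium")}
        assert len(openings) == 12
        assert len(geo.ostia) == 12
        quad_counts = collections.Counter(geo.ostium_quadrant(k) for k in range(12))
        assert set(quad_counts) == {"left_upper", "right_upper", "left_lower", "right_lower"}
        assert all(v == 3 for v in quad_counts.values())

    def test_boundary_faces_classified_exactly_once(self):
        geo = small_ostia_geometry()
        labels = geo.boundary_face_labels()
        assert labels["lower"].shape == (geo.grid_nx,)
        assert labels["upper"].shape == (geo.grid_nx,)
        # every face carries exactly one valid label
        valid = {"wall"} | {f"ostium_{k}" for k in range(len(geo.ostia))}
        assert set(labels["lower"]) | set(labels["upper"]) <= valid
        # each ostium's faces appear on exactly one wall, with no overlap
        total_open = sum(l.startswith("ostium") for l in labels["lower"]) + sum(
            l.startswith("ostium") for l in labels["upper"]
        )
        assert total_open == sum(
            i1 - i0 for side in ("lower", "upper") for i0, i1 in geo.ostium_faces(side)
        )

    def test_invalid_geometries_rejected(self):
        with pytest.raises(GeometryError, match="width"):
            build_channel({"length_L": 6 * H, "height_h": H, "grid_nx": 32,
                           "grid_ny": 16, "ostia": [("lower", 3 * H, H / 2)]})
        with pytest.raises(GeometryError, match="overlap"):
            build_channel({"length_L": 6 * H, "height_h": H, "grid_nx": 32,
                           "grid_ny": 16,
                           "ostia": [("lower", 3 * H, 0.2 * H), ("lower", 3.05 * H, 0.2 * H)]})

    def test_split_normalization_is_exact(self):
        s = OutletSplit.paper_default(12)
        f = s.normalized()
        assert sum(f.values()) == 1.0
        # relative proportions preserved: each ostium is 0.14/69.8 of main
        assert f["ostium_0"] / f["main"] == pytest.approx(0.0014 / 0.698, rel=1e-12)
        with pytest.raises(GeometryError):
            OutletSplit({"main": -1.0})


class TestStep:
    def test_zero_inlet_is_fixed_point(self, props):
        geo = small_ostia_geometry()
        solver = make_solver(geo, props, 0.0, OutletSplit.paper_default(4), dt=1e-4)
        state = solver.initial_state()
        for _ in range(5):
            state = solver.step(state)
        assert np.all(state.u == 0.0) and np.all(state.v == 0.0)

    def test_mass_balance_and_divergence_every_step(self, props, mouse_spline):
        geo = small_ostia_geometry()
        wf = scale_waveform(mouse_spline, 0.3)
        solver = make_solver(geo, props, wf, OutletSplit.paper_default(4), dt=T / 500)
        state = solver.initial_state()
        v_scale = 0.45 / geo.height_h  # peak velocity over channel height
        for _ in range(25):
            state = solver.step(state)
            assert state.mass_error < 1e-10
            assert state.max_divergence < 1e-8 * v_scale
            errs = solver.ostium_flux_errors(state)
            assert np.max(errs) < 1e-6

    def test_cfl_violation_is_signalled(self, props):
        geo = small_ostia_geometry()
        solver = make_solver(geo, props, 0.5, OutletSplit.paper_default(4), dt=0.05)
        state = solver.initial_state()
        with pytest.raises(SolverError, match="CFL"):
            for _ in range(10):
                state = solver.step(state)


class TestSteadyFlow:
    def test_wall_shear_matches_plane_poiseuille(self, props):
        U = 0.1
        geo = build_channel({"length_L": 8 * H, "height_h": H, "grid_nx": 48,
                             "grid_ny": 64, "ostia": []})
        state, _ = run_to_steady(geo, props, U, OutletSplit({"main": 1.0}), tol=1e-10)
        wss = extract_wall_shear(state, geo, props)
        band = wss[(wss.x > 2 * H) & (wss.x < 5 * H)]
        exact = plane_poiseuille_wss(props, U, H)
        assert np.max(np.abs(band.tau_x - exact)) / exact < 0.02

    def test_wall_shear_field_mirror_symmetric(self, props):
        geo = build_channel({"length_L": 6 * H, "height_h": H, "grid_nx": 32,
                             "grid_ny": 32, "ostia": []})
        state, _ = run_to_steady(geo, props, 0.1, OutletSplit({"main": 1.0}), tol=1e-10)
        wss = extract_wall_shear(state, geo, props)
        lo = wss[wss.side == "lower"].sort_values("x")["tau_x"].to_numpy()
        up = wss[wss.side == "upper"].sort_values("x")["tau_x"].to_numpy()
        assert np.max(np.abs(lo - up)) < 1e-6 * np.max(np.abs(lo))

    def test_quiescent_state_has_zero_wall_shear(self, props):
        geo = small_ostia_geometry()
        solver = make_solver(geo, props, 0.0, OutletSplit.paper_default(4), dt=1e-4)
        wss = extract_wall_shear(solver.initial_state(), geo, props)
        assert np.all(wss.tau_x == 0.0) and np.all(wss.tau_y == 0.0)

    def test_wall_points_exclude_ostium_openings(self, props):
        geo = small_ostia_geometry()
        solver = make_solver(geo, props, 0.1, OutletSplit.paper_default(4), dt=1e-4)
        wss = extract_wall_shear(solver.initial_state(), geo, props)
        for side in ("lower", "upper"):
            xs = wss[wss.side == side].x.to_numpy()
            for (i0, i1) in geo.ostium_faces(side):
                assert not np.any((xs >= i0 * geo.dx) & (xs <= i1 * geo.dx))


class TestRunCycles:
    def test_steady_inlet_gives_time_constant_wss(self):
        # a quickly-settling fluid so two cycles reach steady state from rest
        thick = FluidProperties(density_rho=100.0, dynamic_viscosity_eta=0.04)
        geo = build_channel({"length_L": 6 * H, "height_h": H, "grid_nx": 32,
                             "grid_ny": 16, "ostia": []})
        recs, diag = run_cycles(geo, thick, 0.1, OutletSplit({"main": 1.0}),
                                n_cycles=2, steps_per_cycle=250, period_T=T)
        for r in recs:
            series = r.tau_vectors[:, 0]
            assert np.std(series) / np.abs(series.mean()) < 1e-3

    def test_scaled_inlet_lowers_tawss_everywhere(self, props, mouse_spline):
        from aortashear.metrics import compute_metrics

        geo = small_ostia_geometry(nx=64, ny=16)
        splits = OutletSplit.paper_default(4)
        out = {}
        for fac in (1.0, 0.8):
            wf = scale_waveform(mouse_spline, 0.3 * fac)
            recs, _ = run_cycles(geo, props, wf, splits, n_cycles=2, steps_per_cycle=500)
            out[fac] = compute_metrics(recs).sort_values("point_id")["tawss_pa"].to_numpy()
        assert np.all(out[0.8] < out[1.0])

    def test_records_carry_region_labels_and_periods(self, props, mouse_spline):
        geo = small_ostia_geometry()
        wf = scale_waveform(mouse_spline, 0.3)
        recs, diag = run_cycles(geo, props, wf, OutletSplit.paper_default(4),
                                n_cycles=2, steps_per_cycle=500)
        regions = {r.region_label for r in recs}
        assert "non-ostial" in regions and len(regions) > 1
        for r in recs[:5]:
            assert r.period_T == T and r.times.size == 500
            assert abs(np.linalg.norm(r.outward_normal) - 1) < 1e-12

    def test_single_cycle_rejected(self, props, mouse_spline):
        geo = small_ostia_geometry()
        with pytest.raises(SolverError, match="warm-up"):
            run_cycles(geo, props, mouse_spline, OutletSplit.paper_default(4), n_cycles=1)
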