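"""Particle transport: interpolation, random-walk physics, arrivals."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

import stepstone as st
from stepstone.ptm import FlowInterpolator, PTMConfig, _reflect


def grid_flow(u_values, x, y, t):
    """Flow dataset from explicit u values (t, y, x); v = 0."""
    u = np.asarray(u_values, dtype=float)
    return xr.Dataset(
        {"u": (("t", "y", "x"), u), "v": (("t", "y", "x"), np.zeros_like(u))},
        coords={"t": t, "y": y, "x": x},
    )


class TestInterpolation:
    def test_exact_at_grid_node_and_snapshot(self):
        flow = grid_flow(
            [[[1.0, 2.0], [3.0, 4.0]], [[5.0, 6.0], [7.0, 8.0]]],
            x=[0.0, 10.0], y=[0.0, 10.0], t=[0.0, 1.0],
        )
        u, v = st.interpolate_velocity(flow, (10.0, 0.0), 0.0)
        assert u == 2.0 and v == 0.0

    def test_bilinear_cell_centre_mean(self):
        corners = [[0.0, 0.0], [0.0, 4.0]]
        flow = grid_flow(
            [corners, corners], x=[0.0, 10.0], y=[0.0, 10.0], t=[0.0, 1.0],
        )
        u, _ = st.interpolate_velocity(flow, (5.0, 5.0), 0.0)
        assert u == pytest.approx(1.0)

    def test_linear_time_blend(self):
        flow = grid_flow(
            [[[1.0, 1.0], [1.0, 1.0]], [[3.0, 3.0], [3.0, 3.0]]],
            x=[0.0, 10.0], y=[0.0, 10.0], t=[0.0, 2.0],
        )
        u, _ = st.interpolate_velocity(flow, (5.0, 5.0), 1.0)
        assert u == pytest.approx(2.0)

    def test_time_outside_range_rejected(self):
        flow = grid_flow(
            [[[0.0, 0.0], [0.0, 0.0]]], x=[0.0, 10.0], y=[0.0, 10.0], t=[0.0],
        )
        with pytest.raises(ValueError):
            FlowInterpolator(flow)  # single snapshot: degenerate axis

    def test_nonfinite_velocity_rejected(self):
        flow = grid_flow(
            [[[np.nan, 0.0], [0.0, 0.0]], [[0.0, 0.0], [0.0, 0.0]]],
            x=[0.0, 10.0], y=[0.0, 10.0], t=[0.0, 1.0],
        )
        with pytest.raises(ValueError, match="finite"):
            FlowInterpolator(flow)


class TestAdvance:
    def test_pure_advection_exact(self):
        flow = st.make_flow_field(extent_km=(100, 50), resolution_km=10,
                                  duration_days=1, residual=(0.1, 0.0),
                                  tide_amplitude=0.0)
        interp = FlowInterpolator(flow)
        pos = np.array([[10.0, 25.0], [50.0, 10.0]])
        new, alive = st.advance_particles(pos, interp, 0.0, 1800.0, 0.0,
                                          np.random.default_rng(0))
        np.testing.assert_allclose(new - pos, [[0.18, 0.0], [0.18, 0.0]])
        assert alive.all()

    def test_diffusion_law_variance(self):
        flow = st.make_flow_field(extent_km=(2000, 2000), resolution_km=200,
                                  duration_days=2, residual=(0.0, 0.0),
                                  tide_amplitude=0.0)
        interp = FlowInterpolator(flow)
        rng = np.random.default_rng(42)
        D, dt = 10.0, 1800.0
        pos = np.full((10_000, 2), 1000.0)
        for step in range(24):
            pos, _ = st.advance_particles(pos, interp, step * 0.5, dt, D, rng)
        T = 24 * dt
        var_m2 = pos.var(axis=0) * 1e6
        np.testing.assert_allclose(var_m2, 2 * D * T, rtol=0.05)

    def test_reflection_preserves_wall_distance(self):
        # strong eastward flow pushes past the x = 100 wall
        flow = st.make_flow_field(extent_km=(100, 50), resolution_km=10,
                                  duration_days=1, residual=(1.0, 0.0),
                                  tide_amplitude=0.0)
        interp = FlowInterpolator(flow)
        pos = np.array([[99.0, 25.0]])  # step of 1.8 km -> 0.8 km past wall
        new, _ = st.advance_particles(pos, interp, 0.0, 1800.0, 0.0,
                                      np.random.default_rng(0))
        assert new[0, 0] == pytest.approx(100.0 - 0.8)

    def test_reflect_helper_stays_inside(self):
        q = _reflect(np.array([-5.0, 3.0, 17.0, 29.0]), 0.0, 10.0)
        assert ((q >= 0.0) & (q <= 10.0)).all()
        np.testing.assert_allclose(q, [5.0, 3.0, 3.0, 9.0])

    def test_absorbing_boundary_kills_leavers(self):
        flow = st.make_flow_field(extent_km=(100, 50), resolution_km=10,
                                  duration_days=1, residual=(1.0, 0.0),
                                  tide_amplitude=0.0)
        interp = FlowInterpolator(flow)
        pos = np.array([[99.5, 25.0], [10.0, 25.0]])
        new, alive = st.advance_particles(pos, interp, 0.0, 1800.0, 0.0,
                                          np.random.default_rng(0),
                                          boundary="absorb")
        assert alive.tolist() == [False, True]


class TestRunPTM:
    def test_zero_flow_diagonal_matrix(self, line_sites):
        sites, positions = line_sites
        flow = st.make_flow_field(extent_km=(100, 50), resolution_km=10,
                                  duration_days=1, residual=(0.0, 0.0),
                                  tide_amplitude=0.0)
        cfg = PTMConfig(particles_per_release=5, release_interval_min=60,
                        release_duration_days=0.25, tracking_duration_days=0.5,
                        time_step_min=30, dispersion_m2_s=0.0)
        arr = st.run_ptm(flow, sites, cfg, seed=0, positions_km=positions)
        c = arr.counts.to_numpy()
        assert (np.diag(c) == arr.released.to_numpy()).all()
        assert (c - np.diag(np.diag(c)) == 0).all()

    def test_uniform_flow_carries_origin_over_destination(self, line_sites):
        sites, positions = line_sites
        # 0.1 m/s = 0.36 km/h covers the 20 km gap in ~56 h < 4 d window
        flow = st.make_flow_field(extent_km=(100, 50), resolution_km=10,
                                  duration_days=5, residual=(0.1, 0.0),
                                  tide_amplitude=0.0)
        cfg = PTMConfig(particles_per_release=3, release_interval_min=120,
                        release_duration_days=0.5, tracking_duration_days=4,
                        time_step_min=30, dispersion_m2_s=0.0)
        arr = st.run_ptm(flow, sites, cfg, seed=0, positions_km=positions)
        released = arr.released
        for src, dst in [("A", "B"), ("B", "C"), ("C", "D")]:
            assert arr.counts.loc[src, dst] == released[src]
            assert arr.counts.loc[dst, src] == 0  # no upstream transport

    def test_counts_monotone_in_capture_radius(self, line_sites):
        sites, positions = line_sites
        flow = st.make_flow_field(extent_km=(100, 50), resolution_km=10,
                                  duration_days=3, residual=(0.05, 0.0),
                                  tide_amplitude=0.3)
        kw = dict(particles_per_release=5, release_interval_min=180,
                  release_duration_days=1, tracking_duration_days=2,
                  time_step_min=60, dispersion_m2_s=10.0)
        small = st.run_ptm(flow, sites, PTMConfig(capture_radius_km=2, **kw),
                           seed=5, positions_km=positions)
        large = st.run_ptm(flow, sites, PTMConfig(capture_radius_km=6, **kw),
                           seed=5, positions_km=positions)
        assert (large.counts.to_numpy() >= small.counts.to_numpy()).all()

    def test_identical_origins_exchangeable_in_expectation(self):
        from stepstone.sites import SiteTable

        ids = ["P", "Q", "T"]
        tbl = SiteTable(pd.DataFrame({"site_id": ids, "lat": [0.2, 0.2, 0.3],
                                      "lon": [0.2, 0.2, 0.4]}))
        positions = pd.DataFrame({"x_km": [30.0, 30.0, 60.0],
                                  "y_km": [25.0, 25.0, 25.0]},
                                 index=pd.Index(ids, name="site_id"))
        flow = st.make_flow_field(extent_km=(100, 50), resolution_km=10,
                                  duration_days=2, residual=(0.1, 0.0),
                                  tide_amplitude=0.0)
        cfg = PTMConfig(particles_per_release=10, release_interval_min=360,
                        release_duration_days=0.5, tracking_duration_days=1.5,
                        time_step_min=60, dispersion_m2_s=20.0,
                        capture_radius_km=4.0)
        rows_p, rows_q = [], []
        for seed in range(12):
            arr = st.run_ptm(flow, tbl, cfg, seed=seed, positions_km=positions)
            rows_p.append(arr.counts.loc["P", "T"])
            rows_q.append(arr.counts.loc["Q", "T"])
        # same release point -> arrival rates differ only by sampling noise
        mp, mq = np.mean(rows_p), np.mean(rows_q)
        pooled_se = np.sqrt((np.var(rows_p) + np.var(rows_q)) / 12)
        assert abs(mp - mq) <= max(4 * pooled_se, 2.0)

    def test_site_outside_domain_rejected_before_run(self, line_sites):
        sites, positions = line_sites
        positions = positions.copy()
        positions.loc["D", "x_km"] = 500.0
        flow = st.make_flow_field(extent_km=(100, 50), resolution_km=10,
                                  duration_days=1)
        with pytest.raises(ValueError, match="outside"):
            st.run_ptm(flow, sites, PTMConfig(particles_per_release=1,
                                              release_duration_days=0.1,
                                              tracking_duration_days=0.2),
                       seed=0, positions_km=positions)

    def test_default_schedule_arithmetic(self):
        cfg = PTMConfig()
        assert cfg.n_release_events == 672
        assert cfg.particles_per_origin == 1489 * 672


class TestProportions:
    def test_entries_in_unit_interval_and_scale_invariance(self, line_sites):
        sites, _ = line_sites
        counts = pd.DataFrame(
            [[5, 3, 0, 0], [0, 10, 1, 0], [0, 0, 10, 0], [0, 0, 0, 10]],
            index=list("ABCD"), columns=list("ABCD"),
        )
        arr1 = st.ArrivalMatrix(counts, pd.Series(10, index=list("ABCD")))
        arr2 = st.ArrivalMatrix(counts * 10, pd.Series(100, index=list("ABCD")))
        p1 = st.arrivals_to_proportions(arr1)
        p2 = st.arrivals_to_proportions(arr2)
        assert ((p1.to_numpy() >= 0) & (p1.to_numpy() <= 1)).all()
        pd.testing.assert_frame_equal(p1, p2)

    def test_zero_row_flagged_without_retention(self):
        counts = pd.DataFrame(
            [[4, 0, 0], [0, 4, 2], [0, 1, 4]], index=list("XYZ"), columns=list("XYZ")
        )
        arr = st.ArrivalMatrix(counts, pd.Series(4, index=list("XYZ")))
        props = st.arrivals_to_proportions(arr, include_retention=False)
        assert props.attrs["zero_rows"] == ["X"]
        assert (props.loc["X"] == 0).all()
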