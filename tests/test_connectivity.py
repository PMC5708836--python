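import numpy as np
import pandas as pd
import pytest

import tunadrift as td
from tunadrift.connectivity import (SuccessArea, age_at_arrival,
                                    arrivals_series, convergence_check,
                                    density_map, origin_table, sea_fraction,
                                    weighted_success, raw_count)
from tunadrift.transport import (STATUS_ACTIVE, STATUS_OUT, SECONDS_PER_DAY,
                                 TrajectorySet)

from conftest import make_coast_field, make_uniform_field


def manual_traj(lon, lat, times=(0.0,), origin=None, status=None,
                release_time=None):
    """Hand-built trajectory set; lon/lat are (n_times, n_particles)."""
    lon = np.atleast_2d(np.asarray(lon, dtype=float))
    lat = np.atleast_2d(np.asarray(lat, dtype=float))
    nt, n = lon.shape
    status = (np.full((nt, n), STATUS_ACTIVE, dtype=np.int8)
              if status is None else np.asarray(status, dtype=np.int8))
    origin = np.array(["src"] * n) if origin is None else np.asarray(origin)
    release = (np.zeros(n) if release_time is None
               else np.asarray(release_time, dtype=float))
    age = (np.asarray(times, dtype=float)[:, None] - release[None, :]) / SECONDS_PER_DAY
    return TrajectorySet(times=np.asarray(times, dtype=float), lon=lon,
                         lat=lat, depth=np.zeros((nt, n)), age_days=age,
                         status=status, origin=origin, release_time_s=release,
                         pid=np.arange(n))


class TestDensityMap:
    def test_all_particles_in_one_cell(self):
        f = make_uniform_field(n=11)
        traj = manual_traj([np.full(100, 0.101)], [np.full(100, 0.099)])
        dm = density_map(traj, f)
        assert dm.counts.max() == 100
        assert dm.total == 100

    def test_edge_particle_counted_once_in_upper_cell(self):
        # Integer-spaced nodes at 0.5, 1.5, ... so the cell edges 0, 1, 2,
        # ... are exactly representable; the query sits exactly on edge 2.
        from tunadrift.fields import GridAxes, GridField

        nodes = np.arange(10) + 0.5
        axes = GridAxes(lon=nodes, lat=nodes, depth=np.array([0.0, 10.0]),
                        time=np.array([0.0, 1.0]))
        f = GridField(axes=axes, u=np.zeros(axes.shape),
                      v=np.zeros(axes.shape),
                      mask=np.ones(axes.shape[2:], bool))
        traj = manual_traj([[2.0]], [[2.5]])
        dm = density_map(traj, f)
        iy, ix = np.argwhere(dm.counts == 1)[0]
        assert dm.total == 1
        # lower-left inclusive: the edge belongs to the cell it bounds below
        assert f.lon_edges()[ix] == 2.0

    def test_total_equals_active_count(self, forward_traj, basin_field):
        dm = density_map(forward_traj, basin_field, time_index=-1)
        assert dm.total == int(forward_traj.active(-1).sum())


class TestSeaFraction:
    def test_all_sea_square(self):
        f = make_uniform_field(n=21)
        area = SuccessArea(lon=0.0, lat=0.0, area_km2=400.0)
        assert sea_fraction(area, f) == 1.0

    def test_half_sea_constructed_mask(self):
        f = make_coast_field(n=10, land_from_ix=5)
        # Square spanning lon 0.3-0.7: nodes 0.35, 0.45 sea; 0.55, 0.65 land.
        side_km = 0.4 * 111.19492664455873
        area = SuccessArea(lon=0.5, lat=0.45, area_km2=side_km ** 2)
        assert sea_fraction(area, f) == pytest.approx(0.5)

    def test_all_land_square(self):
        f = make_coast_field()
        side_km = 0.2 * 111.19492664455873
        area = SuccessArea(lon=0.8, lat=0.45, area_km2=side_km ** 2)
        assert sea_fraction(area, f) == 0.0

    def test_square_outside_grid_raises(self):
        f = make_uniform_field()
        with pytest.raises(ValueError, match="no grid points"):
            sea_fraction(SuccessArea(lon=50.0, lat=50.0, area_km2=1.0), f)


class TestWeightedSuccess:
    def test_all_sea_weight_is_identity(self):
        f = make_uniform_field(n=21)
        area = SuccessArea(lon=0.0, lat=0.0, area_km2=400.0)
        traj = manual_traj([np.zeros(100)], [np.zeros(100)])
        assert weighted_success(traj, area, f) == 100.0

    def test_fraction_times_count(self):
        f = make_coast_field(n=10, land_from_ix=5)
        side_km = 0.4 * 111.19492664455873
        area = SuccessArea(lon=0.5, lat=0.45, area_km2=side_km ** 2)
        traj = manual_traj([np.full(50, 0.45)], [np.full(50, 0.45)])
        assert weighted_success(traj, area, f) == pytest.approx(0.5 * 50)

    def test_empty_square_is_zero(self):
        f = make_coast_field()
        side_km = 0.2 * 111.19492664455873
        area = SuccessArea(lon=0.25, lat=0.45, area_km2=side_km ** 2)
        traj = manual_traj([[0.05]], [[0.05]])
        assert weighted_success(traj, area, f) == 0.0

    def test_weighted_never_exceeds_raw(self, forward_traj, basin_field,
                                        basin_areas):
        for area in basin_areas.values():
            w = weighted_success(forward_traj, area, basin_field)
            r = raw_count(forward_traj, area)
            assert w <= r + 1e-9
            if sea_fraction(area, basin_field) == 1.0:
                assert w == r

    def test_out_of_domain_particles_not_counted(self):
        f = make_uniform_field(n=21)
        area = SuccessArea(lon=0.0, lat=0.0, area_km2=400.0)
        status = np.array([[STATUS_ACTIVE, STATUS_OUT]])
        traj = manual_traj([[0.0, 0.0]], [[0.0, 0.0]], status=status)
        assert raw_count(traj, area) == 1


class TestArrivalsSeries:
    def test_permanently_inside_particle_constant_series(self):
        f = make_coast_field(n=10, land_from_ix=5)
        side_km = 0.4 * 111.19492664455873
        area = SuccessArea(lon=0.5, lat=0.45, area_km2=side_km ** 2,
                           label="a")
        times = [0.0, 3600.0, 7200.0]
        traj = manual_traj([[0.45]] * 3, [[0.45]] * 3, times=times)
        ser = arrivals_series(traj, [area], f)
        assert np.allclose(ser["weighted_count"], 0.5)

    def test_never_visited_area_all_zero(self):
        f = make_uniform_field(n=21)
        area = SuccessArea(lon=0.9, lat=0.9, area_km2=25.0, label="far")
        traj = manual_traj([[0.0], [0.0]], [[0.0], [0.0]],
                           times=[0.0, 3600.0])
        ser = arrivals_series(traj, [area], f)
        assert (ser["weighted_count"] == 0.0).all()

    def test_backward_run_reaches_only_up_current_farm(
            self, backward_traj, basin_field, basin_areas):
        farms = ["farm_north_a", "farm_north_b", "farm_south"]
        ser = arrivals_series(backward_traj,
                              [basin_areas[k] for k in farms], basin_field)
        peak = ser.groupby("area")["weighted_count"].max()
        assert peak["farm_south"] > 0
        assert peak["farm_north_a"] == 0
        assert peak["farm_north_b"] == 0


class TestOriginTable:
    def test_single_source_single_row(self):
        f = make_uniform_field(n=21)
        area = SuccessArea(lon=0.0, lat=0.0, area_km2=400.0)
        traj = manual_traj([np.zeros(10)], [np.zeros(10)])
        tab = origin_table(traj, area)
        assert len(tab) == 1
        assert tab["count"].iloc[0] == 10

    def test_rows_partition_in_area_total(self, forward_traj, basin_field,
                                          basin_areas):
        area = basin_areas["catch_site"]
        tab = origin_table(forward_traj, area)
        assert tab["count"].sum() == raw_count(forward_traj, area)

    def test_only_up_current_source_connects(self, forward_traj, basin_areas):
        tab = origin_table(forward_traj, basin_areas["catch_site"])
        counts = dict(zip(tab["origin"], tab["count"]))
        assert counts["farm_south"] > 0
        assert counts["farm_north_a"] == 0
        assert counts["farm_north_b"] == 0


class TestAgeAtArrival:
    def test_single_release_event_single_bin(self):
        f = make_uniform_field(n=21)
        area = SuccessArea(lon=0.0, lat=0.0, area_km2=400.0)
        t_end = 5 * SECONDS_PER_DAY
        traj = manual_traj([np.zeros(20)], [np.zeros(20)], times=[t_end])
        hist = age_at_arrival(traj, area)
        assert len(hist) == 1
        assert hist["count"].iloc[0] == 20
        assert hist["age_day_bin"].iloc[0] == 5

    def test_bin_total_equals_in_area_count(self, forward_traj, basin_field,
                                            basin_areas):
        area = basin_areas["catch_site"]
        hist = age_at_arrival(forward_traj, area)
        assert hist["count"].sum() == raw_count(forward_traj, area)

    def test_release_schedule_bounds_ages(self, forward_traj, basin_areas):
        # 20 daily releases, 30-day window: any in-area age must lie in
        # (30 - 20, 30] days up to the snapshot stride.
        hist = age_at_arrival(forward_traj, basin_areas["catch_site"])
        assert hist["age_day_bin"].min() >= 30 - 20
        assert hist["age_day_bin"].max() <= 30


class TestConvergence:
    @staticmethod
    def _iid_run_factory(area, box_half_deg):
        """Stub experiment: particles i.i.d. uniform in a box around (0,0)."""
        def run(cfg):
            n = sum(r.count * len(r.schedule_s) for r in cfg.releases)
            rng = np.random.default_rng(cfg.seed + n)
            lon = rng.uniform(-box_half_deg, box_half_deg, n)
            lat = rng.uniform(-box_half_deg, box_half_deg, n)
            return manual_traj([lon], [lat])
        return run

    def test_deterministic_point_release_zero_change(self):
        f = make_uniform_field(u0=0.0, n=21)
        area = SuccessArea(lon=0.0, lat=0.0, area_km2=400.0)

        def run(cfg):
            n = sum(r.count for r in cfg.releases)
            return manual_traj([np.zeros(n)], [np.zeros(n)])

        from tunadrift.transport import ExperimentConfig, ReleaseSpec
        cfg = ExperimentConfig(
            orientation="forward",
            releases=(ReleaseSpec(label="s", lon=0.0, lat=0.0, radius_m=1.0,
                                  depth_min_m=0.0, depth_max_m=1.0, count=10,
                                  schedule_s=(0.0,)),),
            epsilon=0.0, duration_days=1.0)
        out = convergence_check(cfg, f, area, counts=[100, 200], run=run)
        assert (out["rel_change"] == 0.0).all()

    def test_iid_placement_error_shrinks_like_sqrt_n(self):
        f = make_uniform_field(u0=0.0, n=21)
        area = SuccessArea(lon=0.0, lat=0.0, area_km2=400.0)
        bounds = area.bounds()
        box_half = 2 * (bounds[1] - bounds[0]) / 2  # area covers 1/4 of box

        from tunadrift.transport import ExperimentConfig, ReleaseSpec
        base = ReleaseSpec(label="s", lon=0.0, lat=0.0, radius_m=1.0,
                           depth_min_m=0.0, depth_max_m=1.0, count=10,
                           schedule_s=(0.0,))
        small, large = [], []
        for seed in range(40):
            cfg = ExperimentConfig(orientation="forward", releases=(base,),
                                   epsilon=0.0, duration_days=1.0, seed=seed)
            run = self._iid_run_factory(area, box_half)
            out = convergence_check(cfg, f, area,
                                    counts=[200, 400, 3200, 6400], run=run)
            small.append(out["rel_change"].iloc[0])
            large.append(out["rel_change"].iloc[-1])
        ratio = np.mean(small) / np.mean(large)
        # 16x more particles: sampling error should drop ~4x.
        assert 2.0 < ratio < 8.0
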