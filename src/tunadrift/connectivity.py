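"""Connectivity statistics on trajectory sets.

The dispersal runs are summarized the way the source-attribution analysis
needs them: particle density on the model grid cells (2.5 km nominal),
presence counts inside fixed "areas of success" (a square around a farm
for backward runs, around the catch site for forward runs), weighting of
those counts by the fraction of sea points inside the square, arrival time
series, counts by origin, age-at-arrival histograms, and a particle-number
convergence check.

The success-square side is computed from its area on the local spherical
metric at the square's center; counts use instantaneous presence at each
output time, not first passage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fields import DEG, EARTH_RADIUS_M, GridField
from .transport import SECONDS_PER_DAY, STATUS_ACTIVE, TrajectorySet


@dataclass(frozen=True)
class SuccessArea:
    """An axis-aligned square region of given area (km^2) around a site."""

    lon: float
    lat: float
    area_km2: float
    label: str = "area"

    def __post_init__(self):
        if self.area_km2 <= 0:
            raise ValueError("area must be > 0")

    @property
    def side_km(self) -> float:
        return float(np.sqrt(self.area_km2))

    def bounds(self) -> tuple[float, float, float, float]:
        """(lon_min, lon_max, lat_min, lat_max) of the square in degrees."""
        half_m = self.side_km * 500.0
        dlat = half_m / (EARTH_RADIUS_M * DEG)
        dlon = half_m / (EARTH_RADIUS_M * np.cos(self.lat * DEG) * DEG)
        return (self.lon - dlon, self.lon + dlon, self.lat - dlat, self.lat + dlat)

    def contains(self, lon, lat) -> np.ndarray:
        x0, x1, y0, y1 = self.bounds()
        lon = np.asarray(lon)
        lat = np.asarray(lat)
        return (lon >= x0) & (lon <= x1) & (lat >= y0) & (lat <= y1)


@dataclass
class DensityMap:
    """Particle counts per grid cell at one output time."""

    lon: np.ndarray       # cell centers
    lat: np.ndarray
    counts: np.ndarray    # (lat, lon) integer counts
    t_s: float
    cell_km: float

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def density_map(traj: TrajectorySet, field: GridField, time_index: int = -1
                ) -> DensityMap:
    """Bin active particles onto the field's grid cells at one output time.

    Cells are half-open (lower-left edge inclusive), so each particle lands
    in exactly one cell and the map total equals the in-domain active count.
    """
    i = range(traj.n_times)[time_index]
    act = traj.active(i)
    iy, ix, inside = field.cell_index(traj.lon[i, act], traj.lat[i, act])
    counts = np.zeros((field.axes.lat.size, field.axes.lon.size), dtype=np.int64)
    np.add.at(counts, (iy[inside], ix[inside]), 1)
    cell_km = float(np.mean(field.mean_cell_size_m(field.axes.lat))) / 1000.0
    return DensityMap(lon=field.axes.lon, lat=field.axes.lat, counts=counts,
                      t_s=float(traj.times[i]), cell_km=cell_km)


def sea_fraction(area: SuccessArea, field: GridField) -> float:
    """Fraction of grid points inside the square that are sea."""
    x0, x1, y0, y1 = area.bounds()
    in_lon = (field.axes.lon >= x0) & (field.axes.lon <= x1)
    in_lat = (field.axes.lat >= y0) & (field.axes.lat <= y1)
    n_pts = int(in_lon.sum()) * int(in_lat.sum())
    if n_pts == 0:
        raise ValueError(
            f"success area {area.label!r} contains no grid points")
    sub = field.mask[np.ix_(in_lat, in_lon)]
    return float(sub.sum()) / n_pts


def raw_count(traj: TrajectorySet, area: SuccessArea, time_index: int = -1) -> int:
    """Number of active particles inside the square at one output time."""
    i = range(traj.n_times)[time_index]
    act = traj.active(i)
    return int(area.contains(traj.lon[i, act], traj.lat[i, act]).sum())


def weighted_success(traj: TrajectorySet, area: SuccessArea, field: GridField,
                     time_index: int = -1) -> float:
    """Sea-fraction-weighted particle count inside the success square.

    The in-square count is multiplied by the fraction (0-1) of sea points in
    the square, down-weighting squares that are mostly land so presence is
    comparable across sites.
    """
    return sea_fraction(area, field) * raw_count(traj, area, time_index)


def arrivals_series(traj: TrajectorySet, areas, field: GridField) -> pd.DataFrame:
    """Weighted in-square counts per output time for each area.

    Snapshot convention: a row reflects presence at that time, not the
    cumulative number of particles that ever entered.
    """
    fracs = {a.label: sea_fraction(a, field) for a in areas}
    rows = []
    for i in range(traj.n_times):
        act = traj.active(i)
        lon_i, lat_i = traj.lon[i, act], traj.lat[i, act]
        for a in areas:
            raw = int(a.contains(lon_i, lat_i).sum())
            rows.append({"t_s": float(traj.times[i]), "area": a.label,
                         "raw_count": raw,
                         "weighted_count": fracs[a.label] * raw})
    return pd.DataFrame(rows)


def origin_table(traj: TrajectorySet, area: SuccessArea, time_index: int = -1
                 ) -> pd.DataFrame:
    """In-square active particles grouped by origin label at one time."""
    i = range(traj.n_times)[time_index]
    act = traj.active(i)
    inside = np.zeros(traj.n_particles, dtype=bool)
    inside[act] = area.contains(traj.lon[i, act], traj.lat[i, act])
    labels = np.unique(traj.origin)
    rows = [{"origin": lab, "count": int((inside & (traj.origin == lab)).sum())}
            for lab in labels]
    return pd.DataFrame(rows)


def age_at_arrival(traj: TrajectorySet, area: SuccessArea, time_index: int = -1
                   ) -> pd.DataFrame:
    """Histogram of in-square particle ages, one bin per release day.

    Because age equals elapsed time since release, binning ages by whole
    days is equivalent to grouping by release date.
    """
    i = range(traj.n_times)[time_index]
    act = traj.active(i)
    inside = act.copy()
    inside[act] = area.contains(traj.lon[i, act], traj.lat[i, act])
    ages = traj.age_days[i, inside]
    rel_day = np.abs(traj.release_time_s[inside] - traj.times[0]) / SECONDS_PER_DAY
    if ages.size == 0:
        return pd.DataFrame(columns=["age_day_bin", "release_day", "count"])
    bins = np.floor(ages).astype(int)
    df = pd.DataFrame({"age_day_bin": bins,
                       "release_day": np.floor(rel_day).astype(int)})
    out = (df.groupby(["age_day_bin", "release_day"]).size()
             .reset_index(name="count")
             .sort_values("age_day_bin", ignore_index=True))
    return out


def convergence_check(config, field: GridField, area: SuccessArea,
                      counts, run=None) -> pd.DataFrame:
    """Relative change of the end-time success fraction across N doublings.

    For each particle number N in ``counts`` the experiment is re-run with
    every release scaled to N particles per event, and the end-time weighted
    success per released particle is compared between successive levels:
    ``rel_change = |s(N) - s(2N)| / s(2N)``.  The per-particle normalization
    makes the statistic invariant to N itself, so a deterministic flow with
    a point release gives exactly zero change.
    """
    from dataclasses import replace

    from .transport import run_experiment

    counts = sorted(int(n) for n in counts)
    if len(counts) < 2:
        raise ValueError("need at least two particle-number levels")
    run = run or (lambda cfg: run_experiment(cfg, field))
    fractions = {}
    for n in counts:
        releases = tuple(replace(r, count=n) for r in config.releases)
        cfg = replace(config, releases=releases)
        traj = run(cfg)
        total = sum(r.count * len(r.schedule_s) for r in cfg.releases)
        fractions[n] = weighted_success(traj, area, field) / total
    rows = []
    for n0, n1 in zip(counts[:-1], counts[1:]):
        s0, s1 = fractions[n0], fractions[n1]
        rel = abs(s0 - s1) / s1 if s1 != 0 else (0.0 if s0 == 0 else np.inf)
        rows.append({"n": n0, "n_next": n1, "fraction": s0,
                     "fraction_next": s1, "rel_change": rel})
    return pd.DataFrame(rows)
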