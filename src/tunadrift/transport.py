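"""Individual-based transport core.

Particles are eggs/larvae advected through a gridded velocity field with a
fourth-order Runge-Kutta scheme (forward or backward in time), an isotropic
random-walk representing unresolved turbulent diffusion, optional
age-dependent swimming, and a "bouncing" coastline that specularly reflects
any step ending on land.  The time step (600 s by default) is much shorter
than the hourly field cadence.

Per step and per active particle the operators compose in a fixed order —
advection, diffusion, swimming, then a single coastline bounce — so that
after every step each active particle provably sits on a sea cell.
Particles leaving the grid hull are flagged ``out_of_domain`` and frozen.

Backward runs integrate the same equations with a negated time step: the
clock runs backward and velocities reverse, while diffusion keeps its
forward stochastic law (it is irreversible) and age counts elapsed
backward time.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior
from .behavior import SwimmingSpec
from .fields import DEG, EARTH_RADIUS_M, GridField, interpolate

SECONDS_PER_DAY = 86400.0

STATUS_UNRELEASED = 0
STATUS_ACTIVE = 1
STATUS_OUT = 2
STATUS_NAMES = {STATUS_UNRELEASED: "unreleased",
                STATUS_ACTIVE: "active",
                STATUS_OUT: "out_of_domain"}
STATUS_CODES = {v: k for k, v in STATUS_NAMES.items()}

DEFAULT_EPSILON = 1e-9  # turbulent dissipation, m^2/s^3


class ConfigError(ValueError):
    """An experiment configuration violates its contract."""


@dataclass(frozen=True)
class ReleaseSpec:
    """A release stain: uniform disc in the horizontal, uniform depth layer.

    ``schedule_s`` lists absolute release instants in field-clock seconds;
    ``count`` particles are released per instant.
    """

    label: str
    lon: float
    lat: float
    radius_m: float
    depth_min_m: float
    depth_max_m: float
    count: int
    schedule_s: tuple[float, ...]

    def __post_init__(self):
        if self.radius_m <= 0:
            raise ConfigError("stain radius must be > 0")
        if not self.depth_min_m < self.depth_max_m:
            raise ConfigError("release depth range needs min < max")
        if self.count < 1:
            raise ConfigError("release count must be >= 1")
        if len(self.schedule_s) < 1:
            raise ConfigError("release schedule must have at least one instant")
        object.__setattr__(self, "schedule_s", tuple(float(t) for t in self.schedule_s))


@dataclass(frozen=True)
class ExperimentConfig:
    """One dispersal experiment: orientation, releases and movement options."""

    orientation: str
    releases: tuple[ReleaseSpec, ...]
    passive: bool = True
    swimming: SwimmingSpec = dc_field(default_factory=SwimmingSpec)
    dt_s: float = 600.0
    duration_days: float = 30.0
    epsilon: float = DEFAULT_EPSILON
    seed: int = 0
    output_stride_steps: int = 144
    use_vertical_velocity: bool = False
    name: str = "experiment"

    def __post_init__(self):
        if self.orientation not in ("forward", "backward"):
            raise ConfigError("orientation must be 'forward' or 'backward'")
        if self.dt_s <= 0:
            raise ConfigError("dt_s must be > 0")
        if self.duration_days <= 0:
            raise ConfigError("duration_days must be > 0")
        if not self.passive and self.swimming.mode == "none":
            raise ConfigError(
                "at least one of passive movement / swimming must be enabled")
        if self.output_stride_steps < 1:
            raise ConfigError("output_stride_steps must be >= 1")
        if not self.releases:
            raise ConfigError("at least one release is required")
        object.__setattr__(self, "releases", tuple(self.releases))


# -- elementary operators --------------------------------------------------

def meters_to_degrees(dx_m, dy_m, lat):
    """Convert metric displacements to (dlon, dlat) at the given latitude."""
    dlat = dy_m / (EARTH_RADIUS_M * DEG)
    dlon = dx_m / (EARTH_RADIUS_M * np.cos(np.asarray(lat) * DEG) * DEG)
    return dlon, dlat


def release_stain(spec: ReleaseSpec, field: GridField, rng: np.random.Generator,
                  count: int | None = None
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample positions for one release event, resampled until on sea.

    Horizontal positions are area-uniform over the disc; depths uniform over
    the layer.  Raises if the stain contains no sea at all.
    """
    n = spec.count if count is None else int(count)
    # Pre-check: probe the disc for sea before sampling.
    probe_t = np.linspace(0.0, 2.0 * np.pi, 16, endpoint=False)
    probe_r = np.concatenate([[0.0], np.full(16, spec.radius_m * 0.7),
                              np.full(16, spec.radius_m * 0.99)])
    probe_a = np.concatenate([[0.0], probe_t, probe_t + 0.1])
    dlon, dlat = meters_to_degrees(probe_r * np.cos(probe_a),
                                   probe_r * np.sin(probe_a), spec.lat)
    if not field.on_sea(spec.lon + dlon, spec.lat + dlat).any():
        raise ConfigError(
            f"release stain {spec.label!r} at ({spec.lon:.4f}, {spec.lat:.4f}) "
            "does not intersect any sea cell")

    lon = np.empty(n)
    lat = np.empty(n)
    todo = np.ones(n, dtype=bool)
    for _ in range(1000):
        m = int(todo.sum())
        if m == 0:
            break
        r = spec.radius_m * np.sqrt(rng.uniform(size=m))
        theta = rng.uniform(0.0, 2.0 * np.pi, size=m)
        dlon, dlat = meters_to_degrees(r * np.cos(theta), r * np.sin(theta), spec.lat)
        lon[todo] = spec.lon + dlon
        lat[todo] = spec.lat + dlat
        todo[todo] = ~field.on_sea(lon[todo], lat[todo])
    else:  # pragma: no cover - guarded by the probe above
        raise ConfigError(f"could not place release stain {spec.label!r} on sea")
    depth = rng.uniform(spec.depth_min_m, spec.depth_max_m, size=n)
    return lon, lat, depth


def rk4_step(field: GridField, lon, lat, depth, t: float, dt_signed: float
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One classical RK4 advection step; ``dt_signed`` < 0 tracks backward.

    Velocities are sampled at the four substage positions and times.
    Returns (new_lon, new_lat, inside) where ``inside`` is False if any
    substage left the horizontal grid hull.
    """
    h = dt_signed

    def rate(lo, la, tt):
        env = interpolate(field, lo, la, depth, tt)
        dlon, dlat = meters_to_degrees(env.u, env.v, la)
        return dlon, dlat, env.inside

    k1lon, k1lat, in1 = rate(lon, lat, t)
    k2lon, k2lat, in2 = rate(lon + 0.5 * h * k1lon, lat + 0.5 * h * k1lat, t + 0.5 * h)
    k3lon, k3lat, in3 = rate(lon + 0.5 * h * k2lon, lat + 0.5 * h * k2lat, t + 0.5 * h)
    k4lon, k4lat, in4 = rate(lon + h * k3lon, lat + h * k3lat, t + h)
    new_lon = lon + h / 6.0 * (k1lon + 2 * k2lon + 2 * k3lon + k4lon)
    new_lat = lat + h / 6.0 * (k1lat + 2 * k2lat + 2 * k3lat + k4lat)
    return new_lon, new_lat, in1 & in2 & in3 & in4


def horizontal_diffusivity(epsilon: float, dx_m) -> np.ndarray:
    """Scale-dependent diffusivity K = epsilon^(1/3) * dx^(4/3) (m^2/s)."""
    return epsilon ** (1.0 / 3.0) * np.asarray(dx_m, dtype=float) ** (4.0 / 3.0)


def diffusion_step(dx_m, dt_s: float, rng: np.random.Generator,
                   epsilon: float = DEFAULT_EPSILON, size: int | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Random-walk displacement (metres) with per-axis std sqrt(2*K*dt).

    ``dx_m`` is the local grid cell size entering the mixing-length
    diffusivity.  The ensemble mean-square displacement is 4*K*dt (2-D).
    """
    K = horizontal_diffusivity(epsilon, dx_m)
    sigma = np.sqrt(2.0 * K * dt_s)
    n = size if size is not None else np.size(sigma)
    return rng.normal(0.0, 1.0, size=n) * sigma, rng.normal(0.0, 1.0, size=n) * sigma


def bounce(field: GridField, old_lon, old_lat, new_lon, new_lat
           ) -> tuple[np.ndarray, np.ndarray]:
    """Coastline bounce: accept sea proposals, reflect the rest.

    A proposal ending on land is specularly reflected about the crossed
    cell face (longitude face, latitude face, or both for a corner
    crossing); if no reflection lands on sea the particle stays put.  The
    accepted position is always on sea given ``old`` on sea.
    """
    old_lon = np.atleast_1d(np.asarray(old_lon, dtype=float))
    old_lat = np.atleast_1d(np.asarray(old_lat, dtype=float))
    acc_lon = np.atleast_1d(np.asarray(new_lon, dtype=float)).copy()
    acc_lat = np.atleast_1d(np.asarray(new_lat, dtype=float)).copy()

    on_sea = field.on_sea(acc_lon, acc_lat)
    if on_sea.all():
        return acc_lon, acc_lat

    lon_e, lat_e = field.lon_edges(), field.lat_edges()
    iy_o, ix_o, _ = field.cell_index(old_lon, old_lat)
    iy_p, ix_p, _ = field.cell_index(acc_lon, acc_lat)
    for i in np.flatnonzero(~on_sea):
        cands = []
        r_lon, r_lat = acc_lon[i], acc_lat[i]
        if ix_p[i] != ix_o[i]:
            edge = lon_e[ix_o[i] + 1] if ix_p[i] > ix_o[i] else lon_e[ix_o[i]]
            r_lon = 2.0 * edge - acc_lon[i]
        if iy_p[i] != iy_o[i]:
            edge = lat_e[iy_o[i] + 1] if iy_p[i] > iy_o[i] else lat_e[iy_o[i]]
            r_lat = 2.0 * edge - acc_lat[i]
        if ix_p[i] != ix_o[i]:
            cands.append((r_lon, acc_lat[i]))
        if iy_p[i] != iy_o[i]:
            cands.append((acc_lon[i], r_lat))
        if ix_p[i] != ix_o[i] and iy_p[i] != iy_o[i]:
            cands.append((r_lon, r_lat))
        for clon, clat in cands:
            if field.on_sea(clon, clat):
                acc_lon[i], acc_lat[i] = clon, clat
                break
        else:
            acc_lon[i], acc_lat[i] = old_lon[i], old_lat[i]
    return acc_lon, acc_lat


# -- trajectories ----------------------------------------------------------

@dataclass
class TrajectorySet:
    """Recorded particle states at the experiment's output times.

    Arrays are (n_times, n_particles) except the static per-particle
    ``origin``, ``release_time_s`` and ``pid``.
    """

    times: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    depth: np.ndarray
    age_days: np.ndarray
    status: np.ndarray
    origin: np.ndarray
    release_time_s: np.ndarray
    pid: np.ndarray
    orientation: str = "forward"
    attrs: dict = dc_field(default_factory=dict)

    @property
    def n_particles(self) -> int:
        return self.pid.size

    @property
    def n_times(self) -> int:
        return self.times.size

    def active(self, time_index: int) -> np.ndarray:
        return self.status[time_index] == STATUS_ACTIVE

    def index_at_time(self, t_s: float) -> int:
        """Output-time index closest to ``t_s``."""
        return int(np.argmin(np.abs(self.times - t_s)))

    def status_counts(self) -> pd.DataFrame:
        """Per-output-time particle status tally (the run log)."""
        rows = []
        for i, t in enumerate(self.times):
            rows.append({
                "t_s": t,
                "unreleased": int((self.status[i] == STATUS_UNRELEASED).sum()),
                "active": int((self.status[i] == STATUS_ACTIVE).sum()),
                "out_of_domain": int((self.status[i] == STATUS_OUT).sum()),
            })
        return pd.DataFrame(rows)

    def to_dataframe(self) -> pd.DataFrame:
        nt, n = self.n_times, self.n_particles
        status_names = np.array([STATUS_NAMES[STATUS_UNRELEASED],
                                 STATUS_NAMES[STATUS_ACTIVE],
                                 STATUS_NAMES[STATUS_OUT]])
        return pd.DataFrame({
            "pid": np.tile(self.pid, nt),
            "origin": np.tile(self.origin, nt),
            "release_time_s": np.tile(self.release_time_s, nt),
            "t_s": np.repeat(self.times, n),
            "lon": self.lon.ravel(),
            "lat": self.lat.ravel(),
            "depth_m": self.depth.ravel(),
            "age_days": self.age_days.ravel(),
            "status": status_names[self.status.ravel()],
        })

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.8g")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, orientation: str = "forward"
                       ) -> "TrajectorySet":
        required = {"pid", "origin", "release_time_s", "t_s", "lon", "lat",
                    "depth_m", "age_days", "status"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"trajectory table missing columns: {sorted(missing)}")
        times = np.sort(df["t_s"].unique())
        pids = np.sort(df["pid"].unique())
        df = df.sort_values(["t_s", "pid"], kind="mergesort")
        nt, n = times.size, pids.size
        if len(df) != nt * n:
            raise ValueError("trajectory table is not a complete time x particle grid")
        first = df.iloc[:n]
        shape = (nt, n)
        return cls(
            times=times,
            lon=df["lon"].to_numpy().reshape(shape),
            lat=df["lat"].to_numpy().reshape(shape),
            depth=df["depth_m"].to_numpy().reshape(shape),
            age_days=df["age_days"].to_numpy().reshape(shape),
            status=df["status"].map(STATUS_CODES).to_numpy(dtype=np.int8).reshape(shape),
            origin=first["origin"].to_numpy(),
            release_time_s=first["release_time_s"].to_numpy(dtype=float),
            pid=first["pid"].to_numpy(),
            orientation=orientation,
        )

    @classmethod
    def read_csv(cls, path, orientation: str = "forward") -> "TrajectorySet":
        try:
            df = pd.read_csv(path)
        except pd.errors.ParserError as exc:
            raise ValueError(f"malformed trajectory file {path}: {exc}") from exc
        return cls.from_dataframe(df, orientation=orientation)

    def to_xarray(self):
        import xarray as xr

        return xr.Dataset(
            {
                "lon": (("time", "pid"), self.lon),
                "lat": (("time", "pid"), self.lat),
                "depth": (("time", "pid"), self.depth),
                "age_days": (("time", "pid"), self.age_days),
                "status": (("time", "pid"), self.status),
                "origin": (("pid",), self.origin.astype("S")),
                "release_time_s": (("pid",), self.release_time_s),
            },
            coords={"time": self.times, "pid": self.pid},
            attrs={"orientation": self.orientation, **self.attrs},
        )

    def write_netcdf(self, path) -> None:
        self.to_xarray().to_netcdf(path, engine="scipy")


# -- experiment loop -------------------------------------------------------

def run_experiment(config: ExperimentConfig, field: GridField,
                   registry=None) -> TrajectorySet:
    """Run one dispersal experiment and return the recorded trajectories.

    The integration is seed-deterministic: a single named random stream
    drives stain sampling, diffusion and swimming in a fixed order.
    """
    sign = 1.0 if config.orientation == "forward" else -1.0
    dt = config.dt_s
    n_steps = int(round(config.duration_days * SECONDS_PER_DAY / dt))

    instants = [t for rel in config.releases for t in rel.schedule_s]
    t_start = min(instants) if sign > 0 else max(instants)
    t_end = t_start + sign * n_steps * dt
    t_lo, t_hi = min(t_start, t_end), max(t_start, t_end)
    ax_t = field.axes.time
    if t_lo < ax_t[0] - 1e-6 or t_hi > ax_t[-1] + 1e-6:
        raise ConfigError(
            f"field time span [{ax_t[0]:.0f}, {ax_t[-1]:.0f}] s does not cover "
            f"the experiment window [{t_lo:.0f}, {t_hi:.0f}] s")

    # Map release instants onto the step grid.
    events = []  # (step index, release spec)
    offset = 0
    pid_slices = []
    for rel in config.releases:
        for inst in rel.schedule_s:
            k = int(round((inst - t_start) / (sign * dt)))
            if k < 0 or k > n_steps:
                raise ConfigError(
                    f"release instant {inst:.0f} s of {rel.label!r} falls "
                    "outside the experiment window")
            events.append((k, rel, offset))
            pid_slices.append((offset, rel))
            offset += rel.count
    n_total = offset
    events.sort(key=lambda e: (e[0], e[2]))

    rng = np.random.default_rng(config.seed)

    lon = np.full(n_total, np.nan)
    lat = np.full(n_total, np.nan)
    depth = np.full(n_total, np.nan)
    age = np.zeros(n_total)
    status = np.full(n_total, STATUS_UNRELEASED, dtype=np.int8)
    release_time = np.full(n_total, np.nan)
    origin = np.empty(n_total, dtype=object)
    for off, rel in pid_slices:
        origin[off:off + rel.count] = rel.label
    origin = origin.astype(str)

    rec_times, rec = [], {k: [] for k in ("lon", "lat", "depth", "age", "status")}

    def record(t_now):
        rec_times.append(t_now)
        rec["lon"].append(lon.copy())
        rec["lat"].append(lat.copy())
        rec["depth"].append(depth.copy())
        rec["age"].append(age.copy())
        rec["status"].append(status.copy())

    swim_on = config.swimming.mode != "none"
    ev_i = 0
    for k in range(n_steps + 1):
        t_now = t_start + sign * k * dt
        while ev_i < len(events) and events[ev_i][0] == k:
            _, rel, off = events[ev_i]
            s_lon, s_lat, s_depth = release_stain(rel, field, rng)
            sl = slice(off, off + rel.count)
            lon[sl], lat[sl], depth[sl] = s_lon, s_lat, s_depth
            status[sl] = STATUS_ACTIVE
            release_time[sl] = t_now
            age[sl] = 0.0
            ev_i += 1

        if k % config.output_stride_steps == 0 or k == n_steps:
            record(t_now)
        if k == n_steps:
            break

        act = status == STATUS_ACTIVE
        if not act.any():
            continue
        a_lon, a_lat, a_depth = lon[act], lat[act], depth[act]
        inside = np.ones(a_lon.size, dtype=bool)

        if config.passive:
            new_lon, new_lat, inside = rk4_step(field, a_lon, a_lat, a_depth,
                                                t_now, sign * dt)
            if config.epsilon > 0:
                dx_cell = field.mean_cell_size_m(a_lat)
                ddx, ddy = diffusion_step(dx_cell, dt, rng, epsilon=config.epsilon,
                                          size=a_lon.size)
                dlo, dla = meters_to_degrees(ddx, ddy, new_lat)
                new_lon = new_lon + dlo
                new_lat = new_lat + dla
        else:
            new_lon, new_lat = a_lon.copy(), a_lat.copy()

        if swim_on:
            sdx, sdy = behavior.swim_step(config.swimming, age[act], dt, rng,
                                          registry=registry)
            dlo, dla = meters_to_degrees(sdx, sdy, new_lat)
            new_lon = new_lon + dlo
            new_lat = new_lat + dla

        if config.use_vertical_velocity and field.w is not None:
            env = interpolate(field, a_lon, a_lat, a_depth, t_now)
            a_depth = np.clip(a_depth + sign * dt * env.w,
                              field.axes.depth[0], field.axes.depth[-1])

        ax = field.axes
        in_hull = (inside
                   & (new_lon >= ax.lon[0]) & (new_lon <= ax.lon[-1])
                   & (new_lat >= ax.lat[0]) & (new_lat <= ax.lat[-1]))

        acc_lon = a_lon.copy()
        acc_lat = a_lat.copy()
        if in_hull.any():
            b_lon, b_lat = bounce(field, a_lon[in_hull], a_lat[in_hull],
                                  new_lon[in_hull], new_lat[in_hull])
            acc_lon[in_hull] = b_lon
            acc_lat[in_hull] = b_lat

        idx = np.flatnonzero(act)
        exited = idx[~in_hull]
        stayed = idx[in_hull]
        status[exited] = STATUS_OUT  # frozen at the last in-domain position
        lon[stayed] = acc_lon[in_hull]
        lat[stayed] = acc_lat[in_hull]
        depth[idx] = a_depth
        age[stayed] += dt / SECONDS_PER_DAY

    return TrajectorySet(
        times=np.asarray(rec_times, dtype=float),
        lon=np.asarray(rec["lon"]),
        lat=np.asarray(rec["lat"]),
        depth=np.asarray(rec["depth"]),
        age_days=np.asarray(rec["age"]),
        status=np.asarray(rec["status"], dtype=np.int8),
        origin=origin,
        release_time_s=release_time,
        pid=np.arange(n_total),
        orientation=config.orientation,
        attrs={"name": config.name, "seed": config.seed, "dt_s": dt,
               "epsilon": config.epsilon},
    )


# -- config files ----------------------------------------------------------

def config_to_dict(config: ExperimentConfig) -> dict:
    d = asdict(config)
    d["releases"] = [dict(asdict(r), schedule_s=list(r.schedule_s))
                     for r in config.releases]
    d["swimming"] = asdict(config.swimming)
    return d


def save_config(config: ExperimentConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


def config_from_dict(d: dict) -> ExperimentConfig:
    try:
        releases = tuple(ReleaseSpec(**dict(r, schedule_s=tuple(r["schedule_s"])))
                         for r in d["releases"])
        swimming = SwimmingSpec(**d.get("swimming", {}))
        rest = {k: v for k, v in d.items() if k not in ("releases", "swimming")}
        return ExperimentConfig(releases=releases, swimming=swimming, **rest)
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"invalid experiment config: {exc}") from exc


def load_config(path) -> ExperimentConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))
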