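"""Gridded environmental fields and their space-time interpolation.

Hourly (or coarser) ocean-model output is held on a regular
longitude/latitude/depth grid with a static land-sea mask.  Particles step
much faster than the field cadence, so everything the transport core sees
goes through :func:`interpolate`, which is linear in all four dimensions and
treats land cells as zero-velocity contributors with renormalized weights —
currents then vanish smoothly at the coast instead of pushing particles
onshore.

Horizontal metric conversions use a spherical Earth of radius 6371 km:
``dx = R cos(lat) dlon``, ``dy = R dlat``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import NamedTuple

import numpy as np
import xarray as xr

EARTH_RADIUS_M = 6_371_000.0
DEG = np.pi / 180.0


class FieldFormatError(ValueError):
    """A gridded-field file violates the documented layout."""


def _check_axis(name: str, a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 1:
        raise ValueError(f"axis {name!r} must be 1-D")
    if a.size >= 2 and not np.all(np.diff(a) > 0):
        raise ValueError(f"axis {name!r} must be strictly increasing")
    return a


@dataclass(frozen=True)
class GridAxes:
    """Coordinate axes of a gridded field.

    lon/lat in degrees east/north, depth in metres positive downward,
    time in seconds since the simulation reference (UTC).
    """

    lon: np.ndarray
    lat: np.ndarray
    depth: np.ndarray
    time: np.ndarray

    def __post_init__(self):
        for name in ("lon", "lat", "depth", "time"):
            object.__setattr__(self, name, _check_axis(name, getattr(self, name)))

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return (self.time.size, self.depth.size, self.lat.size, self.lon.size)


@dataclass
class GridField:
    """Velocity (and optional scalar) fields on a regular lon/lat/z grid.

    ``u``/``v`` are eastward/northward velocity in m/s with dimensions
    (time, depth, lat, lon); ``mask`` is True on sea points, (lat, lon).
    """

    axes: GridAxes
    u: np.ndarray
    v: np.ndarray
    mask: np.ndarray
    w: np.ndarray | None = None
    temperature: np.ndarray | None = None
    salinity: np.ndarray | None = None
    attrs: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        shape = self.axes.shape
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != shape[2:]:
            raise ValueError("mask shape must be (lat, lon)")
        if not self.mask.any():
            raise ValueError("mask has no sea cell")
        for name in ("u", "v", "w", "temperature", "salinity"):
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=float)
            if arr.shape != shape:
                raise ValueError(
                    f"{name} has shape {arr.shape}, expected {shape} from axes"
                )
            if not np.isfinite(arr[..., self.mask]).all():
                raise ValueError(f"{name} is not finite on sea cells")
            setattr(self, name, arr)

    # -- geometry helpers -------------------------------------------------

    def lon_edges(self) -> np.ndarray:
        if "_lon_edges" not in self.__dict__:
            self.__dict__["_lon_edges"] = _edges(self.axes.lon)
        return self.__dict__["_lon_edges"]

    def lat_edges(self) -> np.ndarray:
        if "_lat_edges" not in self.__dict__:
            self.__dict__["_lat_edges"] = _edges(self.axes.lat)
        return self.__dict__["_lat_edges"]

    def cell_index(self, lon, lat) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map positions to (iy, ix) of the containing grid cell.

        Cells are half-open boxes around each grid node (edges at midpoints,
        lower edge inclusive).  Also returns a boolean ``inside`` array for
        positions within the outermost edges.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        lon_e, lat_e = self.lon_edges(), self.lat_edges()
        ix = np.searchsorted(lon_e, lon, side="right") - 1
        iy = np.searchsorted(lat_e, lat, side="right") - 1
        inside = (ix >= 0) & (ix < self.axes.lon.size) & (iy >= 0) & (iy < self.axes.lat.size)
        return (
            np.clip(iy, 0, self.axes.lat.size - 1),
            np.clip(ix, 0, self.axes.lon.size - 1),
            inside,
        )

    def on_sea(self, lon, lat) -> np.ndarray:
        """True where the containing cell is sea (False outside the grid)."""
        iy, ix, inside = self.cell_index(lon, lat)
        return self.mask[iy, ix] & inside

    def mean_cell_size_m(self, lat) -> np.ndarray:
        """Local horizontal cell size in metres (mean of dx and dy)."""
        dlon = float(np.mean(np.diff(self.axes.lon))) if self.axes.lon.size > 1 else 0.0
        dlat = float(np.mean(np.diff(self.axes.lat))) if self.axes.lat.size > 1 else dlon
        dx = EARTH_RADIUS_M * np.cos(np.asarray(lat) * DEG) * dlon * DEG
        dy = EARTH_RADIUS_M * dlat * DEG
        return 0.5 * (np.abs(dx) + dy)


def _edges(axis: np.ndarray) -> np.ndarray:
    if axis.size == 1:
        half = 0.5
        return np.array([axis[0] - half, axis[0] + half])
    mid = 0.5 * (axis[:-1] + axis[1:])
    first = axis[0] - (mid[0] - axis[0])
    last = axis[-1] + (axis[-1] - mid[-1])
    return np.concatenate([[first], mid, [last]])


class EnvSample(NamedTuple):
    """Interpolated local environment at particle positions."""

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    temperature: np.ndarray
    inside: np.ndarray


def _bracket(axis: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Lower bracketing index and linear weight along one axis."""
    if axis.size == 1:
        return np.zeros(x.shape, dtype=np.intp), np.zeros_like(x)
    i1 = np.clip(np.searchsorted(axis, x, side="right"), 1, axis.size - 1)
    i0 = i1 - 1
    f = (x - axis[i0]) / (axis[i1] - axis[i0])
    return i0, np.clip(f, 0.0, 1.0)


def interpolate(field: GridField, lon, lat, depth, t) -> EnvSample:
    """Sample the field linearly in lon, lat, depth and time.

    Land grid points contribute zero velocity; the weights of the remaining
    sea points are renormalized so the estimate stays unbiased near the
    coast.  If every bracketing point is land the velocity is zero.

    Positions outside the horizontal grid hull are not an error: they come
    back with ``inside=False`` and zero velocity (the caller flags the
    particle out-of-domain).  A query time outside the time axis span is a
    hard error.  Depth is clamped to the vertical axis range.
    """
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    depth = np.broadcast_to(np.asarray(depth, dtype=float), lon.shape).copy()
    t = np.broadcast_to(np.asarray(t, dtype=float), lon.shape)

    ax = field.axes
    tmin, tmax = ax.time[0], ax.time[-1]
    if np.any(t < tmin - 1e-6) or np.any(t > tmax + 1e-6):
        raise ValueError("query time outside the field's time axis span")
    t = np.clip(t, tmin, tmax)
    depth = np.clip(depth, ax.depth[0], ax.depth[-1])

    inside = (
        (lon >= ax.lon[0]) & (lon <= ax.lon[-1])
        & (lat >= ax.lat[0]) & (lat <= ax.lat[-1])
    )

    ix0, fx = _bracket(ax.lon, np.clip(lon, ax.lon[0], ax.lon[-1]))
    iy0, fy = _bracket(ax.lat, np.clip(lat, ax.lat[0], ax.lat[-1]))
    iz0, fz = _bracket(ax.depth, depth)
    it0, ft = _bracket(ax.time, t)

    n = lon.size
    nt, nz, ny, nx = ax.shape
    # 16 corners of the 4-D bracket, flattened for a single gather per array.
    corner_flat = np.empty((n, 16), dtype=np.intp)
    weight = np.empty((n, 16))
    sea = np.empty((n, 16), dtype=bool)
    k = 0
    for dt_ in (0, 1):
        wt = (1 - ft) if dt_ == 0 else ft
        it = it0 + dt_ if nt > 1 else it0
        for dz in (0, 1):
            wz = (1 - fz) if dz == 0 else fz
            iz = iz0 + dz if nz > 1 else iz0
            for dy in (0, 1):
                wy = (1 - fy) if dy == 0 else fy
                iy = iy0 + dy if ny > 1 else iy0
                for dx in (0, 1):
                    wx = (1 - fx) if dx == 0 else fx
                    ix = ix0 + dx if nx > 1 else ix0
                    corner_flat[:, k] = ((it * nz + iz) * ny + iy) * nx + ix
                    weight[:, k] = wt * wz * wy * wx
                    sea[:, k] = field.mask[iy, ix]
                    k += 1

    sea_w = weight * sea
    total = sea_w.sum(axis=1)
    ok = total > 0
    norm = np.where(ok, total, 1.0)

    def sample(arr: np.ndarray | None) -> np.ndarray:
        if arr is None:
            return np.zeros(n)
        vals = arr.ravel()[corner_flat]
        out = (vals * sea_w).sum(axis=1) / norm
        return np.where(ok, out, 0.0)

    u = np.where(inside, sample(field.u), 0.0)
    v = np.where(inside, sample(field.v), 0.0)
    w = np.where(inside, sample(field.w), 0.0)
    temp = sample(field.temperature)
    return EnvSample(u=u, v=v, w=w, temperature=temp, inside=inside)


# -- I/O -------------------------------------------------------------------

_MANDATORY = ("u", "v", "mask")
_OPTIONAL = ("w", "temperature", "salinity")


def to_dataset(field: GridField) -> xr.Dataset:
    coords = {
        "lon": ("lon", field.axes.lon, {"units": "degrees_east"}),
        "lat": ("lat", field.axes.lat, {"units": "degrees_north"}),
        "depth": ("depth", field.axes.depth, {"units": "m", "positive": "down"}),
        "time": ("time", field.axes.time, {"units": "s"}),
    }
    data = {
        "u": (("time", "depth", "lat", "lon"), field.u, {"units": "m s-1"}),
        "v": (("time", "depth", "lat", "lon"), field.v, {"units": "m s-1"}),
        "mask": (("lat", "lon"), field.mask.astype(np.int8), {"flag_meanings": "0 land 1 sea"}),
    }
    for name in _OPTIONAL:
        arr = getattr(field, name)
        if arr is not None:
            data[name] = (("time", "depth", "lat", "lon"), arr)
    return xr.Dataset(data, coords=coords, attrs=dict(field.attrs))


def from_dataset(ds: xr.Dataset) -> GridField:
    for name in ("lon", "lat", "depth", "time"):
        if name not in ds.variables:
            raise FieldFormatError(f"missing mandatory coordinate {name!r}")
    for name in _MANDATORY:
        if name not in ds.variables:
            raise FieldFormatError(f"missing mandatory variable {name!r}")
    axes = GridAxes(
        lon=ds["lon"].values, lat=ds["lat"].values,
        depth=ds["depth"].values, time=ds["time"].values,
    )
    kwargs = {}
    for name in _OPTIONAL:
        if name in ds.variables:
            kwargs[name] = ds[name].values
    return GridField(
        axes=axes,
        u=ds["u"].values,
        v=ds["v"].values,
        mask=ds["mask"].values.astype(bool),
        attrs=dict(ds.attrs),
        **kwargs,
    )


def write_fields(field: GridField, path) -> None:
    """Write a field to a NetCDF file (round-trips exactly with read_fields)."""
    to_dataset(field).to_netcdf(path, engine="scipy")


def read_fields(path) -> GridField:
    """Read a gridded field written by :func:`write_fields`."""
    with xr.open_dataset(path, engine="scipy") as ds:
        return from_dataset(ds.load())


def snapshot_to_csv(field: GridField, path, time_index: int = 0, depth_index: int = 0,
                    variable: str = "u") -> None:
    """Dump one horizontal level of one variable as tidy CSV, for debugging."""
    arr = getattr(field, variable)
    if arr is None:
        raise ValueError(f"field has no variable {variable!r}")
    lon, lat = np.meshgrid(field.axes.lon, field.axes.lat)
    import pandas as pd

    pd.DataFrame({
        "lon": lon.ravel(),
        "lat": lat.ravel(),
        variable: arr[time_index, depth_index].ravel(),
        "sea": field.mask.ravel().astype(int),
    }).to_csv(path, index=False)
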