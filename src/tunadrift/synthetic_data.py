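"""Synthetic inputs: analytic flow fields, an idealized coastal basin, and
specimen morphometric tables.

The coastal basin emulates the summertime eastern Adriatic situation that
drives the dispersal analysis: an elongated basin with land margins, a
narrow along-shore jet hugging the eastern coast whose sign is configurable
(+1 for the climatological northwestward coastal current, -1 for the
reversed southeastward flow), a cyclonic mid-basin gyre, and an open
southern boundary through which particles leave the domain.  The flow is
built from an analytic streamfunction, so it is non-divergent in the local
metric and has no normal component at the jet-side coast.  No attempt is
made to reproduce real bathymetry or stratification.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import erf
from scipy.stats import truncnorm

from .behavior import ABFT, BULLET, LITTLE_TUNNY
from .fields import DEG, EARTH_RADIUS_M, GridAxes, GridField

KM_PER_DEG_LAT = EARTH_RADIUS_M * DEG / 1000.0  # ~111.19 km

SPECIMEN_COLUMNS = ["species", "TL_cm", "FL_cm", "W_g"]


# -- analytic oracle field -------------------------------------------------

def make_solid_body_rotation(omega: float, center: tuple[float, float] = (0.0, 0.0),
                             radius_km: float = 30.0, resolution_km: float = 2.5,
                             depths=(0.0, 20.0), duration_s: float | None = None,
                             ) -> GridField:
    """Solid-body rotation u = -omega*y, v = omega*x about ``center``.

    A closed-form oracle for the advection core: every particle orbits its
    release radius with period 2*pi/omega.  The velocity components are
    linear in the metric offsets (evaluated with the fixed metric of the
    center latitude), so multilinear interpolation reproduces them exactly
    at off-node points.
    """
    if omega == 0:
        raise ValueError("omega must be nonzero")
    lon0, lat0 = center
    half_deg_lat = (radius_km * 1.3) / KM_PER_DEG_LAT
    coslat = np.cos(lat0 * DEG)
    half_deg_lon = (radius_km * 1.3) / (KM_PER_DEG_LAT * coslat)
    n = max(3, int(np.ceil(2 * radius_km * 1.3 / resolution_km)) + 1)
    lon = np.linspace(lon0 - half_deg_lon, lon0 + half_deg_lon, n)
    lat = np.linspace(lat0 - half_deg_lat, lat0 + half_deg_lat, n)
    if duration_s is None:
        duration_s = 2.0 * 2.0 * np.pi / abs(omega)
    axes = GridAxes(lon=lon, lat=lat, depth=np.asarray(depths, dtype=float),
                    time=np.array([0.0, duration_s]))

    glon, glat = np.meshgrid(lon, lat)
    x_m = EARTH_RADIUS_M * coslat * (glon - lon0) * DEG
    y_m = EARTH_RADIUS_M * (glat - lat0) * DEG
    u2d = -omega * y_m
    v2d = omega * x_m
    shape = axes.shape
    u = np.broadcast_to(u2d, shape).copy()
    v = np.broadcast_to(v2d, shape).copy()
    mask = np.ones(shape[2:], dtype=bool)
    return GridField(axes=axes, u=u, v=v, mask=mask,
                     attrs={"scenario": "solid_body_rotation", "omega": omega})


# -- idealized coastal basin ----------------------------------------------

@dataclass(frozen=True)
class BasinScenario:
    """Parameters of the idealized coastal basin (distances in km).

    ``direction_sign`` +1 puts the along-coast jet northward (climatological
    coastal current); -1 reverses it southeastward, the configuration that
    carries larvae from the mid-basin farm down-coast to the catch site.
    The jet only reaches full strength south of ``jet_onset_km`` (it is fed
    laterally across a tanh ramp), which together with the gyre leaves the
    northern sources dynamically separated from the down-coast corridor.
    """

    length_km: float = 400.0
    width_km: float = 120.0
    resolution_km: float = 2.5
    lon0: float = 16.0           # southwest corner
    lat0: float = 42.0
    coastal_current_speed: float = 0.15   # m/s, jet core
    direction_sign: int = -1
    jet_center_offshore_km: float = 8.0
    jet_width_km: float = 10.0
    jet_onset_km: float = 270.0
    jet_ramp_km: float = 12.0
    gyre_center_km: tuple[float, float] = (60.0, 340.0)
    gyre_radius_km: float = 30.0
    gyre_strength: float = 0.12  # m/s, peak tangential speed
    margin_km: float = 10.0      # land strip on west/east/north edges
    temperature_offset: float = 0.0
    open_south: bool = True
    duration_days: float = 50.0
    n_time: int = 2
    depths: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0)
    seed: int = 0

    def __post_init__(self):
        if self.coastal_current_speed < 0 or self.gyre_strength < 0:
            raise ValueError("speeds must be >= 0")
        if self.gyre_radius_km >= self.width_km / 2:
            raise ValueError("gyre radius must be smaller than the basin half-width")
        if self.resolution_km <= 0 or self.n_time < 2:
            raise ValueError("resolution must be > 0 and n_time >= 2")

    @property
    def coast_x_km(self) -> float:
        """Offshore coordinate of the eastern land-sea edge."""
        return self.width_km - self.margin_km

    def lonlat(self, x_km: float, y_km: float) -> tuple[float, float]:
        """Map basin-local km offsets to degrees (fixed mid-basin metric)."""
        lat = self.lat0 + y_km / KM_PER_DEG_LAT
        lon = self.lon0 + x_km / (KM_PER_DEG_LAT * np.cos(self._lat_ref * DEG))
        return float(lon), float(lat)

    @property
    def _lat_ref(self) -> float:
        return self.lat0 + 0.5 * self.length_km / KM_PER_DEG_LAT


def _basin_velocity(sc: BasinScenario, x: np.ndarray, y: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Analytic (u, v) in m/s at basin-local km coordinates."""
    u = np.zeros(np.broadcast_shapes(x.shape, y.shape))
    v = np.zeros_like(u)

    if sc.coastal_current_speed > 0:
        xj = sc.coast_x_km - sc.jet_center_offshore_km
        sig = sc.jet_width_km
        xc = sc.coast_x_km
        xw = sc.margin_km  # western land-sea edge

        def F(xx):  # integral of the Gaussian cross-shore profile
            return sig * np.sqrt(np.pi) / 2.0 * (1.0 + erf((xx - xj) / sig))

        # Close the return flow inside the basin so the streamfunction is
        # constant along both coasts (zero normal flow at west and east).
        ret = (F(xc) - F(xw)) / (xc - xw)
        f = np.exp(-((x - xj) / sig) ** 2)
        G = (F(x) - F(xc)) + ret * (xc - x)
        arg = (sc.jet_onset_km - y) / sc.jet_ramp_km
        S = 0.5 * (1.0 + np.tanh(arg))
        dSdy = -0.5 / sc.jet_ramp_km / np.cosh(arg) ** 2
        amp = sc.direction_sign * sc.coastal_current_speed
        v = v + amp * (f - ret) * S
        u = u - amp * G * dSdy

    if sc.gyre_strength > 0:
        xc, yc = sc.gyre_center_km
        sig = sc.gyre_radius_km
        r2 = (x - xc) ** 2 + (y - yc) ** 2
        # Gaussian vortex, cyclonic; peak tangential speed at r = sigma.
        # Its streamfunction is tapered to zero at the west and east coasts
        # so the vortex tail has no normal flow there.
        A = sc.gyre_strength * sig * np.sqrt(np.e)
        e = np.exp(-r2 / (2.0 * sig ** 2))
        lt = 15.0  # coast taper scale, km
        tw = 1.0 - np.exp(-((x - sc.margin_km) / lt) ** 2)
        te = 1.0 - np.exp(-((x - sc.coast_x_km) / lt) ** 2)
        dtw = 2.0 * (x - sc.margin_km) / lt ** 2 * np.exp(-((x - sc.margin_km) / lt) ** 2)
        dte = 2.0 * (x - sc.coast_x_km) / lt ** 2 * np.exp(-((x - sc.coast_x_km) / lt) ** 2)
        taper = tw * te
        dtaper = dtw * te + tw * dte
        u = u - A * (y - yc) / sig ** 2 * e * taper
        v = v + A * (x - xc) / sig ** 2 * e * taper - A * e * dtaper

    return u, v


def make_coastal_basin(scenario: BasinScenario | None = None) -> GridField:
    """Build the idealized basin flow, mask and hydrography as a GridField.

    The field is steady (identical snapshots bracketing the experiment
    window) and deterministic: the same scenario always yields bit-identical
    arrays.  Temperature stays above 19.5 C in the top 10 m whenever
    ``temperature_offset >= 0``, mirroring favourable spawning conditions
    along the coastal corridor.
    """
    sc = scenario or BasinScenario()
    res = sc.resolution_km
    nx = int(round(sc.width_km / res))
    ny = int(round(sc.length_km / res))
    x = (np.arange(nx) + 0.5) * res   # cell-center offsets, km
    y = (np.arange(ny) + 0.5) * res

    coslat = np.cos(sc._lat_ref * DEG)
    lon = sc.lon0 + x / (KM_PER_DEG_LAT * coslat)
    lat = sc.lat0 + y / KM_PER_DEG_LAT
    times = np.linspace(0.0, sc.duration_days * 86400.0, sc.n_time)
    axes = GridAxes(lon=lon, lat=lat, depth=np.asarray(sc.depths, dtype=float),
                    time=times)

    gx, gy = np.meshgrid(x, y)
    sea = (gx > sc.margin_km) & (gx < sc.width_km - sc.margin_km) & (gy < sc.length_km - sc.margin_km)
    if not sc.open_south:
        sea &= gy > sc.margin_km

    u2d, v2d = _basin_velocity(sc, gx, gy)
    u2d = np.where(sea, u2d, 0.0)
    v2d = np.where(sea, v2d, 0.0)

    shape = axes.shape
    u = np.broadcast_to(u2d, shape).copy()
    v = np.broadcast_to(v2d, shape).copy()
    temp = 23.5 + sc.temperature_offset - 0.08 * np.asarray(sc.depths)
    temperature = np.broadcast_to(temp[None, :, None, None], shape).copy()
    salinity = np.full(shape, 38.5)
    return GridField(axes=axes, u=u, v=v, mask=sea, temperature=temperature,
                     salinity=salinity, attrs={"scenario": "coastal_basin"})


def scenario_sites(sc: BasinScenario | None = None) -> dict[str, tuple[float, float]]:
    """Named release/catch sites of the standard connectivity scenario.

    Two farm sites sit north of the jet onset in the gyre's sphere
    ("shielded"), one farm sits up-current of the catch site inside the jet,
    and the catch site lies 190 km down-coast — the layout whose forward and
    backward runs single out the up-current farm as the only source.
    """
    sc = sc or BasinScenario()
    x_site = sc.coast_x_km - 10.0
    frac = sc.length_km / 400.0  # scale along-basin placement with length
    spots = {
        "farm_north_a": (x_site, 355.0 * frac),
        "farm_north_b": (x_site, 330.0 * frac),
        "farm_south": (x_site, 245.0 * frac),
        "catch_site": (x_site, 55.0 * frac),
    }
    return {name: sc.lonlat(px, py) for name, (px, py) in spots.items()}


def save_scenario(sc: BasinScenario, path) -> None:
    d = asdict(sc)
    d["gyre_center_km"] = list(sc.gyre_center_km)
    d["depths"] = list(sc.depths)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def load_scenario(path) -> BasinScenario:
    d = yaml.safe_load(Path(path).read_text())
    d["gyre_center_km"] = tuple(d["gyre_center_km"])
    d["depths"] = tuple(d["depths"])
    return BasinScenario(**d)


# -- specimen tables -------------------------------------------------------

@dataclass(frozen=True)
class SpeciesSpec:
    """Morphometric generator for one species.

    Fork length is a truncated normal; total length follows the
    length-length line (FL = ll_slope*TL + ll_intercept, inverted) with a
    small measurement noise; weight follows W = lw_a * FL**lw_b with
    multiplicative lognormal noise of coefficient of variation ``w_cv``.
    """

    label: str
    fl_mean_cm: float
    fl_sd_cm: float
    fl_min_cm: float
    fl_max_cm: float
    ll_slope: float
    ll_intercept: float
    lw_a: float
    lw_b: float
    w_cv: float = 0.05
    tl_noise_cm: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not (self.fl_max_cm > self.fl_min_cm > 0):
            raise ValueError("fork-length range must be positive and non-degenerate")
        if self.lw_a <= 0:
            raise ValueError("length-weight coefficient a must be > 0")
        if self.fl_sd_cm <= 0:
            raise ValueError("fork-length SD must be > 0")


# September 2011 Adriatic purse-seine cohort, per-species published summary
# statistics and regression coefficients.
ABFT_SPEC = SpeciesSpec(ABFT, 12.7, 1.09, 10.8, 15.0, 0.9424, -0.456, 0.0039, 3.5152)
BULLET_SPEC = SpeciesSpec(BULLET, 16.1, 2.27, 13.2, 21.8, 0.9517, -0.016, 0.0035, 3.4435)
LITTLE_TUNNY_SPEC = SpeciesSpec(LITTLE_TUNNY, 13.6, 1.73, 11.6, 18.4, 0.9283, 0.164, 0.0019, 3.7387)
DEFAULT_SPECIES = (ABFT_SPEC, BULLET_SPEC, LITTLE_TUNNY_SPEC)


def _rows_for_species(spec: SpeciesSpec, fl: np.ndarray,
                      rng: np.random.Generator | None) -> pd.DataFrame:
    tl = (fl - spec.ll_intercept) / spec.ll_slope
    w = spec.lw_a * fl ** spec.lw_b
    if rng is not None:
        tl = tl + rng.normal(0.0, spec.tl_noise_cm, size=fl.size)
        if spec.w_cv > 0:
            sigma = np.sqrt(np.log1p(spec.w_cv ** 2))
            w = w * rng.lognormal(-0.5 * sigma ** 2, sigma, size=fl.size)
    return pd.DataFrame({
        "species": spec.label,
        "TL_cm": tl,
        "FL_cm": fl,
        "W_g": w,
    })


def make_specimen_table(specs=DEFAULT_SPECIES, n_per_species: int = 30,
                        seed: int = 0) -> pd.DataFrame:
    """Random specimen table with the documented CSV schema.

    Deterministic in (specs, n, seed).  ``n_per_species`` may also be a
    sequence giving one count per spec; each count must be >= 3.
    """
    if np.isscalar(n_per_species):
        counts = [int(n_per_species)] * len(specs)
    else:
        counts = [int(n) for n in n_per_species]
    if len(counts) != len(specs):
        raise ValueError("one count per species spec required")
    if min(counts) < 3:
        raise ValueError("need at least 3 specimens per species")
    rng = np.random.default_rng(seed)
    frames = []
    for spec, n in zip(specs, counts):
        a = (spec.fl_min_cm - spec.fl_mean_cm) / spec.fl_sd_cm
        b = (spec.fl_max_cm - spec.fl_mean_cm) / spec.fl_sd_cm
        fl = truncnorm.rvs(a, b, loc=spec.fl_mean_cm, scale=spec.fl_sd_cm,
                           size=n, random_state=rng)
        frames.append(_rows_for_species(spec, fl, rng))
    return pd.concat(frames, ignore_index=True)[SPECIMEN_COLUMNS]


def synthetic_cohort_table() -> pd.DataFrame:
    """Deterministic synthetic stand-in for the measured 87-fish cohort.

    The measured specimen table itself is not redistributable, so this
    reconstruction places each species' fork lengths at equally spaced
    quantiles of a range-truncated normal and then rescales them so the
    sample mean and SD match the published per-species values exactly
    (ABFT n=29: 12.7 +/- 1.09 cm in 10.8-15.0; bullet n=30: 16.1 +/- 2.27
    in 13.2-21.8; little tunny n=28: 13.6 +/- 1.73 in 11.6-18.4).  Total
    length and weight are noise-free transforms of fork length.  Summary
    statistics computed from it approximate, but do not equal, those of the
    real specimens.
    """
    counts = {ABFT: 29, BULLET: 30, LITTLE_TUNNY: 28}
    frames = []
    for spec in DEFAULT_SPECIES:
        n = counts[spec.label]
        a = (spec.fl_min_cm - spec.fl_mean_cm) / spec.fl_sd_cm
        b = (spec.fl_max_cm - spec.fl_mean_cm) / spec.fl_sd_cm
        q = (np.arange(n) + 0.5) / n
        fl = truncnorm.ppf(q, a, b, loc=spec.fl_mean_cm, scale=spec.fl_sd_cm)
        # Alternate rescaling and range clipping until the sample mean and
        # SD equal the published values while staying inside the range.
        for _ in range(60):
            fl = (fl - fl.mean()) / fl.std(ddof=1) * spec.fl_sd_cm + spec.fl_mean_cm
            fl = np.clip(fl, spec.fl_min_cm, spec.fl_max_cm)
        frames.append(_rows_for_species(spec, fl, rng=None))
    return pd.concat(frames, ignore_index=True)[SPECIMEN_COLUMNS]
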