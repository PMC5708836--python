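"""Preset experiment suite on the synthetic coastal basin.

Ten numbered dispersal experiments mirror the study design this package
reproduces: four backward runs from the catch site released over different
depth layers, five forward runs from the farm cages crossing passive
transport with the two swimming modes, and one forward run from the open
southern boundary.  All run on the idealized reversed-jet basin, with the
release sites taken from :func:`tunadrift.synthetic_data.scenario_sites`.

Backward releases use a 500 m stain; forward cage releases use a 250 m
stain with 20 daily release events at 03:00 (1000 particles each by
default, 20000 per source).  Backward runs last 46 days; forward runs end
46 days after the first release so that the final snapshot matches the
backward release instant.
"""

from __future__ import annotations

from .behavior import ABFT, SwimmingSpec
from .synthetic_data import BasinScenario, scenario_sites
from .transport import ExperimentConfig, ReleaseSpec

PRESET_NAMES = tuple(f"experiment{i}" for i in range(1, 11))

_BACKWARD_DEPTHS = {
    "experiment1": (0.0, 15.0),
    "experiment2": (15.0, 30.0),
    "experiment3": (30.0, 50.0),
    "experiment4": (20.0, 50.0),
}
_FORWARD_MOVEMENT = {
    "experiment5": (True, "none"),
    "experiment6": (True, "constant"),
    "experiment7": (True, "random"),
    "experiment8": (False, "constant"),
    "experiment9": (False, "random"),
}

_DAY = 86400.0
_RELEASE_HOUR_S = 3.0 * 3600.0
_N_EVENTS = 20
_WINDOW_DAYS = 46.0


def preset_experiment(name: str, scenario: BasinScenario | None = None,
                      particles_per_event: int | None = None,
                      duration_days: float | None = None,
                      seed: int = 0) -> ExperimentConfig:
    """Build one of the ten preset experiment configurations.

    ``particles_per_event`` and ``duration_days`` scale the run down
    without changing its structure (useful for quick checks); defaults are
    the full-size study values.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    sc = scenario or BasinScenario()
    sites = scenario_sites(sc)
    farms = ("farm_north_a", "farm_north_b", "farm_south")

    if name in _BACKWARD_DEPTHS:
        dmin, dmax = _BACKWARD_DEPTHS[name]
        n = particles_per_event or 20000
        dur = duration_days or _WINDOW_DAYS
        lon, lat = sites["catch_site"]
        releases = (ReleaseSpec(label="catch_site", lon=lon, lat=lat,
                                radius_m=500.0, depth_min_m=dmin,
                                depth_max_m=dmax, count=n,
                                schedule_s=(_WINDOW_DAYS * _DAY,)),)
        return ExperimentConfig(orientation="backward", releases=releases,
                                passive=True, dt_s=600.0, duration_days=dur,
                                seed=seed, name=name)

    if name in _FORWARD_MOVEMENT:
        passive, mode = _FORWARD_MOVEMENT[name]
        n = particles_per_event or 1000
        schedule = tuple(k * _DAY + _RELEASE_HOUR_S for k in range(_N_EVENTS))
        releases = tuple(
            ReleaseSpec(label=farm, lon=sites[farm][0], lat=sites[farm][1],
                        radius_m=250.0, depth_min_m=0.0, depth_max_m=15.0,
                        count=n, schedule_s=schedule)
            for farm in farms)
        dur = duration_days or (_WINDOW_DAYS - _RELEASE_HOUR_S / _DAY)
        swimming = SwimmingSpec(mode=mode, body_lengths_per_s=1, species=ABFT) \
            if mode != "none" else SwimmingSpec()
        return ExperimentConfig(orientation="forward", releases=releases,
                                passive=passive, swimming=swimming,
                                dt_s=600.0, duration_days=dur, seed=seed,
                                name=name)

    # experiment10: forward release from the open southern boundary
    n = particles_per_event or 5000
    xs = (0.25, 0.42, 0.58, 0.75)
    releases = tuple(
        ReleaseSpec(label=f"south_boundary_{i+1}",
                    lon=sc.lonlat(fx * sc.width_km, 15.0)[0],
                    lat=sc.lonlat(fx * sc.width_km, 15.0)[1],
                    radius_m=500.0, depth_min_m=0.0, depth_max_m=50.0,
                    count=n, schedule_s=(0.0,))
        for i, fx in enumerate(xs))
    return ExperimentConfig(orientation="forward", releases=releases,
                            passive=True, dt_s=600.0,
                            duration_days=duration_days or 30.0,
                            seed=seed, name=name)


def preset_areas(scenario: BasinScenario | None = None) -> dict:
    """Standard success areas: 225 km^2 farm squares, 625 km^2 catch square."""
    from .connectivity import SuccessArea

    sc = scenario or BasinScenario()
    sites = scenario_sites(sc)
    areas = {}
    for farm in ("farm_north_a", "farm_north_b", "farm_south"):
        lon, lat = sites[farm]
        areas[farm] = SuccessArea(lon=lon, lat=lat, area_km2=225.0, label=farm)
    lon, lat = sites["catch_site"]
    areas["catch_site"] = SuccessArea(lon=lon, lat=lat, area_km2=625.0,
                                      label="catch_site")
    return areas
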