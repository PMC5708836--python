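import numpy as np
import pytest

import tunadrift as td
from tunadrift.fields import DEG, EARTH_RADIUS_M, GridAxes, GridField
from tunadrift.presets import preset_areas, preset_experiment
from tunadrift.transport import run_experiment

ROT_PERIOD_S = 2 * 86400.0
ROT_OMEGA = 2 * np.pi / ROT_PERIOD_S


def make_uniform_field(u0=0.2, v0=0.0, extent_deg=1.0, n=11, nt=2,
                       t_span=4 * 86400.0):
    """All-sea field with spatially uniform velocity, centered on (0, 0)."""
    lon = np.linspace(-extent_deg, extent_deg, n)
    lat = np.linspace(-extent_deg, extent_deg, n)
    axes = GridAxes(lon=lon, lat=lat, depth=np.array([0.0, 30.0]),
                    time=np.linspace(0.0, t_span, nt))
    shape = axes.shape
    return GridField(axes=axes, u=np.full(shape, float(u0)),
                     v=np.full(shape, float(v0)),
                     mask=np.ones(shape[2:], dtype=bool))


def make_coast_field(u0=0.0, v0=0.0, n=10, land_from_ix=5):
    """Field with a straight meridional coastline: land for ix >= land_from_ix.

    Grid spacing is 0.1 degrees with nodes at 0.05, 0.15, ...; the land-sea
    edge sits at lon = land_from_ix * 0.1.
    """
    lon = 0.05 + 0.1 * np.arange(n)
    lat = 0.05 + 0.1 * np.arange(n)
    axes = GridAxes(lon=lon, lat=lat, depth=np.array([0.0, 30.0]),
                    time=np.array([0.0, 86400.0]))
    shape = axes.shape
    mask = np.ones(shape[2:], dtype=bool)
    mask[:, land_from_ix:] = False
    u = np.where(mask, u0, 0.0) * np.ones(shape)
    v = np.where(mask, v0, 0.0) * np.ones(shape)
    return GridField(axes=axes, u=u, v=v, mask=mask)


@pytest.fixture(scope="session")
def rotation_field():
    return td.make_solid_body_rotation(ROT_OMEGA, radius_km=15.0)


@pytest.fixture(scope="session")
def basin_scenario():
    return td.BasinScenario()


@pytest.fixture(scope="session")
def basin_field(basin_scenario):
    return td.make_coastal_basin(basin_scenario)


@pytest.fixture(scope="session")
def basin_areas(basin_scenario):
    return preset_areas(basin_scenario)


@pytest.fixture(scope="session")
def forward_traj(basin_scenario, basin_field):
    """Scaled forward cage run: 100 particles x 20 daily events x 3 farms,
    30 days — the standard three-source connectivity scenario."""
    cfg = preset_experiment("experiment5", basin_scenario,
                            particles_per_event=100, duration_days=30.0,
                            seed=1)
    return run_experiment(cfg, basin_field)


@pytest.fixture(scope="session")
def backward_traj(basin_scenario, basin_field):
    """Scaled backward run from the catch-site stain, 2000 particles, 30 d."""
    cfg = preset_experiment("experiment1", basin_scenario,
                            particles_per_event=2000, duration_days=30.0,
                            seed=2)
    return run_experiment(cfg, basin_field)
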