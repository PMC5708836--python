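"""Growth models, age-length conversion and larval swimming behaviour.

Three published early-juvenile growth curves ship as defaults, one per
species in the September 2011 Adriatic cohort:

* Atlantic bluefin tuna (*Thunnus thynnus*): linear, FL[mm] = 41.20 + 2.37 t
  with t in days,
* bullet tuna (*Auxis rochei*): von Bertalanffy, FL[cm] =
  29.74 (1 - exp(-10 (t_yr + 0.018))) with t in years (k = 10 / yr,
  t0 = -0.018 yr),
* little tunny (*Euthynnus alletteratus*): linear, FL[cm] = 2.036 + 0.396 t
  with t in days.

Coefficient units differ between sources, so every model carries an explicit
``length_unit``; :func:`length_at_age` always returns millimetres and
:func:`age_at_length` always takes centimetres, matching how field data are
reported.

Swimming is parameterized as in larval-fish IBMs: cruise speed is a fixed
multiple (1, 2 or 4) of body length per second, with body length a function
of age through the growth model, and a direction drawn uniformly at random
each time step.  "Constant" mode swims at that age-dependent maximum;
"random" mode draws the speed uniformly between zero and the maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

DAYS_PER_YEAR = 365.0

_FORMS = ("linear", "von_bertalanffy")
_UNITS = ("mm", "cm")


@dataclass(frozen=True)
class GrowthModel:
    """An age->fork-length curve with an algebraic inverse.

    ``length_unit`` is the unit the coefficients are expressed in; the
    public conversion functions normalize to mm (lengths) and days (ages).
    Linear: FL = intercept + slope * t_days.
    von Bertalanffy: FL = linf * (1 - exp(-k * (t_years - t0))).
    """

    species: str
    form: str
    length_unit: str = "mm"
    intercept: float = 0.0   # linear, in length_unit
    slope: float = 0.0       # linear, length_unit per day
    linf: float = 0.0        # von Bertalanffy asymptote, length_unit
    k: float = 0.0           # von Bertalanffy rate, 1/yr
    t0: float = 0.0          # von Bertalanffy age offset, yr

    def __post_init__(self):
        if self.form not in _FORMS:
            raise ValueError(f"unknown growth form {self.form!r}")
        if self.length_unit not in _UNITS:
            raise ValueError(f"unknown length unit {self.length_unit!r}")
        if self.form == "linear" and self.slope <= 0:
            raise ValueError("linear growth needs slope > 0")
        if self.form == "von_bertalanffy" and (self.k <= 0 or self.linf <= 0):
            raise ValueError("von Bertalanffy growth needs k > 0 and linf > 0")

    @property
    def _to_mm(self) -> float:
        return 10.0 if self.length_unit == "cm" else 1.0

    def min_length_cm(self) -> float:
        """Fork length at age 0 (hatch), in cm — lower bound for inversion."""
        return float(length_at_age(self, 0.0)) / 10.0

    def max_length_cm(self) -> float | None:
        """Asymptotic length in cm, or None for unbounded (linear) growth."""
        if self.form == "von_bertalanffy":
            return self.linf * self._to_mm / 10.0
        return None


def length_at_age(model: GrowthModel, t_days) -> np.ndarray | float:
    """Fork length in mm at age ``t_days`` (days since hatch)."""
    t = np.asarray(t_days, dtype=float)
    if np.any(t < 0):
        raise ValueError("age must be non-negative")
    if model.form == "linear":
        fl = model.intercept + model.slope * t
    else:
        t_yr = t / DAYS_PER_YEAR
        fl = model.linf * (1.0 - np.exp(-model.k * (t_yr - model.t0)))
    fl = fl * model._to_mm
    return float(fl) if np.isscalar(t_days) else fl


def age_at_length(model: GrowthModel, fl_cm) -> np.ndarray | float:
    """Age in days at fork length ``fl_cm`` (cm): exact inverse of growth."""
    fl = np.asarray(fl_cm, dtype=float)
    fl_unit = fl * 10.0 / model._to_mm  # back to coefficient units
    if model.form == "linear":
        t = (fl_unit - model.intercept) / model.slope
        if np.any(t < -1e-12):
            raise ValueError(
                f"{model.species}: FL below length at age 0 "
                f"({model.min_length_cm():.3f} cm)"
            )
        t = np.maximum(t, 0.0)
    else:
        if np.any(fl_unit >= model.linf):
            raise ValueError(
                f"{model.species}: FL at or above the asymptote "
                f"L_inf = {model.max_length_cm():.2f} cm is not invertible"
            )
        t_yr = model.t0 - np.log(1.0 - fl_unit / model.linf) / model.k
        t = t_yr * DAYS_PER_YEAR
        if np.any(t < -1e-12):
            raise ValueError(
                f"{model.species}: FL below length at age 0 "
                f"({model.min_length_cm():.3f} cm)"
            )
        t = np.maximum(t, 0.0)
    return float(t) if np.isscalar(fl_cm) else t


# -- default registry ------------------------------------------------------

ABFT = "atlantic_bluefin_tuna"
BULLET = "bullet_tuna"
LITTLE_TUNNY = "little_tunny"

DEFAULT_MODELS: dict[str, GrowthModel] = {
    ABFT: GrowthModel(
        species=ABFT, form="linear", length_unit="mm",
        intercept=41.20, slope=2.37,
    ),
    BULLET: GrowthModel(
        species=BULLET, form="von_bertalanffy", length_unit="cm",
        linf=29.74, k=10.0, t0=-0.018,
    ),
    LITTLE_TUNNY: GrowthModel(
        species=LITTLE_TUNNY, form="linear", length_unit="cm",
        intercept=2.036, slope=0.396,
    ),
}


def default_registry() -> dict[str, GrowthModel]:
    """Fresh copy of the shipped species -> growth model registry."""
    return dict(DEFAULT_MODELS)


def save_registry(registry: dict[str, GrowthModel], path) -> None:
    payload = {
        name: {k: v for k, v in vars(m).items() if k != "species"}
        for name, m in registry.items()
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def load_registry(path) -> dict[str, GrowthModel]:
    payload = yaml.safe_load(Path(path).read_text())
    return {name: GrowthModel(species=name, **kw) for name, kw in payload.items()}


# -- swimming --------------------------------------------------------------

_MODES = ("none", "constant", "random")
_MULTIPLIERS = (1, 2, 4)


@dataclass(frozen=True)
class SwimmingSpec:
    """Swimming options: mode, body-lengths-per-second multiplier, species."""

    mode: str = "none"
    body_lengths_per_s: int = 1
    species: str = ABFT

    def __post_init__(self):
        if self.mode not in _MODES:
            raise ValueError(f"unknown swimming mode {self.mode!r}")
        if self.mode != "none" and self.body_lengths_per_s not in _MULTIPLIERS:
            raise ValueError("body_lengths_per_s must be 1, 2 or 4")


def swim_speed(spec: SwimmingSpec, age_days, rng: np.random.Generator | None = None,
               registry: dict[str, GrowthModel] | None = None) -> np.ndarray:
    """Swimming speed in m/s at the given ages.

    The maximum is ``multiplier x body length`` per second; constant mode
    returns the maximum, random mode a uniform draw on [0, max].
    """
    if spec.mode == "none":
        raise ValueError("swim_speed undefined for mode 'none'")
    registry = registry or DEFAULT_MODELS
    model = registry[spec.species]
    length_m = np.asarray(length_at_age(model, age_days)) / 1000.0
    v_max = spec.body_lengths_per_s * length_m
    if spec.mode == "constant":
        return v_max
    if rng is None:
        raise ValueError("random swimming mode needs an rng")
    return rng.uniform(0.0, v_max)


def swim_step(spec: SwimmingSpec, age_days, dt_s: float, rng: np.random.Generator,
              registry: dict[str, GrowthModel] | None = None
              ) -> tuple[np.ndarray, np.ndarray]:
    """Horizontal swimming displacement (dx, dy) in metres over one step.

    Direction is uniform on [0, 2*pi), redrawn independently every step.
    """
    speed = swim_speed(spec, age_days, rng=rng, registry=registry)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=np.shape(speed))
    r = speed * dt_s
    return r * np.cos(theta), r * np.sin(theta)


def dvm_depth(day_depth_m: float, night_depth_m: float, t_s, lon_deg=0.0) -> np.ndarray | float:
    """Diel vertical migration target depth (off by default in experiments).

    Day depth between 06:00 and 18:00 local solar time, night depth
    otherwise.  ``t_s`` is seconds since UTC midnight of the reference day;
    local solar time adds 1 h per 15 degrees of longitude.
    """
    hour = (np.asarray(t_s, dtype=float) / 3600.0 + np.asarray(lon_deg) / 15.0) % 24.0
    depth = np.where((hour >= 6.0) & (hour < 18.0), day_depth_m, night_depth_m)
    return float(depth) if np.isscalar(t_s) else depth
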