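# Methods

This note documents the models implemented in `tunadrift`, the parameter
choices that matter, what the synthetic data do and do not emulate, and the
numerical conventions. Every number quoted here is computed by the test
suite or by `scripts/acceptance.py`; nothing is asserted that the code does
not reproduce.

## Transport model

Particles represent individual eggs/larvae. Per time step (default
`dt = 600 s`) and per active particle, four operators compose in a fixed
order:

1. **Advection** (if passive movement is on): classical 4th-order
   Runge–Kutta, with velocity sampled by 4-D linear interpolation at the
   four substage positions and times. Positions are kept in geographic
   degrees; metric conversions use a spherical Earth with R = 6371 km,
   dx = R·cos(lat)·dlon, dy = R·dlat. Backward tracking integrates the
   same equations with a negated time step (velocities reverse and the
   clock runs backward).
2. **Diffusion** (if passive movement is on): isotropic horizontal random
   walk with per-axis standard deviation √(2·K·dt) and mixing-length
   diffusivity K = ε^(1/3)·Δx^(4/3), where Δx is the local grid cell size.
   The default dissipation ε = 10⁻⁹ m²/s³ gives K ≈ 34 m²/s on a 2.5 km
   grid — a standard larval-IBM closure; ε is config-exposed. Backward runs
   keep the forward stochastic law: diffusion is irreversible and the
   backward experiment is an as-is integration of reversed currents, not a
   probabilistic inverse.
3. **Swimming** (if enabled): displacement of magnitude v·dt with a
   heading drawn uniformly on [0, 2π) independently every step. The speed
   scale is `multiplier × body length` per second (multiplier 1, 2 or 4),
   with body length a function of age through the species growth model;
   "constant" mode uses that maximum, "random" mode draws uniformly on
   [0, v_max]. Swimming applies from age 0 at hatch length. With the
   bluefin growth curve this gives 8.9 cm/s at day 20 and 15.5 cm/s at day
   48 for 1 BL/s (rounded figures of 8 and 15 cm/s are sometimes quoted
   for the same curve; the formula values are used here).
4. **Coastline bounce**: a proposal ending on a land cell is specularly
   reflected about the crossed cell face (both faces for a corner
   crossing); if the reflection is still on land the particle stays at its
   pre-step position. Because the bounce is the last operator, the
   invariant "no active particle on a land cell" holds after every step.

Particles whose step (or any RK4 substage) leaves the horizontal grid hull
are flagged `out_of_domain` and frozen; active + out-of-domain +
not-yet-released always equals the number released. Age advances by dt per
step and counts elapsed time in both orientations.

Vertical motion: particles keep their release depth by default. The
analysis this package reproduces found depth-layer choice (0–15 m down to
30–50 m) immaterial because the along-coast flow is vertically coherent in
the upper 50 m; vertical advection by a `w` field is available behind a
config switch but off by default. Egg buoyancy, temperature-dependent
growth/mortality and food limitation are out of scope, as is the ~30 h egg
incubation phase (particles hatch at release).

A single seeded random generator per experiment drives stain sampling,
diffusion and swimming in a fixed order, so runs are bit-reproducible.

### Releases

A release "stain" is a disc: horizontal positions area-uniform over the
given radius (resampled until on sea; a stain wholly on land is a
configuration error), depths uniform over the layer. Schedules are lists of
absolute instants; the preset forward experiments release 1000 particles
per farm per day for 20 days (20 000 per source), the preset backward
experiments release 20 000 at once from a 500 m stain. Release instants
are exact — no sub-step jitter — since release-time sensitivity was found
negligible in this configuration.

## Field interpolation

Fields live on a regular lon/lat/depth/time grid with a static sea/land
mask. Interpolation is linear in all four dimensions (16-corner weights).
Land corners contribute zero velocity and their weight is redistributed
over the sea corners, so currents go smoothly to zero at the coast and no
spurious onshore component is created; if every bracketing corner is land
the velocity is zero. Queries outside the horizontal hull are a signal
(out-of-domain), not an exception; a query time outside the time axis is a
hard error; depth is clamped to the vertical axis (release layers may start
above the first model level). Only regular lon/lat/z grids are supported —
no curvilinear or terrain-following coordinates; regridding to z-levels is
assumed done upstream.

## The synthetic coastal basin

`make_coastal_basin` builds a 400 × 120 km basin (2.5 km cells, six
z-levels to 50 m, steady in time) from an analytic streamfunction, so the
flow is non-divergent in the local metric by construction:

* **Coastal jet**: Gaussian cross-shore profile (width 10 km) centred 8 km
  off the eastern coast, core speed 0.15 m/s. `direction_sign = −1` (the
  default) makes it flow down-basin — the reversed, southeastward summer
  configuration; +1 restores the climatological up-basin flow. The jet
  reaches full strength only south of a tanh onset ramp (centre 270 km,
  width 12 km) and is fed laterally across the ramp; a uniform return flow
  closes the circulation inside the basin so the streamfunction is constant
  along both coasts (zero normal flow).
* **Gyre**: a cyclonic Gaussian vortex, centre mid-basin at (60, 340) km,
  radius 30 km, peak tangential speed 0.12 m/s, with its streamfunction
  tapered to zero at both coasts.
* **Margins**: 10 km land strips on the west, east and north edges; the
  south edge is open sea — particles crossing it leave the domain.
* **Hydrography**: temperature 23.5 °C − 0.08 °C/m (≥ 19.5 °C in the top
  10 m, the spawning threshold) plus a configurable offset; salinity
  38.5.

Four named sites sit 10 km off the eastern coast: two farms north of the
jet onset inside the gyre's sphere (y = 355 and 330 km), one farm inside
the jet (y = 245 km), and the catch site 190 km down-coast (y = 55 km).
With a 0.15 m/s jet the farm→catch transit is ≈ 15 days, so a 20-day daily
release schedule keeps the catch square populated at day 30: particles
released around day 15 are in the square when a 30-day run ends. The
northern farms are dynamically separated from the down-coast corridor: to
reach the catch square a particle would first have to cross into the jet
(≥ 10 days of gyre circulation and diffusion) and then transit ≥ 15 more
days, which exceeds the 30-day window — hence their weighted success is
exactly zero in both forward and backward runs, reproducing the
qualitative single-source attribution structure.

What the basin does **not** emulate: real bathymetry and stratification,
unsteady (wind-driven, tidal, mesoscale) variability, islands and channel
topography, and any quantitative particle counts from a realistic
hydrodynamic solution. Passing the connectivity tests shows the method
recovers the dispersal structure its flow field encodes — not that it would
reproduce observed counts in a real basin.

## Growth models and ageing

Three published early-juvenile growth curves ship as defaults:

| species | form | curve | coefficient units |
| --- | --- | --- | --- |
| Atlantic bluefin tuna | linear | FL = 41.20 + 2.37·t (t in days) | mm |
| bullet tuna | von Bertalanffy | FL = 29.74·(1 − e^(−10·(t_yr + 0.018))) | cm, k = 10/yr, t₀ = −0.018 yr |
| little tunny | linear | FL = 2.036 + 0.396·t (t in days) | cm |

Two unit/sign conventions deserve note. The bullet-tuna source prints the
age offset as "(t − 0.018)"; only t₀ = −0.018 yr reproduces the standard
worked inversion (13.2 cm → 14.8 d), so the negative sign is adopted. The
bullet and little-tunny coefficients are only dimensionally consistent with
centimetres (an L∞ of 29.74 mm or a 2 mm hatch length would be absurd for
these species), so those two models carry `length_unit="cm"` while the
bluefin linear model is in millimetres as printed; every model has an
explicit unit field, `length_at_age` always returns mm and `age_at_length`
always takes cm. Inversion is algebraic and exact: the round-trip
age→length→age holds to 10⁻⁹ relative tolerance across each model's valid
range, and is rejected outside it (FL ≥ L∞, or below length at age 0).

The allometry test is t = (b − 3)/SE(b) with df = n − 2, two-sided p from
the t distribution, where b and SE(b) come from the log–log OLS fit of
W = a·FL^b (the standard fisheries form, which is what makes SE(b)
well-defined). The companion statistic b/SE(b) — a test of b against zero,
which some published tables print instead — is reported alongside. On a
perfect zero-residual fit SE(b) = 0 and the test is degenerate; it is then
reported as t = 0 (b = 3) or ±∞ rather than raised as an error, because
noise-free synthetic tables are legitimate inputs. Cohort summaries use
the sample (n − 1) SD, reported as absent for groups of one.

## Synthetic specimen tables

`make_specimen_table` draws fork lengths from a range-truncated normal per
species, total lengths by inverting the length–length line plus small
measurement noise (SD 0.05 cm), and weights from the power law with
multiplicative lognormal noise (CV 5% by default, mean-one). The default
species parameters are the published September 2011 Adriatic cohort values:
FL 12.7 ± 1.09 cm in 10.8–15.0 (bluefin), 16.1 ± 2.27 in 13.2–21.8
(bullet), 13.6 ± 1.73 in 11.6–18.4 (little tunny), with the published
regression coefficients as generators.

`synthetic_cohort_table` is a deterministic stand-in for the measured
87-fish table, which is not redistributable: 29/30/28 fork lengths placed
at equally spaced truncated-normal quantiles, then iteratively rescaled and
clipped until each species' sample mean and SD equal the published values
exactly while staying inside the published range. Its derived age summary
(mean 29.2 d, SD 7.73 d) approximates but does not equal the published
29.5 ± 7.02 d, because matching per-species length summaries does not pin
down the individual lengths; the acceptance test allows ±1 day on both
numbers for exactly this reason. Age extremes land on the published
14.8–45.9 d range because the species length ranges map onto it.

## Connectivity statistics

* **Density maps** bin active particles onto the field's grid cells
  (half-open edges, lower-left inclusive, so each particle counts exactly
  once); the map total equals the in-domain active count at that time.
* **Areas of success** are axis-aligned lon/lat squares whose side is
  computed from the prescribed area (225 km² around farms for backward
  runs, 625 km² around the catch site for forward runs) on the local
  metric at the square's centre.
* **Sea-fraction weighting** multiplies the in-square count by the
  fraction (0–1) of grid points inside the square that are sea. The
  multiplicative form (rather than dividing to estimate "density over
  water") is implemented exactly as specified in the analysis this package
  reproduces; since only relative comparisons across sites are made, the
  choice of fraction keeps the statistic in units of particles and bounded
  by the raw count.
* **Arrival series** use instantaneous presence at each output time, not
  first passage: the reference figures show particle numbers within the
  rectangle over time.
* **Convergence** across particle numbers compares the end-time weighted
  success *per released particle* between N and 2N (otherwise independent
  seeded draws). The normalization makes the statistic invariant to N, so
  a deterministic flow with a point release gives exactly zero change and
  an i.i.d. placement null model shrinks like 1/√N. This simple doubling
  check replaces the original statistic-stability criterion.

## Numerical conventions and edge cases

* Axes must be strictly increasing; any interpolated axis needs ≥ 2 points.
* Cell membership is half-open with the lower edge inclusive (ties go to
  the cell whose lower-left corner the point matches).
* The RK4 uniform-flow step is exact (0.2 m/s × 600 s = 120 m); a
  solid-body-rotation orbit closes after one period to ~3×10⁻⁶ of its
  radius at dt = 600 s, against the analytic closed-orbit oracle.
* Diffusion displacement is drawn per-axis Gaussian, so the 2-D ensemble
  MSD is 4·K·dt by construction; the acceptance check verifies the
  implementation at 10⁵ samples within 2%.
* Swim-only transport has zero mean displacement and RMS radius
  v·dt·√N — random-walk scaling, sublinear in time, fundamentally unlike
  advective transport. Published swim-only dispersal envelopes of tens of
  kilometres are not reproducible from a per-600 s random-heading walk
  (the RMS radius after 46 days at ~0.1 m/s is ~5 km) and are therefore
  not used as checks; the discrepancy is inherent to the ambiguity of the
  original mechanism description, and the √N law is checked instead.
* File I/O: NetCDF-3 via xarray's scipy engine (dimension names
  lon/lat/depth/time; `u`, `v`, `mask` mandatory); trajectories as tidy
  CSV (pid, origin, release_time_s, t_s, lon, lat, depth_m, age_days,
  status) with an equivalent NetCDF layout; metrics as tidy CSV.

## Scaled problem sizes

The packaged scenario runs used by the tests and by `scripts/acceptance.py`
are scaled to 100 particles per release event (2000 per source, 6000 total
forward; 2000 backward) over 30 days. The dispersal structure is already
converged at these sizes — the acceptance output includes the N-doubling
convergence number — and full-size runs (20 000 per source, 46 days) are
available through the presets' defaults.

## Known limitations

* Regular z-level grids only; the original hydrodynamic fields were on
  terrain-following levels, and the z-level simplification is a deliberate
  substitution, not a claim about the original tooling.
* The bounce geometry (specular reflection about the crossed cell face) is
  a documented choice; the original tool's exact coastline behaviour is
  not specified at this level of detail.
* The diel-vertical-migration helper (06–18 local-solar day window) is
  provided but off by default; enabling behaviours beyond those exercised
  by the experiment presets has not been validated against any reference.
* Statistics on the synthetic cohort characterize the reconstruction, not
  the measured fish; per-fish quantities (individual ages, regression
  residuals) should not be compared against the real specimen table.
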