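# Methods

`leptoflow` is an individual-based biophysical larval dispersal model
(LDM): a Lagrangian transport engine coupled to a simple larval biology
and a settlement/connectivity assessment layer, exercised on analytic
synthetic ocean fields. This note documents the model, its parameters,
the numerical choices, and what the synthetic fields do and do not
emulate.

## Transport model

Particles carry (lon, lat, depth, age) and are advanced with a Forward
Euler step through linearly interpolated velocity fields (tri-linear in
lon/lat/depth, linear in time). Metre displacements convert to degrees
with local spherical scaling (111 320 m per degree latitude, ×cos φ for
longitude); at a 3 h step the neglected great-circle curvature is far
below the Euler truncation error. The timestep must respect the
fine-scale Courant–Friedrichs–Lewy bound dt ≤ 0.7·dGrid/Umax, where
dGrid is the mean grid length and Umax the order of the fastest
currents; the engine refuses configurations that violate it.

Sub-grid stirring is a 3-D random walk. Each horizontal component adds
δ·√(6·K_h·dt) with δ ~ U[−1, 1] drawn independently per axis, so the
per-axis variance is 2·K_h·dt and the mean squared planar displacement
is 4·K_h·dt — the normalization is forced by Var(δ) = 1/3. The
horizontal diffusivity defaults to Okubo's empirical power law for the
grid length, K_h = 0.0103·l^1.15 in cgs (≈2.13 m²/s at l = 3.1 km).
The vertical walk uses the same uniform-δ construction scaled by the
locally interpolated vertical diffusivity, with mirror reflection at
the surface and the bottom; for constant kz this satisfies the
well-mixed condition (an initially concentrated cloud relaxes to a
uniform depth distribution), which the tests check with a KS test at
α = 0.01 on 10⁴ particles.

The per-step update order is fixed and documented: advection →
horizontal dispersion → vertical dispersion → buoyancy → DVM clamp →
tracer sampling → thermal fate → onshore mortality → out-of-domain →
settlement. Fates (alive, out of domain, dead beached, dead cold, dead
hot, settled) are exclusive and absorbing; at every record the fate
counts sum to the released number. Each replicate iteration draws its
noise from a generator derived purely from (master seed, iteration
index), so runs are reproducible and iteration-order independent.

## Spawning release

Observed spawning couples to the thermocline, so releases are
parameterized relative to it rather than at absolute depths. The model
thermocline is the depth of maximum |dT/dz| estimated by centred finite
differences on the native levels with parabolic sub-level refinement;
ties break shallow, and isothermal or constant-gradient profiles raise
an explicit "no distinct thermocline" error rather than returning 0.
The upper release depth is (observed upper rush depth / observed
thermocline) × model thermocline — the ratio is carried unrounded
(63.7/75.9 = 0.83926…, not the rounded 84%), since with a 50 m model
thermocline the translated upper depth must come out at 41.96 m. The
lower extent is the depth strictly below the thermocline where |dT/dz|
is again maximal (ties break shallow, so a constant-gradient deep layer
yields the first level below). Particles (default 10 000) are released
uniformly in depth across that band — gamete release is modelled over
the whole ascent, which is unconfirmed either way observationally — and
area-uniformly (radius ∝ √U) over a 150 m stain disc.

## Larval biology

- **Ontogenetic buoyancy.** A density-ratio schedule (larval density ÷
  seawater density at the upper thermocline, tabulated against age/PLD)
  is interpolated piecewise-linearly with clamped ends. The packaged
  table is a synthetic stand-in, constructed so the age-0 ratio
  (0.99560 at ρ_w = 1024.4 kg/m³, i.e. a 4.51 kg/m³ deficit) gives an
  initial Stokes rise of ≈8.5 m/day decaying to neutral by
  mid-development — the qualitative ontogeny measured for anguillid
  leptocephali. Buoyancy enters the depth update as an explicit Stokes
  velocity w = (2/9)·g·r²·Δρ/μ each step (the equivalent spherical
  radius defaults to 1×10⁻⁴ m, half a 2×10⁻⁴ m head diameter;
  configurable because the drag shape is ambiguous), and is disabled
  while the DVM clamp is active.
- **DVM.** Settlement-competent larvae (41–71 days post spawn, closed
  interval) are held at or above 2 m, independent of proximity to
  settlement habitat.
- **Lethal temperatures.** Strict bounds: death below 14 °C or above
  32 °C; a larva at exactly 14 or 32 °C survives.
- **Onshore mortality.** A pre-competent particle whose containing grid
  cell is land dies ("beaching", standing in for habitat-mismatch
  mortality). Competent larvae on land outside any settlement zone also
  die; on land *inside* a zone they settle instead — zones are
  deliberately over-extended beyond the shoreline, so land contact
  within a zone is successful settlement, not mortality.

## Settlement and connectivity

Settlement zones are named GeoJSON polygons grouped by island. A larva
settles when its post-step position is covered by a zone (closed
polygons: boundary counts as inside, favouring settlement) during the
closed competency window; pre-competent presence in a zone has no
effect. Overlaps resolve by file order. Assessment statistics:
per-day mean fate proportions across iterations; gridded occupancy
densities (all-steps and final-step); a settlement KDE with per-axis
normal-reference bandwidth h = σ·n^(−1/6), normalized to a maximum of
1; island totals and the fraction of iterations with ≥1 settler;
per-iteration settlement footprints (island sets, frequencies summing
to 1 including the empty set); and per-settler development-environment
records. All distances are haversine with R = 6371 km. The coefficient
of dispersal is the spawn→settlement chord divided by the along-track
path length over recorded positions up to settlement inclusive — in
(0, 1] by the triangle inequality, 1 for linear transport, →0 for
circuitous retention. Mean dispersal depth includes every record up to
settlement, including DVM-clamped ones.

## Island contrasts

Per-settler variables grouped by island are screened for normality with
a Lilliefors-corrected KS test (parameters estimated from the sample),
compared with a tie-corrected Kruskal–Wallis omnibus test, then Dunn's
rank-based pairwise z tests with Bonferroni correction. Effect sizes
are Hedges' g = J·d with the pooled-SD Cohen's d and
J = 1 − 3/(4(n₁+n₂) − 9); magnitude classes use exclusive lower bounds
(negligible < 0.2 ≤ small < 0.5 ≤ medium < 0.8 ≤ large). Confidence
intervals are percentile bootstrap (default 2000 resamples, seeded and
recorded). Two zero-variance groups make g undefined and are flagged
rather than silently zero. Larvae are treated as independent
observations despite sharing iterations, matching standard practice in
this kind of analysis; iteration-level dependence is a known
limitation.

## Synthetic ocean fields

The analytic scenario components reproduce the *structures* the
analysis depends on, not any real archive: a two-layer tanh
stratification with a controllable thermocline; solid-body or Rankine
gyres defined on a tangent plane anchored at the gyre centre (so the
rendered velocity is exactly divergence-free in those metric
coordinates); uniform background/boundary currents; half-plane or
circular-island coastlines rasterized to the landmask; constant or
depth-decaying vertical diffusivity. Depth is positive down with the
surface at 0; vertical velocity is positive down; time is seconds from
a configurable origin. Fields round-trip losslessly through NetCDF
(classic format with CF-style coordinate metadata).

What passing tests on these fields show: the transport numerics,
biology rules, bookkeeping and statistics behave correctly under known
analytic conditions. What they do not show: skill against real
mesoscale variability, tides, vertical shear, or realistic coastlines —
reproducing any real archipelago's connectivity numbers is explicitly
out of scope.

## The retention benchmark

The qualitative benchmark scenario superposes a solid-body gyre
(30 km core, centred at 77°W 24°N) on a 0.04 m/s eastward jet, with
one settlement zone over the gyre ("GyreIsle") and one 170 km
downstream ("JetCay"). Release uses the thermocline-proportional rule
(upper depth 41.96 m for the default observation against the 50 m
model thermocline). Sweeping the gyre's peak tangential speed over
0.10, 0.14, 0.18 m/s crosses the trapping transition (closed
streamlines appear once rotation outruns the jet), so the gyre-fed
island's settled proportion and iteration-settlement fraction rise
monotonically while its settlers' mean coefficient of dispersal falls
— retained larvae orbit, lengthening their paths. Problem sizes
(10 iterations × 500 particles × 71 days at a 3 h step, grid
90×48×21×4) were chosen as the smallest sweep that resolves the
transition cleanly; the declared grid length (4600 m) and Umax
(0.25 m/s) keep the 3 h step inside the CFL bound.

## Numerical details and edge cases

- Land cells carry NaN fields; for interpolation the sampler fills
  velocities/diffusivity with 0 (flow tapers toward the coast) and
  tracers with the wet mean of their time/depth slice, while the
  landmask itself (nearest-cell lookup, no sub-cell coastline) decides
  beaching.
- Out-of-domain is assessed on the post-step position and is absorbing;
  sampled tracers freeze at their last in-domain values.
- Proposed depths fold into [0, bottom] by mirror reflection.
- The 71-day run at 3 h cadence records 569 states per larva
  (71×8 + 1, including the release instant); records are frozen after
  an absorbing fate.
- Trajectory output is NetCDF with dims (iteration, particle, record)
  and an integer-coded fate legend; positions are stored float32, which
  bounds coordinate round-off near 1 m — negligible against the grid
  scale and dispersion amplitudes.

## Known limitations

No volitional swimming, feeding, predation or growth dynamics — these
are unparameterizable with current knowledge of the species.  Buoyancy
as an explicit velocity (rather than an equilibrium-depth scheme) is a
modelling choice exposed in configuration.  The KDE treats settlers as
independent points.  Synthetic coastlines are analytic; no attempt is
made to emulate shoreline masking rules used with real grids.
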