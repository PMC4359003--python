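# Methods

## Scope and model structure

The package couples two independent stages on a shared regular
latitude/longitude/depth grid: a mechanistic climate-envelope classification
of monthly hydrographic conditions, and an offline Lagrangian simulation of
passive larval drift. Both consume gridded fields — either external NetCDF
files or the built-in synthetic generator — and neither feeds back on the
other: the envelope maps describe where conditions permit reproduction and
metamorphosis; the connectivity matrix describes where passively drifting
larvae end up.

## Synthetic hydrography

The generator emulates the statistical structure of a salinity-stratified
marginal sea, not its dynamics. For a scenario with parameters (defaults in
parentheses):

* **Surface salinity** is linear in longitude from `salinity_west` (32 PSU)
  at the westernmost sea column to `salinity_east` (3 PSU) at the easternmost,
  and time-invariant. Anchoring at the sea columns (not the bounding box)
  makes the boundary values exact regardless of the land fringe.
* **Surface temperature** is `sst_mean` (9 °C) plus a cosine seasonal cycle of
  amplitude `sst_amplitude` (8 °C) peaking on `sst_peak_day` (day 210, late
  July), plus an optional linear `warming_trend` (°C per decade) measured
  from the first generated year.
* **Vertical structure** is a sharp two-layer stratification at
  `halocline_depth` (60 m): below it salinity is the surface value + 4 PSU,
  temperature is `sst_mean` − 4 °C with no seasonal cycle or trend, and
  oxygen drops from `surface_oxygen` (9 mg l⁻¹) to `bottom_oxygen`
  (3 mg l⁻¹, i.e. hypoxic by default, as in deep stagnant basins). The step
  profile keeps every layer value a closed-form function of the scenario,
  which the tests exploit.
* **Bathymetry** is a bowl-shaped basin (> 100 m in the centre) with a
  shallow (< 25 m) southern shelf, a one-cell land fringe, and small seeded
  roughness. A `flat_depth` option yields an all-sea constant-depth domain
  for degenerate test cases.
* **Velocity** derives from a node-registered streamfunction (single or
  double basin gyre of amplitude `gyre_strength` = 10⁴ m² s⁻¹ ≈ 0.1 m s⁻¹
  peak speeds, a solid-body-rotation mode for integrator oracles, or zero).
  Face transports are pure differences of node values, so the discrete
  divergence telescopes to exactly zero and setting ψ = 0 on every node
  touching land enforces zero normal flow through land faces; zeroing ψ on
  the coastal ring also produces a boundary-current-like rim flow. Scalars
  and velocities are stored cell-centred; the face-flux construction exists
  to guarantee the conservation properties at generation time. A uniform
  drift option adds a constant (u, v); with land present such a drift is not
  divergence-free and relies on the integrator's beaching guard.

The scalar fields are purely parametric: the scenario seed perturbs only the
bathymetry roughness and the release-lattice jitter, so generated
temperature/salinity/oxygen values are exactly reproducible closed forms.
What the generator deliberately omits: inter-annual and synoptic
variability, advective heat/salt transport, tides, ice, and any
temperature–salinity covariance. Tests passing on these fields therefore
validate the *pipeline logic* (classification, aggregation, integration,
bookkeeping), not the realism of any particular ocean state.

## Envelope classification and aggregation

Layer values are thickness-weighted means over the layer interval — surface:
0 to min(9 m, local depth); bottom: the lowest 2 m above the seabed — so a
bottom layer spanning two depth bins draws proportionally from each, and in
water ≤ 9 m deep the two layers legitimately overlap. The mean is classified,
not the individual bins. Monthly binning is the arithmetic mean of all time
steps in the calendar month; months with no samples are dropped from both
numerator and denominator of every frequency rather than counted
unfavourable. Classification uses inclusive comparisons (≥) against the
threshold table, all three criteria combined with logical AND; the surface
model applies the stricter 12 °C metamorphosis temperature, the bottom model
the 11 °C reproduction-only column. An `ignore_oxygen` switch exists solely
to demonstrate when oxygen is non-limiting.

Frequencies are reported in percent per cell. `frequency_overall` counts
favourable cell-months over defined cell-months in a year range;
`frequency_by_month` counts favourable years for one calendar month;
`frequency_period_month` evaluates the latter over disjoint (quasi-decadal)
year ranges. A structural consequence of the seasonal generator worth noting:
with a 9 °C mean and 8 °C amplitude, monthly means exceed 12 °C only in
June–September, so the overall frequency is capped near 33% even where
salinity always passes — the >60% correspondence threshold is only exceeded
under warmer scenarios (e.g. `sst_mean = 15`), which is how the validation
tests construct maps with both sides of the 60% contour.

## Dispersal simulation

Releases: a fixed near-square lattice (7 × 14 for 98 particles) of start
positions per cell, offset by one seeded jitter common to all cells and
events and spread uniformly over 0–12 m; a stochastic-start variant draws
uniform positions for Monte-Carlo convergence checks. Release events fall on
the first day of each release month (May–October by default) — the calendar
of events within the season is a convention, fixed here for reproducibility.

Integration: fourth-order Runge–Kutta in longitude/latitude with the
spherical metric (dλ = u/(R cos φ), dφ = v/R), velocities depth-averaged
over the tracked 0–12 m layer, interpolated bilinearly from cell centres and
linearly in time between velocity snapshots, with a 30-minute default
substep. Land cells carry zero velocity; a projection guard reverts any
substep that would end on land (preventing artificial beaching losses), and
crossing the domain boundary terminates the trajectory with a `left_domain`
sentinel. There is no vertical velocity in the kinematic fields, so particle
depth is carried as metadata; larvae have no behaviour (no vertical
migration, no settlement delay or competency window) — they are passive
throughout and their end cell is recorded at exactly the trajectory duration
(30 days).

Connectivity: P[j, i] = settled count / released count per row, with
receiving cells restricted to depth ≤ 100 m; trajectories ending in deeper
water or outside the domain are tallied per row as losses. Conservation is
exact at the count level (settled + deep + domain = released, an integer
identity checked independently of the float matrix); the float row sums agree
with 1 − loss to within summation round-off (≤ 1 ulp per entry), and exactly
in the zero-flow philopatry limit. Entries are computed as count/n in a
single division so simple proportions (3 of 10 → 0.3) are bit-exact.

Numerical accuracy, measured on analytic flows at the equator (where the
lon-lat metric is effectively Cartesian): uniform 0.1 m s⁻¹ flow gives the
closed-form 259.2 km 30-day displacement to ~10⁻¹³ relative; solid-body
rotation (10-day period) shows < 5 × 10⁻⁴ % radial drift over 30 days; RK4
agrees with a 2-second forward-Euler oracle to < 10⁻³ relative displacement;
halving the substep changes end-cell assignment for < 1% of particles on
smooth gyre flow. At mid-latitudes the equirectangular projection used to
define the solid-body streamfunction is itself distorted by ~cos φ, which is
a property of the test construction, not of the integrator.

## Source/sink maps and validation

Forward maps average the probability rows of an area's release cells with
equal weights (no habitat weighting information exists to do otherwise);
their values are raw mean probabilities. Backward maps sum each release
cell's probability of ending in the target area and are normalised by the
maximum to a relative source strength in [0, 1]; the unnormalised sums are
retained (`raw_values`) because they, not the normalised values, satisfy the
forward/backward duality (both directions count the same trajectory mass).
`summarize_spread` reports philopatry (mass inside the area), east/west mass
split about the area centroid, and the largest value beyond a stated
distance — descriptive only.

Validation samples the frequency map at record coordinates (nearest cell by
default; bilinear optional) and tabulates a confusion table at the 60%
threshold. It is a correspondence check: the rule holds when no infested
record falls below threshold. No skill scores are fitted. The bundled
`occurrence_synthetic.csv` is an illustrative, synthetic set of points with
the qualitative west-infested / east-clear pattern; it is not survey data.

## Sizes, defaults, and degenerate inputs

Demo problem sizes (20 × 36 × 6 grid, single-year daily hydrography,
scaled-down release campaigns of 4–98 particles per cell over 1 year) were
chosen so that every example and test completes in seconds while still
exercising land masking, deep-basin losses, and all twelve calendar months;
the release *protocol defaults* retain the full-campaign bookkeeping
(98 × 6 × 8 = 4704). Degenerate inputs are handled explicitly: months with
no samples are dropped; all-land maps export as all-nodata rasters; empty
trajectory sets, land release cells, non-monotone depth axes, overlong hydro
time steps (> 1 month, which would make monthly binning ill-defined) and
velocity records that do not cover a trajectory window all raise
configuration errors before any computation starts. ESRI ASCII export
requires square cells (the format has a single CELLSIZE); anisotropic grids
must use GeoTIFF, which is written and read back through plain TIFF tags
(pixel scale, tiepoint, nodata).

## Known limitations

* Velocity realism is kinematic only — no pressure gradients, wind forcing,
  tides or ice; gyre flows are steady in time.
* Oxygen is generated and thresholded as a concentration (mg O₂ l⁻¹); no
  saturation conversion is implemented.
* 2-D transport with depth-averaged velocity is the only advection mode that
  matters here, since the kinematic fields are depth-uniform over 0–12 m and
  carry no vertical velocity.
* The envelope model assumes fixed tolerances (no adaptation or plasticity)
  and the dispersal model a fixed 30-day passive drift; both are structural
  assumptions of the method, not tunables.
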