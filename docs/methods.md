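# Methods

## Model

The unit of the model is the nest-year.  A nest founded in spring by a single
overwintered queen lives one season; at the end of the season it releases a
Poisson-distributed number of daughter queens that survive hibernation and
found next year's nests, and the colony dies.  The Poisson mean for a nest at
location `x` is

    mu(x) = sigma · R_A · L(lat(x)) · g(n(x)),            mu = 0 on water,

with the factors:

* `R_A` — successful daughter queens per nest at low density at the
  Andernos-les-Bains reference latitude (44.74° N).  Default **8.7**, obtained
  by requiring that a nest at the Tetbury latitude (51.64° N), which retains
  38 % of baseline potential under the default cline, produce 3.3 expected
  daughters.  Override it (or supply a posterior-draw CSV) when fitted values
  are available.
* `L(lat) = clamp((lat_zero − lat) / (lat_zero − lat_A), 0, 1)` — linear
  decline of reproduction with latitude, zero at `lat_zero` = **55.9° N**
  (northern England), clamped at 1 south of the reference latitude so the
  model never extrapolates above the fitted baseline.  `lat_zero` follows from
  inverting the 38 %-at-Tetbury anchor and is configurable.
* `g(n) = 1 / (1 + n / K_half)` — density dependence, with `n` the number of
  other *active* nests within the competition radius `r_c` of the mother nest
  in the same year (boundary inclusive, simultaneous across nests so results
  are replicate-order independent).  An exponential form
  `g(n) = exp(−n / K_half)` is selectable; both equal 1 at `n = 0`, so all
  low-density results are insensitive to the choice.
* `sigma` — a global multiplier on reproductive potential, the knob of the
  sensitivity analyses (default 1).

**Choice of `K_half` and `r_c`.**  Neither is identifiable from the headline
low-density quantities, so they are set once from equilibrium density:
`r_c = 2 km` (the kilometre scale of colony foraging, hence of competition for
prey) and `K_half = 2` give a replacement-level density
`n* = K_half (R_A − 1)` nests per competition disc, i.e. ≈ 1.2 nests/km² at
the French baseline and ≈ 0.37 nests/km² at the GB founder latitude — the
latter implying ≈ 55 000 nests for the ~150 000 km² of England and Wales at
carrying capacity, matching the scale of a saturated GB invasion a decade
after establishment.

**Dispersal.**  A queen displaces by an exponentially distributed distance
(mean `delta = 28 km`) in a uniform direction.  `delta` is treated as a
calibrated constant: `engine.calibrate_delta` bisects it against a target
invasion-front speed (front speed is monotone in `delta`, asserted at run
time).  Settlement is by rejection: the destination cell is accepted with
probability `weight(class)/max(weight)` (defaults: urban 1.0, agricultural
1.0, woodland 0.5, other 0.25, water 0); off-grid, water or rejected habitat
causes a complete re-draw of the displacement, up to `max_attempts = 20`
attempts, after which the queen founds no nest.  Re-drawing (rather than
snapping to the nearest suitable cell) preserves the exponential marginal
distance distribution on homogeneous landscapes.  Habitat preference acts
*only* at settlement; reproduction sees habitat only through the water
exclusion, so suitability is not double-counted.

**Control.**  From `start_year` on, every active nest is independently
detected with probability `p_detect` each year, *before* queen release;
detected nests are destroyed and contribute no daughters.  Each
primarily-detected nest triggers one radial search in which every other
active nest within `search_radius_km` is found with probability
`search_efficiency`.  Searches do not chain by default (nests found radially
trigger no further searches) — the most conservative reading of a thorough
one-off local search; a `chain_searches` flag enables chaining.  Repeated
introductions are modelled as a Poisson arrival process whose invasions are
controlled independently; "colonisation" is the first arrival whose lineage
survives the 25-year horizon.

## Analytic risk maps

All Figure-style risk quantities are computed from the probabilistic rates,
not by simulation.  The key object is the cell-integrated settlement kernel:
the single-draw probability of landing in a cell offset Δ is the 2-D point
density `f(d)/(2πd)` (f the exponential distance density) integrated by the
midpoint rule, with a 9×9 sub-cell refinement for cells within four cell
widths of the origin and the exact radial CDF over the origin cell's
equal-area radius (`r_eq = h/√π`), which removes the `d → 0` singularity.
The kernel is truncated at six mean dispersal distances (tail mass < 0.3 %,
carried explicitly as rejection) and renormalised to the analytic in-support
mass.  With per-cell acceptance `alpha`, single-draw acceptance
`a = K ∗ alpha`, and `m` attempts, the settlement operator and failure mass
are

    T(x→y) = alpha(y) · K(y−x) · (1 − (1−a(x))^m) / a(x),
    fail(x) = (1 − a(x))^m,

and `Σ_y T + fail = 1` exactly.  All spatial sums are FFT convolutions.

* **Founder posterior** — `posterior(x) ∝ settleable(x) · Π_i K(x → obs_i)`,
  evaluated with the same cell-integration conventions.  It uses settleability
  and dispersal only (no reproduction weighting): the simplest likelihood for
  "where did the nest one dispersal step upstream of these sightings sit".  A
  worker-hornet sighting is treated as evidence of a nest at the sighting
  location (workers forage near their nest); a foraging-radius blur is a
  possible refinement, not implemented.  Note that with an exponential
  *distance* kernel the point density has an integrable singularity at each
  observation, so the posterior mode falls in an observation's cell rather
  than strictly midway between two observations; the mode latitude differs
  from the midpoint's by ~0.1°, which moves downstream totals by ~3 %.
* **Intensity propagation** — `lambda'(y) = Σ_x lambda(x) mu0(x) T(x→y)` with
  `mu0` the low-density (crowding-0) mean; linear in `lambda` and equal to the
  mean of the stochastic simulator at low density (property-tested against
  10⁴ one-year simulations).  Density dependence is deliberately ignored here:
  the fields of interest carry a few expected nests over thousands of km².
* **Undiscovered nests.**  Detection-and-destruction is an independent
  thinning of the Poisson daughter set, so destroying a discovered nest does
  not reshape the distribution of the undiscovered remainder; the year-1
  field is simply the propagated founder posterior, and
  `P(≥1 undiscovered) = 1 − exp(−total)`.
* **Year-2 field.**  Observed year-1 nests are *extra* conditioning
  information on top of the undiscovered Poisson field (again by thinning),
  so the year-2 field propagates the undiscovered intensity **plus a unit
  point mass per observed nest**.  This includes a nest destroyed at the end
  of its season — its queens had already dispersed — while control applied
  *before* queen release (the control module's convention) would remove it.
  For the two GB records this choice is what lifts the year-2 expectation
  from ~11 to ~18 nests; both nests are believed to have released queens (one
  destroyed only in late September, the other never found).
* **High-risk contour** — cells sorted by intensity, smallest prefix with
  less than `budget` (default 1) expected nests outside; returns mask, area
  and the marginal intensity level.
* **Extinction probability** — the branching fixed point
  `q(x) = exp(mu0(x)·[Σ_y T(x→y) q(y) + fail(x) − 1])`, iterated from `q ≡ 0`
  (monotone, converging to the minimal fixed point, i.e. the true extinction
  probability) until the sup-norm change is below 1e−9 (cap 5000 iterations,
  error on non-convergence).  Density dependence is ignored, which is valid
  near the extinction threshold where densities are minimal.  The solve runs
  on a coarsened grid (4-km cells) — the threshold quantity is a smooth
  functional of the field.  On this model's GB-like island the extinction
  threshold is governed by the southernmost suitable latitude: extinction is
  certain once `sigma · R_A · L(lat_south) ≤ 1`, which corresponds to ≈ 10 %
  of the Andernos baseline realised at the founder location (≈ 8 % would be
  exact if the island reached 49.9° N with no settlement losses).

## Synthetic landscapes

`generate_landscape` builds a coastal raster from a target class composition:
water occupies the lowest quantile of an "inland score" (distance from the
raster edge plus smooth Gaussian noise), giving a contiguous, irregular
coastal margin; land classes are quantile bands of an independent smoothed
noise field with correlation length `patch_scale_km`.  Realised proportions
are exact up to cell rounding, and the generator is a pure function of
(spec, seed).  The GB-like preset is a fixed 560 × 740 km island (seed fixed
as part of the geography): ~50 km water margin, land spanning ≈ 50.0–55.8° N
under the affine latitude map (111 km/degree), 7 % urban / 38 % agricultural /
12 % woodland / 13 % other / 30 % water, with the two 2016 sighting records
placed at their true latitudes ~48 km apart.

What the synthetic island does *not* emulate: the real shape of Great
Britain (peninsulas, estuaries, the Bristol Channel next to the founder
region), real Corine habitat geography, and coastal-latitude detail.
Quantities that integrate over geography (the year-2 nest total, high-risk
areas, the extinction threshold) therefore carry an O(10–25 %) geography
uncertainty, and passing tests demonstrate internal consistency of the
method, not calibration to real GB land cover.

## Numerical and implementation choices

* Coordinates are projected km (y = northing); cells classify habitat, nests
  carry continuous coordinates; latitude is affine in northing — the only
  geographic property the model uses is a linear north–south gradient.
* Fixed-radius crowding counts use an exact O(n) cell-list (numba) above
  3000 nests, an O(n²) vectorised brute force below, and a cKDTree fallback
  without numba; the three agree exactly and are property-tested against each
  other.
* Replicates derive their generators from `SeedSequence(master, spawn_key=k)`,
  so replicate `k` is bit-reproducible in isolation; every CLI run writes a
  manifest (config echo, seed, version).
* Front-speed estimation: the 97.5th percentile of nest distance from the
  seed (robust to single outliers), regressed on year over the last four
  years with ≥ 10 nests.  The fit window excludes the establishment
  transient deliberately: until the founding core saturates, the population
  percentile lags the true front and a full-window fit underestimates the
  speed by ~25 %.  With the default parameters the simulated front advances
  at ~63–66 km/yr — a discrete-population front, which travels measurably
  slower than the deterministic linearised speed of the same kernel/growth
  pair (~92 km/yr).
* Problem sizes used by the shipped experiments: risk maps on the 2-km GB
  grid (370 × 280 cells), extinction fixed points on the 4-km grid, front
  speed from 10 replicates × 10 years on a 1200 × 1200 km, 4-km-cell
  homogeneous landscape (~0.5–1.5 M nests per replicate in the final years);
  Monte-Carlo consistency checks use 10⁴–10⁵ draws.

## Known limitations

* Human-mediated long-jump dispersal, anisotropy, and within-year colony
  dynamics (primary vs secondary nests, queen trapping) are not modelled.
* The exact density-dependence form, `K_half`, `r_c`, and the fitted
  posterior distributions behind the reference parameters are external
  inputs; defaults are anchored to the low-density reproduction values and an
  equilibrium-density argument.
* Resource competition or complacency across concurrent invasions is ignored
  (introductions are controlled independently).
* The founder posterior ignores how many descendants an upstream nest would
  have produced; a reproduction-weighted likelihood would shift the posterior
  slightly south.
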