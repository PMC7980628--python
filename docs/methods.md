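# Methods

## Model

A location is a point on a flat projected plane (meters; any reprojection
from geographic coordinates happens before the data enter this package).
Pseudonymization replaces the point by the set of labels of all grid
points *strictly* within radius r of it. Distance recovery rests on three
facts:

1. **Lens area.** Two disks of common radius r with centers d apart
   intersect in area A(d) = 2r²·arccos(d/2r) − (d/2)·√(4r² − d²), a
   continuous, strictly decreasing bijection [0, 2r] → [0, πr²]. The
   implementation evaluates it as 2r²·(θ − sin 2θ / 2) with
   θ = arccos(d/2r) and validates it against an independent Monte-Carlo
   rejection-sampling oracle (agreement within 4 standard errors across
   the domain, in the test suite).
2. **Area from set overlap.** Each label set is a count proxy for disk
   area: with grid density 1/h² the expected count in a disk is πr²/h²,
   and in the lens A/h². The Dice coefficient s = 2|𝒢_P ∩ 𝒢_Q| /
   (|𝒢_P| + |𝒢_Q|) therefore estimates A/πr², giving Â = s·πr². Dice is
   used rather than a direct count-times-cell-area estimate because the
   analyst knows neither h nor the working area — only the sets and r.
3. **Inversion.** d̂ solves A(d) = Â, found by Brent's method on [0, 2r]
   to absolute tolerance 1e-9. Monotonicity makes the root unique.

**Censoring.** d > 2r implies disjoint disks, hence disjoint label sets,
with certainty. An empty intersection is reported as "d ≥ 2r"
(`censored=True`, `d_hat = 2r` as a bound, never averaged as an
estimate). Consequently r should be at least half the largest distance of
interest.

## Parameters

- **r (radius, m).** Controls both the censoring horizon (2r) and
  accuracy: the distance error per miscounted grid cell is
  h²/√(4r² − d²), worst near d → 0 and d → 2r. No default; the worked
  examples use 30,000 m.
- **n (grid points) / h (spacing, m).** Regular grids use
  h = √(bbox area / n), cell-centered so no point lies on the boundary;
  the realized count differs from n by edge effects and is reported, not
  forced. h² is the area-quantization unit; accuracy improves roughly as
  h^(3/2) for lattices.
- **Working-area enlargement.** `enlarge_bbox` expands the data bounding
  box symmetrically to `target_area_factor` times its area (default 11.4)
  with a hard floor of `min_buffer` (callers pass r) on every side, so
  every encoding circle lies fully inside the grid. The large default
  factor also serves privacy: the grid's extent reveals little about
  where the data sit. Circles leaking past the grid edge trigger a
  warning (precision loss), not an error.
- **Labels.** Default: a seeded uniform permutation of 1..n, stored as
  strings; opaque downstream. Keyed mode: HMAC-SHA256 of the grid-point
  index truncated to 16 hex characters (collision-checked), for two-party
  settings where label sets double as hash-value sets. The two modes are
  interchangeable; the key never appears in any serialized artifact.
- **Minimum cardinality warning (default 30).** Below ~30 grid points per
  circle, Dice quantization noise dominates; encoding warns but proceeds.
  An empty label set is an error: it carries no information.

## Error metric

The signed relative error convention is **(d_true − d̂) / d̂** — the
denominator is the *approximated* distance. `relative_error` offers the
conventional d_true denominator behind a flag. The estimate d̂ = 0
(identical label sets for distinct points, i.e. a pair below the grid's
resolving power) makes the default convention undefined; such pairs are
counted separately (`n_degenerate`) in sweep summaries rather than
silently averaged or dropped.

## Synthetic geography

`generate_scenario` emulates a two-population setting: many residential
points, few facilities, in a rectangular region. Defaults — 1,000
residential, 80 facilities, 400 × 350 km — keep realistic point- and
grid-density ratios at desk scale rather than any country's absolute
counts. `uniform` placement is the null geography (its nearest-facility
distances follow the binomial nearest-neighbor law, checked by a KS test);
`clustered` placement draws both populations around shared Gaussian
cluster centers (6 centers, 30 km spread, clipped to the region), which
concentrates nearest-facility distances in the tens-of-kilometers band
typical of health-services data. What the generator does **not** emulate:
road networks, coastline/boundary shapes, the strong density contrast of
cities versus countryside, and correlation between facility placement and
population density beyond shared clusters. Passing simulation tests
therefore demonstrate the estimator's statistical behavior under
controlled geometry, not performance on any particular real geography.

`run_sweep` runs a full factorial over (radius, grid count). One fresh
grid — new geometry and labels — is built per cell, seeded from
(master seed, cell index) via `numpy.random.SeedSequence`, so sweeps are
reproducible yet cells are independent. Per (cell, neighbor rank) it
reports mean absolute relative error, signed-error variance, censoring
fraction and degenerate-pair count; per cell, the order-preservation
rate, defined strictly: the fraction of residential points whose ranking
of their k (default 3) true-nearest facilities by estimated distance
equals the true ranking exactly (censored estimates sort at 2r; exact
ties break by facility id).

`distance_band_study` is the controlled-error experiment: pairs at
exactly known true distances, uniform in a band, every circle fully
interior to the grid, so measured error is purely the method's
quantization noise.

## Numerical choices

- arccos argument clamped to [−1, 1]; near d = 2r the lens area is
  evaluated by a small-angle series in θ (θ < 1e-3) because θ − sin 2θ/2
  cancels catastrophically there; the result is clamped to ≥ 0.
- Estimated areas within 1e-9·πr² outside [0, πr²] are snapped to the
  boundary (3-decimal Dice rounding can overshoot); larger excursions are
  rejected. Â = 0 and Â = πr² return the endpoints exactly without
  iteration.
- Radius membership is strict (< r), so boundary ties are excluded
  deterministically. The KD-tree query is post-filtered to the strict
  definition and tested for exact agreement with a brute-force scan.
- Grid fingerprints (SHA-256 over kind, bbox, coordinates and labels,
  truncated to 16 hex chars) gate every pairwise comparison: pseudonyms
  from different grids or radii raise instead of returning nonsense.
- Duplicate coordinates in random grids are not deduplicated
  (measure-zero under continuous sampling); labels are unique regardless.

## Scale of the shipped studies

Tests and the acceptance script size their simulations to run on a
laptop-class machine in seconds to a few minutes: error-band studies use
1,000 pairs (properties: 25 pairs × 20 seeds), sweeps use tens of
residential points per cell, and the Monte-Carlo geometry checks use
2×10⁶–10⁷ samples. These sizes give standard errors comfortably below the
asserted margins; all aggregate claims are averaged over ≥ 20 seeds where
seed noise could matter.

## Known limitations

- **Accuracy floor at moderate density.** On a ~4.98 km lattice (60,000
  points per 1.49 million km²) with r = 30 km, the package's controlled
  study over pairs 10–55 km apart measures a mean absolute relative error
  of ≈ 1.7% (`scripts/acceptance.py`). This is consistent with the
  per-cell quantization bound h²/√(4r² − d²) (≈ 420 m at d = 10 km,
  ≈ 1,030 m at d = 55 km): sub-1% mean error over such a band requires a
  finer grid, a larger radius, or a distance distribution concentrated in
  the mid-range. Random grids at equal density are several times worse
  (binomial count noise), which the property tests assert.
- Euclidean distances only; geodesic or travel-time metrics are out of
  scope, as are triangular/spherical grids.
- The security model is not analyzed here: the package guarantees that
  released artifacts contain no coordinates (asserted structurally in
  tests), but quantifying re-identification risk from a censored distance
  matrix plus side information is a separate problem.
- Coordinates must share one projected CRS in meters; the package neither
  checks nor converts projections.
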