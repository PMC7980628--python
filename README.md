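# isgp

Privacy-preserving approximation of pairwise distances between sensitive
point locations, via **intersecting sets of randomly labeled grid points**
(ISGP).

## The problem

Research on geo-located health data (distance from a residence to the
nearest hospital, exposure gradients, access studies) needs pairwise
Euclidean distances — but releasing coordinates, even perturbed ones, is a
re-identification risk. ISGP is a geomasking scheme in which each data
holder replaces every location by an opaque *set of labels*, such that an
analyst who only ever sees the label sets can still recover the distances,
approximately, and nothing else.

## The method

Two (or more) data holders agree on a secret: a grid of *n* points over an
enlarged working area, each grid point carrying a random label (a seeded
permutation of 1..n, or keyed-hash digests). A location *P* is
pseudonymized as

&nbsp;&nbsp;&nbsp;&nbsp;𝒢_P = { labels of grid points at distance < r from P },

for an agreed radius *r*. The analyst receives only the sets. Two disks of
equal radius *r* whose centers are *d* apart intersect in a lens of area

&nbsp;&nbsp;&nbsp;&nbsp;A(d) = 2r² · arccos(d / 2r) − (d/2) · √(4r² − d²),

which is a strictly decreasing bijection of d ∈ [0, 2r] onto [0, πr²].
The Dice coefficient of the two label sets,

&nbsp;&nbsp;&nbsp;&nbsp;s = 2 |𝒢_P ∩ 𝒢_Q| / (|𝒢_P| + |𝒢_Q|),

estimates the lens area as a fraction of a disk, Â = s·πr², and inverting
A(d) = Â by bracketed root finding on [0, 2r] yields the distance estimate
d̂. Pairs farther apart than 2r have disjoint disks, hence disjoint label
sets: only "d ≥ 2r" can be stated (censoring), which also truncates any
distance matrix an attacker might try to reconstruct.

The package provides the geometry (`isgp.geometry`), grid generation and
labeling (`isgp.grid`), pseudonymization (`isgp.encoder`), distance
recovery (`isgp.estimator`), a synthetic-geography simulation harness for
the error behavior (`isgp.simulation`), and delimited-text file formats
plus an `isgp` command line for the three-party workflow (`isgp.io`,
`isgp.cli`).

## Worked example

```python
from isgp import (BoundingBox, GridSpec, PlanarPoint, make_regular_grid,
                  enlarge_bbox, encode, estimate_distance, relative_error)

home = PlanarPoint("residence", 210_000.0, 190_000.0)
hospital = PlanarPoint("hospital", 240_000.0, 220_000.0)

region = BoundingBox.of_points([home.x, hospital.x], [home.y, hospital.y])
working_area = enlarge_bbox(region, target_area_factor=11.4, min_buffer=30_000.0)
grid = make_regular_grid(GridSpec("regular", 2_000, working_area, seed=42))
print(f"grid: {len(grid)} points, spacing {grid.spacing:.0f} m")

ps_home = encode(home, grid, r=30_000.0)
ps_hosp = encode(hospital, grid, r=30_000.0)
print(f"pseudonym sizes: {ps_home.cardinality}, {ps_hosp.cardinality}")

est = estimate_distance(ps_home, ps_hosp)
print(f"Dice s = {est.s:.3f}, estimated distance = {est.d_hat:.0f} m")
d_true = ((home.x - hospital.x)**2 + (home.y - hospital.y)**2) ** 0.5
print(f"true distance = {d_true:.0f} m, relative error = {relative_error(d_true, est):.3f}")
```

prints

```
grid: 2025 points, spacing 2265 m
pseudonym sizes: 549, 548
Dice s = 0.180, estimated distance = 42506 m
true distance = 42426 m, relative error = -0.002
```

The two locations are 42.4 km apart; each pseudonym is a set of ~550
opaque labels; their 18% Dice overlap, pushed through the lens-area
inversion, recovers the distance to 80 m (0.2%) — without either party
revealing a coordinate. The same steps are available from the shell as
`isgp make-grid`, `isgp encode` and `isgp distance` (plus `isgp simulate`
for the error study); run each with `--help`.

Accuracy is governed by the grid spacing h (cell area h² is the
quantization unit of the area estimate) and by r: the per-miscounted-cell
distance error is h²/√(4r² − d²), so errors grow for d near 0 and near the
censoring horizon 2r. Regular lattices give lower error than random grids
of equal density, whose per-circle counts carry binomial noise.

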