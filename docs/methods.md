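# Methods

This note records the models implemented, the conventions the numbers
depend on, and the design choices made where the literature leaves the
definition open.

## Data model

All coordinates are planar/projected (e.g. UTM metres); distances are
Euclidean throughout. No CRS handling or geodesic support is provided. The
observation window is a simple polygon; its area |T| is the shoelace area,
and point-in-polygon tests count the boundary as inside so that no
observation is silently lost.

Rasters store categorical (or, for covariates, continuous) values with a
boolean NODATA mask; masked cells are never read by any statistic, so
padding a grid with NODATA rows changes nothing. Row 0 is the southernmost
row and the centroid of cell (r, c) is (x0 + (c+0.5)·dx, y0 + (r+0.5)·dy).
Cells are half-open [x_lo, x_hi) × [y_lo, y_hi): a point on a shared edge
belongs to the cell with the larger index, and points on the outermost
east/north edge are clamped into the last cell. File I/O uses ESRI ASCII
grids; rectangular cells are supported by a documented dialect that
replaces the `cellsize` header line with `dx` and `dy` lines (the writer
emits it only when dx ≠ dy).

Pixellation of a point pattern covers the window's bounding box, labels a
cell 1 when at least one point falls in it (multiplicities collapse to
presence), and masks cells whose centroid lies outside the polygon. Points
landing in such masked boundary cells are not represented in the raster;
this is inherent to centroid-based masking and is one of the ways the
discretised data lose information relative to the points.

## Entropy measures

All entropies use natural logarithms (nats) and plug-in probabilities
(relative frequencies), with the continuity convention 0·ln(1/0) = 0.
Model-based probability estimators and bias corrections are out of scope.

**Shannon.** H(X) = Σ p(xᵢ) ln 1/p(xᵢ), range [0, ln I], relative H/ln I.
When only one category is observed the range degenerates to [0, 0] and the
relative value is defined as 1 (the value trivially attains its maximum).

**Batty.** H_B = Σ_g p_g ln(T_g/p_g) over a partition into G sub-areas;
empty sub-areas contribute zero terms but stay in the component table. The
range is [ln T_g*, ln |T|] (g* the smallest sub-area). When some T_g ≤ 1 in
working units the logarithms change sign; sizes are multiplied by the
smallest power of ten c with min T_g·c > 1, the entropy computed, and ln c
subtracted, which recovers the original-unit value exactly (this identity is
tested). The *relative* value is H_B/ln|T|; this reproduces the published
relative values from the published frequencies and sizes, unlike the
range-anchored form (H_B − ln T_g*)/(ln|T| − ln T_g*), which does not. When
the rescale triggers, the relative value is computed in the rescaled units,
(H_B + ln c)/ln(c|T|) — the only normalisation that is both defined and in
[0, 1] for sub-unit areas; it coincides with H_B/ln|T| whenever c = 1.
Working units default to the coordinate unit squared (metres → m²).

**Batty-LISA.** p̃_g aggregates the probabilities of sub-area g and its
`neigh` nearest sub-areas by centroid distance (ties broken by lower id;
self always included; `neigh` counts neighbours beyond self). Two schemes
are exposed because the literature does not pin the convention down:
"average" (row-standardised weights, the default) and "sum". The default is
"average" because it alone drives the entropy to exactly ln G under full
smoothing (neigh = G−1), matching the measure's described behaviour; with
neigh = 0 both schemes reduce exactly to Shannon's entropy of {p_g}. The
conventional range [0, ln G] is reported, but it is not a theorem under the
average scheme: for intermediate neighbourhoods the smoothed masses need
not sum to one, so H can exceed ln G slightly, and it is not monotone in
`neigh` in general (a three-sub-area counterexample: collinear centroids
0, 1, 2 with p = (0.2, 0.6, 0.2) give H(neigh=1) < H(neigh=0)). Published
LISA values are therefore treated as convention-dependent and not used as
reference values.

**O'Neill / contagion / Parresol–Edwards.** Ordered couples of rook-adjacent
valid cells are enumerated exactly once by scanning each cell's east and
north neighbour. H_O is the Shannon entropy of the couple frequencies,
range [0, ln I²]; relative contagion is 1 − H_O/ln I²; Parresol–Edwards is
−H_O with the same relative form as O'Neill's. The identities (contagion +
relative O'Neill = 1, PE = −O'Neill) hold exactly by construction and are
asserted in tests.

**Leibovici.** Couples are unordered pairs of observations within distance
d, *inclusive* (≤ d), so that on a square-cell grid d = cell size reproduces
the contiguity pair multiset (diagonal neighbours sit at d·√2). Each pair is
counted once, ordered by the canonical coordinate order (ascending x, then
y, then input order). Double counting both directions is deliberately
avoided: published point-data couple tables show maj-min ≠ min-maj, which is
impossible under symmetric double counting, so the single-visit enumeration
with a deterministic order is the reproducible choice. A `symmetrise` flag
splits mixed ordered counts equally between the two directions when the
symmetric convention is wanted; it preserves the pair total. Grid distances
are centroid-to-centroid in physical units. Pair search uses a k-d tree; the
output is defined (and tested against) the O(n²) brute-force enumeration.

**Decomposable entropy.** Z is built from *unordered* category pairs (I(I+1)/2
of them — co-occurrences have no direction in space, which also removes the
ordering ambiguity above); W has K distance classes (b_{k−1}, b_k] covering
(0, ∞), half-open so a pair at exactly a break belongs to the lower class;
coincident observations (distance 0) fall in the first class. All pairs of
observations enter (no cutoff), enumerated blockwise in O(n²) but identical
to the definition. PI(Z|w_k) is a Kullback–Leibler divergence, hence ≥ 0,
and H(Z) = Σ_k p(w_k)[PI(Z|w_k) + H(Z|w_k)] holds to machine precision on
every input; both facts are tested, along with the data-processing
inequality (merging classes never increases MI) and a brute-force oracle.
Default classes: on square-cell grids, breaks (0, c], (c, 2c], (2c, ∞) — the
4 rook neighbours, then the next 12 cells (diagonals c√2 and axials 2c),
then the residual; rectangular cells have no sensible default and the user
must supply breaks. On points, breaks at the deciles of the nearest-
neighbour distance distribution (starting at 0, residual class to ∞),
deduplicated to a 1e−9 relative tolerance. Empty classes are dropped from
the weighted sums with a warning (their weight is zero regardless).

## Partitions

Random Voronoi partitions draw G generators uniformly in the polygon by
seeded rejection sampling from the bounding box (PCG64 streams via NumPy's
`default_rng`/`SeedSequence`), resample generators closer than 1e−9 of the
bbox diagonal, tessellate with GEOS and clip to the window; sub-area sizes
then sum to |T| to rounding. Point assignment is by nearest generator with
ties broken by the lowest sub-area id. Covariate partitions cut valid cells
at empirical type-7 (linear-interpolation) quantiles, left-open right-closed
with the lowest class closed at the minimum; a covariate with fewer distinct
values than classes is an error naming the covariate. Raster-class
partitions make one sub-area per observed category, sized by cell count ×
cell area, with the centroid at the mean of member cell centroids. Sizes of
raster-derived partitions are computed from the supplied grid; when that
grid covers more than the analysis window (e.g. covariates over the
enclosing rectangle) the class sizes can exceed |T|, and the package reports
what the geometry implies rather than reconciling the two.

## Synthetic data

The generators are pure functions of (configuration, seed). CSR (uniform
points, optionally with independent categorical marks) is the null model:
under it, sub-area mass tracks area (relative Batty ≈ 1), couples are
near-uniform (relative Leibovici ≈ 1), and MI ≈ 0 up to O(K·R/n²) plug-in
bias. The cluster generator is Thomas-like — uniform parents, Poisson
offspring counts, isotropic Gaussian displacement, offspring outside the
window discarded — with marks either independent or inherited from the
parent; inheritance plants genuine short-range category association that
the distance-based measures must detect. Autocorrelated rasters threshold a
Gaussian-smoothed noise field at the empirical (1 − p1) quantile, giving
marginal presence frequency ≈ p1 and contagion increasing with the
smoothing radius; at smoothing 0 the couple probabilities factorise and
contagion matches its closed-form independent-cells value. None of these
emulate inhomogeneous intensity driven by covariates, irregular sampling
effort, or mark-location dependence beyond parent inheritance, so passing
tests establish the measures' arithmetic and null behaviour, not their
field performance on such data.

## Study sizes and numerics

The resolution-sensitivity study pixellates a pattern at each requested
resolution and reports occupied cells, occupied fraction, and the relative
measures. Tests and the examples use 500-point CSR fixtures and resolutions
10–200 (40,000 cells at the finest), enough to show the characteristic
behaviour — occupied fraction and all couple-based relative entropies decay
toward 0 and contagion rises toward 1 as cells outnumber points — while
each run stays in the sub-second range. In the sensitivity table a
degenerate resolution (all valid cells in one category) reports 0 for the
entropy columns and 1 for contagion, the limits the decay converges to,
rather than the standalone single-category convention (relative := 1). The random-partition study uses
spawned child seeds per (G, replicate), so results are reproducible and
independent of the order of evaluation; percentile intervals are empirical
(2.5, 97.5). The randomisation null for MI uses 20 replicates of 500 marked
CSR points. O(n²) pair enumeration is blocked at 512 rows per chunk; all
accumulations are exact integer counts, and entropy sums drop exact-zero
probabilities rather than adding epsilons.

## Known limitations

- Only rook contiguity and Euclidean distance rules; no queen contiguity,
  polygon-adjacency neighbourhoods, or toroidal edge correction.
- Co-occurrence sets are pairs only (no triples or larger m-sets).
- Relative frequencies are the only probability estimator.
- The LISA range/monotonicity caveats above; published LISA values are
  convention-dependent.
- GeoTIFF and shapefile I/O are not supported; rasters travel as ESRI ASCII
  text, geometries as WKT/GeoJSON.
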