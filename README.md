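# spatentropy

Spatial entropy and diversity measures for marked point patterns and
categorical rasters.

Classical Shannon entropy, H(X) = Σᵢ p(xᵢ) ln 1/p(xᵢ), measures the
diversity of a categorical variable but is blind to *where* the outcomes
occur: rearranging observations in space leaves it unchanged. Ecologists,
epidemiologists and spatial statisticians therefore use a family of spatial
entropy indices that fold location into the measure. This package implements
that family for planar point patterns (optionally carrying categorical
marks, e.g. species or group size) observed in a polygonal window, and for
categorical grids with a NODATA mask:

- **Shannon's entropy** on marks or raster categories, with relative form
  H/ln I and frequency tables;
- **Batty's entropy** over a partition of the window into G sub-areas of
  sizes T_g: H_B = Σ_g p_g ln(T_g/p_g), maximal (ln|T|) when the intensity
  λ_g = p_g/T_g is constant, with automatic power-of-ten rescaling when
  sub-areas are smaller than one working unit;
- **Batty-LISA entropy** (Karlström–Ceccato): H = Σ_g p_g ln(1/p̃_g), the
  neighbourhood-smoothed variant, with configurable neighbourhood size and
  averaging scheme;
- **O'Neill's entropy** on the I² ordered couples of rook-adjacent grid
  cells, plus the **relative contagion index** (1 − H_O/ln I²) and
  **Parresol–Edwards entropy** (−H_O);
- **Leibovici's entropy** on couples of observations within a chosen
  distance d, for both points and grids;
- the **decomposable entropy**: with Z the unordered-pair category variable
  and W a distance-class variable, H(Z) = MI(Z,W) + H(Z)_W splits pair
  diversity exactly into spatial mutual information and residual entropy,
  with per-distance-class partial terms.

Supporting machinery: window/point/raster I/O (CSV, WKT/GeoJSON, ESRI ASCII
grids with a rectangular-cell dx/dy extension), pixellation of point
patterns, partition builders (random Voronoi, covariate quantiles, raster
classes, user GeoJSON), distance summaries, seeded synthetic generators
(CSR, Thomas-type clusters, autocorrelated rasters), and the two sensitivity
studies practitioners run: grid-resolution sweeps and random-partition
replication.

## Worked example

```python
import spatentropy as se

win = se.ObservationWindow.from_vertices([(0, 0), (1000, 0), (1000, 800), (0, 800)])
pattern = se.generate_clustered(win, parents=25, offspring_mean=20, spread=30,
                                seed=42, mark_probs={"oak": 0.6, "pine": 0.4},
                                inherit_marks=True)

print(se.shannon_entropy(se.tabulate(pattern)))
print(se.leibovici_entropy(pattern, d=100.0))
part = se.voronoi_partition(win, G=10, seed=42)
print(se.batty_entropy(pattern, part))
print(se.batty_lisa(pattern, part, neigh=1))
dec = se.altieri_decomposition(pattern)
print(f"H(Z) = {dec.H_Z:.3f} nats, MI = {dec.MI:.3f}, residual = {dec.residual:.3f}")
```

prints

```
shannon: 0.59 nats (range [0.00, 0.69], relative 0.85)
leibovici: 0.87 nats (range [0.00, 1.39], relative 0.63)
batty: 13.55 nats (range [10.37, 13.59], relative 1.00)
batty_lisa: 2.22 nats (range [0.00, 2.30], relative 0.96)
H(Z) = 0.901 nats, MI = 0.003, residual = 0.898
```

Reading the numbers: the marks are fairly diverse overall (relative Shannon
0.85), but because offspring inherit their parent's mark, couples within
100 m are much more homogeneous than the marginal frequencies suggest —
Leibovici's relative entropy drops to 0.63. The point *locations* are spread
almost uniformly across a random 10-cell Voronoi partition (relative Batty
≈ 1.00), so the clustering acts on marks, not on overall intensity at that
scale. The decomposition confirms it: most pairs are long-range, so global
MI is small, but `se.decomposition_profile(dec)` shows the spatial share
exceeding 0.5 in the shortest distance classes.

The same analyses run from the shell:

```sh
spatentropy simulate clustered --parents 25 --spread 30 --seed 42 --out sim/
spatentropy batty --points sim/points.csv --window sim/window.wkt --g 10 --seed 42 --out run/
spatentropy leibovici --raster grid.asc --distance 100 --out run/
spatentropy altieri --points sim/points.csv --window sim/window.wkt --mark mark --out run/
```

Every run writes `result.json` (12 significant digits), the frequency table
as CSV, a resolved configuration and a log into the output directory.

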