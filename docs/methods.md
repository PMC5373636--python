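# Methods

`gridscape` analyses the racial makeup of a region as a *diversity
landscape*: a high-resolution categorical raster in which every cell is
either uninhabited or belongs to one of 39 communities defined by
diversity, dominant group, and population density.  This note documents
the models, the parameter choices, and the limits of what the test suite
demonstrates.

## Raster model and units

Grids are row-major with the (0, 0) cell at the upper-left corner; a cell
is identified by its centre in every distance computation.  The canonical
storage unit is people per cell (as in downloadable census grid products);
people/km² is derived on demand as `count × 10⁶ / cell_size_m²`.  The
default cell size is 30 m.  `nodata` marks cells outside the study area
and is distinct from a zero count: both classify as uninhabited, but
nodata cells are excluded from every landscape area and edge tally.

GeoTIFF output is single-band (int32 categorical, float64 counts),
uncompressed, carrying georeferencing in the standard ModelPixelScale /
ModelTiepoint / GDAL_NODATA / GeoAsciiParams tags; legends travel in a
`<file>.legend.json` side-car.  Reprojection and resampling are out of
scope: all inputs to a run must already share one grid geometry
(`assert_aligned` enforces this).

## Dasymetric disaggregation

Census counts come aggregated to irregular zones; a categorical
land-cover raster (urban / vegetation / uninhabited, or any legend with a
declared uninhabited class) serves as ancillary data correlated with
density.  The model:

1. **Weights.** One relative density weight per land-cover class,
   `w_class ≥ 0` in people/cell, fitted by non-negative least squares of
   zone totals on the zone-by-class cell-count matrix
   (`scipy.optimize.nnls`).  The uninhabited class is pinned to 0.  NNLS
   is the simplest estimator consistent with a monotone class → density
   relation; richer regression models on multi-class land-cover/land-use
   stacks exist, but the downstream pipeline only consumes relative
   within-zone weights, so any weight table proportional to the truth is
   sufficient.
2. **Totals.** Within zone *z* each cell receives
   `T_z · w(c) / Σ_{c'∈z} w(c')`.  Per-zone grid sums reproduce the
   census totals exactly (the pycnophylactic property); the ≲1e-9
   floating-point residual of each zone is folded into its
   heaviest-weighted cell.  A populated zone whose cells all carry zero
   weight is spread uniformly with a warning — this preserves counts at
   the price of placing people on nominally uninhabited land, and it is
   logged precisely because it signals a weight table that disagrees
   with the zone table.
3. **Sub-populations.** Each group reuses the total-population weight
   grid: group proportions are constant within a zone.  The grids
   therefore locate sub-populations away from uninhabited land and scale
   them with overall density, but deliberately do not model sub-zone
   mixing gradients.

## Community classification

Per cell, six group densities (NHW, NHB, NHAS+NHPI, NHAM, NHO, H —
Asians and Pacific Islanders merged for 1990 compatibility) yield:

* standardized entropy `E = −Σ pᵢ ln pᵢ / ln 6` of the shares
  (`0·ln 0 = 0`), so `E ∈ [0, 1]`, base-invariant, scale-invariant;
* the dominant group (argmax density; ties go to the first group in the
  fixed order — deterministic, and practically irrelevant on real-valued
  densities);
* diversity: **low** iff `E < 0.37` and dominant share `> 80%`;
  **high** iff `E > 0.73` and share `< 50%`; else **medium**.  All four
  inequalities are strict: a cell sitting exactly on a threshold is
  medium;
* density class of the total (people/km²): **low** `< 3`, **medium**
  `3–30` inclusive, **high** `> 30`.

Zero total ⇒ code 0 (uninhabited).  Otherwise the label is one of
(6 groups × {low, medium} + high-diversity) × 3 density classes = 39.
Code numbering is ours (the published grid product's numeric encoding is
not documented): codes 1–13 low density, 14–26 medium, 27–39 high, each
block ordered NHW-low, NHW-medium, NHB-low, …, H-medium, high-diversity;
`(code − 1) mod 13 + 1` is the density-collapsed code.  The shipped
colour table (hue by dominant group, saturation by diversity, lightness
by density) is a convenience, not a fidelity target.

## Landscape metrics

Patches are maximal connected components of equal-code cells;
8-connectivity is the default (4 by flag).  The landscape area `A` is
the inhabited area only, and edges between a community and background
(uninhabited or nodata) are excluded from all edge tallies — LPI and
PLAND are read against the *populated* area of a site.

Definitions follow the standard FRAGSTATS formulations: like-adjacencies
are single-count with the maximum from the largest-square construction
(`n = ⌊√a⌋`, `m = a − n²`: `2n(n−1)` if `m = 0`; `+2m−1` if `m ≤ n`;
`+2m−2` otherwise); CONTAG uses double-count adjacency proportions;
GYRATE is the mean centroid-to-cell-centre distance; ENN the minimum
cell-centre distance between a patch and its nearest same-class patch.
Areas are hectares (100 ha = 1 km²), distances metres.  Undefined values
are NaN, never 0: ENN for a single-patch class, AI for a single-cell
class (such classes are skipped in the area-weighted landscape AI with
weights still `aᵢ/A`), IJI below three classes, CONTAG rows with no
tallied adjacencies are skipped.  A single-class landscape has
CONTAG = 100 and SHEI defined as 0.

TECI needs a class-by-class dissimilarity matrix `d_ik ∈ [0, 1]`, which
is an analyst judgement.  The shipped default grades contrast by label
structure: different dominant groups start at 1 for two low-diversity
communities and decrease by 0.25 per diversity level on either side
(diversity indexed low = 0, medium = 1, high = 2, the high-diversity
category counting as its own "dominant"); a shared dominant group
contributes 0.15 per diversity step; a density-class gap adds 0.05 per
step; values clip to [0, 1].  Any other matrix can be supplied as CSV.

Every metric is cross-checked against an independent brute-force oracle
(flood fill, exhaustive pair enumeration, direct formulas, in
`tests/_oracle.py`) to 1e-9 on hundreds of random small rasters — the
two routes share no code.

## Segregation indices

From a unit table (aggregated from the grids over any areal partition):
`D = ½ Σ_j |x_j/X − y_j/Y|` with *y* = everyone else (a two-group
reference variant is available), `I = Σ_j (x_j/X)(x_j/t_j)`, and the
multigroup Theil index `H = Σ_j t_j (E_tot − E_j) / (E_tot T)` with
natural-log entropies over the six merged groups (standardization
cancels).  Zero-population units are dropped with a logged count.

## Temporal change

Transition matrices cross-tabulate the 40 labels cell-by-cell between
two years; nodata tallies as code 0, so coverage changes appear as
inhabited↔uninhabited transitions, which are real signal.  The people
matrix weights cells by a population raster — year-1 population by
default (who lived under the old label); pass the year-2 raster to count
arrivals instead.  Percent changes are `100(new − old)/old` rounded to
the nearest integer, halves away from zero, undefined (NaN) for a zero
base.

## Synthetic scenarios

The generator emulates the pipeline's real inputs with known ground
truth.  Land cover is a smoothed Gaussian random field split at the
quantiles of the requested class fractions (default 30% urban, 50%
vegetation, 20% uninhabited).  Zones grow by multi-source BFS from
random seeds, guaranteeing 4-connected, non-empty zones.  Population
surfaces are Gaussian clusters centred on urban cells with default peak
densities of 5000 (NHW), 3000 (NHB), 2500 (H), 1500 (NHAS), 300 (NHAM),
200 (NHO), 100 (NHPI) people/km² — urban-census-like magnitudes — at
full strength on urban cells, 0.15× on vegetation, zero on uninhabited
land (the vegetation attenuation keeps the weight fit a genuine
two-class problem).  Zone tables are aggregated exactly from the truth.
One `numpy.random.default_rng(seed)` per product with a fixed draw order
makes every fixture bit-reproducible.

`make_proportional_scenario` builds the analytically solvable case —
cell totals equal to the class weights (urban 5, vegetation 1 people per
cell), Dirichlet group shares constant per zone — where NNLS must
recover the weights and disaggregation the full truth exactly.

What the synthetic fixtures do **not** emulate: spatial autocorrelation
of group shares across zone boundaries, census integer rounding and
disclosure noise, zone-size heterogeneity between urban and rural
tracts, and multi-year land-cover change.  Passing tests therefore
demonstrate the correctness of the arithmetic and the conservation
properties, not the real-world accuracy of dasymetric population
placement, which depends on the quality of the ancillary data.

## Problem sizes and numerical choices

The default verification runs use 200×200 grids with 60 zones for the
dasymetric checks, 120×120 for the pipeline classification, and 200
random rasters up to 8×8 with up to 4 classes for the metric-oracle
equivalence — sizes at which the brute-force oracle is exact and fast
while exercising every code path.  Conservation tolerances are 1e-9
relative (observed: ~1e-14); oracle agreement is asserted at 1e-9
absolute (observed: ~4e-14).  ENN uses exact per-patch KD-tree queries;
for very large maps with many patches this is the dominant cost and a
raster-distance-transform approximation would be the natural extension.

## Known limitations

* Headline published metric values for a real metropolitan area are not
  reproducible without the corresponding census grid downloads; the
  suite verifies the arithmetic (e.g. the percent-change series) and the
  metric definitions against an oracle instead.
* No reprojection; zone polygons must be rasterized to the analysis grid
  upstream.
* The classifier's thresholds are configurable but the 39-label taxonomy
  shape (6 groups, 3 diversity, 3 density classes) is fixed.
* Shape/contrast metrics beyond the implemented set (PARA, SHAPE, FRAC,
  CONTIG, DIVISION, CONNECT, PROX, CWED) are not provided.
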