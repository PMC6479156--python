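# Methods

`oceub` maps areas of high biodiversity relevance from point occurrence
records and phylogenies. It optimizes, inside biogeographic regions of
unique biota, a weighted combination of four biodiversity surfaces and a
quantization threshold, trading captured biodiversity against selected
area, and it models sampling effort explicitly so that poorly known areas
are reported as such rather than as low priority. This note documents the
model, its assumptions, the tunable parameters, and the numerical choices
that are not forced by the method itself.

## Spatial scaffold

All analyses run on a grid of flat-top hexagonal cells laid out in WGS84
lon/lat, with the across-flats width equal to `cell_size_deg` (default 1°).
Hexagons are the Voronoi cells of their centers, so point binning is
nearest-center assignment with an explicit tie rule (a point on a shared
edge goes to the lower cell id). The grid overhangs the requested extent by
one ring so every interior point lies in exactly one cell. Cells are built
in geographic, not projected, space; distances in km use great-circle
(haversine) arithmetic, and the kriging/kernel machinery uses a local
equirectangular projection, adequate at subcontinental extents. Duplicate
records are kept: they carry sampling-effort information, and the richness
resampling neutralizes them for diversity estimates.

## Biodiversity surfaces

* **Weighted endemism (WE).** Each species gets weight `1 / (number of
  occupied cells)`; a cell's endemicity is the sum over present species.
  "Distribution area" is operationalized as occupied cell count, which makes
  the conservation identity Σ_cells WE = S exact and testable.
* **Phylogenetic weighted endemism (PWE).** The branch-level analogue: each
  branch of a cell's minimal root-inclusive subtree contributes
  `L_b / R_b`, with `R_b` the number of cells where the branch occurs (≥ 1
  descendant tip present). Σ_cells PWE equals the total represented branch
  length exactly. Branch "occurrence area" is counted in cells, consistent
  with the analysis unit.
* **Resampled species richness.** Naive per-cell species counts track
  collecting effort more than diversity. Instead, per cell and repetition:
  draw `n_per_sample` records (default 50) *with replacement* from the
  cell's record pool, keep `floor(50 · 0.25) = 12` of them without
  replacement, count distinct species; the estimate is the mean over
  `reps` (default 1000) repetitions. Drawing with replacement lets cells
  with fewer than 50 records participate (a bootstrap of the empirical
  species distribution) rather than being dropped, which would empty most
  cells in sparse data; the estimate is invariant in distribution to record
  duplication. Cells with zero records are no-data.
* **Areas of endemism (GIE).** Species are classified into nine range-size
  classes by the distance from their occurrence centroid to the farthest
  occurrence (upper edges 50, 200, 400, 600, 800, 1000, 1500, 2000,
  3299 km; larger ranges are classed 9 with a warning). Per class, an
  Epanechnikov kernel surface of the class's species centroids is computed
  with kernel radius equal to the class's upper edge, floored at one cell
  width because a radius below the grid's resolving power would miss every
  cell center. Class surfaces are combined with weight `1/edge_k`, so
  narrow-ranged species dominate, and the consensus is min-max rescaled to
  [0, 1]. The kernel form and combination rule are this package's
  documented choices, validated by planted-hotspot recovery rather than by
  fidelity to any particular prior implementation.
* **Redundancy screen.** Pairwise Pearson correlations between candidate
  surfaces with effective sample sizes corrected for spatial
  autocorrelation (Clifford–Richardson/Dutilleul style: `n_eff = 1 + n² /
  tr(R_x R_y)` with correlation matrices estimated from binned
  correlograms). Pairs with `|r|` above 0.7 are flagged for manual drop —
  the screen reports, it does not delete.

## Interpolation and effort

Quantitative surfaces (richness, WE, PWE) are observed only in occupied
cells and are interpolated to the full grid by **ordinary kriging with
bootstrap variogram refits**: the semivariogram model (exponential by
default) is fitted by weighted least squares to the empirical
semivariogram, then refitted on `n_subsets` (default 20) random sample
subsets; the per-cell mean over refits is the prediction and the spread
estimates variogram-parameter uncertainty. This reproduces the rationale
of empirical Bayesian kriging — parameter uncertainty via subsetting and
bootstrap — with fully documented internals. With a zero nugget the
interpolator is exact at sample locations; duplicate sample locations are
jittered (logged) to keep the system nonsingular.

Sampling effort is the quartic-kernel density of all geographically valid
records, reported as expected record count per cell. The default bandwidth
is the spatial variant of Silverman's rule,
`0.9 · min(SD, sqrt(1/ln 2) · D_m) · n^{-0.2}` (SD the standard distance,
D_m the median distance to the mean center), floored at one cell width for
the same quadrature reason as above.

## Regionalization

Cell assemblages are compared by Sørensen dissimilarity (species
composition) and PhyloSor dissimilarity (phylogenetic composition; shared
branch length over mean assemblage PD, which reduces exactly to Sørensen
on a star tree). Cells under `min_records` (default 5) are excluded from
the dissimilarity stage and filled by interpolation instead. Each matrix
is ordinated by non-metric MDS (SMACOF majorization with isotonic
regression; Kruskal stress-1; best of `nmds_rounds` random restarts, 20 by
default in the pipeline and configurable up to many thousands; labels at
zero dissimilarity are collapsed and share coordinates). The default
ordination dimensionality is 3 per matrix. Each axis is kriged to the full
grid, and the resulting composition vector per cell is classified by an
EM-fitted Gaussian mixture with maximum-posterior assignment — the
unsupervised form of maximum-likelihood classification. `k` can be fixed
or chosen by BIC over a configurable range (default 2–12 in the library,
2–8 in the pipeline); labels are canonicalized by descending region size.
No spatial smoothing is applied by default; a single-pass hex-neighborhood
majority filter is available behind a flag.

## Prioritization and the genetic algorithm

Within each region the four variable surfaces are min-max rescaled to
[0, 1] (a constant region rescales to zeros, with a warning), summed with
weights `(w_richness, w_endemism, w_aoe, w_pe)`, rescaled to [0, 1]
globally — so the threshold allele means the same thing for every weight
vector — and cut at the threshold to give the binary relevance map. The
fitness of the resulting selection is

    (r + pl + e + pe) / 4 − a / A

where all four capture terms are fractions of grid-wide totals: `r` the
fraction of species with at least one selected occupied cell, `pl` the
captured fraction of total branch length, `e` the captured fraction of
total WE weight, `pe` of total PWE weight, and `a/A` the selected fraction
of cells. Reading the terms as captured fractions is what makes a value
near 1 attainable and the select-all selection score exactly 0. Endemism
capture is species-level (a species' full weight counts once any of its
cells is selected) by default; a `cell_sum` mode that sums the per-cell
surfaces over the selection is available behind a flag.

The GA searches `[0,1]^5` (four weights + threshold). Population 20, with
individual 0 the primeval genome (0.5, …, 0.5) and the rest uniform; per
generation the top `elite_fraction` (0.25) are kept plus a
`random_pick_fraction` (0.15) random sample of the remainder, and the
population is refilled by uniform crossover (rate 0.9) of random selected
parents followed by per-allele Gaussian mutation (probability 0.2,
sd 0.1, clipped to bounds). Elitism guarantees a nondecreasing best
fitness. Termination at 100 generations or after 15 stalled generations.
The operator fractions and mutation kernel are this package's defaults —
config-exposed, chosen to balance exploration against the 2,000-evaluation
budget of a default run.

Experiment modes: `all_groups` (everything), `surrogate:<group>` (surfaces
and regionalization from one taxonomic group only), and `no_phylo`
(phylogenetic composition dropped from regionalization, phylogenetic
endemism dropped from the weighted sum). Whatever the mode, fitness is
always scored against all groups and all four dimensions, so surrogate and
phylogeny-free models are judged on what they fail to capture.

## Supertree and phylogenetic conventions

Source trees are merged by matrix representation with parsimony: every
non-trivial clade of every source tree becomes a binary character (taxa
absent from that tree scored `?`), and the supertree is the tree of
minimum Fitch parsimony length found by random-addition stepwise insertion
plus NNI hill climbing with restarts (exhaustive search is used only as a
test oracle at ≤ 6 taxa). Branch lengths from digitized trees are not
comparable, so all branches are set to exactly 1. PD uses the
tip-to-root-inclusive convention, which makes PD of a single tip its
depth, keeps the PWE conservation identity exact, and leaves PhyloSor
defined for single-species assemblages; the root has no parent edge, so no
root-edge length is ever counted. Species present in the occurrence data
but absent from the tree are excluded from phylogenetic metrics with a
logged count.

## Categorization

Cells whose kernel effort falls below a quantile (default 0.5) of the
positive-effort distribution — or an absolute cutoff — are *insufficiently
sampled*, and insufficiency always overrides modelled relevance: the final
categories are high-relevance-sampled, low-relevance-sampled, and
insufficient-information. An optional vegetation-remnant mask is stamped
as a sub-flag (remnant/cleared) without changing the main category, which
keeps the three-way core auditable. Summaries report per-zone percentages
that partition to 100%.

## Synthetic landscape

The generator plants the structure the pipeline assumes, with defaults
that define the package's reference study conditions: 3 contiguous regions
(vertical strips of an 18° × 12° extent at 1° cells, 360 cells), 50
species per region of which 30% are narrow-ranged endemics (disc radii
25–140 km, range-size classes 1–2) co-centered at one planted hotspot per
region, the rest wide-ranged (250–500 km) around the region core; a
phylogeny with one clade per region (so phylogenetic composition carries a
regional signal); and a smooth west–east accessibility gradient
(0.15–1.0) as the effort field. Sampling draws species proportional to
range area, locations uniform in the disc, and thins records by
`effort^bias`; the reference biased condition uses 20,000 records at
`bias = 2`. Disc ranges keep every expectation available in closed form;
the generator makes no attempt at niche realism, temporal structure, or
taxonomic error, so passing tests demonstrate correct mechanics and
recovery of planted structure, not performance on real collections data.
Truth layers recorded per landscape: region labels, the per-region peak
endemism cell, per-species ranges, the effort field, and the tree.

The end-to-end harness runs the full pipeline on a sampled landscape (with
the planted region count supplied as the classifier's `k`, standing in for
an external class-number selection step) and scores: adjusted Rand index
of recovered vs planted regions, the fraction of planted hotspot peak
cells inside the optimized high-relevance area, the optimized coverage
fractions, and the effort correlation of the resampled vs naive richness
surfaces. At the reference conditions the optimized model captures ≈ 99%
of species and endemism weight in 2–4% of cells and the resampled
richness correlates less with the planted effort field than the naive
count does; `scripts/acceptance.py` recomputes these quantities for any
seed.

## Numerical details and limitations

* Ties: point-on-edge → lower cell id; equal GA fitness → stable rank
  order; equal BIC → smaller k.
* Degenerate inputs: constant kriging samples return a constant surface;
  all-coincident kernel points fall back to a one-cell bandwidth (warned);
  constant regions rescale to zeros (warned); zero-dissimilarity NMDS
  inputs are an error, zero-dissimilarity *pairs* are collapsed.
* Kriging is planar and stationary; no geodesic kriging on the sphere.
* The effort-sufficiency cutoff is a quantile rule with a config override;
  there is no calibration of "sufficient" against external inventories.
* Richness resampling assumes within-cell records are an exchangeable
  sample of the cell's community; strong within-cell spatial clustering
  violates this and is not modelled.
* Problem sizes in the shipped tests and the acceptance script (360 cells,
  150 species, 20,000 records, 20 NMDS restarts) are the package's desk
  reference scale; every size is config-exposed and scales up unchanged.
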