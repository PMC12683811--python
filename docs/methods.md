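# Methods

This note records the model, the numerical choices, and the limits of what
the test suite demonstrates.  It is written for a maintainer deciding
whether a behavior is a contract or an accident.

## Bin-to-cell aggregation

The aggregation stage assumes segmented nucleus contours (simple polygons,
µm coordinates, image convention: origin top-left, y downward) and a grid
of square capture bins with half-open extents `[col·s, (col+1)·s) ×
[row·s, (row+1)·s)` (side `s` = 2 µm by default), so adjacent bins never
share a point.

*Nucleus size filter.* Log areas (natural log) above
`mean + 2·sd` are removed, with the sample (n−1) standard deviation and a
strict comparison, so a zero-variance population is never filtered and a
single extreme nucleus inflates its own cutoff.  Fewer than two nuclei
pass through unfiltered.

*Overlap estimator.* Square/nucleus overlap is approximated by splitting
the square into a `g × g` grid (default `g = 10`, i.e. 100 subsquares) and
counting subsquare centers covered by the polygon, boundary included.
`count/g²` converges to the exact intersection-area fraction; the suite
checks a mean absolute deviation < 0.01 against exact shapely clipping at
`g = 100`, and ≥ 99% assignment agreement with the exact-area argmax at
the default `g = 10` on separated layouts.

*Assignment.* Pass 1 assigns each bin with positive overlap to the
argmax-overlap nucleus; pass 2 repeats for leftover bins against the
expanded nuclei (similarity scaling about the centroid by `√r`, default
`r = 2`, so expanded area is exactly `r` × nucleus area).  Overlap ties
break toward the smaller nucleus id — the paper-level procedure does not
specify a tie rule, and a total order is required for byte-identical
reruns.  Bins overlapping nothing are dropped and counted in the log; no
ambient pool is modeled.

*Abnormal cells.* A cell is removed when (a) no bin reached it in pass 1,
(b) its assigned-bin area (`s²` per bin, both passes) is below half the
cell area, or (c) its bins are not one 4-connected lattice component.
"Cell area" in (b) defaults to the expanded area `r·A_nucleus` because
bins are collected up to the expanded boundary; `coverage_basis="nucleus"`
switches to the bare nucleus area.  Connectivity uses shared edges only;
diagonal contact does not connect.

## Preprocessing

Cells need positive counts in ≥ 300 genes (configurable; scale it down for
small synthetic panels — see below), then genes need positive counts in
≥ 1% of retained cells.  Log-normalization is `ln(1 + count/total ×
10,000)`.  Clustering: top-2,000 variable genes (variance-stabilizing
ranking), per-gene scaling clipped at 10, top-10 PCs, a 20-nearest-neighbor
graph, and Leiden community detection at resolution 1.2.  The PCA is a
deterministic arpack partial SVD so identical inputs give identical
embeddings; the only seed-sensitive step is Leiden, which is exactly the
property the significance stage exploits: `cluster_cells(seed)` is
reproducible, and `recluster(seed')` re-runs only the community detection
on the cached graph.

*Isolation filter.* Per cluster, each cell's isolation score is its mean
Euclidean distance to its `k` nearest cluster mates,
`k = clamp(ceil(0.01·n), 10, 50)` further capped at `n − 1` (ceil chosen
for the "1% nearest" reading; tiny clusters stay defined).  Cells above
`mean + 6·sd` of the scores are excluded from spatial fitting.  Six sigma
is deliberately lax: on uniform clusters it removes essentially nothing
(the suite tolerates < 0.1% removals over 100 uniform clusters — scores
are right-skewed, so a literal "never" is not exactly true), while a cell
displaced far from its cluster is always caught.

## Spatial spline model

Within cluster `c` with expression `Y` (m genes × n cells) and coordinates
`S` (n × 2), every gene is regressed on an intercept, the per-dimension
cubic B-spline bases, and all pairwise products of the two bases.  With
`K` equidistant internal knots strictly between the per-cluster coordinate
min and max (boundary knots at min/max, multiplicity 4), the standard
basis has `K + 4` functions summing to one everywhere; the first is
dropped, leaving `K + 3` columns per dimension that are not collinear with
the intercept, and `1 + 2(K+3) + (K+3)²` design columns in total.
`K = 3` by default (49 columns) — small enough to fit hundreds of cells,
flexible enough for gradients and blobs; it is a config knob, not a fitted
quantity.

The design is factorized once per cluster by SVD; the numerical rank `p`
uses the `max(m,n)·eps·σ_max` tolerance, and the pseudoinverse is reused
for every gene and every permutation replicate (a permutation only
reorders rows, and the fit is refit on the permuted coordinate set, which
has the same marginal knots).  Per gene: minimum-norm least squares,
`F = [(TSS − RSS)/(p − 1)] / [RSS/(n − p)]` against the intercept-only
null.  A conventional overall F is used deliberately; degrees of freedom
come from the numerical rank so near-collinear designs stay sane.
Sums of squares below a relative round-off floor are treated as zero: a
constant gene gets `F = 0`, an exact fit gets the `+inf` sentinel whose
p-value is later floored at machine epsilon.  Clusters with fewer than
`rank + 10` cells are skipped with a warning rather than fitted.

## Significance with clustering uncertainty

Community detection is re-run under seeds `1…n_seeds` (default 1,000) on
the cached neighbor graph.  Per seed and original cluster, the
argmax-Jaccard reassigned cluster is matched (ties toward the smaller
reassigned label); across seeds the `n_keep` (default 100) highest-Jaccard
matches are kept (ties toward the smaller seed).  Duplicate matched sets
are kept — each still receives an independent location permutation, which
is the quantity being averaged over.  For each kept match, the coordinates
of its cells are permuted uniformly (expression fixed), the design is
rebuilt, and all genes' F statistics are recorded.  Matched clusters may
contain cells outside the original cluster; expression for them comes from
the full retained matrix restricted to the original cluster's gene list.
Permutation RNG streams derive from `(global seed, cluster id, replicate
index)`, so results are independent of evaluation order and reproducible.

A Gamma distribution (shape/scale, location 0) is fitted to each gene's
null statistics by maximum likelihood from a method-of-moments start; the
p-value is the fitted upper tail at the observed F, floored at machine
epsilon.  When fewer than 10 finite nulls exist, the nulls are degenerate,
or the fit fails, the empirical estimate `(#{null ≥ obs} + 1)/(n + 1)` is
used and flagged per gene.  Note the floor this implies: with `n_keep`
below 10 every p-value is empirical and cannot go below `1/(n_keep + 1)`,
so very small ensembles are only useful for smoke tests.  BH FDR is
applied within each cluster across genes (global adjustment available via
a flag); significance is `q ≤ 0.05`.

The reduced profile (`n_seeds = 50`, `n_keep = 20`) is the down-scaled
configuration used throughout the simulation-based checks; 20 nulls are
enough for a stable Gamma fit while keeping a ten-replicate calibration
study in the minutes range.

## Gene modules

Fitted surfaces of significant SVGs are standardized per gene (mean 0,
sd 1 across cells); flat fits are excluded.  k-means (10 restarts, fixed
seed) groups the standardized surfaces; the module count is the elbow of
the within-SS/total-SS curve over `k = 1…k_max` (default 10, lowered to
the number of distinct patterns), operationalized as the point of maximum
perpendicular distance from the chord joining the curve's endpoints — a
transparent approximation of dedicated elbow-selection tools.  The
metagene is the unweighted per-cell mean of the module's standardized
fitted values; standardized (not raw) fits are averaged so one
highly-expressed member cannot dominate the module summary.  Enrichment is
a one-sided hypergeometric test per term of a user-supplied GMT against
the cluster's tested genes as background, BH-adjusted, retained at
`q ≤ 0.05` and ordered by decreasing fold change.  No ontology-graph
decorrelation is attempted; terms are treated as flat sets.

## Synthetic data

The generator is the package's instrument for studying its own operating
characteristics; it emulates, and simplifies, the real inputs.

*Geometry.* Convex 12–24-vertex nuclei (jittered ellipse rings, radius
2.5–4.5 µm) placed by dart throwing with spacing that keeps even expanded
polygons disjoint; a canvas auto-sized to roughly half occupancy.  Cell
types occupy partially distinct regions via type-specific Gaussian
placement weights — reproducing the confounding between cell-type
composition and space that motivates within-cluster testing.

*Counts.* Gene baselines are lognormal; ~30% of genes are markers of one
type (+1.5 log-effect) so expression clustering can recover the types; per
(gene, type), 10% of genes are flagged SVGs and receive a planted surface
(linear gradient across the canvas or a Gaussian bump, centered over the
type's cells) scaled by the effect size (default 1 on the log scale).
Counts are Poisson (negative-binomial behavior is not modeled); bin-level
datasets scatter each cell's counts uniformly over the bins inside its
expanded polygon, with 5% leaked to adjacent background bins, and the
positions table includes the zero-count bins covering each cell, as a real
capture grid would.

*Study conditions.* `simulate.study_conditions()` (base mean 2, baseline
log-sd 0.5) plants effects only in decently expressed genes, mirroring how
SVG benchmarks select the most ubiquitously expressed genes before
planting signal; the generic `SimulationConfig` default keeps a broader
lognormal baseline under which weakly expressed SVGs are genuinely
undetectable.  The companion `pipeline.simulation_study_config()` scales
the 300-expressed-gene cell filter to a quarter of the panel (synthetic
panels have only 100–200 genes) and sets clustering resolution to 0.1 so
clusters align with the handful of planted types.  Calibration and power
runs use 2,000 cells × 200 genes × 3 types with the reduced significance
profile, and the full-default machinery is exercised on 500 cells × 20
genes; these sizes are the package's declared simulation scale.

*What passing does not show.* Poisson counts, convex non-touching nuclei
and perfectly segmented contours are all cleaner than real tissue;
calibration on this generator demonstrates the statistical machinery, not
robustness to segmentation error, overdispersion, or dense tissue where
expanded polygons overlap.  Sample-wide (cross-cluster) spatial structure
is only present through type placement, so the generator cannot measure
how much cell-type confounding the within-cluster design removes relative
to sample-wide methods.

## Degenerate inputs and tie-breaking, collected

- Polygons: < 3 vertices, self-intersections, zero area → explicit error.
- All cells sharing one coordinate value → degenerate-geometry error.
- Cluster smaller than design rank + 10 → skipped with warning.
- Empty jaccard union → 0 by convention.
- All-null or single-class ground truth in AUPRC → explicit error.
- Assignment ties → smaller nucleus id; Jaccard ties → smaller reassigned
  label, then smaller seed; k-means → fixed seed, 10 restarts.
- Every RNG stream derives from an explicit seed; two runs with the same
  configuration produce byte-identical tables.

## Known limitations

- The aggregation loop is per-square Python over candidate polygons;
  adequate to ~10⁵ squares, not tuned for whole-slide Visium HD.
- The Gamma tail extrapolates beyond the permutation support by design;
  with heavy-tailed null statistics the far tail can be optimistic, which
  is why the fallback flag is reported per gene.
- `run_svg` re-runs preprocessing rather than deserializing the neighbor
  graph; simple, deterministic, but redundant work for very large inputs.
- Enrichment ignores gene-length or expression-level bias and the GO DAG.
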