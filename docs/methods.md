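# Methods

This note records the modelling choices, defaults and known limitations
behind the package, in the order the pipeline runs.

## Raster and vector conventions

All rasters share one data model: square pixels, top-left origin, row
index increasing southward, half-open pixel extents, point-to-pixel by
`floor((x − origin_x) / cell)`. A single coordinate reference system is
assumed throughout; the CRS tag is carried opaquely and never
interpreted — reprojection is out of scope. On disk rasters use the
ESRI ASCII grid format with values written at 17 significant digits, so
the write→read round trip is bit-exact for doubles; vectors use
GeoJSON. Areas of raster classes are always cell counts × cell
area — nothing downstream of binarization re-measures vectors.

Line rasterization is *all-touched*: a cell is flagged when any segment
intersects its square, including corner clips. Trails must not vanish
when they cut a pixel corner; for risk flagging the conservative
direction is to over-mark, not under-mark. Polygon rasterization labels
a cell by the polygon containing its center, ties resolved to the
lowest id with a warning.

Bilinear resampling interpolates the four surrounding source cell
centers; within half a source cell of the border the border value is
replicated, and target cells outside the source extent (or whose
stencil touches nodata) become nodata. It reproduces affine surfaces to
numerical precision away from the replicated border and is meant for
continuous layers only — callers flag categorical layers and are
rejected.

## Terrain derivatives

Slope uses the Horn 3×3 operator (the common GIS default) in degrees,
with replicated borders; a nodata neighbor inside the window is
substituted with the center elevation (a local-flat assumption) so
slope does not bleed across mask edges. TPI is the center elevation
minus the mean of its square neighborhood with the center excluded;
the neighborhood radius is a first-class parameter (default 1, i.e.
3×3) because the landform literature defines TPI at many scales and
the analysis resolution is the only scale the data pin down. Edge
cells use the neighbors that exist. TPI is antisymmetric under DEM
negation and invariant to constant offsets; both invariants are tested.

## Occurrence preparation

Presence records are thinned to at most one per pixel; the survivor
within a pixel is drawn uniformly at random under a named seed, because
survey record order carries no meaning. Output order is row-major by
pixel, making thinning idempotent and deterministic.

Pseudo-absences are cell centers drawn uniformly *without replacement*
from study-mask cells not containing a presence point — sampling with
exclusion avoids label contradictions at the analysis resolution. The
default count is 10,000 points, which on the default 256×256 grid also
reproduces the ~6.6:1 background-to-presence ratio of the original
survey data for the largest species. Each species draws its own pool
under its own seed, keeping the three models independent.

## Collinearity screening

For every predictor pair the screen computes Pearson, Spearman and
Kendall coefficients on the *model dataset* (presences plus
pseudo-absences — the screen serves the model, not the map). Percent
deviance explained per predictor comes from a univariate binomial
regression: a penalized B-spline smooth (df 6) when it can be fit, else
a linear logit; residual deviance within 0.01 % of zero is reported as
100 with a separation warning, since the unpenalized MLE is unbounded
there. While any retained pair exceeds the threshold (default 0.75) on
any coefficient, the worst pair (largest max-|r|) is resolved first and
its lower-deviance member dropped; deviance ties drop the
alphabetically later name. The procedure is deterministic and, when
deviances are distinct, invariant to column order.

## The random-forest SDM

The classifier is a bagged ensemble of unpruned trees on bootstrap
resamples (default 1000 trees); presence probability is the tree-vote
fraction. The number of split variables (`mtry`) is tuned by out-of-bag
error over a doubling/halving ladder around ⌊√p⌋ (50-tree forests per
candidate, ties to the smaller value).

Evaluation protocol, in order:

* **Split** — stratified 70/30 per class, round-half-up, seeded.
* **Training-side scores are out-of-bag votes.** Each training point is
  scored only by trees whose bootstrap omitted it. In-bag votes are
  memorized (≈1 for presences) and would drive the max-sens+spec
  threshold to the top of the score range, collapsing the habitat maps;
  the out-of-bag convention is also what the reference R implementation
  returns for training data.
* **Threshold** — candidates are midpoints between consecutive sorted
  unique scores plus {0, 1}; presence is predicted at score ≥ t; the
  smallest maximizer of sensitivity + specificity wins. Selected on
  training (out-of-bag) scores only, then applied unchanged to the test
  split — no test leakage.
* **TSS** is computed as sensitivity + specificity − 1 from the stored
  sensitivity/specificity at construction time, so the identity holds
  exactly in every report.
* **Cross-validation** — stratified k-fold (default 10) on the training
  data, re-tuning mtry inside each fold to avoid tuning leakage;
  per-fold AUC, mean and sample SD are reported.
* **Importance** — mean decrease Gini computed from tree internals: the
  sample-weighted impurity decrease summed over each tree's splits on a
  variable, averaged over trees (the unnormalized quantity the R
  randomForest package reports, not sklearn's normalized variant). The
  median across the three species ranks variables; the top three get
  response curves.
* **Response curves** — partial dependence: set the variable to each of
  50 grid values for every row, average the predicted probability.
  Rows are deterministically subsampled to 1000 for tractability and
  all grid values are scored in one batched pass. Deep-forest partial
  dependence carries a small local wiggle (each grid value is in effect
  a nearest-training-neighbor average), so flatness of null-variable
  curves is a statement about the replicate average, not every point.

Binary maps are probability ≥ threshold with nodata propagated; the
combined map is the cell-wise OR (nodata only where all inputs are
nodata).

## Risk statistics

Regional incidence is 10⁴ × patients / population, kept unrounded
internally and rounded to 2 decimals for reporting — recomputing the
bundled 2016 Korean regional table from its printed counts and
populations reproduces the printed rate for 14 of 16 regions; the two
exceptions differ in the final digit only because the published
populations are themselves rounded to 0.01 million. The
habitat-incidence association uses Spearman's rho (mid-rank Pearson)
with the two-sided t-approximation on n − 2 degrees of freedom — at the
regional n of 16 the approximation is adequate, and an exact
permutation p-value is available for n ≤ 10. Park risk is habitat
cells / park cells; trail risk is evaluated cell-wise on the rasterized
trails (no segment-level aggregation — the trails enter the analysis as
30 m raster pieces), undefined-denominator cases return missing with a
warning. Cover composition is the mean percent cover over habitat
cells, generic over whichever cover layers are supplied.

## The synthetic study system

The generator emulates the statistical structure the analysis assumes,
not any real geography:

* **DEM** — three superposed Gaussian random fields: macro (σ = 64
  cells) so whole provinces differ in elevation the way a mountain
  range divides a country; coarse (σ = 16) for mountain-scale relief;
  fine (σ = 2, amplitude 0.2 of coarse) for local relief. The fine
  scale puts valleys at every elevation, keeping TPI largely
  uncorrelated with raw elevation (r ≈ 0.25) — with a single-scale
  field, TPI degenerates into an elevation proxy. Elevations span
  50–1200 m on a 256×256 grid of 30 m cells (~59 km²).
* **Climate** — temperature = 22 °C − 0.0065·elevation + smooth noise
  (sd 0.75 °C), redrawn up to five times until |r(temp, elev)| > 0.78:
  the collinear pair the screen is meant to find, with enough
  independent variation that the causally relevant temperature beats
  its elevation proxy in deviance explained. Precipitation is an
  independent smooth field (900–1600 mm).
* **Covers** — four percent layers. Herbaceous cover tracks a generic
  growing-season temperature window (12–19.5 °C, logistic shoulders),
  the way grassland follows climate; the window transform keeps its
  correlation with raw temperature below the 0.75 screen while giving
  it genuine marginal signal. Shrubland = 0.85·herbaceous + noise
  (sd 9), an attenuated copy with |r| > 0.78 — the second engineered
  pair, whose weaker member the screen should drop. Forest and bare are
  independent smooth fields.
* **Species truth** — suitability is logistic in: baseline −8; a valley
  term (−1.2 per m of TPI); a Gaussian slope bump (amplitude 3, optimum
  15°, width 6°); and a plateau temperature window (amplitude 7,
  shoulders 0.5 °C) — 18–20 °C for the warm-lowland species, 14–19 °C
  for the widespread species, 13–17 °C for the cool-highland species.
  Effect sizes were set so the three terms contribute logit standard
  deviations of roughly 3 / 1 / 2–3 and the species' suitable areas
  individually cover ~10–30 % of the grid with a union near 40–50 %,
  echoing the relative importance ranking and map fractions of real
  *Gloydius* analyses. Presences are drawn without replacement with
  probability proportional to suitability (defaults 700 / 1500 / 100
  points, echoing published survey counts).
* **Regions and incidents** — 16 rectangles tiling the grid (the macro
  DEM scale makes them genuinely different), log-uniform populations
  (2×10⁵–5×10⁶), and Poisson counts with per-10⁴ rate 0.3 + 4 ×
  true-habitat proportion — the simplest mechanism consistent with a
  monotone habitat-incidence association. All generator parameters are
  recorded in the output metadata as the recovery tests' answer key.
* **Trails and parks** — trails are seeded random walks stepping to
  neighbors with weight exp(−TPI), i.e. biased along valleys like real
  hiking routes; parks are random rectangles of ≥ 100 cells.

What the generator does *not* emulate: real topographic anisotropy and
drainage networks, spatial sampling bias in survey effort, species
interactions, imperfect detection, and the healthcare-access biases
that distort reported snakebite counts. Passing recovery tests
therefore shows the pipeline recovers structure *that is present and
correctly specified* — it does not validate the ecological realism of
any particular real-world map.

## Problem sizes in tests and the acceptance script

The library defaults mirror the full protocol (1000 trees, 10-fold CV).
The executed synthetic study uses a desk-scale profile chosen for a
single CPU: 250 trees and 5-fold CV in the end-to-end run, and 150-tree
forests with mtry = 2 and no CV inside the 100-seed recovery batteries;
at these sizes the recovery margins are already wide (test AUC ≥ 0.8
and correct top-3 importance in ≥ 97 of 100 seeds in design runs).
Unit tests use 96×96 grids with proportionally reduced point counts.

## Known limitations

* Vote-fraction probabilities are step functions of the ensemble; with
  few trees the threshold grid is coarse (resolution 1/n_trees).
* The deviance-explained comparison between a collinear pair can tie
  almost exactly on low-signal draws; the screen then falls back to its
  deterministic alphabetical rule, which need not match the causal
  ordering (observed in ~2 % of seeded replicates).
* The Spearman p-value is a t-approximation; at n = 16 this is
  standard, but exact inference is only offered for n ≤ 10.
* Single CRS, no reprojection, no multi-band rasters, no cartography.
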