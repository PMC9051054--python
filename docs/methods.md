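# Methods

This note documents the models implemented in `paleoniche`, the choices
made where the design was genuinely open, and what the synthetic-data
tests do and do not demonstrate.

## Raster model

All analysis rasters share one equal-area projected grid (default an
EPSG:3035-style Lambert azimuthal equal-area grid, cell size in metres),
so cell area is the constant `(cell_size/1000)²` km² and the suitable
area `A` is a cell count times that constant.  Grids use the GeoTIFF
top-left convention: `origin` is the top-left corner, rows advance
southward, cell centres sit at `origin + (index + 0.5)·cell_size` along
each axis.  Geographic (degree) grids are supported only for area
computation, using the exact spherical-quadrilateral formula
`R²·Δλ·(sin φ_top − sin φ_bot)` with R = 6371.0088 km; any other CRS is
rejected rather than approximated.  Nodata cells are NaN in memory and a
sentinel on disk; they are excluded from every statistic and never
treated as zero.  GeoTIFF I/O (single band, float32 layers, uint8
masks) is implemented on `tifffile`, writing ModelPixelScale,
ModelTiepoint, a minimal GeoKey directory carrying the EPSG code, and
GDAL's nodata tag.

## Interval climates and NPP

Analysis intervals aggregate one or more 10-ka climate slices by
per-cell arithmetic mean, per variable.  A cell missing in *any* member
slice is missing in the interval (partial means would bias interval
climates along shifting coastlines).  NPP uses the Miami model with
Lieth's (1972) constants — asymptote 3000 g DM/m²·yr, temperature curve
`3000/(1+exp(1.315−0.119·T))`, precipitation curve
`3000·(1−exp(−0.000664·P))`, minimum of the two.  NPP is computed from
the interval-averaged BIO1/BIO12, not as an average of per-slice NPP;
because the Miami response is concave this can differ slightly from the
slice-mean alternative, and the choice follows the order
"average climate first, then derive NPP".

## Covariate preselection

Two stages on a pooled, seeded sample of onshore cells across all
slices (default n = 10,000; the sampling frame is a package choice —
pooled palaeo slices rather than any single reference slice):

1. *Correlation filter*: a covariate is dropped if Pearson **or**
   Spearman |r| with a retained higher-priority covariate exceeds 0.9.
   "Priority" operationalises "keep the more general variable" as an
   explicit ordering (annual means > ranges > seasonality >
   quarter/month extremes; elevation least removable).  Scanning in
   priority order makes the outcome independent of column order.
2. *Iterative VIF*: remove the argmax of VIF_j = 1/(1−R²_j) until all
   VIF < 5.  Exact dependence gives VIF = +∞ and is removed first; ties
   break by reverse priority.

On small, smooth synthetic worlds the second stage can legitimately
remove a "primary" covariate: a Gaussian field with correlation length
15 cells on a 60–100-cell grid has only ~15–40 effective spatial
degrees of freedom, so genuinely independent fields show substantial
sample collinearity.  Tests therefore assert the contract (all planted
collinear derivatives eliminated, final max VIF < 5) rather than an
exact retained set.

## Occurrence sampling

Sites dated to several intervals contribute one record per dated
assemblage, each with its own interval's environment; undated
assemblages form the external validation set.  Presence cells are the
union over sites of onshore cells whose centre lies within 10 km
(centre-to-centre in the projected CRS) of the site, deduplicated with
each cell attributed to its nearest site.  Cross-validation folds are
site-grouped (a site and its whole buffer share a fold; k = 5 by
default, configurable — random cell-level folds leak spatially
autocorrelated points and overfit).  Background points are a uniform
without-replacement sample of onshore cells (default 10,000) drawn once
from the pooled (all-slice mean) climate on the common onshore mask and
shared by every candidate model, which is what makes AICc/AUC
comparisons across candidates well defined.

## Maximum-entropy model

The fitted object is a Gibbs density over background cells subject to
L1-regularised feature matching.  Covariates are min–max scaled to
[0, 1] on the pooled training sample; feature classes are

* L: scaled covariates (d columns), Q: squares (d), P: pairwise
  products (C(d,2));
* H: forward hinges `max(0, z−t)/(1−t)` at t = k/knots (k = 0…knots−1)
  and reverse hinges `max(0, t−z)/t` at t = k/knots (k = 1…knots);
* T: step indicators `1[z > t]` at the knots−1 interior knots.

Default 50 knots per covariate.  Per-feature penalties are
β_j = RM · β0(class, m) · s_j/√m with s_j the feature s.d. over the
normalisation background, m the presence count, and β0 the class-default
interpolation tables of MaxEnt 3.4.4 (L/Q/P: 1.3→0.05 as m grows to
100; H: 0.5; T: 2.0→1.0).  Presences are appended to the normalisation
background (standard presence–background construction; a flag disables
this).  Constant features cannot be matched and are frozen at zero.

The optimiser is FISTA (accelerated proximal gradient) with
backtracking line search and gradient-scheme adaptive restarts;
convergence is declared when the KKT residual — |gradient| ≤ β on
inactive coordinates, gradient + sign·β = 0 on active ones — falls
below `tol` (default 1e-5, default cap 500 iterations).  Correctness is
the KKT contract, not the algorithm: the suite re-checks
normalisation (Σ raw = 1) and the feature-matching bound after every
fit, and a one-feature problem against a bisection oracle.

The reported output is the cloglog transform
`1 − exp(−e^H · raw)` (H = entropy of the fitted background
distribution), matching MaxEnt 3.4.4's default; raw and logistic
outputs are selectable.  Projection clamps covariates to the training
range by default.  Binarisation thresholds at the empirical 5% quantile
of presence predictions under the **lower (inverted-CDF) convention**
— the q-quantile of n values is the ceil(q·n)-th order statistic — a
convention shared with the 10%-omission threshold.  The presence pool
for the threshold is the pooled training sample of the single fitted
model (not per-interval pools).

## Candidate evaluation and selection

AICc follows the Warren–Seifert convention: lnL is the sum over
presences of log raw density renormalised over the shared grid
background, k counts non-zero coefficients, and n ≤ k+1 yields +∞ (the
candidate ranks last).  OR.10 is the mean over folds of the fraction of
test presences strictly below the 10%-lower-percentile of training
presences; AUC is the rank-based (Mann–Whitney) test AUC, ties counting
one half.  Selection rules: `min_aicc`, `min_or10`, and the default
`compromise` — minimise OR.10 among candidates with AUC at or above the
grid median and ΔAICc under a cap (default 2000) — a formalisation of
the judgement call that trades a mid-field AICc for low omission; any
reproduction of a published pick by this rule is qualitative, not
numeric.  Background-size sensitivity reports, per sample size, the
maximum over covariates of the Kolmogorov–Smirnov distance to the
full-mask distribution, averaged over seeded repeats.  Covariate
importance combines permutation importance (mean training-AUC drop when
one covariate is shuffled across presence + background) and model
contribution (Σ|λ_j|·s_j per covariate, normalised to percent).

## Forager regressions

Preparation keeps groups at latitude ≥ 30° N (boundary inclusive),
drops trade-dependent societies, averages a second density estimate
where present, rejects non-positive density/NPP, and adds log10
columns.  Strategy labels come from k-means (k = 3, k-means++, 25
restarts, fixed seed) on the diet composition; clusters are named by a
maximum-weight assignment of centroids to diet components so each
strategy name is used exactly once.  The k-means labels — not any
pre-existing classification — are carried downstream.

Average fits are OLS of LOGD on LOGNPP with Pearson r and two-sided p
from the t distribution (n−2 df).  Outliers beyond the 95% OLS
prediction interval are removed in a single pass (no iteration) and the
model refitted.  Envelope fits bin LOGNPP with width 0.1 anchored at
`floor(min/0.1)·0.1`; each non-empty bin contributes its max-LOGD point
to the upper fit and its min-LOGD point to the lower fit (a singleton
bin feeds both); at least three non-empty bins are required.  Anchoring
and singleton handling perturb the envelope coefficients slightly and
are therefore config-exposed.  The horseback sensitivity test takes two
explicit record subsets and reports both a residual variance-ratio F
(two-sided) and the t of the group×LOGNPP interaction in the pooled
four-parameter model.

## Population

Density maps apply `D = 10^(a + b·log10 NPP)` (individuals/100 km²)
inside the habitat mask; masked cells with non-positive NPP become
nodata with a warning.  Only the hunter lower/upper envelope equations
feed the maps by default (strategy configurable); headline numbers use
the lower bound.  `P = D̄ × A / 100` with A in km² — the /100 makes the
density unit explicit — and equals the cell-wise sum exactly on the
equal-area grid (asserted to 1e-9).  The interval series reports
per-interval A, D̄ and P, the extreme intervals and the percent drop;
band counts are `floor(P/25)`.

## Synthetic study conditions

The generator emulates the statistical structure of the real inputs,
not their content:

* Climate layers are Gaussian random fields (white noise smoothed by a
  Gaussian kernel of the stated correlation length, renormalised to the
  target mean/s.d.), six primary covariates (BIO1, BIO2, BIO7, BIO12,
  BIO15, elevation) plus five deliberately collinear derived extras to
  exercise preselection.  Cold slices shift BIO1 by −6…−8 °C and BIO12
  by −200…−300 mm; the coastline is elevation > 0 and is shared across
  slices.
* Sites: 46 site cells drawn with probability proportional to a known
  log-quadratic (Gaussian) niche in BIO1/BIO12; 68 assemblages
  distributed over them, ~half dated and assigned to intervals.
* Forager table: 215 groups (60 hunters, 65 gatherers, 90 fishers) with
  planted per-strategy laws (hunter average −2.362 + 0.9427·LOGNPP,
  gatherer −4.0253 + 1.8485·LOGNPP), LOGNPP uniform on (1.4, 3.4) — the
  Miami-model span from polar desert to temperate forest — and residual
  scatter 0.30–0.35 dex, typical of ethnographic density compilations.
  The implied r² of the synthetic fits is consequently higher than in
  real compilations; the planted laws, not the dispersion statistics,
  are the ground truth the tests target.

What passing tests therefore show: the algorithms recover known truth
under realistic spatial autocorrelation, coastline masking, interval
aggregation and sampling noise.  What they do not show: performance
under real-data pathologies absent from the generator — dating error,
taphonomic site bias, sea-level-driven coastline change between slices,
non-stationary niches, or geographically clustered ethnographic
sampling.

## Problem sizes and determinism

Tests and the acceptance script run on reduced worlds (60–100 cells per
side, 800–4,000 background points, 8–20 hinge knots, candidate grids of
4–54 models) — sizes at which every contract above is already binding
while the whole suite stays fast.  All sampling is driven by explicit
seeds; fixed seed means byte-identical worlds, tables and fits.

## Known limitations

* No reprojection: inputs are assumed to already share the equal-area
  grid; geographic grids are handled for area computation only.
* The optimiser caps at `max_iter` and returns a flagged, non-converged
  model rather than failing; heavily penalised LQHPT fits at small tol
  can hit the cap.
* The envelope regression uses bin extremes and is sensitive to bin
  anchoring for sparse strategies (by design, exposed as config).
* The external validation counts an undated assemblage as "inside" if
  any of its candidate intervals' masks covers it — a permissive
  criterion (an assemblage with no interval constraint checks against
  all intervals).
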