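# Methods

This note documents the models and procedures implemented in `rhizosdm`,
their assumptions, the defaults that matter, and what the synthetic
study can and cannot demonstrate.

## Data model

A **report** is a genus-level presence record: genus, decimal
coordinates, calendar month, optional year, and a source tag
(`inaturalist` or `legacy`). Citizen-science reports must carry a
parseable observation date because environmental pairing is
month-specific; legacy literature records often lack dates, so their
month is optional and they are only ever scored against month-collapsed
suitability masks. Coordinates are rounded to tenths of a degree with a
pinned round-half-away-from-zero rule: abundance aggregation counts
reports per rounded coordinate, and banker's rounding would split ties
platform-dependently.

The **climatology** is a set of monthly mean fields for temperature,
salinity, dissolved oxygen, percent oxygen saturation, silicate,
phosphate and nitrate at 0, 5, 10 and 20 m — 28 predictors named
`<variable>_<depth>m` — on a regular cell-registered lat/lon grid with a
shared NaN land mask. I/O uses classic-format NetCDF (one file per
variable) or an equivalent long-format CSV.

## Sample-coverage screen

Reports per genus are reduced to an abundance vector (count per distinct
rounded coordinate) and screened with the abundance-based sample
coverage estimator of Chao & Jost, as used by iNEXT's rarefaction
machinery:

    C = 1 − (f1/n) · (n−1)f1 / ((n−1)f1 + 2 f2)

with the bias-corrected substitution `(n−1)(f1−1)/((n−1)(f1−1)+2)` when
`f2 = 0`. Coverage is evaluated at the observed sample size (not
extrapolated), and retention requires strictly `C > 0.95`. Two pinned
conventions: `C = 1` whenever there are no singletons, and a sample of a
single report returns `C = 0` — the raw formula would report perfect
coverage for `n = 1`, which inverts the estimator's meaning, so the
degenerate case is defined as uninformative instead.

One property worth knowing: adding a duplicate report strictly increases
the estimate except when it promotes a doubleton to a tripleton, which
removes an `f2` and can lower it by O(1/n²). The tests assert exactly
this structure.

## Environmental pairing

A report is paired with every grid cell whose center lies within
±`window` degrees (default 2) in both axes — a lat/lon box, not a
great-circle disc, matching the screening rule's phrasing — in the
report's month. Longitude wraps across ±180°; latitude clamps at the
poles. All matched non-missing cells are averaged per (variable, depth).
A report whose window is entirely land is "unpairable" and excluded with
a count. Reports are then snapped to a mapping grid (2° default, 1° for
the robustness check) and accumulated into the curated frame: one row
per occupied cell × month, carrying genus counts and the mean of its
member reports' profiles. Rows are cell × month because pairing is
seasonal; a `collapse_months` option merges them. Missing profile
entries are median-imputed only inside model fitting, with an audit
table recording which entries were imputed.

## Multivariate GLM niche test

Counts are modelled per genus with a negative-binomial (NB2) log-link
GLM — overdispersed counts are the norm for aggregated presence data.
The mean model is fit by IRLS (statsmodels) at fixed dispersion α, and α
is re-estimated by method of moments (solving Σ(y−μ)² = Σ(μ+αμ²)) until
stable. All-zero count vectors admit no finite intercept and are
returned flagged rather than raised.

The multivariate statistic is the sum over genera of the
likelihood-ratio statistic comparing intercept+predictors to
intercept-only, each at the genus' observed dispersion. Significance
comes from jointly permuting predictor rows against the count matrix;
`p = (1 + #{perm ≥ obs}) / (1 + B)` with B = 199 by default. Two
deliberate simplifications relative to the mvabund reference: the
resampling is unrestricted row permutation rather than PIT-trap residual
resampling (asymptotically valid for this global test), and the
dispersion is held at its observed per-genus value across permutations
(the inner refits use a fast fixed-α IRLS warm-started at the observed
coefficients; a unit test pins it against the statsmodels fit).
Predictors are standardized before fitting, so coefficients are per-SD
effects.

Genus niche positions are the first two principal components of the
column-standardized genus × predictor coefficient matrix, with a
deterministic sign convention (largest-magnitude loading positive).
Distribution grouping uses Kruskal–Wallis with tie correction and
pairwise Dunn z-tests (unadjusted at α = 0.05 by default; Holm
available). The compact letter display is built from the maximal cliques
of the non-significance graph, which makes "share a letter" exactly
equivalent to "not significantly different".

## Random forests and predictor selection

Rows of the curated frame become per-genus binary labels: presence
where the genus has a positive count, absence otherwise — the co-report
pseudo-absence assumption (an observer who photographs one jellyfish
would report any other present). One uniform 80/20 split is shared by
all genera so test folds are comparable; each genus gets a 500-tree
Gini-impurity forest (scikit-learn, unweighted classes by default).
"Relative importance" is the impurity-based mean decrease Gini;
scikit-learn normalizes it to sum to one per model, a constant scale
that leaves gap ordering untouched.

Selection sorts predictors by decreasing importance (ties broken by a
fixed canonical predictor order) and cuts at the largest consecutive
gap, keeping everything above it. If that keeps exactly one predictor,
the cut moves to the second-largest gap. Gap ties break toward the
earlier (larger-importance) position; when no extension is possible
(two predictors, or all gaps tied at the top) the single top predictor
is kept — the smallest deviation from the written rule.

## Envelope prediction and evaluation

The habitat envelope is the central 90% interval — 5th to 95th
percentile, linear-interpolation quantiles — of each selected
predictor among positive rows ("inner 90th percentile" read as the
central 90%; the fraction is configurable). A cell is suitable when
every selected predictor lies within bounds jointly in at least one
month (`any_month` default; per-month masks are available). The envelope
is a hard box, not a density score, and land is never suitable. For
mapping, suitable cells are rendered as an isotropic Gaussian kernel
density on the lat/lon plane (longitude-wrapping, unit mass over the
grid, Scott-style default bandwidth floored at one grid step); the KDE
is written in-house because the usual covariance-based estimators fail
on the degenerate inputs the pipeline must tolerate (a single suitable
cell, collinear cells).

Evaluation is percent overlap: a legacy record is "inside" when its
containing grid cell (optionally any cell within a Chebyshev tolerance
radius) is suitable, and accuracy is `100 × inside/total`, rounded to
0.1. Because no density cut level is canonical, a sensitivity option
scores records against the 95% highest-density region of the rendered
density surface instead of the hard mask. Because a near-global envelope earns high overlap trivially, the
suitable-ocean-area fraction is always reported alongside, and genera
above a configurable fraction (default 0.5) are flagged as
inflation-prone. A calibration identity anchors the metric: for
uniformly distributed points over the ocean, expected accuracy equals
100 × the suitable-area fraction.

## Synthetic study

The generator emulates the statistical structure the pipeline assumes,
not any real dataset.

* **Fields** are a per-variable latitudinal profile (warm tropics,
  nutrient-rich high latitudes, a subtropical salinity maximum) plus a
  hemisphere-antisymmetric seasonal cycle, mild linear depth effects,
  and smoothed Gaussian noise (12° smoothing length by default; shared,
  depth- and month-specific components), clipped to plausible physical
  ranges. The land mask is thresholded smooth noise — blobby synthetic
  continents covering 30% of cells by default, not real coastlines.
* **Niches** are Gaussian suitability kernels on 1–3 informative
  predictors per genus. The ten defaults echo the field's qualitative
  expectations: temperature/salinity dominate most genera, *Lychnorhiza*
  is nutrient-driven, and several genera key on 20 m rather than surface
  conditions.
* **Reports** follow an inhomogeneous Poisson process with intensity ∝
  (product of kernels) × participation weight. The participation surface
  concentrates effort near North America, Europe and Australia.
  Crucially, coordinates are *clustered*: by default ~97% of a genus'
  reports fall on a small set of fixed "popular access point"
  coordinates (≈1.2√n sites, Zipf-weighted), with the remainder jittered
  uniformly. Citizen-science coordinates repeat heavily at popular
  beaches, and it is exactly this reuse that lets rarefied coverage
  saturate; under pure uniform jitter (available as `clustering="none"`)
  almost every rounded coordinate is unique and no genus could ever pass
  the screen. Default per-genus targets follow the observed abundance
  ranking of rhizostome genera, scaled to ≈2000 total reports so the
  full pipeline runs in about a minute.
* **Legacy records** are drawn from the same niches with uniform
  participation and uniform jitter — independent, less biased, smaller
  (15 per genus by default).

What passing tests show: the estimators are algebraically correct
against brute force; the selection rule matches exhaustive enumeration;
the permutation test holds its nominal size and has power; envelopes
contain the stated mass and recover a known informative predictor; the
overlap metric is calibrated; and the whole pipeline is bit-reproducible
from seeds. What they cannot show: behaviour under real-world features
the generator omits — species-level misidentification, temporal trends,
depth-dependent missingness in the climatology, coastline/bathymetry
effects (mid-ocean over-prediction is expected and deliberately not
clipped), and observer effort that varies within cells.

## Numerical choices and degenerate inputs

* Quantiles: linear interpolation between order statistics, pinned
  explicitly because conventions differ across ecosystems.
* NB dispersion clipped to [1e-8, 100]; linear predictors clipped at
  ±30 before exponentiation; the Poisson limit is used for α < 1e-6 in
  likelihood evaluation.
* Permutation p-values use the add-one rule, so p ∈ (0, 1] always.
* The shared 80/20 split errors rather than silently producing an empty
  fold; single-class training labels skip the genus with a warning.
* All seeds are named in the run configuration (`synth_seed`,
  `split_seed`, `rf_seed`, `perm_seed`); every filter logs its counts
  (rejected rows, unpairable reports, dropped genera) into the run
  manifest, because presence-only bookkeeping drifts easily.

## Known limitations

The ±2° box window is an approximation that widens with latitude in
true distance; the pairing window's meaning (±2° vs a 2° box) is
configurable because sources phrase it ambiguously. The GLM biplot
inherits the instability of coefficients under collinear predictors
(depth replicates of a variable are strongly correlated); it is a
visual-grouping device, not an inferential one. Envelope prediction
ignores dispersal, biotic interactions and bathymetry, and the overlap
metric rewards breadth — always read it next to the area fraction.
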