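# Methods

This note documents the models, conventions and numerical choices behind
`invadegeo`, and what the synthetic-data generators do and do not
emulate.

## Invasion timing from annual observation counts

A biological invasion founded at time `t0` by a population of size `N0`
is modelled as logistic growth toward a carrying capacity `K` at
intrinsic rate `r` (per year):

    N(t) = N0 * K / (N0 + (K - N0) * exp(-r * (t - t0)))

The observable is not `N(t)` but the number of occurrence records
reported per calendar year, assumed proportional to population size:
`n_t = c * N_t` with an unknown, constant reporting rate `c`.  The model
is fit directly to the counts by unweighted ordinary least squares, so
the fitted `n0` and `k` are proxies (`c` times the true values) and are
not interpretable on their own; `r` and `t0` are invariant to `c` and
are the quantities of interest.  Counts are evaluated at the integer
calendar year of each series entry, and zero-count years contribute to
the residual sum of squares — which is why the count-series constructor
zero-fills years missing from the raw export.

### Identifiability and the founding-fraction convention

The curve above can be rewritten as `K / (1 + C * exp(-r * t))` with
`C = (K - N0)/N0 * exp(r * t0)`.  Only `(K, r, C)` are determined by
data; `(N0, t0)` trade off along an exact zero-residual ridge, for any
data set.  An "invasion time" is therefore only defined relative to a
founding population size.  `invadegeo` reports the ridge point at a
fixed *founding fraction* `n0/k` (default `1e-3`, i.e. `t0` is the
moment the population stood at one thousandth of its carrying
capacity).  The convention is dimensionless and scale-invariant, so the
reported `r` and `t0` are unaffected by the unknown reporting rate `c`
— multiplying a series by any `c > 0` rescales only `n0` and `k`.
Passing `founding_fraction=None` to `fit_logistic` returns the raw
optimizer solution (an arbitrary ridge point).

### Optimizer

The residual surface is multimodal in the box, so the fit is a
multi-start bounded trust-region least-squares search
(`scipy.optimize.least_squares`, method `trf`, tolerances `1e-15`):
50 Latin-hypercube starting points by default (`scipy.stats.qmc`,
seeded), with `n0` and `k` sampled on a log scale.  Default bounds
encode weak prior knowledge: `n0 in (1e-6, max_count]`,
`k in [max_count/2, 100*max_count]`, `r in (0, 5]` per year, and
`t0 in [window_start - 15, first positive-count year]` — the invasion
must precede first detection and is unlikely to predate the window by
more than 15 years.  The lowest-RSS solution is returned; an all-zero
series raises a degeneracy error, and fewer than five years raises an
insufficient-data error.

Decimal years convert to dates as `Jan 1 + floor(frac * 365)` days by
default (a fixed 365-day year); the `calendar` option uses the true year
length.  Only month-level precision is meaningful at the accuracy the
estimates carry.

## Range areas and the fair-comparison procedure

The extent of occurrence of a taxon is the area of the convex hull of
its occurrence points, computed in the raw (longitude, latitude) plane
and reported in **square degrees** (planar shoelace area; shapely
provides the hull).  This is a deliberate convention, not an equal-area
measurement: square degrees shrink with distance from the equator, but
the quantity is used comparatively between lineages occupying similar
latitudes.  Degenerate sets (fewer than three non-collinear points)
have area zero; duplicate points do not affect the hull.  Longitudes
spanning more than a hemisphere trigger a warning, since a planar hull
across the antimeridian is meaningless.

Hull area grows with sample size, so the raw areas of a well-sampled
and a poorly-sampled taxon are not comparable.  The comparison
procedure subsamples the better-sampled (focal) taxon down to the
smaller taxon's `n`, without replacement, `B` times (default 100), and
classifies the smaller taxon's full-sample area against the 2.5th and
97.5th percentiles of the subsampled areas.  A reference area below the
lower percentile supports the conclusion that the focal range is
genuinely wider.  Percentile intervals were chosen because subsample
area distributions are strongly right-skewed (a few subsamples catch
the extreme points); a symmetric interval would be misleading.  An
exhaustive mode enumerates all `C(n, m)` subsets when that count is
small, and is the oracle the Monte-Carlo mode is tested against.

Calibration: with focal (`n = 170`) and reference (`n = 20`) drawn from
the same spatial distribution, the "focal wider" verdict occurs at
roughly the nominal 2.5% rate (the acceptance suite checks a 0.5–6%
band over 400 seeded trials).  Because subsamples of one finite point
set overlap each other, the interval is slightly anti-conservative; the
reference falls inside it ~92% of the time rather than 95%.

## Index of invasiveness

`I_inv = A / T`: distribution area per unit divergence time.  Absolute
divergence times are rarely known, so for sister lineages — equal-aged
by definition — `T` may be replaced by root-to-tip branch-length sums
(`mean_root_to_tip` averages within each clade; under a roughly constant
substitution rate the two clade means are nearly equal, and averaging
symmetrizes the noise).  With equal `T` the sister contrast reduces to
an area ratio, and the focal area should be the subsample-corrected
mean from the comparison procedure; raw areas are accepted with a
warning because they carry the sample-size bias the correction exists
to remove.

## Geophylogeny layout

Tips are anchored at specimen coordinates.  Conventions (each is a
choice this package defines explicitly, since no standard exists):

- **Coincident tips** (identical sequences collected at one locality,
  or province-centroid placeholders) are displaced onto a regular k-gon
  of radius `offset_deg` (default 0.05°) around the shared point, in
  tip-label sort order — deterministic, and the group centroid is
  preserved.
- **Internal nodes** are placed at the centroid of their children's
  anchors.
- **Branch lengths** render as north-pointing bars of length
  `bar_scale * branch_length` at each node's anchor; a connector joins
  each bar top to the parent's anchor.  Zero-length branches (identical
  sequences) yield connectors with no bar, so the sum of bar lengths
  along any root-to-tip path is exactly `bar_scale` times the root-to-
  tip branch-length sum.
- **Collapsed clades** (a monophyletic tip set) become a single
  pseudo-tip at the members' coordinate centroid carrying the clade's
  stem length; member anchors are kept as unlinked markers so the
  clade's spread stays visible.

Layouts export to GeoJSON (RFC 7946, coordinates ordered longitude,
latitude) and to a minimal KML document.  Rendering onto tile maps is
out of scope; standard layers keep the output testable and viewer-
agnostic.

## Occurrence cleaning

Darwin-Core exports are parsed tolerantly: rows with blank or
unparseable coordinates are kept (they still count toward annual
series) but never enter point sets; out-of-bounds coordinates are a
hard error naming the row.  Event deduplication collapses records
sharing a year (and day, when dates are present) within a Chebyshev
radius of 0.001° (~100 m) under transitive closure, keeping the first
record — this reproduces the rule that many specimens collected from a
single nest count as one observation.  All bases of record are included
by default; sightings can be dropped with a flag (their exclusion does
not change the pipeline's conclusions on the bundled scenarios).
Records whose collection country differs from the storing institution
cannot be detected automatically; that remains a documented limitation
of occurrence data.

## Synthetic data: what it does and does not emulate

- `simulate_series` produces counts whose expectation follows the
  logistic curve exactly, optionally with Poisson sampling noise —
  the minimal noise model for "number of observations" data.  Real
  reporting effort is not constant through time (media attention,
  mandatory control programs), so real series are over-dispersed and
  trend-contaminated in ways the generator does not reproduce; passing
  recovery tests shows the machinery is correct, not that GBIF series
  satisfy the proportionality assumption.
- `simulate_cloud` draws uniform points in a convex polygon (rejection
  sampling) or from a Gaussian mixture.  Real occurrence points are
  spatially autocorrelated and effort-biased toward roads and cities;
  the calibration results quantify the decision rule's behaviour under
  ideal sampling only.
- `simulate_geo_tree` grows a random bifurcating topology by uniform
  pairwise joins with exponential branch lengths and evolves
  coordinates by a Brownian walk (per-branch displacement
  `N(0, dispersal_sd^2 * L)` per axis).  It exercises the geophylogeny
  machinery, including the coincident-tip case at `dispersal_sd = 0`;
  it is not a model of hornet dispersal.

Bundled scenarios: the France-like series uses `r = 1.3667`/yr,
`t0 = 2002.40`, years 2003–2011; the Korea-like series `r = 0.2812`/yr,
`t0 = 2002.77`, years 2003–2015.  The population proxies are the
package's choice (France `n0 = 0.4`, `k = 400`; Korea `n0 = 1`,
`k = 1000`, both at the canonical founding fraction `1e-3`), picked so
the expected series resemble the respective regimes: a fast rise to
saturation for France, a sparse slowly-growing series for Korea.

## Problem sizes and determinism

All stochastic components (optimizer starts, subsampling, generators)
take explicit seeds and are reproducible bit-for-bit.  Default test and
acceptance problem sizes — 50 optimizer starts, 1,000 hull-oracle point
sets, B = 100–2,000 subsampling replicates, 400 calibration trials —
run in well under a minute each on a single CPU and were chosen as the
smallest sizes at which the Monte-Carlo properties are stable.

## Known limitations

- Square-degree areas are not equal-area; comparisons across very
  different latitudes would need a projection (not the method here).
- The fitted `t0` is conventional (founding fraction), not an absolute
  observable; different conventions shift `t0` by `ln(ratio)/r` years.
- No confidence intervals on the logistic parameters; the fit is a
  point estimate, and sparse series (small counts, long zero runs) make
  `r` unreliable under realistic noise — visible in the precision tests.
- No antimeridian handling and no geodesic areas.
- Newick trees are consumed as rooted; no inference, rooting or
  bootstrap handling.
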