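# Methods

This note documents the models, algorithms, defaults and numerical choices
behind `photobackcast`, and what the synthetic-data tests do and do not
establish about real repeat-photography data.

## Photo alignment

Historical and repeat classified masks are registered from manually selected
control points marking unchanging features. `estimate_affine` solves the
six-parameter least-squares problem mapping historical points onto repeat
points (the repeat frame is the reference, because repeat photographs are
the higher-quality frame; the direction is configurable by swapping the
point sets). A four-parameter similarity model (translation + rotation +
uniform scale, the family a straight-line-preserving manual tool applies) is
available via `model="similarity"`; the default remains the full affine.
With exactly three non-collinear pairs the solution interpolates exactly;
collinear configurations raise a degenerate-geometry error rather than
returning a rank-deficient solve.

Labels are categorical, so `apply_transform` resamples strictly by nearest
neighbour under inverse mapping; pixels whose source falls outside the input
grid, or on an invalid input pixel, are invalid in the output. Pixel
coordinates are 0-based `(x=column, y=row)` with origin at the top-left.
Residuals are reported per pair with RMS and a flag threshold of 3 px
(the "within a few pixels" alignment standard); flagged pairs are retained,
and exclusion is an analysis-level choice recorded in run outputs.

## Land cover accounting

Compositions are percent of *valid* pixels per category (foreground and
uncertain areas carry `valid=False` and never enter a denominator), so each
vector is closed: values sum to 100. Fine categories (e.g., conifer density
classes) merge by summation through the scheme's `merge_map`.

Shannon diversity uses the natural logarithm (the convention of vegan's
`diversity`; switchable via `base=`). Change per category is tested as
`after - before` in percentage points (matching the from-X%-to-Y% framing of
cover change; relative change is available behind a flag), with a paired
Wilcoxon signed-rank test and a 10,000-resample percentile bootstrap CI over
pairs (seeded; the CI method is this package's choice since SE/CI
construction for such tables is rarely stated). No multiple-testing
correction is applied by default.

The Wilcoxon test is implemented in-package: zero differences dropped,
midranks for tied magnitudes, W = positive-rank sum. The exact two-sided
p-value is computed from the full null distribution of the rank sum
(dynamic-programming enumeration over sign assignments) whenever n <= 25 and
no magnitudes tie; otherwise a normal approximation with tie correction and
continuity correction is used. Tests cross-check both branches against
brute-force 2^n enumeration and `scipy.stats.wilcoxon`.

## Multi-scale species distribution models

The response is the per-site detection count out of k = 9 sampling units,
treated as k Bernoulli trials: zeros are interpreted as temporary emigration
(site non-use), not false absences, which is defensible only where
detectability is high — hence the PFA summary `(1-p)^k` with a 0.15
reliability threshold. The link is the logit throughout: coefficients are
log-odds per percentage point of cover, which is the scale on which
published per-percent coefficient tables (magnitudes like 0.04/%) and their
logistic back-transform are coherent.

The binomial GLM is fit by iteratively reweighted least squares with SEs
from the inverse Fisher information; AIC uses the full binomial
log-likelihood. Quasi-separation is flagged when any |beta| exceeds 50
(per-percent scale), non-convergence after 100 iterations likewise; model
validation requires convergence, no separation, residual
deviance/df within [0.3, 3], and no (near-)constant design column.

Buffer covariates are extracted over cells whose centers fall within the
radius; buffers crossing the raster edge are truncated (the excluded
fraction of the ideal disc is reported) rather than dropping edge sites.
Collinearity is screened per radius by VIF < 3, computed as 1/(1-R²) from
OLS of each covariate on the rest. Closed compositions are perfectly
collinear, so the screen always sheds at least one category; ties for the
largest VIF — every VIF is infinite in the fully closed case — are broken by
dropping the least-variable covariate first. This keeps the variance-rich,
ecologically dominant categories identifiable and makes the retained set
stable across radii; with an arbitrary tie-break the fitted model is a
closure-equivalent reparameterisation that need not transfer to scenarios
where only some categories change.

Stepwise selection is bidirectional from the full post-VIF model: every
single-term deletion and addition is scored, the lowest-AIC move taken, and
the search stops when no move strictly reduces AIC (deterministic
tie-breaks: deletion before addition, then alphabetical). AIC rather than
AICc matches the common stepwise default; AICc is easy to add but not
currently exposed. Scale selection runs the screen + stepwise independently
at each radius and keeps the minimum-AIC radius (ties toward the smaller
radius), retaining the full AIC-by-radius profile. The loop order
(covariates within radius, then radii compared) is the standard
pseudo-optimisation; a joint search over radius x subset space would be
combinatorial without changing the selected model in the regimes tested.

## Backcasting and uncertainty

`predict_occurrence` is the pure logistic back-transform; categories in the
model but absent from a composition count as 0%. Zero land cover change
therefore yields exactly zero occurrence change — an identity the end-to-end
tests assert bitwise. Species change across photo pairs is tested exactly as
land cover change is (Wilcoxon + percentile bootstrap CI on the mean delta);
"no substantial change" means the 95% bootstrap CI contains 0, a criterion
this package defines explicitly because classification rules are often left
unstated. Sensitivity analysis shifts *all* coefficients, intercept
included, by -SE and +SE simultaneously (one-at-a-time shifts can be built
from `SDMFit.shifted` per term); a species is direction-consistent when the
sign of its mean change agrees across the three scenarios. Because covariate
percentages are non-negative, predictions under beta+SE dominate those under
beta-SE at any fixed composition.

Community-level diversity has no single canonical construction from
occurrence probabilities, so two are emitted: Shannon H over per-pair
renormalised probabilities q_s = P_s / sum(P_s) (treating relative
occurrence probability as relative "abundance"), and expected species
richness sum(P_s). Neither is claimed to be uniquely correct; both are
computed per pair and epoch and tested with the paired Wilcoxon.

## Synthetic data: what it emulates, and what it does not

Landscapes are generated by thresholding a Gaussian-smoothed standard-normal
field at the cumulative quantiles of the target composition, giving
seed-reproducible, spatially autocorrelated categorical rasters whose pixel
fractions match the target to integer rounding. Defaults describe a
conifer-dominated subalpine mosaic: 45% conifer, 18% herbaceous, 12% shrub,
8% wetland, rarer remaining categories; 50-m cells on a 400x400 grid
(20 x 20 km); smoothing sigma of 4 cells (~200 m), the grain of subalpine
meadow/krummholz patchiness. The ~200-m grain also matters statistically:
much smoother landscapes make buffer compositions at adjacent radii nearly
collinear, and no selection procedure can then resolve the characteristic
scale to one 250-m step.

Surveys draw detection counts as Binomial(k, P) at the composition of the
species' true scale; an optional `detection_p < 1` thins detections to
exercise the PFA machinery. Default species truths span conifer, generic
forest, shrub and meadow associations, with the conifer specialist reusing
the magnitude of a published conifer-associated corvid model (intercept
-4.41, +0.04/% conifer, +0.06/% shrub at 1250 m). Photo pairs apply
independent per-pixel category transitions (e.g., herbaceous -> conifer
in-filling) for the modern frame and push the base classification through a
known affine warp for the historical frame, emitting noisy tie points so
alignment must actually be recovered; per-category ground-truth change is
recorded for verification.

The generator does **not** emulate: classification error (masks are
consumed as truth), photographic rendering (haze, exposure, foreground
geometry beyond validity masks), oblique perspective distortion of pixel
areas, spatially varying detectability, species interactions, or temporal
non-stationarity of habitat preference. Passing tests therefore establish
that the *estimators* recover known generative parameters — not that those
generative assumptions hold in any particular photographic archive.

## Problem sizes and seeds

Test and acceptance runs use 500 survey sites, 200 replicate surveys for
coefficient/scale recovery, 12 photo pairs at 150x150 px, and 10,000
bootstrap resamples — sizes at which the recovery statistics are stable from
run to run. Every stochastic routine takes an explicit seed or
`numpy.random.Generator`; there is no global random state, and identical
configs + seeds produce byte-identical CSV outputs (asserted in the CLI
determinism test).

## Known limitations

* The reproduction of published headline numbers requires the study's
  deposited per-pair compositions; only the printed coefficient table ships
  with the package.
* VIF screening on closed compositions necessarily removes at least one
  category, so fitted terms are interpretable only up to compositional
  closure; the dominant category's effect may appear as negative
  coefficients on its complements.
* Stepwise AIC retains a pure-noise covariate with probability ~0.16 each;
  selected term sets should be read as predictive, not confirmatory.
* GeoTIFF export is not implemented; rasters and masks are exchanged as
  8-bit PNG with JSON sidecars for geometry.
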