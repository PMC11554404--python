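# Methods

This note records the statistical models coatmorph implements, the design
choices made where the design was genuinely open, the numerical details,
and what the synthetic-data tests do and do not demonstrate.

## Coat taxonomy

Images carry a (pattern, colour, white) triple. Thirteen fully determined
raw coat types exist: five tabby patterns (blotched, broken, spotted,
striped, ticked) × two colours (brown, orange), plus solid black,
tortoiseshell (always mixed colour) and tuxedo (mostly-white, always
`white=True`). Grey is recoded to brown at ingest (grey cats sit on a
gradient to brown); `unknown` in either field is a legal terminal state
for poor-quality images, never silently coerced. Validation rejects
impossible pairs (e.g. solid + orange) instead of coercing them, so
labelling errors surface at ingest with row numbers.

The five modelling categories pool raw types of assumed ecological
similarity: solid black; blotched brown; mackerel brown (broken, spotted,
striped, ticked × brown); orange (all orange tabbies, pooled because colour
is assumed to dominate pattern at their sample sizes); tortoiseshell.
Tuxedo and unknown map to `excluded`. The white flag never changes a
category — it is a separate locus — except that tuxedo is *defined* by
white coverage and is excluded outright. Tuxedo is an input label, not
computed: the "more than half the body" judgement cannot be reproduced from
labels, so the label is treated as authoritative.

## Events, daily records and site retention

An **event** is a maximal run of images at one site whose consecutive gaps
are ≤ 60 s (strictly larger gaps split). Images of distinct known
individuals never merge; unidentified images stream by coat category within
a site, since an event carries a single category and the coat is observed
per image. Event counts are invariant to input order and non-increasing in
the gap parameter. Duplicate timestamps within a stream warn and keep the
first image.

A **daily event** flags a (site, calendar date, category) with at least one
event; the date is the local calendar date of the event start (the survey
records dates, so no noon-to-noon windows are used).

**Retention**: a site is kept iff it recorded a cat or operated at least
`threshold_days` (default 83). The threshold can be re-derived from data as
the 95th percentile of first-detection latencies, computed with the
linear-interpolation quantile and then ceiled to whole days — the ceiling
is the conservative direction, discarding more short cat-free deployments.
A site with a detection is never discarded.

**Black-cat abundance**: solid black cats cannot be individually
identified, so the survey-wide ratio `images_per_cat` (identifiable images
÷ identified individuals, where identifiable = all images that are neither
solid black nor unknown-coat) converts black image counts to an estimated
individual count. The estimator is exact when images-per-individual is
homogeneous across coat types and biased upward for black cats otherwise;
this is why the spatial response is the *modal* coat type rather than
individual counts. Per-site black tallies for the modal computation apply
the global ratio locally, floored at one cat when any black image exists:
`max(1, round(site_black_images / images_per_cat))` (configurable; mild
overcounting is tolerable because black would usually dominate such sites
regardless). Residual ties after the individuals-then-events rule resolve
by fixed prevalence order (solid black > mackerel brown > blotched brown >
orange > tortoiseshell) and are flagged `tie_broken`.

## Lunar model

The temporal analysis needs only a full/new dichotomy, so the moon is
modelled by its age in a mean synodic month: `fraction(t) = (1 − cos(2π ·
age/P))/2`, age measured from the reference new moon 2000-01-06 18:14 UTC
modulo P = 29.530588 d. Against a full ephemeris this mean model drifts by
at most a few hours near the 20%/80% thresholds, which can flip individual
near-threshold nights; a CSV ephemeris (date, fraction) can be substituted
when exactness matters. Nights are evaluated at local midnight in a single
configured survey timezone (default UTC+10); classification uses strict
inequalities, so fractions of exactly 0.20 or 0.80 are excluded with the
mid-range.

Because the illuminated fraction is arcsine-distributed under this model,
each 20%-luminosity tail covers ≈ 29.5% of nights and the full/new subset
retains ≈ 59% of a long window, with full and new counts within 1% of
parity.

## Multinomial logistic regression

Fitted from first principles by Newton–Raphson on the log-likelihood with
the reference category's coefficient row fixed at zero. Step halving keeps
the (optionally ridge-penalised) log-likelihood monotone; convergence is
declared when the maximum absolute score component falls below `tol ·
max(1, n)` (default tol 1e-8, comfortably inside the 1e-6·n score bound the
tests assert). The coefficient covariance is the inverse observed
information at the optimum (plus the ridge, when used). Design matrices are
checked for full column rank by pivoted QR, naming the collinear or
constant columns; with fewer rows than columns the check warns instead
(identifiability, not construction, is what fails there).

Degenerate inputs are flagged, never silent: a modelled category with zero
observed count has no finite MLE (its intercept diverges), so the fit warns
and reports `converged=False`; likewise coefficient norms above 40 on the
log-odds scale trip a divergence guard (separation). A small ridge
(suggested 1e-4) returns a finite shrunk fit, recorded on the result.

**Spatial model**: response = modal coat category per retained site,
reference solid black (absence is not meaningful since all retained sites
detected cats); predictors = intercept, five continuous site covariates,
and vegetation dummies over three classes (grassland reference,
configurable). Continuous predictors are z-scored by default with the
(mean, sd) transform recorded, because odds-ratio scale per raw unit is
otherwise arbitrary across predictors; raw-unit mode is available.

**Temporal model**: one row per (site, full-or-new night, observed
category), plus one `absence` row per cat-free camera-night; reference =
absence. A night with several coat types contributes one row per category
and no absence row — this preserves the one-outcome-per-row likelihood
while counting every category's detection. Predictors = intercept,
rainfall (mm), solar exposure (MJ/m²), minimum temperature (°C), a moon
dummy coded new = 1 (so a positive coefficient means more activity on dark
nights), and the moon × solar interaction (solar exposure proxies cloud
cover, whose effect plausibly depends on moonlight). A night classified
`excluded` reaching the builder is an error, not a silent drop.

Intervals are two-sided Wald at a default **97.5% level** (z ≈ 2.2414),
taken literally; 95% is one configuration flag away since "97.5% CI" is
sometimes used loosely for ±97.5% quantiles. Significance is
interval-excludes-1; no multiple-testing correction is applied, matching
standard practice for these survey models.

## PDE activity index

`PDE = 100 × capture nights / operating nights`, computed per moon stratum
on disjoint night sets. The bootstrap resamples **camera sites** with
replacement (nights within a site are dependent, so night-level resampling
would understate uncertainty); the pooled estimator (total captures ÷ total
nights) is primary and the unweighted mean of per-site PDEs is also
reported, each with the standard deviation of B = 1000 replicates as its
SE. The seed is mandatory and fully determines the resamples.

## Synthetic surveys

The generator emulates the study conditions: 651 sites and a full year of
nights by default; site covariates on Tasmanian scales (elevation uniform
0–1500 m, roughness 0–100, isothermality ~N(50, 5)%, FPAR 0.1–0.95,
distance-to-town exponential with 15 km scale, vegetation
grassland/woodland/forest at 25/35/40%). Site coat probabilities are
softmax(B*·x) over z-scored covariates; default intercepts are calibrated
so the marginal category mix matches the surveyed image shares
(solid black ≈ 43%, mackerel brown ≈ 33%, blotched brown ≈ 16%, orange ≈
4.7%, tortoiseshell ≈ 3.1% over the five categories), and a handful of
non-zero slopes (elevation effects for orange +0.5, tortoiseshell +0.7,
blotched −0.3; FPAR +0.3 and forest +0.6 for mackerel) give recovery tests
signal. One dominant category per site (mean 2 resident individuals)
coexists with minority intruders (presence probability 0.3, capturing at
8% of the dominant rate), giving the modal-coat computation realistic tie
pressure.

Each resident individual triggers a capture on a given night with
probability 0.015 on full-moon nights, times a per-category new-moon
multiplier (defaults 1.4/1.5/1.3/1.0/2.0 for black/mackerel/blotched/
orange/tortoiseshell, spanning the 1.2–2 range observed in the field, with
orange flat; intermediate nights interpolate geometrically). This puts the
simulated PDE near the observed 3.4% (full) / 4% (new) anchors. Captures
expand into bursts of 1 + Poisson(2) images 10 s apart, confined to
19:00–23:59 so a night and its calendar date coincide. Individual IDs drop
with probability 0.3; black cats are never identifiable; 5.5% of images are
quality-unclassifiable; individuals carry a white-patch trait with
probability 0.02; rare tuxedo cats appear at 2×10⁻⁴ events per
camera-night. Weather (rain occurrence 0.45 with 4 mm exponential falls,
solar ~N(15, 5) MJ/m², minimum temperature ~N(8, 4)°C) is independent of
moon class by default — a deliberate null matching the finding of no
weather effects — with an optional correlation knob for stress tests.

What the generator does **not** emulate: spatial autocorrelation between
neighbouring cameras, territory structure or movement (captures are
independent across nights and sites given the rates), seasonal activity
cycles, weather-station distance error, and misidentification of
individuals (IDs are either correct or missing). Passing recovery tests
therefore show the estimators are correct *under the stated generative
model*, not that real surveys are free of these additional error sources.

## Problem sizes and runtimes

The test suite simulates at reduced but statistically meaningful scales
chosen as the package's own verification budget: a shared 300-site,
120-night survey for pipeline tests; a single 2,000-site, 365-night
replicate for end-to-end recovery; 50 replicates of 2,000 sites for Wald
coverage (the drawn dominant category is the response there, isolating the
estimator from modal-coat noise, which the end-to-end replicate covers
separately); and a 300-site year with all moon multipliers at 2.0 for
temporal recovery, checked on the solid-black category where the sample is
largest. The acceptance script runs the same computations from scratch,
seeding every random source from `--seed`.

## Known limitations

- The mean-synodic lunar model can misclassify nights within a few hours
  of a threshold crossing relative to a true ephemeris.
- Wald intervals are first-order; for categories modal at very few sites
  (tortoiseshell in small surveys) they can be anti-conservative, and
  quasi-separation triggers the divergence guard rather than a
  profile-likelihood fallback.
- The black-cat ratio estimator inherits the heterogeneity bias discussed
  above; it is reported, but downstream modelling deliberately uses modal
  categories instead.
- The per-site black individual tally is a modelling convention, not an
  observable; its floor-at-one rule slightly favours solid black as the
  modal type at sites with few black images.
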