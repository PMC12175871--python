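# Methods

This note documents the statistical models, the default parameters, and
the design choices behind prhismkit, in the order a user meets them:
scoring, agreement estimation, the simulation machinery, the synthetic
data generator, and the analysis pipeline.

## Instrument scoring

PRHISM ratings hold 13 principle responses on a 0–4 Likert scale, any of
which may be not applicable (NA), plus a single 0–4 overall-quality
judgment.  The PRHISM score is

    score = 100 · (sum of applicable responses) / (4 · n_applicable),

i.e. the mean over applicable items rescaled to 0–100.  The overall
judgment never enters the score; it exists only for agreement analyses.
A rating whose 13 principles are all NA raises an explicit error rather
than scoring 0 — silence here would bias score distributions downward.

The quality bands are published as integer ranges (0–25 poor, 26–50
mediocre, 51–75 good, 76–100 excellent) but scores are fractional
whenever n_applicable is not a divisor of the sum, so a rounding rule is
required.  We round half-up to the nearest integer before banding: this
preserves the printed integer bands exactly and makes boundary cases
(75.5 → 76 → excellent) deterministic.  Whether the original instrument
rounded before banding is unstated; any monotone rule differing only
inside (k, k+1) intervals would change at most hairline cases.

DISCERN holds 15 items plus an overall judgment, each 1–5.  The classic
total is the plain sum (16–80) and is only defined on complete ratings.
The modified DISCERN score drops the overall judgment and rescales the 15
items over the applicable ones, `100 · sum / (5 · n_applicable)`, mirroring
the PRHISM conversion so the two scores share a 0–100 scale; because
DISCERN items floor at 1, its minimum is 20, not 0.  The NA-denominator
rule generalizes the instrument's "applicable questions" wording to
DISCERN — an extrapolation, flagged in output whenever it is exercised.

Expert accuracy and harm are collected on the source tool's orientation
(1 = accurate / not harmful) and reverse-coded, value → 6 − value, so
that 5 = accurate / nonharmful matches the polarity of the other
instruments.  The recoding is an involution, which the tests exploit.

## Weighted kappa and its uncertainty

Two raters' ratings over K shared ordered categories are cross-tabulated
(subjects with an NA on either side are dropped pairwise) and summarized
with weighted Cohen's kappa, κ_w = (p_o − p_e)/(1 − p_e).  Weights are
identity (unweighted), linear, or quadratic; quadratic is the default
because it is the convention for Likert-type ordinal data (and makes κ_w
interchangeable with an ICC in large samples).  Every output records the
scheme actually used.  Tables in which both raters concentrate all mass
on the same single category have p_e = 1 and no defined kappa; these
raise a diagnostic error, and multi-rater summaries exclude such pairs
with a logged warning rather than imputing anything.

The standard error is the Fleiss–Cohen–Everitt large-sample variance of
weighted kappa in its non-null form.  A nonparametric bootstrap SE is
provided as an independent cross-check; the test suite verifies the two
agree within 15% on moderate-size tables, that the analytic SE scales as
1/√n under table replication, and that it vanishes on perfect-agreement
tables.  CIs are normal approximations, κ ± z·SE, deliberately not
truncated to [−1, 1]: a limit outside the parameter space is a visible
warning that the approximation is strained, and clipping would hide it.

### Multi-rater agreement

With R raters the reliability summary is the mean of all C(R,2) pairwise
kappas (15 pairs for 6 raters).  The pairs share subjects, so they are
strongly dependent and no closed-form variance of their mean is
trustworthy.  The default CI is therefore a delete-one-subject jackknife
of the mean-of-pairs: remove one video, recompute all pair kappas and
their mean, and use the jackknife variance of these leave-one-out means.
A naive alternative that propagates the per-pair SEs as if the pairs were
independent is available (`ci_method="independent"`), but only for
comparison: it understates the variance severalfold (see the power
section).  Measured over 200 synthetic 60-video studies per condition,
the 90% jackknife CI covers the generating kappa 86–90% of the time at
true kappas 0.3, 0.61 and 0.8 — close to nominal, slightly under because
the normal approximation ignores the estimator's skew at small n.

### Cross-instrument agreement

Validity analyses compare ratings given on different supports (PRHISM
overall 0–4, DISCERN overall and expert judgments 1–5, band codes 1–4).
Both scales are shifted to a common 0-based support (value minus the
scale minimum) and kappa is computed on the union of the shifted
supports; inter-category distances are never rescaled, so a one-step
disagreement costs the same on either instrument.  Any alignment of
unequal supports is a convention; an analysis that instead stretched the
4-category scale over the 5-category one would weight near-misses
differently, and published analyses of this kind rarely state their
choice — exact agreement with any particular study's numbers is therefore
not guaranteed.

### ICC

Continuous 0–100 scores are summarized with the two-way random-effects,
absolute-agreement, single-rater ICC — McGraw & Wong's ICC(A,1) — from the
two-way ANOVA mean squares, with the standard F-based CI.  It is
implemented directly (rather than delegated) so the CI level follows the
pipeline configuration; the test suite cross-checks both the point
estimate and the 95% CI against an independent implementation and against
hand ANOVA arithmetic.  Rows with missing cells are deleted listwise, the
usual convention for ICC; kappa analyses, in contrast, drop NAs pairwise
per analysis.  When the between-subject variance does not exceed the
error variance the ICC is reported at the 0 boundary with a warning.

## The copy model and power analysis

The simulation experiment answers: how many videos must 6 raters each
rate so that a z-test of the mean pairwise kappa rejects κ₀ = 0.53 with
80% power when the true agreement is κ = 0.61, at two-sided α = 0.10?

Raters are generated by a latent copy model: video i has a true category
Tᵢ ~ π over the 5 overall-quality levels; each rater independently
reports Tᵢ with probability θ and otherwise draws from π.  The pairwise
joint distribution is available in closed form, and its weighted kappa
reduces to exactly θ² for every weight scheme with unit diagonal — so any
target kappa in [0, 1] is attainable and `calibrate_theta` solves
expected_kappa(θ) = κ_target by bisection to |Δκ| ≤ 1e−6 (the θ²
identity is kept as a test oracle rather than hard-coded).  The model was
chosen over an ordinal-probit rater precisely because of this closed
form; the generation interface is pluggable if heavier-tailed rater
behavior is needed, and per-rater θ heterogeneity is supported but off by
default (the estimand is then the mean pairwise kappa).

Each power replicate simulates the full videos × raters matrix, computes
the mean pairwise kappa with its jackknife SE — the same statistic the
reliability analysis reports — and applies the two-sided z-test.
Replicates containing a degenerate rater pair are redrawn, capped at 5%
of the requested replicates (beyond that the marginal is too concentrated
for the design and the run aborts).  Degenerate replicates are a
non-event at the default settings; the cap exists for near-degenerate
marginals.  The minimum sample size is the smallest grid n whose
isotonically smoothed power curve (power is nondecreasing in n up to
Monte-Carlo noise) reaches the target; if none does, the achieved maximum
is reported instead of an extrapolation.

Measured calibration at the design point (n = 55, 6 raters, uniform π):
the type-I error of the jackknife-based test is 0.104 at 20,000
replicates — essentially nominal.

### Why 55 videos does not give 80% power here

Under this calibrated test, the power at 55 videos for κ = 0.61 vs
κ₀ = 0.53 is about 0.33, and it rises only slowly with n (≈ 0.50 by
n = 100).  A design that expects 80% at n = 55 is implicitly assuming a
much smaller SE for the mean of the 15 pair kappas — about SE/√15 of a
single pair, i.e. treating the pairs as independent replicates.  That
assumption is contradicted by the sharing of subjects and raters across
pairs: implemented as `se_method="independent"`, the same test shows a
type-I error of roughly 0.43 at the null.  Both variants are provided;
the jackknife is the default because it is the one whose test size is
honest.  The pilot category distribution that such a calculation would
also condition on was never published numerically (only as a histogram),
so the uniform marginal is the default stand-in; experiments with
plausible unimodal marginals move the jackknife power by only a few
points.  The package therefore reports the design-replication power as
computed rather than reproducing the 80% figure, and the corresponding
acceptance test documents the discrepancy.

## Synthetic study data

The generator produces study-shaped data, not real data.  What it
emulates:

* **Catalog** — n videos with source categories multinomial over the
  observed 8-category mix (10%, 7%, 15%, 0%, 25%, 22%, 20%, 2%;
  categories 1–4 are reliable sources), and length/views/months drawn
  from log-normals with medians 8 min / ~30,500 views / 29 months and
  spreads bracketing the observed ranges.  The log-normal shapes are
  explicitly arbitrary — only medians and ranges of the motivating
  catalog are known.
* **Latent quality** — Beta(2 + shift, 2) for reliable sources vs
  Beta(2, 2) otherwise (shift defaults to 1.0, giving mean 0.60 vs 0.50);
  increasing the shift provably widens the reliable-vs-other score gap,
  which the tests check at two shift values.
* **Truth categories** — videos are ranked by latent quality and sliced
  into contiguous blocks matching the target marginal, so the category
  distribution is controlled independently of the agreement level.
* **Overall-quality ratings** — copy-model reports at θ calibrated to the
  requested kappa (default 0.61); PRHISM (0–4) and DISCERN (1–5) overall
  judgments are independent reports of the same truth.
* **Item responses** — the rater's own overall judgment plus Gaussian
  jitter (mean = rater severity bias, default 0; SD = rater noise,
  default 0.7 — mostly 0/±1-step perturbations), rounded and clipped to
  the instrument support.  PRHISM items are NA with probability 0.10 per
  item (a placeholder — item-level NA frequencies are not reported
  anywhere — accepting a scalar or a per-item vector); DISCERN items
  default to no NA.
* **Expert judgments** — the truth category (a monotone map of latent
  quality) plus Gaussian noise (SD 0.8), clipped to 1–5, then stored in
  the source tool's original orientation so the pipeline exercises the
  recoding step.  With zero noise the experts agree perfectly with the
  overall judgments, which pins the θ = 1 invariant used in the tests.
* **Rater panel** — six raters with physician-years (8, 9, 10, 16, 24,
  37); the senior stratum is physician-years > 10, yielding a 3/3 split
  (a "10 or more" reading would move the 10-year rater; the report notes
  the convention).

What it does not emulate: rater-specific marginal styles, item-level
difficulty structure, correlation between NA propensity and content,
video-length effects on ratings, or any text content.  Passing tests on
this generator establish that the estimators recover known parameters
under a clean dependence structure — not that real rating panels behave
like copy models.

## Pipeline conventions

* CI levels: 90% for the primary reliability analyses, 95% for
  everything else; both configurable.  The primary success criterion is
  the lower 90% CI limit exceeding 0.53 (configurable), flagged per row.
* Per-item agreement uses the configured (quadratic) weights for complete
  items and falls back to unweighted kappa on pairwise-complete subsets
  whenever an item carries NAs, recording the scheme per row.
* The modified DISCERN score has no published banding; the PRHISM bands
  are reused for its 4-band classification so the score-level kappa lives
  on a common support.  Every such row carries a note saying so.
* The validity standard is the recoded expert accuracy item; harm is
  analyzed as parallel optional rows.  Pooled validity rows are means of
  per-rater kappas with a delete-one-video jackknife CI, for the same
  dependence reason as the reliability mean.
* All outputs are deterministic functions of (dataset, config); report
  bundles are byte-identical across reruns, and dataset generation is
  byte-identical per seed.

## Problem sizes used in the checks

The test suite and the acceptance script run entirely on simulated data:
2,000–10,000 Monte-Carlo replicates for type-I error and power, 1,000–
2,000 replicates per point on a 9-point sample-size grid, 200 seeded
60-video studies per condition for CI coverage, and exhaustive
enumeration of all 2×2 tables with n ≤ 6 plus 1,000 random K ≤ 5 tables
for the kappa oracle check.  These sizes give Monte-Carlo SEs well inside
the tolerances being asserted while keeping a full run to a few minutes
on one CPU.

## Known limitations

* Exchangeable raters (single θ) are the default; real panels are
  heterogeneous, and the observed spread of per-rater validity kappas in
  studies of this kind (0.07–0.65) is far wider than the copy model
  produces.
* The jackknife CI is first-order; at n ≪ 30 subjects per subgroup its
  coverage degrades and subgroup rows should be read with care.
* The normal-approximation CI can exceed [−1, 1] near the boundary; it is
  reported as computed, with a warning.
* Scale alignment for cross-instrument kappa is a convention (integer
  shift to a common 0-based support); other alignments are defensible and
  would give different numbers.
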