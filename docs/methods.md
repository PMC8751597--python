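# Methods

## Data model and preprocessing

A participant record holds an opaque id, integer age, years of education
(8–20 in simulated data), immediate/delayed 10-word recall counts (0–10)
at two waves, and 33 ordinal activity codes with 6 or 7 ordered
categories.  Missing cells are a dedicated sentinel (`None`), never a
coerced zero.  Cleaning follows the study protocol:

1. *Eligibility*: age 65–89 inclusive and a computable memory score at
   both waves (ΔM cannot be formed otherwise, so such records are
   excluded rather than imputed).
2. *Missingness filter*: a record is dropped iff its missing fraction
   over the 36 tracked cells (33 activities + education + the two wave
   scores) exceeds 15%.  The 36-cell denominator is a design choice; the
   protocol wording ("across all variables") does not fix one.
3. *Imputation*: remaining missing activity/education cells take the
   per-variable median over the full retained sample (not per age
   group — the simpler reading of "across participants"), rounded to the
   nearest valid category with ties rounded half up.  Filtering precedes
   imputation, matching the order in which the protocol states the two
   rules.  Imputation is idempotent and raises if a variable has no
   observed values at all.

Sign convention: ΔM = follow-up − baseline, so negative means decline.
All downstream statistics are sign-symmetric; only labels depend on this.

Age bins are the five inclusive 5-year groups 65–69 … 85–89; the design
matrix orders features as activities, then education, then baseline
memory, with activities entering as their integer ordinal codes (they are
ordered engagement levels; one-hot encoding would discard the ordering).

## Stage 1 — screening

*Distance correlation* is computed from doubly-centered pairwise-distance
matrices; dCor = sqrt(dCov² / sqrt(dVar_x² dVar_y²)), with dCor = 0 when
either dVar is zero.  Significance uses a permutation null: permuting the
response and recentering is equivalent to simultaneously permuting rows
and columns of the centered matrix, so each null draw costs one O(n²)
product.  The add-one estimator p = (1 + #{null ≥ obs})/(1 + R) keeps
p ∈ (0, 1].  The test is run activity-by-activity against ΔM within each
age group (education and baseline memory are never screened; they always
enter stage 2).

*Random-forest screen*: a regression forest (default 500 trees, minimum
leaf 5, features-per-split = ⌈p/3⌉ — conventional regression-forest
settings, config-overridable) is fit on all predictors; the null
distribution of each feature's impurity importance comes from refitting
on permuted responses, with the same add-one p-value.

Union selection: an activity is retained iff its minimum p over both
methods and all five groups is ≤ α, *inclusively* — a p-value printed as
.05 counts as significant.  No multiple-testing correction is applied, by
design; the log records the total test count (330 at defaults) so readers
can judge the expected false-positive load (~5% of inactive activities).

## Stage 2 — SVR + data-based sensitivity analysis

The regressor is an ε-SVR with RBF kernel on per-column standardized
inputs.  The "10-range grid" is read as 10 kernel widths, log-spaced
between the 0.1 and 0.9 quantiles of pairwise input distances (the
standard bandwidth bracket), selected by inner-holdout MSE (20%
validation split, seeded; ties go to the smaller width).  The remaining
hyper-parameters use the standard data-driven prescriptions:
C = max(|ȳ ± 3 s_y|) and ε = 3 σ̂ √(ln n / n) with σ̂ the noise scale
from 5-NN regression residuals (small-sample inflated).  On a noiseless
target ε collapses and the fit interpolates; on low-R² data the wide tube
keeps the support-vector set small.  `predict` evaluates the RBF decision
function explicitly through BLAS; it is the same function libsvm
evaluates (agreement to ~1e-14), just batched.

Importance of feature j: sweep it over L probe levels spanning its
observed range — for an ordinal feature with K ≤ L categories, exactly
its categories; L = 7 matches the maximum activity category count — while
all other features keep their observed values; average the predictions
over the reference rows at each level; take the **variance** of the L
level means as the sensitivity s_j (the dispersion measure is
config-switchable to range).  Relative importance r_j = s_j/Σs_k.
Sensitivities within 1e-9 (relative to the prediction scale) of zero are
snapped to exactly zero so an ignored input reports no importance.
A model with zero sensitivity everywhere is an error, not a zero vector.

The repetition loop draws an 80% subsample without replacement, refits
the SVR on it, and uses the subsample as the reference matrix (the
protocol's "random training sub-samples" precede the importance
computation; a fit-once variant is available via `refit=False` for
sensitivity checking).  Default R = 200 repetitions per group; summary SE
is the cross-repetition standard deviation divided by √R.  Predictive
accuracy is reported separately as the mean holdout R² over repeated
seeded 80/20 splits (default 100).

On linear-additive ground truth with standardized independent predictors,
r_j should rank with the squared standardized coefficient, which is what
the recovery tests assert.

## Stage 3 — trends

For each series (combined activities = per-repetition sum of activity
importances; education; baseline memory) the five groups' repetition
values enter a classical one-way ANOVA and all-pairs Tukey HSD, the
latter computed from the studentized-range distribution
(q = |mean diff| / sqrt(MSW/2 · (1/n_a + 1/n_b)), tail probability via
`scipy.stats.studentized_range`, numerically good to ~1e-6).  The trend
summary adds the rank correlation of group means against age order (0 is
reported for a flat series, where the correlation is undefined) and the
relative change (oldest − youngest)/youngest — the baseline of the
"percent increase by age 90" figure is ambiguous in general, so the
youngest-group-relative convention is fixed and stated.  **Caveat:**
repetitions are overlapping subsamples of one dataset, so these p-values
quantify estimator dispersion, not population inference
(pseudo-replication); a series whose importance is identically zero in
every repetition is skipped with a warning rather than tested.

## Synthetic cohorts

The generator emulates the survey's structure: group sizes default to the
study populations (757/840/800/518/295); ages uniform within bins;
baseline total recall ~ Binomial(20, p_g) with p_g declining from .55 to
.40; the total is split into immediate/delayed by a constrained binomial
so both components stay in 0–10; education ~ round N(13, 2.5²) clipped to
[8, 20]; activities independent Binomial(K_j − 1, ½) codes (an
equicorrelation knob exists, default off — treating the activity set as
weakly interconnected keeps recovery targets clean); then
ΔM = round(μ_g + α_g z(B) + β_g z(E) + Σ γ_gj z(A_j) + ε) with
ε ~ N(0, σ²) and z the within-group standardization; follow-up =
clip(B + ΔM, 0, 20) is resplit into components; finally activity and
education cells are set missing MCAR (default 5%).  Rounding reflects
integer word counts; clipping can attenuate realized changes at the score
bounds.  Every cohort has a ground-truth ledger (all coefficients + seed).

Preset magnitudes (`trend_preset`): eight active activities; per group
youngest→oldest, γ = .09/.16/.26/.40/.55 per active activity,
α = −1.10/−.72/−.47/−.29/−.15, β = .85/.55/.35/.21/.10, σ = 1.  These
were fixed by a power analysis: the squared coefficients are spaced
geometrically so the implied importance shares have monotone gaps well
above the cohort-level coefficient standard error (≈ σ_res/√n ≈ 0.07 at
200 per group), and σ = 1 puts per-group holdout R² near 0.5, the
accuracy scale typical of this design.  "null" copies the middle group's
coefficients to all groups; "reversed" flips the order.

What the simulation does *not* emulate: real activity marginals or
inter-activity correlation structure, informative missingness, survey
weights, practice effects, or any causal structure (education is drawn
independently of baseline memory).  Passing recovery tests therefore
shows the estimator chain works under a known additive model, not that
the substantive findings hold in real survey data.

## Seeds and determinism

One master seed drives everything; each stage derives an independent
child stream as `SeedSequence([master, crc32(stage_name)])`, so stages
are reproducible in isolation and a rerun with the same config writes
byte-identical artifacts.

## Problem sizes in the shipped checks

The test suite and the acceptance script run the pipeline on the
reduced "smoke" profile — 200 participants per group, 50 permutations,
50 sensitivity repetitions, 60-tree forests, 10 R² splits — which keeps
a full pipeline run under a minute while leaving every statistical check
well-powered; module-level checks use a few hundred observations.  Null
calibrations use 100 permutations with 200 (distance correlation) and 20
(forest) replicate datasets of n = 500.

## Known limitations

* Probe levels span the observed range, so for a long-tailed feature the
  extreme levels sit in sparse regions where an RBF model flattens toward
  its mean; importance shares for such features carry extra
  cohort-to-cohort variability driven by sample extremes.  At a few
  hundred records per group this, plus incidental O(n^-1/2) predictor
  correlations, bounds how finely two weakening series can be ordered —
  a five-group strict ordering of *every* series should not be expected
  from a single small cohort, even when each trend is individually clear.
* Stage-1 selection is marginal (per-activity); jointly redundant or
  conditionally relevant activities are out of scope.
* ANOVA/Tukey on repetition values inherit the pseudo-replication caveat
  above.
* The SVR hyper-parameter heuristics target attribution stability, not
  maximal predictive accuracy.
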