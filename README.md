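# actimem

Age-stratified machine-learning analysis of how much **daily activities**,
**education**, and **baseline memory** each contribute to predicting
6-year memory change in older adults — together with a synthetic-cohort
generator that makes the whole pipeline verifiable by parameter recovery.

## The problem

Longitudinal aging surveys assess episodic memory with a 10-word immediate
and delayed recall test; the *baseline memory* score B is the 0–20 sum of
the two counts, and the target of interest is the change
ΔM = B(follow-up) − B(baseline) over six years (negative = decline).
Participants aged 65–89 are split into five 5-year age groups, and each
group's records carry 33 ordinal daily-activity engagement codes (6 or 7
ordered categories each), years of education E, and B.  The scientific
question is not predictive accuracy but *attribution*: how much of the
explainable variation in ΔM belongs to the activities versus the
"historical" factors E and B, and how that balance shifts with age.

## The method

The pipeline makes no linearity assumption and proceeds in two stages per
age group *g*:

1. **Screening.** Each activity A_j is tested against ΔM by
   (i) distance correlation, dCor(A_j, ΔM), with a permutation null
   (p = (1 + #{dCor* ≥ dCor}) / (1 + R)), and (ii) a random-forest
   regression of ΔM on all predictors with a permutation test on each
   feature's impurity importance.  An activity is retained if p ≤ α in
   *at least one group by at least one method* (inclusive threshold,
   α = 0.05, no multiplicity correction); the union set is used everywhere
   downstream.
2. **Sensitivity-analysis importance.** An ε-SVR with Gaussian kernel
   (10-candidate kernel-width grid, data-driven C and ε) is fit on a
   random 80% subsample; each input is swept over L = 7 levels spanning
   its observed range (ordinal inputs: exactly their categories), and the
   variance of the level-averaged predictions is that input's
   sensitivity s_j.  Relative importance r_j = s_j / Σ_k s_k, so
   Σ_j r_j = 1.  This is repeated 200 times; the **combined activity
   importance** of a repetition is Σ_{j∈activities} r_j.  Across the five
   age groups the repetition-level importances are compared by one-way
   ANOVA and all-pairs Tukey HSD, and each series' monotone trend is
   summarized by rank correlation and relative change.

Real cohorts of this design come from registered-access surveys and are
not bundled; `actimem.simulate` generates structurally faithful cohorts
with *known* linear-additive ground truth
ΔM = round(μ_g + α_g z(B) + β_g z(E) + Σ_j γ_gj z(A_j) + ε), so every
stage can be validated by recovering the configured coefficients, and the
`"paper-like"` preset encodes the headline trend (activity effects grow
with age, α and β shrink).

## Worked example

```bash
actimem run --preset paper-like --profile smoke --seed 1 \
            --n-per-group 200 --out runs/demo
```

runs the whole chain on a simulated 1000-person cohort (reduced smoke
counts: 50 permutations / 50 repetitions) and writes, among other
artifacts, `trend_summary.csv`:

```
series               F        p_anova   rank_corr rel_change mean_65-69 mean_70-74 mean_75-79 mean_80-84 mean_85-89
COMBINED_ACTIVITIES  7091.9   6.8e-252   1.0       8.73      0.100      0.388      0.543      0.905      0.977
EDUCATION_YEARS       947.5   1.0e-147  -1.0      -0.98      0.256      0.150      0.121      0.046      0.004
BASELINE_MEMORY      3380.4   5.6e-213  -1.0      -0.97      0.644      0.463      0.337      0.049      0.019
```

(13 of 33 activities pass screening on this cohort; per-group holdout R²
runs 0.32–0.67.)  Read: in the youngest group the combined daily
activities carry ~10% of the attributable importance while baseline
memory carries ~64%; by 85–89 the activities carry ~98%.  The rank correlations (+1 / −1) say the group
means are strictly monotone in age, the ANOVA p that the between-group
differences dwarf the repetition-level dispersion (note these repetitions
share data — see `docs/methods.md` on pseudo-replication), and
`selection_pvalues.csv` records the stage-1 p-value matrix with entries
≤ α flagged.  `actimem simulate` writes a cohort CSV plus its
ground-truth coefficient ledger; `actimem selftest --out runs/st` runs
quick structural health checks.

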