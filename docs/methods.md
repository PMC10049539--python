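# Methods

## Data model

A cohort is a table of subject-visits over a fixed six-analyte serum panel —
L-arginine, citrulline, ornithine, ADMA, MMA, SDMA — all in µM, with three
labels: group (`long_covid` / `control`), trial arm (`active` / `placebo` /
`none`), and timepoint (`baseline` / `day28`).  Concentrations must be
finite and strictly positive; controls carry a single baseline visit;
`(subject_id, timepoint)` is unique.  Missing values are rejected rather
than imputed: no imputation rule is defensible for a six-analyte targeted
panel, and complete panels are the norm for LC-MS/MS targeted assays.  All
matrix views use the canonical analyte order above.

## Derived indices

Three dimensionless ratios summarise NO substrate availability per
subject-visit: arg/ADMA (substrate vs the dominant endogenous NOS
inhibitor), GABR = arg/(orn + cit) (substrate vs its catabolic products),
and arg/orn (inverse marker of arginase flux).  GABR ≤ arg/orn always.
Group summaries are means of per-subject ratios, never ratios of group
means — the two differ under skew, and only the former matches how such
panels are reported.  Paired designs use simple concentration differences
(day 28 − baseline, µM) but base-10 log-ratios for the indices, which makes
relative changes symmetric and visit-swap antisymmetric.

## PLS-DA

Class membership is coded as a dummy binary response y ∈ {0, 1}.  PLS1 with
NIPALS X-deflation extracts orthogonal latent variables: scores T = XR,
inner regression y = Tq.  Prediction re-adds the training mean of y and
thresholds at 0.5 — the symmetric choice for 0/1 coding; no prior
correction is applied for class imbalance, and per-class rates are reported
instead.  The single predictive direction w = Rq (unit norm) carries sample
scores and variable weights; its sign is fixed so the class-1 training mean
score is the larger, making weight plots reproducible.

Preprocessing is autoscaling (train-fold mean and SD), the chemometrics
default for panels spanning three orders of magnitude (~200 µM arginine vs
~0.1 µM MMA); without it the first latent variable is arginine-dominated.
Mean-centering only, or no preprocessing, are selectable (`scale=`).

Numerical notes: extraction stops early when the residual X carries no
covariance with y (tolerance 1e-12), with a warning when that truncates a
request; at full rank the PLS prediction equals OLS on centred data
(checked to 1e-8 in the tests, alongside a cross-check against an
independent PLS implementation); one fit yields the prediction path for
every component count, which the inner CV loop exploits.

## Repeated double cross-validation

Defaults: 10 outer and 8 inner cancelation groups, 50 repetitions,
candidate complexities 1–6.  Folds are stratified random partitions: per
class, fold counts differ by at most one, remainders going to the least
loaded folds (so k = n degenerates to leave-one-out).  Per outer fold, the
inner CV selects the number of latent variables maximising inner accuracy
(ties break to the smallest — parsimony, and deterministic); the model is
refit on the whole outer-training portion and scored on the held-out fold.
Per-repetition accuracy is computed on the pooled outer predictions, so the
identity `overall = (r1·n1 + r0·n0)/(n1 + n0)` linking overall and
per-class rates holds exactly within each repetition.  Reported `x ± y`
values are means ± SDs over repetitions; complexity is summarised over all
outer models.  Canonical weights from every outer model are collected
(already sign-aligned by the class-mean convention); a variable is called
significant when the central 95% interval of its weights excludes zero.

Randomness derives from a single seed via spawned child sequences per
repetition, so identical inputs and scheme reproduce results bit for bit.

## Permutation test

The observed accuracy comes from the full repeated run; each of B = 1000
label shuffles is scored by a single double-CV pass, and
p = (1 + #{null ≥ observed})/(B + 1), with floor 1/(B + 1).  Re-running the
entire 50-repetition rDCV per shuffle is available (`full_rerun=True`) but
needless at these sample sizes: the null distribution of a single pass has
the same centre, and 1000 full reruns cost 50× more for no change in the
decision.  For the 46/11 design the null centres near the 80.7%
majority-class rate, not 50% — p-values must therefore be read against the
empirical null, which the result object carries.

Calibration: with the observed statistic taken from a multi-repetition
average and nulls from single passes, the p-value is conservative under H0
(the observed is less dispersed).  The calibration tests therefore use an
exchangeable configuration (1 repetition) where uniformity holds exactly up
to the discreteness of accuracy.

## Univariate battery

Both groups must pass Shapiro–Wilk at α = 0.05 to use Student's t-test with
pooled-SD Cohen's d and the t-based 95% CI; otherwise Mann–Whitney U
(exact when min n ≤ 25 without ties, tie-corrected normal approximation
otherwise) with the rank-biserial correlation r = 2U/(n1·n2) − 1 and a
Hodges–Lehmann interval (Moses order-statistic construction with the
normal-approximation critical rank) for the location shift; the raw mean
difference is reported in both branches.  Signs follow (first − second)
throughout, so swapping groups negates differences and effect sizes.
Three or more groups: one-way ANOVA omnibus F plus Tukey HSD contrasts —
the standard simultaneous pairwise procedure for this design.  No
multiplicity correction is applied across panel variables; p-values are
reported per variable as is conventional for targeted panels of this size.

## Synthetic cohorts

The generator emulates the two study designs at their published summary
statistics, which are also its defaults: a cross-sectional baseline draw
(two long-COVID arms of n = 23, controls n = 11; per-group means/SDs for
the six analytes) and a paired intervention draw (day 28 = baseline +
per-metabolite normal change, per-arm change means/SDs, optional
baseline-change correlation, default 0).  Margins are normal — matching the
mean ± SD parameterisation of the sources — independent across metabolites
by default because no covariances are published; both choices are
overridable (full correlation matrix; moment-matched lognormal margins).
Positivity is enforced by redrawing rows with any non-positive value.

What this emulates and what it does not: group-level location and scale
structure, class imbalance, and paired-visit designs — but not the
inter-metabolite correlation (ADMA–SDMA correlate strongly in real serum),
right-skew of concentration ratios, or assay drift.  Multivariate
figures of merit on synthetic cohorts are therefore bounds/behaviour
checks, not point reproductions of any real-data result.

Known quantitative limitation: positivity redrawing truncates each margin
at zero, biasing margins whose mean/SD ratio is small; the worst case at
the default parameterisation is the placebo-arm MMA (mean/SD = 2.33),
where the realised mean is +1.1% and the SD −3.2% relative to the
nominal values.  All other margins are affected below 0.5%/1.6%.

## Problem sizes

The defaults analyse 57 × 6 (baseline) or 46 × 6 (delta) matrices; a full
50-repetition rDCV runs in ~2 s and the 1000-randomisation permutation test
in ~40 s on one CPU.  Test-suite simulations use reduced designs (e.g.
5-fold outer loops, B = 25–200) chosen to keep each statistical check
well-powered at its stated tolerance.
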