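# Methods

`ccmetab` analyzes diet effects on an untargeted metabolome measured in a
genetically diverse, multi-strain cohort — the setting of a Collaborative
Cross (CC) gene x diet study in which dams on a vitamin-D-sufficient (VDS)
or -deficient (VDD) diet are profiled across 8 inbred strains.  The central
statistical problem is that strain effects on metabolite concentrations are
large enough to mask the diet effect in a multivariate model; the workflow
therefore residualizes strain before supervising on diet.

## Preprocessing

Raw platform abundances are processed in three steps, in this order:

1. **Run-day median normalization.**  For each metabolite and each
   instrument batch (run day), values are divided by the within-day median
   of observed values.  This removes per-(day, metabolite) multiplicative
   batch factors exactly (the invariance is tested, not approximate).  A
   (metabolite, day) block with no observed values, or a zero median, is an
   error naming the block — silent propagation would poison every later
   stage.
2. **Rescaling to unit median.**  Each metabolite is divided by its overall
   median so compounds with very different numeric ranges carry equal
   weight in the multivariate model.
3. **Minimum-value imputation.**  Cells missing because they fell below the
   limit of detection (LOD) are filled with the metabolite's minimum
   observed value, and flagged.  Imputation runs last so imputed values are
   on the normalized scale.

Medians use the standard mean-of-central-order-statistics convention for
even counts.

## Strain residualization

For every metabolite an ordinary least squares model

    metabolite ~ diet + strain

is fit with treatment coding (diet reference VDS; strain reference the
baseline strain, default CC011), and the fitted strain coefficients are
subtracted from the corresponding samples.  Baseline-strain samples are
returned bit-unchanged.  The model is deliberately additive: strain x diet
interactions are left in the residuals so the downstream diet model can
find strain-specific responses.  All metabolites share one design matrix,
so the fits are a single vectorized least-squares solve — algebraically
identical to looping `lm()` per metabolite (verified against statsmodels in
the tests).  Residualization is idempotent, and refitting the same model on
corrected data returns strain coefficients of zero to numerical precision.

## OPLS-DA

The diet model is orthogonal projections to latent structures discriminant
analysis with a single predictive component, implemented from scratch in
the standard NIPALS formulation (see the `oplsda` module docstring for the
update equations).  Choices that matter:

- **Scaling**: unit variance (autoscaling) after centering, the default of
  the commercial and R implementations this emulates; Pareto and
  center-only are exposed.
- **Class encoding**: -1/+1, centered by the class mean.
- **Orthogonal dimension `k_ortho`**: an explicit integer (default 1 for
  direct calls), or `"auto"` — forward search keeping an extra orthogonal
  component only while cross-validated Q2 improves by more than 0.01
  (capped at 5).  The pipeline uses `"auto"`: cross-validated software in
  this family selects the orthogonal dimension rather than forcing one, and
  forcing an orthogonal component on data that carry no class-orthogonal
  structure feeds a pure noise direction into the orthogonal VIP, inflating
  false selections.
- **Q2**: stratified K-fold cross-validation (default 7 folds, seeded).
  The matrix is scaled once on the full data; each held-out fold is
  filtered through the *training* fold's orthogonal components before
  prediction, and PRESS is accumulated against the training-fold class
  mean.
- **R2X** is reported per component; Q2 <= R2Y always holds on the same
  fit.

### Variable importance

With one predictive component and unit-norm weights, the predictive VIP
reduces to `sqrt(p) * |w_j|`.  The orthogonal VIP weights each orthogonal
component by its explained X-variance (the published "VIP_o" convention —
the commercial VIP algorithm itself is proprietary, so an open convention
is used and stated).  Both satisfy `mean(VIP^2) = 1`.  The combined score

    rmsVIP = sqrt((VIP_pred^2 + VIP_ortho^2) / 2)

drives feature selection in diet models at the threshold rmsVIP >= 1.5
(inclusive); strain signature models select on plain predictive VIP.  When
a model has no orthogonal component, rmsVIP falls back to VIP_pred.

### Permutation significance

Class labels are permuted uniformly; every permutation triggers a full
refit including cross-validation.  p-values use the add-one rule
`p = (1 + #{stat_perm >= stat_obs}) / (1 + n_perm)` so the smallest
attainable value is `1/(n_perm + 1)` and p = 0 is impossible.  Defaults:
1000 permutations.

**Permutations and residualization.**  Residualizing `metabolite ~ diet +
strain` on the full cohort leaves the *observed* labels' fitted diet
contrast in every metabolite.  Permuting labels on the already-corrected
matrix therefore compares the observed model against permutations that
never enjoyed that fit; measured on pure-noise data (n = 40, p = 60) this
rejects a true null 33% of the time at a nominal 5%.  The pipeline's
`diet_effect_test` instead re-estimates the adjustment under each permuted
labeling before the refit, which restores the nominal 5% rejection rate
without costing power.  The orthogonal dimension is selected once on the
observed labels and held fixed across permutations, so all refits share
the model complexity.  `permutation_test` (labels permuted on the matrix
as given) remains available as the module-level primitive for models that
need no covariate adjustment.

## Stratified statistics

- **Fold change** is the ratio of arithmetic VDD to VDS group means,
  population-wide or within strain.  A non-positive VDS mean yields a
  flagged NaN.  The robust-change filter applies the 1.5-fold threshold
  symmetrically (`max(FC, 1/FC) >= 1.5`), so decreases count like
  increases.
- **Percentage reduction** for plasma 25(OH)D is
  `100 * (VDD_sample - VDS_mean)/VDS_mean` with the VDS mean taken within
  strain; the per-strain mean of per-sample reductions equals the reduction
  of the strain mean (linearity, asserted exactly).
- **Assumption-gated tests**: per-group Shapiro-Wilk at alpha = 0.05 (a
  group under 3 observations is untestable and assumed normal; a constant
  group counts as non-normal); any failure routes to Wilcoxon rank-sum /
  Kruskal-Wallis.  If normality stands, Bartlett's test gates pooled
  t/ANOVA vs Welch t/ANOVA.  Identical constant data short-circuit to
  p = 1 with a warning, and a group of fewer than 2 observations falls
  back to the nonparametric branch with a warning.
- **Median test**: Brown-Mood classification against the grand median
  (ties counted at-or-below), chi-square on the contingency table
  (Yates-corrected on 2x2, matching the common implementation), with an
  exact two-sided Fisher branch when a 2-group table has any expected
  count below 5.
- **Tukey-Kramer HSD** uses the studentized-range distribution with
  Kramer's unequal-n correction (plain Tukey for balanced groups) and an
  insert-and-absorb compact letter display: one column initially holds all
  groups; each significant pair splits every column containing both;
  columns contained in another are absorbed; letters are ordered by group
  means.  Strain-effect tests and letters operate on per-VDD-sample
  relative responses (`VDD_sample / within-strain VDS mean`), mirroring the
  fold-change bars they annotate.
- Raw p-values are reported at alpha = 0.05; BH-adjusted q-value columns
  are emitted additionally and labeled as an extension.

## Enrichment

Over-representation of the VIP selection against user-supplied metabolite
sets: each set is intersected with the universe (all metabolites present
after preprocessing — the matched-universe convention), sets smaller than 2
after intersection are skipped with a note, and the one-sided hypergeometric
upper-tail probability of the observed overlap is computed with exact
integer arithmetic (correctly rounded, so closed-form extremes are exact).
Benjamini-Hochberg FDR is applied across tested sets; significance is
FDR < 0.05.

## Synthetic-data generator

The generator emulates the study design so the pipeline can be exercised
end to end with known ground truth.  On the natural-log scale,

    log x_ij = b_j + s(strain_i, j) + 1[VDD_i] * d_j(strain_i) * ln 2
               + log f(day_i, j) + e_ij

with metabolite baselines `b_j ~ N(0,1)`; strain main effects on a fraction
(default 0.3) of metabolites, `N(0, 0.5)` per (strain, metabolite); diet
effects `d_j` (log2) on 78 of 654 metabolites; per-(day, metabolite) batch
multipliers `exp(N(0, 0.1))` over 4 run days; residual noise with
coefficient of variation 0.3 (`sigma = sqrt(ln(1 + cv^2))`); and the lowest
2% of each metabolite's raw values censored to missing.  Group sizes are
drawn from {3,...,6} and nudged to a 72-dam total; an explicit per-group
override is available.

Parameter choices and their anchors:

- **Scale** (8 strains, 72 dams, 3-6 per group, 654 metabolites, 78
  diet-responsive) matches the study design.
- **Responder strains**: by default CC017 carries a 4.5-fold total response
  on a 13-member "fatty_acids" set and CC032 a 9-fold response on a
  15-member "glycerophospholipids" set — the magnitudes the study reports
  for its two most responsive strains.  Responder interactions top the
  population effect up to the stated total, so the target strain's
  expected VDD/VDS ratio of group means equals the spec'd fold exactly
  under the log-normal model.
- **Population diet effect sizes** are not printed anywhere; the default
  draws |log2 FC| ~ Uniform(0.5, 1.5) with 80% increases — moderate
  effects, predominantly upward, spanning just-detectable to severalfold
  at n = 72.  Chosen once as a realistic middle ground; the robust
  (>= 1.5-fold) subset then emerges from the interplay of population
  effects and responder interactions rather than being set directly.
- **Run-day assignment** is a diet-paired rotation: the two diet arms of
  each strain are paired and both members of a pair share a run day,
  leftovers continue the rotation.  Every day contains every group (so the
  per-day medians are estimable) and run day is unconfounded with diet, as
  in a randomized, diet-blocked acquisition order.  A plain round-robin
  over diet-grouped samples associates day with diet strongly enough to
  inflate multivariate null rejection severalfold, so the pairing is load-
  bearing for the generator's null calibration.
- **25(OH)D**: strain VDS means and depletion fractions for CC011
  (15.9 ng/mL, 34%), CC017 (7.4 ng/mL, 57%) and CC032 (66%, highest VDS
  mean) follow the printed values; the other five strains are synthetic
  interpolations of that range.  Noise is multiplicative log-normal,
  mean-corrected so sample means recover the inputs; values are strictly
  positive.
- **Seeding**: one global seed fans out to independent substreams per
  component (group sizes, baselines, strain effects, diet effects, day
  factors, noise), so outputs are bit-reproducible and components can be
  varied independently.

What the generator does *not* emulate: raw spectra, retention behavior,
correlated metabolite blocks (pathway co-regulation), heteroscedastic
platform noise, drift within a day, or litter covariates.  Passing
recovery tests therefore demonstrate that the pipeline finds the injected
multiplicative structure at realistic scale and noise — not that it is
robust to every artifact of real LC-MS data.

## Problem sizes in the test suite

The default suite runs the full 72 x 654 design where the claim depends on
scale (end-to-end recovery: 25 replicates at 199 permutations; permutation
calibration: 200 null datasets at n = 40, p = 100, 99 permutations) and
scaled-down cohorts (4 strains, 40 dams, 60-120 metabolites) for unit-level
properties, keeping the whole suite in the minutes range on one CPU.

## Known limitations

- Only two-class OPLS-DA is provided; multi-strain structure is explored
  via PCA and one-vs-rest signature models.
- The gated test battery reports the branch taken but does not adjust
  p-values for the pretesting (matching common practice in the workflow it
  mirrors).
- Welch ANOVA delegates to pingouin; with very small groups (n = 2) the
  gate falls back to nonparametric tests.
- The compact letter display is the standard insert-and-absorb heuristic;
  letter assignments are unique up to alphabetical relabeling.
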