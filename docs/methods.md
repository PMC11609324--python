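# Methods

This note documents the models, estimators and simulation design behind
`ernconn`, the numerical choices that matter, and what the synthetic tests
do and do not establish about real data.

## Scientific setting

The package analyses the relationship between parental psychopathology and
the resting-state functional connectivity of four emotion-regulation
networks (ERN1–ERN4) in youth, and asks whether that connectivity mediates
the association between parental and later youth psychopathology. Four
networks are defined meta-analytically by peak coordinates of task
activation clusters: ERN1 (dorsolateral prefrontal / fronto-parietal,
cognitive regulation), ERN2 (ventrolateral prefrontal), ERN3 (subcortical /
limbic, emotion generation and reactivity), ERN4 (an integrative
subcortical–cortical network linked to interoception). Connectivity is
summarized per subject as 10 features: mean Fisher-z connectivity within
each network (4) and between each unordered network pair (6).

## Atlas mapping

ROI peaks in MNI millimetres are expanded into spheres (default radius
6 mm); a voxel belongs to a sphere when its **center** lies within the
radius — an unambiguous rule that matches common sphere-ROI practice. The
NIfTI affine is the single source of truth for mm ↔ voxel conversion, and
voxels of overlapping same-network ROIs are counted once (union). Weak
(network, parcel) overlaps are dropped: by default all rows with voxel
count at or below the first quartile of the pooled voxel-count distribution
(linear-interpolation quantile; a per-network variant and a fixed threshold
are available). Each surviving parcel is then assigned to the single
network with the largest voxel overlap; exact ties go to the lowest network
index with a warning. Peaks that land in background are dropped with a
warning rather than snapped to the nearest parcel, because snapping invents
data. Every network must retain at least two parcels or mapping fails,
since a within-network mean over fewer than two parcels is undefined.

The packaged 36-row network definition is a synthetic stand-in with
approximate anatomical MNI coordinates for the regions of the four
networks; it exercises the pipeline and is not a published coordinate
table.

## Connectivity features

Correlations are variance-stabilized with the Fisher transform
z = atanh(r), and **all analyses stay on the z scale** — no back-transform.
Within-network features average the k(k−1)/2 unique off-diagonal parcel
pairs; between-network features average all k_a × k_b cross pairs. The
diagonal is always excluded; asymmetry beyond 1e−8 and non-finite
off-diagonal entries are errors, not silently repaired.

## Harmonization

Site/scanner batch effects are removed with a parametric empirical-Bayes
location/scale model (the ComBat family): per feature, an OLS stage
estimates batch intercepts and covariate effects; standardized residuals
give per-batch location and scale estimates which are shrunk toward a
normal (locations) and inverse-gamma (scales) prior, hyperparameters by
method of moments across the 10 features, iterated to convergence
(absolute change < 1e−6 or 100 iterations). Covariates preserved by
default: youth age, sex, and the six parental/youth psychopathology sum
scores. Only the 10 connectivity features are adjusted. A single batch
yields the identity adjustment. The nonparametric ComBat variant and
reference-batch mode are out of scope. Note that batch means can only be
corrected up to their own sampling noise, and EB shrinkage deliberately
under-corrects slightly in exchange for stability; tests therefore check
residual site differences against sampling-noise-scale tolerances, not
zero.

## Association models

One linear mixed model per (psychopathology scale × connectivity feature)
cell — 3 × 10 = 30 models in the main grid. The feature is the outcome;
fixed effects are the scale score, youth age and sex; family is a random
intercept to account for siblings. Coefficients are standardized: outcome
and continuous predictors z-scored on the analysis sample, sex
contrast-coded ±0.5. Complete-case analysis; no imputation.

The fitter profiles the likelihood of the single-variance-ratio
random-intercept model: given λ = τ²/σ², GLS estimates and the residual
quadratic form have closed forms in per-family sums, so REML/ML reduces to
a one-dimensional Brent search over log λ (interior tolerance 1e−8, with
an explicit λ = 0 boundary check). It matches `statsmodels` `MixedLM` to
~1e−6 in coefficients and ~1e−5 in log-likelihood, at roughly two orders
of magnitude less cost — which is what makes resampling-based inference
over the grid feasible.

Inference is by **family-level case bootstrap** (families resampled with
replacement, default B = 1000): each replicate reweights the precomputed
per-family sufficient statistics, with the λ search warm-started in a ±3
log-unit window around the full-sample estimate at tolerance 0.1 (verified
to reproduce tight-tolerance intervals to 4 decimals). Percentile 95% CIs;
two-sided p = 2·min(share ≤ 0, share ≥ 0) with the (1 + count)/(B + 1)
correction. Failed refits are dropped and counted; a cell with > 5%
failures is flagged. The case bootstrap was chosen over residual/parametric
schemes for robustness to misspecification. Benjamini–Hochberg FDR is
applied pooled across the whole grid by default (a per-scale family is
available).

## Multilevel mediation

X (parental scale) is family-constant, M (a connectivity feature) and Y
(youth follow-up scale) are child-level. The mediator is decomposed into
the observed family mean (between) and the deviation from it (within), so
the M → Y path is estimated separately within and between families — the
two paths can reflect different processes. Estimation is two mixed-model
equations, both with a family random intercept, both by **maximum
likelihood** (not REML) so that the free model (separate within/between
coefficients) and the constrained model (single coefficient) can be
compared by a likelihood-ratio chi-square with df = 1:

- M ~ X + age + sex → a
- Y ~ X + M_between + M_within + age + sex → c′, b_between, b_within

indirect = a·b_between, total = c′ + indirect. The indirect-effect CI is
Monte-Carlo by default (a and b_between drawn from their per-equation
normal sampling distributions, percentile bounds of the product; the two
equations share no parameters, so independence is reasonable); a
family-level bootstrap alternative is provided. Observed family means were
chosen over latent (multilevel-SEM) centering because they are closed-form
and directly testable; with small clusters the observed mean is a noisy
estimate of the family mean, which attenuates/blends the two b paths —
with ~30% sibling pairs the simulation studies show a small upward bias of
order +0.01 on b_between, within the acceptance tolerances. Tables in
which siblings carry discrepant parental scores are rejected at load; a
utility subsamples one random child per discrepant family. With
all-singleton families the within path is inestimable and the fit raises
an error rather than returning a coefficient. Baseline-adjusted variants
add the matching parent-reported youth baseline score to the Y-equation
covariates. FDR is applied over the grid's indirect-effect p-values.

## Synthetic cohorts

The generator's defaults are the study conditions: 3952 families with the
observed 3709/236/7 split of one/two/three participating children
(≈ 4200 subjects), 21 sites, and a parent–youth score correlation target
of 0.15 on the latent scale (the discrete marginals attenuate it to ≈ 0.13,
inside the reported 0.1–0.2 band). Sum scores use negative-binomial
marginals coupled by a Gaussian copula — means ≈ 7/5/25 for parental
internalizing/externalizing/total and ≈ 3/2.5/7 for the youth scales, with
small dispersions for realistic right skew; no distributional form is
published for these instruments, so these are the package's own choices.
Connectivity features are network-pair means (within 0.28–0.40 > between
0.10–0.15 on the z scale) plus planted standardized effects, a family
random intercept (SD 0.05), subject noise (SD 0.10), additive site offsets
(SD 0.10) and multiplicative site factors (log-uniform 0.8–1.25). Planted
standardized effects β are realized exactly by the slope
β·σ₀/√(1−β²) on the z-scored score, with σ₀ the noise scale, so the
post-harmonization standardized coefficient targets β itself. A
reported-effects configuration plants the grid of significant
cells (|β| = 0.04–0.05) and a direct mediation effect of 0.17.

Matrix-level emission expands each subject's features into a symmetric
parcel matrix whose block means equal the features exactly (pair jitter is
de-meaned per block), so extraction is tested end-to-end against planted
truth. The mediation generator draws from the structural model itself with
unit-variance scaling so planted paths are directly recoverable.

What the generator does **not** emulate: real BOLD time series or their
preprocessing, spatial autocorrelation between parcels, non-Gaussian
feature distributions, missing data, informative dropout between baseline
and follow-up, or genetic confounding between parental scores and youth
brain features. Passing tests therefore establish the statistical
machinery — calibration, recovery, invariances — not the substantive
claims one could make on real cohort data.

## Problem sizes and calibration results

Simulation-based checks use the study-scale cohort (≈ 4200 subjects) for
effect recovery (20 replicates), n ≈ 1000 with B = 200 over 100 replicate
grids for null calibration, and 2000 families with 30% sibling pairs over
50 replicates for mediation recovery — sizes chosen so the whole suite
runs on a single CPU in well under half an hour while keeping Monte-Carlo
error below the tolerances being tested. The acceptance script re-runs the
same computations at moderately reduced replicate counts and prints only
quantities it computed in that run.

## Known limitations

- Random intercepts only; no random slopes, no crossed random effects
  (e.g. site as a second random factor — site enters through harmonization
  instead).
- Percentile bootstrap CIs (no BCa correction); p-values inherit
  percentile discreteness at small B.
- Observed-mean centering biases between-family paths with small clusters
  (documented above).
- The EB harmonization is property-level compatible with, but not
  bit-identical to, the reference ComBat implementations.
- The bootstrap resamples the mixed model only; it does not propagate the
  estimation uncertainty of the harmonization stage (which shares data and
  covariates with the association models). In composite null simulations
  (harmonize-then-test at n ≈ 1000) this inflates the per-cell rejection
  rate slightly, to ≈ 0.059 against a nominal 0.05; the association module
  in isolation is calibrated. Real-data analyses that harmonize first
  inherit this mild anti-conservatism, as does any pipeline that treats
  harmonized features as fixed inputs.
- Twin/zygosity structure beyond "one row per subject" is out of scope.
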