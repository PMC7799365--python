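# Methods

## Problem and model

The pipeline asks whether common genetic variation, taken jointly, relates
to cognitive — as opposed to motor — phenotypes in ALS, and distils that
relationship into a per-subject polygenic risk score. Its stages are a
linear mixed-effects (LME) trajectory model, a sparse canonical
correlation analysis (sCCA) stabilised by resampling, and association
stages for the resulting scores.

### Trajectory model

For each clinical measure (eight ECAS cognitive scores, ALSFRS-R, UMN and
LMN burden), observations y_ij of subject i at visit month t_ij follow

    y_ij = β₀ + β'x_i + β_t t_ij + b₀ᵢ + b₁ᵢ t_ij + ε_ij

with x_i = (age at baseline, onset-to-baseline lag in years, college
education, bulbar onset), (b₀ᵢ, b₁ᵢ) a bivariate normal random intercept
and slope, and maximum-likelihood (not REML) estimation, via statsmodels
`MixedLM`. Covariate columns are centred inside the fitter; as a result
the population intercept is the expected baseline at the cohort-mean
covariate profile, and per-subject **adjusted** estimates

    intercept_i = β₀ + b̂₀ᵢ        slope_i = β_t + b̂₁ᵢ

(with b̂ the empirical best linear unbiased predictors) are invariant to
affine shifts of covariate coding. Subjects with one observation retain an
intercept but no slope; non-convergent measures are flagged and excluded
downstream. The optimizer tries lbfgs, then cg, then Powell, keeping the
first converged result.

The univariate SNP scan (one extra dosage fixed effect per model,
45 × 11 = 495 models) uses a two-stage estimator by default: the
random-effects covariance and residual scale are estimated once per
measure by full ML, and each SNP's fixed effect is then profiled by exact
generalized least squares with those components plugged in — the standard
fast approximation in genetic association, exact given the variance
components, and accurate here because one added covariate perturbs the
variance estimates negligibly (dosage coefficients agree with full
per-model ML to ~2% and Wald p-values to ~0.01 on test cohorts, and the
null rejection rate at α = 0.05 is calibrated). A ``method="ml"`` toggle
refits every model by full maximum likelihood.

### Sparse CCA

With X the z-scored subjects × 11 adjusted-baseline matrix and Z the
z-scored subjects × 50 genetic matrix, the solver maximises the bilinear
objective u'X'Zv subject to ‖u‖₂ ≤ 1, ‖u‖₁ ≤ c_x (likewise v) — the
penalized matrix decomposition with L1 constraints. Each subproblem has
the closed form w = S(a, δ)/‖S(a, δ)‖₂ with soft-threshold level δ found
by bisection so the L1 constraint is active (tolerance 1e-8; coordinates
left with ≤ 1e-8 of mass by a breakpoint are zeroed so selection counts
are exact; exactly tied inputs resolve to the lowest index). Penalties
t ∈ (0, 1] map to budgets c = max(1, t·√dim); the floor at 1 is the L1
norm of any unit-L2 vector, so the tightest setting forces exactly one
active variable. Initialisation is the leading right singular vector of
X'Z by power iteration from a fixed start; only the first variate pair is
computed, and the reported canonical correlation is the Pearson
correlation of Xu and Zv on the data. Sign convention: (u, v) are flipped
jointly so Σuⱼ ≤ 0, orienting the genetic composite as a risk score
(higher composite ↔ worse clinical scores); without a fixed orientation,
medians over resampled fits would be meaningless.

Both X and Z are standardised before fitting. Standardising Z (the
clinical-only scaling is the minimal reading) prevents allele-frequency
differences from dominating the weight scale; this is a documented
divergence risk accepted deliberately.

### Penalty selection, stabilisation, null

* Grid search over t_x, t_z ∈ {0.1, …, 1.0} (100 cells) on the full data;
  the pair with the largest canonical correlation wins, ties within 1e-12
  broken toward sparsity (smallest t_x + t_z, then smallest t_x).
* Bootstrap: 10,000 iterations by default, each drawing ⌊0.75·n⌋
  *distinct* subjects (without replacement — the stated design is
  "subsamples of 75%"; a with-replacement flag exists), restandardising
  within the subsample, and refitting. Summaries are medians (robust to
  outlying iterations): median canonical correlation with 2.5/97.5
  percentile interval, median per-feature weights, and selection
  percentages (share of iterations with a non-zero weight).
* Permutation null: identical resampling, but after subsampling the rows
  of each dataset are shuffled by independent permutations, severing the
  subject-level clinical-genetic linkage. The upstream description of the
  permutation scheme (a community-ecology matrix randomiser applied "100
  times") is ambiguous; one full independent row permutation per dataset
  per iteration realises the intended null and is the default. The
  p-value is the share of null correlations ≥ the observed median
  (primary, may be 0), with the add-one variant (b+1)/(B+1) reported
  alongside.

**Calibration caveat.** The observed statistic is a median over B
bootstrap refits and is therefore far less variable than a single
permuted refit; its null-exceedance p-value is *under-dispersed*
(concentrated toward 0.5), not Uniform(0, 1). In 50 replicate no-signal
cohorts (n = 300, B = 500) the p-values spanned ≈ 0.11–0.77: the
procedure essentially never produces spuriously small p-values, i.e. it
is conservative, but a literal uniformity test rejects it. This is a
property of the median-versus-single-draw comparison itself, not of the
implementation.

### Polygenic scores and associations

wPRS_i = Σ_j feature_ij · median-weight_j over raw (unstandardised)
dosages and binary codings; uPRS_i = Σ_j feature_ij over selected
features. Ancestry principal components are adjustment features inside
the sCCA but are excluded from both scores by default (a toggle exists):
the score must transfer to cohorts where the discovery-cohort PC axes do
not exist. Associations use Spearman rank correlation with Holm
step-down family-wise error control (the FWE method was unspecified
upstream; Holm is uniformly no less powerful than Bonferroni and still
FWE-controlling); slope associations are restricted to subjects with ≥ 2
observations. Ordinal 0–3 pathology ratings are modelled per region by a
proportional-odds cumulative-logit regression (statsmodels
`OrderedModel`, ML) with age-at-death and disease-duration adjustment;
the reported effect is the odds ratio per unit score with a Wald 95% CI,
replaced by a profile-likelihood CI when quasi-separation is detected
(|β| or its SE > 10). No across-region multiplicity correction is
applied; region-level p-values are labelled uncorrected.

## Synthetic cohorts

The generator emulates a multicentre ALS natural-history study so that
every stage has a recoverable ground truth.

* **Genotypes:** 45 SNP dosages drawn Binomial(2, MAF) under
  Hardy-Weinberg equilibrium, MAFs evenly spread over [0.05, 0.45]
  (the real panel's frequencies are not public); binary sex (0.58),
  C9ORF72 expansion (0.08) and other-mutation (0.05) carriers; two
  standard-normal PC columns. An optional mode draws SNP blocks through
  an equicorrelated Gaussian copula to create linkage-disequilibrium
  structure for pruning sensitivity analyses; there is no LD by default.
* **Planted signal:** a sparse weight vector w* (default: 10 of 45 SNPs,
  alternating signs) defines a latent liability z = Zw*/sd(Zw*)
  (theoretical SD). Cognitive true baselines load on −z (higher
  liability, worse cognition) with `signal_sd_ratio` (default 0.3) the
  variance fraction explained; true slopes share the composite attenuated
  by 0.6, so slope associations are recoverable but weaker than baseline
  ones. Motor measures never see the liability, reproducing the
  cognition-motor independence the analysis is designed to detect.
  Alternating signs make the unweighted allele count nearly orthogonal to
  the liability, preserving the weighted-versus-unweighted score
  contrast. The upstream study states no generative effect sizes; these
  defaults are fixture conventions, chosen once.
* **Measures:** baseline means and SDs follow the published cohort
  table (cohort-size-weighted over diagnosis groups); instrument bounds
  are the real score ranges (e.g. ECAS total 0–136, ALSFRS-R 0–48).
  Monthly slope SDs and visit-level noise SDs are set so that individual
  slopes are estimable from the 0/3/6/12/18-month schedule (reliability
  ≈ 0.7–0.9), matching the premise that per-subject decline rates carry
  signal. Values are clipped to instrument bounds *after* noise; the
  clipped fraction is logged (ceiling effects on visuospatial and
  language are realistic consequences).
* **Attrition:** monotone dropout with per-follow-up-visit probability
  0.153, so the expected share of subjects with ≥ 2 visits is 84.7%,
  matching the published longitudinal retention (277/327). Independent
  per-visit missingness is available as a mode.
* **Assembly:** `simulate_enrollment` generates 339 subjects of whom 9
  carry an incomplete covariate and 3 an extreme (> 5 SD) baseline
  visuospatial outlier; `apply_exclusions` recomputes the published
  arithmetic 339 − 9 − 3 = 327 at run time.

What the generator does **not** emulate: real LD structure (beyond the
copula mode), site effects, practice/alternate-form effects on the ECAS,
non-linear or survival-truncated trajectories, genotype missingness, and
ancestry confounding beyond two synthetic PC axes. Passing tests
therefore demonstrate internal validity of the machinery (recovery of a
known signal under the stated noise model), not external validity on any
clinical cohort.

## Numerical choices and degenerate inputs

* Bisection for the L1 subproblem: 200 iterations, acceptance tolerance
  max(1e-8, 1e-6·c); all-zero input raises (undefined direction).
* Alternation: max 100 iterations, stop when the largest weight change
  < 1e-6; non-convergence returns the best iterate flagged. A debug mode
  asserts the objective is non-decreasing every iteration.
* Constant columns: zeroed (never selectable) inside resampling loops,
  hard error in user-facing scaling.
* Resampling failures are skipped and logged; > 1% failures aborts.
* Mixed-model estimates agree across covariate recodings to ~1e-4
  (optimizer noise), and exactly on noise-free data.
* PCA (for external genotype input): mean-imputed, z-scored, SVD scores,
  sign fixed by making each component's largest-magnitude loading
  positive.

## Test-scale choices

Simulation-based tests and the acceptance script run at reduced problem
sizes chosen to keep the full suite in the minutes range while leaving
each statistical check well-powered: cohorts of n = 300 (the study scale)
with B = 200–500 resampling iterations instead of 10,000, 50 replicate
cohorts for calibration checks, and the full 495-model SNP scan at
n = 150. The 10,000-iteration default remains the production setting.

## Known limitations

* Only the first canonical variate pair; no deflation, no fused or
  ordered penalties, no cross-validated penalty selection.
* The permutation p-value is conservative for the bootstrap-median
  statistic (see calibration caveat above).
* REML, alternate ECAS forms and nonlinear trajectories are out of scope;
  the LME assumes linear decline over the observed window.
* The proportional-odds model assumes a common odds ratio across rating
  thresholds; no test of that assumption is run.
* PLINK binary formats and genotype imputation are not supported; input
  is VCF 4.2 or a 0/1/2 dosage TSV with a panel file fixing the counted
  allele.
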