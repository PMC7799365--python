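# alsprs

Sparse-CCA polygenic risk scoring for cognitive decline in amyotrophic
lateral sclerosis (ALS).

Cognitive dysfunction affects a substantial fraction of people with ALS,
but single-variant analyses are underpowered to explain who is at risk.
`alsprs` implements, as a tested and reusable pipeline, a multivariate
machine-learning approach that links a panel of ALS/FTD risk variants to
longitudinal clinical phenotypes:

1. **Trajectory extraction.** Each of 11 clinical measures — eight
   Edinburgh Cognitive and Behavioural ALS Screen (ECAS) scores, the
   ALSFRS-R, and clinician-rated upper/lower motor-neuron (UMN/LMN) burden
   — is modelled with a linear mixed-effects model (maximum likelihood;
   fixed effects for age, onset-to-baseline lag, college education, bulbar
   onset and visit month; random intercept and slope per subject).
   Per-subject **adjusted baseline** and **rate of decline** are the
   population terms plus the subject's predicted random deviations.
2. **Sparse canonical correlation analysis (sCCA).** Writing X for the
   z-scored subjects × 11 matrix of adjusted baselines and Z for the
   subjects × 50 genetic feature matrix (45 SNP dosages coded 0/1/2, sex,
   C9ORF72 repeat-expansion status, other-mutation status, two ancestry
   PCs), the solver finds sparse weight vectors maximising

       u'X'Zv   subject to   ‖u‖₂ ≤ 1, ‖v‖₂ ≤ 1, ‖u‖₁ ≤ c_x, ‖v‖₁ ≤ c_z,

   by alternating soft-thresholded closed-form updates (penalized matrix
   decomposition). Penalties are chosen by a 10 × 10 grid search
   (t ∈ {0.1, …, 1.0} per side, c = max(1, t·√dim)).
3. **Stabilisation and calibration.** The fit is repeated over 10,000
   bootstrap subsamples of 75% of subjects; features are summarised by
   median canonical weights and selection percentages. A permutation null
   (rows of X and Z shuffled independently per iteration) yields the
   p-value of the observed median canonical correlation.
4. **Polygenic scores.** The weighted score wPRS_i = Σ_j dosage_ij ·
   median-weight_j (ancestry PCs excluded) and the unweighted uPRS
   (dosage sum over selected features) are evaluated against baseline and
   slope estimates by Spearman correlation with Holm family-wise error
   control, and against ordinal 0–3 neuropathology ratings by
   proportional-odds logistic regression.

Because the motivating cohorts are access-restricted, the package ships a
first-class synthetic-cohort generator that plants a known sparse genetic
signal in cognitive (never motor) trajectories, giving every stage a
ground truth to recover.

## Worked example

```python
import numpy as np
from scipy import stats
from alsprs import (CohortConfig, simulate_cohort, bootstrap_scca,
                    permutation_null, compute_scores)
from alsprs.scoring import weights_from_bootstrap

cohort = simulate_cohort(CohortConfig(n_subjects=300, seed=3))
X = cohort.truth.intercepts          # clinical baselines (subjects x 11)
Z = cohort.genotypes                 # genetic features  (subjects x 50)

boot = bootstrap_scca(X, Z, t_x=0.3, t_z=0.4, B=500, seed=7)
null = permutation_null(X, Z, 0.3, 0.4, B=500, seed=8,
                        observed_rho=boot.median_rho)
scores = compute_scores(Z, weights_from_bootstrap(boot))
r = stats.spearmanr(scores["wPRS"], cohort.truth.liability).statistic

print(f"median canonical rho = {boot.median_rho:.3f} "
      f"(95% CI {boot.rho_ci[0]:.3f}-{boot.rho_ci[1]:.3f})")
print(f"permutation p = {null.p_value}")
print(f"wPRS vs planted liability: Spearman = {r:.3f}")
```

Output:

```
median canonical rho = 0.618 (95% CI 0.568-0.662)
permutation p = 0.0
wPRS vs planted liability: Spearman = 0.909
```

The bootstrap-stabilised canonical correlation (0.62) far exceeds every
permuted refit, so the p-value is 0 at B = 500 (add-one variant 1/501),
and the weighted polygenic score strongly tracks the planted liability —
positively, per the risk orientation: a higher score predicts worse
cognitive trajectories.

A full eight-stage run (simulate → trajectories → scale → grid →
bootstrap → null → score → associate) with provenance manifest:

```bash
alsprs run-all --seed 1 --outdir runs/demo
```

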