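"""Seeded synthetic ALS natural-history cohorts.

Generates the three data objects the pipeline consumes — a genetic feature
matrix, a long-format longitudinal clinical table, and per-subject baseline
covariates — together with the generating truth (planted sparse weight
vector, latent liability, true per-subject intercepts and slopes), so every
downstream stage can be tested against a known answer.

Generative model
----------------
* SNP dosages: Binomial(2, MAF) per subject and site (Hardy-Weinberg
  equilibrium, no linkage by default).  An optional block-correlated mode
  draws dosages through a Gaussian copula within consecutive SNP blocks to
  support linkage-disequilibrium sensitivity reruns.
* Non-SNP genetic features: sex, C9ORF72 repeat-expansion carrier and
  other-pathogenic-mutation carrier as Bernoulli variables; two ancestry
  principal-component columns as standard normals.
* Latent liability: the planted sparse weight vector w* applied to the raw
  feature matrix, standardised by its theoretical SD.  Cognitive baseline
  (and, attenuated, cognitive slope) load on -liability — higher liability
  means worse cognition — with ``signal_sd_ratio`` the fraction of
  between-subject baseline variance the composite explains.  Motor measures
  are generated independently of liability.
* Observations: truth + i.i.d. Gaussian measurement noise at scheduled
  visits, clipped to the instrument bounds; visits are lost to monotone
  (attrition-style) dropout by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .measures import BASELINE_COVARIATES, COGNITIVE_MEASURES, MEASURE_NAMES, MEASURES

logger = logging.getLogger(__name__)

__all__ = [
    "CohortConfig",
    "SyntheticTruth",
    "SyntheticCohort",
    "default_maf",
    "default_planted_weights",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_cohort",
    "simulate_enrollment",
    "apply_exclusions",
    "simulate_ordinal_outcome",
    "write_cohort",
]

N_SNPS_DEFAULT = 45
BINARY_COVARIATES = ("sex", "c9orf72", "other_mutation")
PC_FEATURES = ("PC1", "PC2")
VISIT_SCHEDULE = (0.0, 3.0, 6.0, 12.0, 18.0)

# Per-follow-up-visit attrition probability; with monotone dropout the share
# of subjects retaining >= 2 visits is 1 - 0.153 = 84.7%.
DROPOUT_DEFAULT = 0.153


def default_maf(n_snps: int = N_SNPS_DEFAULT) -> np.ndarray:
    """Evenly spread minor-allele frequencies over [0.05, 0.45]."""
    return np.round(np.linspace(0.05, 0.45, n_snps), 3)


def snp_names(n_snps: int = N_SNPS_DEFAULT) -> list[str]:
    return [f"snp{i + 1:03d}" for i in range(n_snps)]


def feature_names(n_snps: int = N_SNPS_DEFAULT) -> list[str]:
    return snp_names(n_snps) + list(BINARY_COVARIATES) + list(PC_FEATURES)


def default_planted_weights(n_snps: int = N_SNPS_DEFAULT, support: int = 10) -> np.ndarray:
    """Sparse truth: ``support`` SNPs with alternating-sign unit weights.

    Alternating signs make the unweighted allele-count score a poor proxy
    for the liability, preserving the weighted-vs-unweighted score contrast
    the analysis is designed to expose.
    """
    w = np.zeros(n_snps + len(BINARY_COVARIATES) + len(PC_FEATURES))
    idx = np.linspace(0, n_snps - 1, support).round().astype(int)
    w[idx] = [1.0 if k % 2 == 0 else -1.0 for k in range(support)]
    return w


@dataclass(frozen=True)
class CohortConfig:
    """All knobs of the synthetic cohort, with study-realistic defaults."""

    n_subjects: int = 327
    n_snps: int = N_SNPS_DEFAULT
    maf: np.ndarray | None = None
    planted_weights: np.ndarray | None = None
    signal_sd_ratio: float = 0.3
    slope_attenuation: float = 0.6
    # None = every cognitive measure loads on the liability; otherwise the
    # named subset carries all the genetic signal.
    signal_measures: tuple[str, ...] | None = None
    visit_months: tuple[float, ...] = VISIT_SCHEDULE
    dropout_prob: float = DROPOUT_DEFAULT
    dropout_mode: str = "monotone"  # or "independent"
    noise_sd: dict | None = None  # per-measure overrides
    # Covariate effects on cognitive baselines, in units of the measure's SD:
    beta_age_per_decade: float = -0.15
    beta_college: float = 0.30
    beta_bulbar: float = -0.20
    # Binary feature prevalences (male sex, C9ORF72 expansion, other mutation):
    p_sex: float = 0.58
    p_c9: float = 0.08
    p_othermut: float = 0.05
    ld_blocks: int = 0  # >0 switches SNP sampling to block-correlated mode
    ld_rho: float = 0.8
    # Enrollment emulation (assembly accounting):
    n_enrolled: int = 339
    n_incomplete: int = 9
    n_outlier: int = 3
    seed: int = 0

    def __post_init__(self):
        maf = default_maf(self.n_snps) if self.maf is None else np.asarray(self.maf, float)
        object.__setattr__(self, "maf", maf)
        w = (
            default_planted_weights(self.n_snps)
            if self.planted_weights is None
            else np.asarray(self.planted_weights, float)
        )
        object.__setattr__(self, "planted_weights", w)
        if len(maf) != self.n_snps:
            raise ValueError("maf length must equal n_snps")
        if np.any(maf < 0) or np.any(maf > 0.5):
            raise ValueError("MAFs must lie in (0, 0.5] (0 allowed only for degenerate tests)")
        n_feat = self.n_snps + len(BINARY_COVARIATES) + len(PC_FEATURES)
        if len(w) != n_feat:
            raise ValueError(f"planted_weights must have length {n_feat}")
        if not 0 <= self.dropout_prob < 1:
            raise ValueError("dropout_prob must be in [0, 1)")
        if not 0 <= self.signal_sd_ratio < 1:
            raise ValueError("signal_sd_ratio must be in [0, 1)")
        if self.dropout_mode not in ("monotone", "independent"):
            raise ValueError("dropout_mode must be 'monotone' or 'independent'")


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generator."""

    planted_weights: np.ndarray
    liability: pd.Series  # standardised latent composite per subject
    intercepts: pd.DataFrame  # subjects x measures, true baselines
    slopes: pd.DataFrame  # subjects x measures, true monthly slopes


@dataclass
class SyntheticCohort:
    genotypes: pd.DataFrame  # subjects x (SNPs + binaries + PCs), raw coding
    clinical: pd.DataFrame  # long table: subject_id, measure, visit_month, value
    covariates: pd.DataFrame  # subject_id-indexed baseline covariates
    truth: SyntheticTruth
    config: CohortConfig


def _feature_variances(config: CohortConfig) -> np.ndarray:
    v_snp = 2 * config.maf * (1 - config.maf)
    v_bin = np.array([p * (1 - p) for p in (config.p_sex, config.p_c9, config.p_othermut)])
    return np.concatenate([v_snp, v_bin, np.ones(len(PC_FEATURES))])


def simulate_genotypes(
    maf: np.ndarray,
    n_subjects: int,
    seed: int,
    p_sex: float = 0.58,
    p_c9: float = 0.08,
    p_othermut: float = 0.05,
    ld_blocks: int = 0,
    ld_rho: float = 0.8,
) -> pd.DataFrame:
    """Draw the raw genetic feature matrix.

    SNP dosages are Binomial(2, MAF) under HWE; with ``ld_blocks`` > 0 the
    SNPs are split into that many consecutive blocks and drawn through an
    equicorrelated Gaussian copula (correlation ``ld_rho``) within each
    block, preserving the Binomial margins.
    """
    maf = np.asarray(maf, float)
    if np.any(maf < 0) or np.any(maf > 0.5):
        raise ValueError("MAFs must lie in (0, 0.5]")
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    n_snps = len(maf)
    if ld_blocks and ld_blocks > 0:
        blocks = np.array_split(np.arange(n_snps), ld_blocks)
        dosages = np.empty((n_subjects, n_snps))
        from scipy import stats

        for blk in blocks:
            k = len(blk)
            cov = np.full((k, k), ld_rho) + (1 - ld_rho) * np.eye(k)
            z = rng.multivariate_normal(np.zeros(k), cov, size=n_subjects, method="cholesky")
            u = stats.norm.cdf(z)
            for j, col in enumerate(blk):
                dosages[:, col] = stats.binom.ppf(u[:, j], 2, maf[col])
    else:
        dosages = rng.binomial(2, maf, size=(n_subjects, n_snps)).astype(float)
    sex = rng.binomial(1, p_sex, n_subjects)
    c9 = rng.binomial(1, p_c9, n_subjects)
    om = rng.binomial(1, p_othermut, n_subjects)
    pcs = rng.standard_normal((n_subjects, len(PC_FEATURES)))
    data = np.column_stack([dosages, sex, c9, om, pcs])
    subjects = [f"S{i + 1:04d}" for i in range(n_subjects)]
    return pd.DataFrame(data, index=pd.Index(subjects, name="subject_id"), columns=feature_names(n_snps))


def simulate_phenotypes(
    genotypes: pd.DataFrame, config: CohortConfig
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate the longitudinal clinical table, covariates and truth.

    Returns ``(clinical_long, covariates, truth)``.  The latent liability is
    the planted composite of the raw feature matrix standardised by its
    theoretical SD; cognitive true baselines are

        mean + sd * (-sqrt(r) * liability + sqrt(1 - r) * noise) + covariate terms

    with r = ``signal_sd_ratio``, and cognitive slopes use the same
    composite attenuated by ``slope_attenuation``.  Motor measures never see
    the liability.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    n = len(genotypes)
    subjects = genotypes.index
    w = config.planted_weights
    raw = genotypes.to_numpy()
    liability_raw = raw @ w
    theo_var = float(_feature_variances(config) @ (w**2))
    if theo_var > 0:
        liability = (liability_raw - (liability_raw.mean())) / np.sqrt(theo_var)
    else:
        liability = np.zeros(n)
    liability = pd.Series(liability, index=subjects, name="liability")

    # Baseline covariates.
    age = rng.normal(57.0, 11.0, n).clip(25, 85)
    onset_lag = rng.gamma(shape=1.8, scale=2.2, size=n).clip(0.1, 25)
    college = rng.binomial(1, 0.70, n)
    bulbar = rng.binomial(1, 0.18, n)
    covariates = pd.DataFrame(
        {
            "age_at_baseline": np.round(age, 1),
            "onset_lag": np.round(onset_lag, 2),
            "college": college,
            "bulbar_onset": bulbar,
        },
        index=subjects,
    )

    r = config.signal_sd_ratio
    att = config.slope_attenuation
    intercepts = {}
    slopes = {}
    for name in MEASURE_NAMES:
        spec = MEASURES[name]
        e_int = rng.standard_normal(n)
        e_slp = rng.standard_normal(n)
        carries_signal = spec.kind == "cognitive" and (
            config.signal_measures is None or name in config.signal_measures
        )
        if carries_signal:
            z_int = -np.sqrt(r) * liability.to_numpy() + np.sqrt(1 - r) * e_int
            z_slp = -att * np.sqrt(r) * liability.to_numpy() + np.sqrt(max(0.0, 1 - (att**2) * r)) * e_slp
        else:
            z_int, z_slp = e_int, e_slp
        if spec.kind == "cognitive":
            cov_term = spec.baseline_sd * (
                config.beta_age_per_decade * (age - 57.0) / 10.0
                + config.beta_college * college
                + config.beta_bulbar * bulbar
            )
        else:
            cov_term = 0.0
        intercepts[name] = spec.baseline_mean + spec.baseline_sd * z_int + cov_term
        slopes[name] = spec.slope_mean + spec.slope_sd * z_slp
    intercepts = pd.DataFrame(intercepts, index=subjects)
    slopes = pd.DataFrame(slopes, index=subjects)

    # Visit attendance (shared across measures within a visit).
    months = np.asarray(config.visit_months, float)
    n_visits = len(months)
    attend = np.ones((n, n_visits), dtype=bool)
    if n_visits > 1:
        if config.dropout_mode == "monotone":
            drop = rng.random((n, n_visits - 1)) < config.dropout_prob
            gone = np.cumsum(drop, axis=1) > 0
            attend[:, 1:] = ~gone
        else:
            attend[:, 1:] = rng.random((n, n_visits - 1)) >= config.dropout_prob

    noise_overrides = config.noise_sd or {}
    rows = []
    n_clipped = 0
    n_total = 0
    for m_idx, name in enumerate(MEASURE_NAMES):
        spec = MEASURES[name]
        sd = float(noise_overrides.get(name, spec.noise_sd))
        noise = rng.normal(0.0, sd, size=(n, n_visits))
        values = intercepts[name].to_numpy()[:, None] + slopes[name].to_numpy()[:, None] * months[None, :] + noise
        clipped = np.clip(values, spec.lo, spec.hi)
        n_clipped += int((clipped != values)[attend].sum())
        n_total += int(attend.sum())
        for j, month in enumerate(months):
            sel = attend[:, j]
            rows.append(
                pd.DataFrame(
                    {
                        "subject_id": subjects[sel],
                        "measure": name,
                        "visit_month": month,
                        "value": np.round(clipped[sel, j], 3),
                    }
                )
            )
    clinical = pd.concat(rows, ignore_index=True)
    if n_total:
        logger.info("clipped %.2f%% of observed values to instrument bounds", 100 * n_clipped / n_total)

    truth = SyntheticTruth(planted_weights=w.copy(), liability=liability, intercepts=intercepts, slopes=slopes)
    return clinical, covariates, truth


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """End-to-end generation of a clean analyzed cohort."""
    genotypes = simulate_genotypes(
        config.maf,
        config.n_subjects,
        seed=int(np.random.SeedSequence([config.seed, 3]).generate_state(1)[0] % (2**31)),
        p_sex=config.p_sex,
        p_c9=config.p_c9,
        p_othermut=config.p_othermut,
        ld_blocks=config.ld_blocks,
        ld_rho=config.ld_rho,
    )
    clinical, covariates, truth = simulate_phenotypes(genotypes, config)
    return SyntheticCohort(genotypes=genotypes, clinical=clinical, covariates=covariates, truth=truth, config=config)


def simulate_enrollment(config: CohortConfig) -> SyntheticCohort:
    """Generate an enrolled cohort including the to-be-excluded subjects.

    Emulates study assembly: of ``n_enrolled`` subjects, ``n_incomplete``
    are given a missing onset-lag covariate (incomplete data) and
    ``n_outlier`` have their baseline visuospatial observation displaced
    more than 5 SD below the group mean (extreme outliers).
    """
    cfg = replace(config, n_subjects=config.n_enrolled)
    cohort = simulate_cohort(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    all_subj = cohort.covariates.index.to_numpy()
    flagged = rng.choice(all_subj, size=config.n_incomplete + config.n_outlier, replace=False)
    incomplete, outlier = flagged[: config.n_incomplete], flagged[config.n_incomplete :]
    cohort.covariates.loc[incomplete, "onset_lag"] = np.nan
    cl = cohort.clinical
    vs = MEASURES["ecas_visuospatial"]
    base_mask = (cl["measure"] == "ecas_visuospatial") & (cl["visit_month"] == 0.0)
    group_mean = cl.loc[base_mask, "value"].mean()
    sd = vs.baseline_sd
    cl.loc[base_mask & cl["subject_id"].isin(outlier), "value"] = group_mean - 7.5 * sd
    return cohort


def apply_exclusions(cohort: SyntheticCohort, outlier_sd: float = 5.0) -> tuple[SyntheticCohort, dict]:
    """Drop subjects with incomplete covariates or extreme baseline outliers.

    Mirrors natural-history cohort assembly: complete-case on baseline
    covariates, then removal of subjects whose baseline visuospatial value
    lies more than ``outlier_sd`` SDs from the group mean.  Returns the
    filtered cohort and an accounting dict.
    """
    cov = cohort.covariates
    incomplete = cov.index[cov[list(BASELINE_COVARIATES)].isna().any(axis=1)]
    cl = cohort.clinical
    base = cl[(cl["measure"] == "ecas_visuospatial") & (cl["visit_month"] == 0.0)].set_index("subject_id")["value"]
    z = (base - base.mean()) / base.std(ddof=1)
    outliers = z.index[z.abs() > outlier_sd].difference(incomplete)
    drop = incomplete.union(outliers)
    keep = cov.index.difference(drop, sort=False)
    accounting = {
        "enrolled": int(len(cov)),
        "excluded_incomplete": int(len(incomplete)),
        "excluded_outlier": int(len(outliers)),
        "analyzed": int(len(keep)),
    }
    logger.info("cohort assembly: %s", accounting)
    filtered = SyntheticCohort(
        genotypes=cohort.genotypes.loc[keep],
        clinical=cl[cl["subject_id"].isin(keep)].reset_index(drop=True),
        covariates=cov.loc[keep],
        truth=SyntheticTruth(
            planted_weights=cohort.truth.planted_weights,
            liability=cohort.truth.liability.loc[keep],
            intercepts=cohort.truth.intercepts.loc[keep],
            slopes=cohort.truth.slopes.loc[keep],
        ),
        config=cohort.config,
    )
    return filtered, accounting


def simulate_ordinal_outcome(
    score: pd.Series,
    beta: float,
    seed: int,
    beta_age: float = 0.0,
    beta_duration: float = 0.0,
    n_levels: int = 4,
) -> pd.DataFrame:
    """Simulate 0..3 ordinal pathology ratings from a latent-logistic model.

    The latent scale is ``beta * standardized score + covariate terms +
    logistic noise``; thresholds are placed at latent quantiles so the
    rating levels are roughly balanced.  Returns a frame with the rating
    plus the age-at-death and disease-duration covariates used.
    """
    rng = np.random.default_rng(seed)
    n = len(score)
    s = (score - score.mean()) / score.std(ddof=1)
    age_at_death = rng.normal(66.0, 9.0, n)
    duration = rng.gamma(2.0, 1.8, n).clip(0.2, 15)
    latent = (
        beta * s.to_numpy()
        + beta_age * (age_at_death - 66.0) / 10.0
        + beta_duration * (duration - 3.6)
        + rng.logistic(0, 1, n)
    )
    cuts = np.quantile(latent, np.linspace(0, 1, n_levels + 1)[1:-1])
    rating = np.searchsorted(cuts, latent)
    return pd.DataFrame(
        {
            "rating": rating,
            "age_at_death": np.round(age_at_death, 1),
            "disease_duration": np.round(duration, 2),
        },
        index=score.index,
    )


def write_cohort(cohort: SyntheticCohort, outdir) -> dict:
    """Write the cohort as TSVs plus a minimal VCF; returns the path map."""
    from . import genio
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes_tsv": outdir / "genotypes.tsv",
        "clinical_tsv": outdir / "clinical_long.tsv",
        "covariates_tsv": outdir / "covariates.tsv",
        "genotypes_vcf": outdir / "genotypes.vcf",
        "panel_tsv": outdir / "snp_panel.tsv",
        "truth_liability_tsv": outdir / "truth_liability.tsv",
    }
    genio.write_tsv(cohort.genotypes.reset_index(), paths["genotypes_tsv"])
    genio.write_tsv(cohort.clinical, paths["clinical_tsv"])
    genio.write_tsv(cohort.covariates.reset_index(), paths["covariates_tsv"])
    n_snps = cohort.config.n_snps
    snp_cols = snp_names(n_snps)
    panel = genio.synthetic_panel(snp_cols, cohort.config.maf)
    genio.write_tsv(panel, paths["panel_tsv"])
    genio.write_vcf(cohort.genotypes[snp_cols], panel, paths["genotypes_vcf"])
    genio.write_tsv(cohort.truth.liability.reset_index(), paths["truth_liability_tsv"])
    return {k: str(v) for k, v in paths.items()}
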