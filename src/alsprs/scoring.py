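"""Polygenic score construction and association stages.

The weighted polygenic risk score (wPRS) multiplies each subject's raw
allele dosage or binary coding by the feature's median canonical weight
from bootstrap-stabilised sparse CCA and sums; the unweighted score (uPRS)
sums raw dosages over the selected (non-zero-weight) features.  Ancestry
principal components are adjustment features inside the CCA but are
excluded from both scores by default, so the score transfers to cohorts
where the discovery PC axes do not exist.

Association stages: Spearman rank correlations with Holm family-wise error
control, proportional-odds ordinal logistic regression for 0-3 pathology
ratings, and sensitivity reruns that compare wPRS variants after dropping
features or subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.stats.multitest import multipletests

from .stability import bootstrap_scca

logger = logging.getLogger(__name__)

__all__ = [
    "WeightVector",
    "compute_scores",
    "spearman_assoc",
    "ordinal_assoc",
    "sensitivity_rerun",
]

PC_FEATURES = ("PC1", "PC2")


@dataclass
class WeightVector:
    """Median canonical weights with provenance."""

    weights: pd.Series  # indexed by genetic feature name
    provenance: dict

    @property
    def selected(self) -> pd.Series:
        return self.weights != 0

    def to_frame(self) -> pd.DataFrame:
        df = self.weights.rename("weight").to_frame()
        df["selected"] = self.selected
        for k, v in self.provenance.items():
            df[k] = str(v)
        return df.rename_axis("feature").reset_index()


def weights_from_bootstrap(summary) -> WeightVector:
    return WeightVector(
        weights=summary.genetic_median_weights.copy(),
        provenance={
            "B": summary.B,
            "frac": summary.frac,
            "seed": summary.seed,
            "penalties": summary.penalties,
        },
    )


def compute_scores(
    raw_features: pd.DataFrame,
    weights: WeightVector,
    exclude: tuple[str, ...] = PC_FEATURES,
) -> pd.DataFrame:
    """Per-subject wPRS and uPRS from raw (unstandardised) features.

    Subjects with any missing value among the included features get NaN
    scores and are logged.
    """
    w = weights.weights.drop(index=[f for f in exclude if f in weights.weights.index])
    missing_feats = w.index.difference(raw_features.columns)
    if len(missing_feats):
        raise KeyError(f"features absent from matrix: {list(missing_feats)}")
    feats = raw_features[w.index]
    incomplete = feats.isna().any(axis=1)
    if incomplete.any():
        logger.warning("%d subject(s) with missing features: scores set to NaN", int(incomplete.sum()))
    wprs = feats @ w
    sel = w.index[w != 0]
    uprs = feats[sel].sum(axis=1) if len(sel) else pd.Series(0.0, index=feats.index)
    out = pd.DataFrame({"wPRS": wprs, "uPRS": uprs})
    out[incomplete] = np.nan
    return out


def spearman_assoc(
    score: pd.Series,
    outcomes: pd.DataFrame,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Spearman rho of the score against each outcome, Holm-adjusted.

    Constant score/outcome pairs are flagged and excluded from the
    correction family.  Returns one row per outcome with ``n``, ``rho``,
    ``p``, ``p_adjusted`` and ``flagged``.
    """
    rows = []
    for col in outcomes.columns:
        paired = pd.concat([score.rename("score"), outcomes[col].rename("y")], axis=1).dropna()
        n = len(paired)
        if n < min_pairs:
            raise ValueError(f"outcome {col!r}: only {n} paired observations (< {min_pairs})")
        if paired["score"].nunique() <= 1 or paired["y"].nunique() <= 1:
            rows.append({"outcome": col, "n": n, "rho": np.nan, "p": np.nan, "flagged": True})
            continue
        rho, p = stats.spearmanr(paired["score"], paired["y"])
        rows.append({"outcome": col, "n": n, "rho": float(rho), "p": float(p), "flagged": False})
    res = pd.DataFrame(rows)
    res["p_adjusted"] = np.nan
    family = ~res["flagged"]
    if family.any():
        res.loc[family, "p_adjusted"] = multipletests(res.loc[family, "p"], method="holm")[1]
    return res


def _profile_ci(model: OrderedModel, result, k: int, alpha: float = 0.05) -> tuple[float, float]:
    """Profile-likelihood CI for one coefficient by LR inversion."""
    from scipy.optimize import brentq, minimize

    params = np.asarray(result.params, float)
    llf_hat = result.llf
    crit = stats.chi2.ppf(1 - alpha, 1) / 2

    def profile_llf(beta_k: float) -> float:
        free = np.delete(np.arange(len(params)), k)

        def nll(theta_free):
            theta = params.copy()
            theta[k] = beta_k
            theta[free] = theta_free
            return -model.loglike(theta)

        res = minimize(nll, params[free], method="BFGS")
        return -res.fun

    def root(beta_k: float) -> float:
        return (llf_hat - profile_llf(beta_k)) - crit

    bhat = params[k]
    step = max(1.0, 4 * abs(bhat))
    lo = hi = bhat
    flo, fhi = None, None
    for mult in (1, 2, 4, 8):
        if flo is None and root(bhat - mult * step) > 0:
            flo = bhat - mult * step
        if fhi is None and root(bhat + mult * step) > 0:
            fhi = bhat + mult * step
    lower = brentq(root, flo, bhat) if flo is not None else -np.inf
    upper = brentq(root, bhat, fhi) if fhi is not None else np.inf
    return lower, upper


def ordinal_assoc(
    score: pd.Series,
    ordinal_outcome: pd.Series,
    covariates: pd.DataFrame,
    min_n: int = 20,
) -> dict:
    """Proportional-odds model of a 0-3 rating on the score.

    The cumulative-logit model is fit by maximum likelihood with the
    covariates (age at death, disease duration) adjusted as fixed effects.
    Returns the odds ratio per unit score with a Wald 95% CI; under
    quasi-separation (inflated Wald SE) the fit is flagged and a
    profile-likelihood CI is reported instead.
    """
    df = pd.concat([score.rename("score"), ordinal_outcome.rename("y"), covariates], axis=1).dropna()
    if len(df) < min_n:
        raise ValueError(f"n={len(df)} < {min_n}")
    levels = np.sort(df["y"].unique())
    if len(levels) < 2:
        raise ValueError("ordinal outcome has a single level")
    exog = df[["score", *covariates.columns]]
    model = OrderedModel(df["y"].astype(int), exog, distr="logit")
    result = model.fit(method="bfgs", maxiter=500, disp=False)
    beta = float(result.params["score"])
    se = float(result.bse["score"])
    flagged = not np.isfinite(se) or se > 10 or abs(beta) > 10
    if flagged:
        logger.warning("possible quasi-separation (beta=%.3g, se=%.3g); profile-likelihood CI used", beta, se)
        lo, hi = _profile_ci(model, result, k=list(result.params.index).index("score"))
    else:
        lo, hi = beta - 1.959963984540054 * se, beta + 1.959963984540054 * se
    return {
        "odds_ratio": float(np.exp(beta)),
        "ci_low": float(np.exp(lo)),
        "ci_high": float(np.exp(hi)),
        "p": float(result.pvalues["score"]),
        "n": int(len(df)),
        "flagged_separation": bool(flagged),
        "converged": bool(result.mle_retvals.get("converged", True)),
    }


def sensitivity_rerun(
    X,
    Z: pd.DataFrame,
    raw_features: pd.DataFrame,
    t_x: float,
    t_z: float,
    base_summary,
    B: int | None = None,
    frac: float | None = None,
    seed: int | None = None,
    exclude_features: tuple[str, ...] = (),
    exclude_subjects: tuple[str, ...] = (),
) -> dict:
    """Re-run the bootstrap stage under a feature/subject exclusion delta.

    Recomputes weights and wPRS on the reduced problem (same penalties and
    seed by default) and reports the Pearson correlation between base and
    delta wPRS over shared subjects plus the sign-agreement of shared
    non-zero weights.  An empty delta is a no-op identity comparison.
    """
    if not exclude_features and not exclude_subjects:
        logger.warning("sensitivity_rerun called with an empty delta; identity comparison")
    B = B if B is not None else base_summary.B
    frac = frac if frac is not None else base_summary.frac
    seed = seed if seed is not None else base_summary.seed
    X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float), index=Z.index)
    keep_subj = X.index.difference(pd.Index(exclude_subjects))
    keep_feat = Z.columns.difference(pd.Index(exclude_features), sort=False)
    Xd = X.loc[keep_subj]
    Zd = Z.loc[keep_subj, keep_feat]
    delta_summary = bootstrap_scca(Xd, Zd, t_x, t_z, B=B, frac=frac, seed=seed)

    base_w = weights_from_bootstrap(base_summary)
    delta_w = weights_from_bootstrap(delta_summary)
    base_scores = compute_scores(raw_features, base_w)
    delta_scores = compute_scores(raw_features, delta_w)
    shared = base_scores.index.intersection(delta_scores.index)
    r = float(np.corrcoef(base_scores.loc[shared, "wPRS"], delta_scores.loc[shared, "wPRS"])[0, 1])

    shared_feat = base_w.weights.index.intersection(delta_w.weights.index)
    bw, dw = base_w.weights[shared_feat], delta_w.weights[shared_feat]
    both = (bw != 0) & (dw != 0)
    sign_agreement = float((np.sign(bw[both]) == np.sign(dw[both])).mean()) if both.any() else np.nan
    return {
        "wprs_pearson_r": r,
        "weight_sign_agreement": sign_agreement,
        "n_shared_subjects": int(len(shared)),
        "base_summary": base_summary,
        "delta_summary": delta_summary,
        "base_weights": base_w,
        "delta_weights": delta_w,
    }
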