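"""Polygenic scores and the association stages."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from alsprs import scoring, simulate
from alsprs.scoring import WeightVector, compute_scores, ordinal_assoc, sensitivity_rerun, spearman_assoc


def _wv(weights: dict) -> WeightVector:
    return WeightVector(weights=pd.Series(weights), provenance={"B": 1, "seed": 0})


class TestComputeScores:
    def test_weighted_sum_arithmetic(self):
        feats = pd.DataFrame({"a": [0.0], "b": [1.0], "c": [2.0]}, index=["s1"])
        scores = compute_scores(feats, _wv({"a": 0.5, "b": -0.2, "c": 0.1}))
        assert scores.loc["s1", "wPRS"] == pytest.approx(0.0)
        assert scores.loc["s1", "uPRS"] == pytest.approx(3.0)

    def test_all_zero_weights_give_zero_scores(self):
        feats = pd.DataFrame({"a": [1.0, 2.0], "b": [0.0, 1.0]})
        scores = compute_scores(feats, _wv({"a": 0.0, "b": 0.0}))
        assert (scores["wPRS"] == 0).all()
        assert (scores["uPRS"] == 0).all()

    def test_pc_features_excluded_by_default(self):
        feats = pd.DataFrame({"a": [1.0], "PC1": [5.0], "PC2": [-3.0]})
        scores = compute_scores(feats, _wv({"a": 1.0, "PC1": 10.0, "PC2": 10.0}))
        assert scores.loc[0, "wPRS"] == pytest.approx(1.0)

    def test_missing_feature_value_gives_nan_score(self):
        feats = pd.DataFrame({"a": [1.0, np.nan], "b": [1.0, 1.0]})
        scores = compute_scores(feats, _wv({"a": 1.0, "b": 2.0}))
        assert np.isfinite(scores.loc[0]).all()
        assert scores.loc[1].isna().all()

    def test_linearity_over_cohort_concatenation(self):
        rng = np.random.default_rng(0)
        w = _wv({"a": 0.4, "b": -0.7})
        f1 = pd.DataFrame(rng.integers(0, 3, (5, 2)).astype(float), columns=["a", "b"], index=[f"x{i}" for i in range(5)])
        f2 = pd.DataFrame(rng.integers(0, 3, (4, 2)).astype(float), columns=["a", "b"], index=[f"y{i}" for i in range(4)])
        combined = compute_scores(pd.concat([f1, f2]), w)
        split = pd.concat([compute_scores(f1, w), compute_scores(f2, w)])
        pd.testing.assert_frame_equal(combined, split)

    def test_recovered_weights_score_tracks_liability(self, planted_cohort):
        from alsprs import stability

        summary = stability.bootstrap_scca(
            planted_cohort.truth.intercepts, planted_cohort.genotypes, 0.3, 0.4, B=500, seed=2
        )
        wv = scoring.weights_from_bootstrap(summary)
        scores = compute_scores(planted_cohort.genotypes, wv)
        rho = stats.spearmanr(scores["wPRS"], planted_cohort.truth.liability).statistic
        assert abs(rho) >= 0.5


def rank_oracle(x):
    """O(n^2) definitional mid-ranks: 1 + #smaller + (#tied - 1) / 2."""
    x = np.asarray(x, float)
    return np.array([1 + np.sum(x < xi) + (np.sum(x == xi) - 1) / 2 for xi in x])


class TestSpearmanAssoc:
    def test_monotone_outcome_gives_rho_one(self):
        score = pd.Series(np.arange(20.0))
        out = pd.DataFrame({"up": np.arange(20.0) ** 2, "down": -np.arange(20.0)})
        res = spearman_assoc(score, out).set_index("outcome")
        assert res.loc["up", "rho"] == pytest.approx(1.0)
        assert res.loc["down", "rho"] == pytest.approx(-1.0)

    def test_matches_definitional_rank_oracle_with_ties(self):
        score = pd.Series([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0, 5.0, 3.0, 5.0, 8.0])
        y = pd.Series([2.0, 7.0, 1.0, 8.0, 2.0, 8.0, 1.0, 8.0, 2.0, 8.0, 4.0, 5.0])
        res = spearman_assoc(score, y.to_frame("y"))
        rx, ry = rank_oracle(score), rank_oracle(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert res.loc[0, "rho"] == pytest.approx(expected, abs=1e-12)

    def test_holm_adjustment_monotone_and_bounded_below_by_raw(self):
        rng = np.random.default_rng(1)
        score = pd.Series(rng.standard_normal(40))
        out = pd.DataFrame(
            {
                "strong": score.rank() + rng.normal(0, 2, 40),
                "weak": rng.standard_normal(40),
                "none": rng.standard_normal(40),
            }
        )
        res = spearman_assoc(score, out)
        assert (res["p_adjusted"] >= res["p"] - 1e-15).all()
        ordered = res.sort_values("p")
        assert ordered["p_adjusted"].is_monotonic_increasing

    def test_constant_outcome_flagged_and_out_of_family(self):
        score = pd.Series(np.arange(15.0))
        out = pd.DataFrame({"flat": np.ones(15), "ok": np.arange(15.0)})
        res = spearman_assoc(score, out).set_index("outcome")
        assert res.loc["flat", "flagged"]
        assert np.isnan(res.loc["flat", "p_adjusted"])
        assert not res.loc["ok", "flagged"]

    def test_too_few_pairs_rejected(self):
        score = pd.Series(np.arange(5.0))
        with pytest.raises(ValueError, match="paired observations"):
            spearman_assoc(score, score.to_frame("y"))


class TestOrdinalAssoc:
    def test_null_simulation_odds_ratio_near_one(self):
        """Score independent of the rating: mean OR across replicates ~ 1."""
        rng = np.random.default_rng(2)
        ors = []
        for rep in range(50):
            score = pd.Series(rng.standard_normal(2000))
            out = simulate.simulate_ordinal_outcome(score, beta=0.0, seed=300 + rep)
            res = ordinal_assoc(score, out["rating"], out[["age_at_death", "disease_duration"]])
            ors.append(np.log(res["odds_ratio"]))
        se = np.std(ors, ddof=1) / np.sqrt(len(ors))
        assert abs(np.mean(ors)) < 3 * se + 1e-3

    def test_recovers_planted_log_odds(self):
        """Latent-logistic truth with per-unit log-odds 0.69 (OR = 2)."""
        rng = np.random.default_rng(3)
        score = pd.Series(rng.standard_normal(2000))
        out = simulate.simulate_ordinal_outcome(score, beta=0.69, seed=4)
        res = ordinal_assoc(score, out["rating"], out[["age_at_death", "disease_duration"]])
        assert 1.7 < res["odds_ratio"] < 2.3
        assert res["ci_low"] < res["odds_ratio"] < res["ci_high"]
        assert res["p"] < 1e-6

    def test_single_level_outcome_rejected(self):
        score = pd.Series(np.arange(30.0))
        flat = pd.Series(np.ones(30))
        cov = pd.DataFrame({"age_at_death": np.full(30, 65.0), "disease_duration": np.full(30, 3.0)})
        with pytest.raises(ValueError, match="single level"):
            ordinal_assoc(score, flat, cov)


class TestSensitivityRerun:
    def test_empty_delta_is_identity(self, planted_cohort):
        from alsprs import stability

        X = planted_cohort.truth.intercepts
        Z = planted_cohort.genotypes
        base = stability.bootstrap_scca(X, Z, 0.3, 0.4, B=100, seed=5)
        res = sensitivity_rerun(X, Z, Z, 0.3, 0.4, base_summary=base)
        assert res["wprs_pearson_r"] == pytest.approx(1.0, abs=1e-12)
        assert res["weight_sign_agreement"] == 1.0

    def test_ld_pruning_leaves_score_stable(self):
        """Dropping one member of each correlated SNP block preserves the
        score ranking (the redundant partner carries the signal)."""
        from alsprs import stability

        w = np.zeros(50)
        w[[0, 5, 10, 15, 20, 25, 30, 35, 40, 44]] = [1, -1, 1, -1, 1, -1, 1, -1, 1, -1]
        cfg = simulate.CohortConfig(n_subjects=300, seed=33, planted_weights=w, ld_blocks=9, ld_rho=0.85)
        cohort = simulate.simulate_cohort(cfg)
        X = cohort.truth.intercepts
        Z = cohort.genotypes
        base = stability.bootstrap_scca(X, Z, 0.3, 0.4, B=500, seed=6)
        # drop the immediate neighbour of each planted block representative
        drop = tuple(f"snp{i + 2:03d}" for i in (0, 5, 10, 15, 20, 25, 30, 35, 40))
        res = sensitivity_rerun(X, Z, Z, 0.3, 0.4, base_summary=base, exclude_features=drop)
        assert res["wprs_pearson_r"] >= 0.8

    def test_subject_exclusion_keeps_weight_signs(self, planted_cohort):
        from alsprs import stability

        X = planted_cohort.truth.intercepts
        Z = planted_cohort.genotypes
        base = stability.bootstrap_scca(X, Z, 0.3, 0.4, B=300, seed=7)
        exclude = tuple(Z.index[::10])  # every tenth subject
        res = sensitivity_rerun(X, Z, Z, 0.3, 0.4, base_summary=base, exclude_subjects=exclude)
        assert res["weight_sign_agreement"] >= 0.9


class TestWprsVersusUprs:
    def test_weighted_score_outperforms_unweighted_on_planted_signal(self):
        """With alternating-sign planted weights the weighted score tracks
        the liability while the raw allele count does not; the weighted
        score wins in nearly every seed."""
        from alsprs import stability

        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = simulate.CohortConfig(n_subjects=300, seed=60 + seed)
            cohort = simulate.simulate_cohort(cfg)
            summary = stability.bootstrap_scca(
                cohort.truth.intercepts, cohort.genotypes, 0.3, 0.4, B=200, seed=seed
            )
            wv = scoring.weights_from_bootstrap(summary)
            scores = compute_scores(cohort.genotypes, wv)
            r_w = abs(stats.spearmanr(scores["wPRS"], cohort.truth.liability).statistic)
            r_u = abs(stats.spearmanr(scores["uPRS"], cohort.truth.liability).statistic)
            wins += r_w > r_u
        assert wins >= 0.8 * n_seeds
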