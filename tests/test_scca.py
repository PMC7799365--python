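"""Sparse-CCA solver: closed-form subproblem, oracle equivalence, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from alsprs.scca import fit_scca, l1_constrained_unit, soft_threshold, standardize_columns


def grid_oracle_l1_unit(a, c, n_grid=1_000_000):
    """Independent brute force for the L1-ball subproblem: scan the
    soft-threshold level over a dense grid, normalise, keep the feasible
    maximiser of w'a."""
    a = np.asarray(a, float)
    best_w, best_val = None, -np.inf
    for delta in np.linspace(0, np.abs(a).max() * 0.999999, n_grid):
        s = np.sign(a) * np.maximum(np.abs(a) - delta, 0)
        n2 = np.linalg.norm(s)
        if n2 == 0:
            continue
        w = s / n2
        if np.abs(w).sum() <= c + 1e-9:
            val = w @ a
            if val > best_val:
                best_val, best_w = val, w
    return best_w


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "a, delta, expected",
        [
            ([3.0], 1.0, [2.0]),
            ([-0.5], 1.0, [0.0]),
            ([0.0, 2.0, -2.0], 2.0, [0.0, 0.0, 0.0]),
            ([1.5, -3.0, 0.2], 0.5, [1.0, -2.5, 0.0]),
        ],
    )
    def test_examples(self, a, delta, expected):
        np.testing.assert_allclose(soft_threshold(np.array(a), delta), expected)

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(np.array([1.0]), -0.1)


class TestL1ConstrainedUnit:
    def test_unconstrained_case_returns_unit_vector(self):
        w = l1_constrained_unit(np.array([3.0, 4.0]), 2.0)
        np.testing.assert_allclose(w, [0.6, 0.8], atol=1e-12)

    def test_maximal_sparsity_limit_selects_largest_coordinate(self):
        w = l1_constrained_unit(np.array([3.0, 4.0]), 1.0)
        np.testing.assert_allclose(w, [0.0, 1.0], atol=1e-8)

    def test_matches_grid_oracle(self):
        a = np.array([2.0, 1.0, 0.5])
        w = l1_constrained_unit(a, 1.2)
        oracle = grid_oracle_l1_unit(a, 1.2)
        np.testing.assert_allclose(w, oracle, atol=1e-4)
        assert abs(np.abs(w).sum() - 1.2) < 1e-6
        assert np.linalg.norm(w) <= 1 + 1e-8

    def test_tied_inputs_break_to_lowest_index(self):
        w = l1_constrained_unit(np.array([1.0, 1.0]), 1.0)
        np.testing.assert_allclose(w, [1.0, 0.0])

    def test_all_zero_errors(self):
        with pytest.raises(ValueError, match="undefined direction"):
            l1_constrained_unit(np.zeros(3), 1.5)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        a=arrays(
            np.float64,
            st.integers(2, 12),
            elements=st.floats(-50, 50, allow_nan=False),
        ).filter(lambda v: np.linalg.norm(v) > 1e-6),
        frac=st.floats(0.0, 1.0),
    )
    def test_solution_feasible_and_beats_single_coordinate(self, a, frac):
        """For any input and any feasible budget, the returned vector obeys
        both norm constraints and scores at least as well as the best
        single coordinate (always feasible)."""
        c = 1.0 + frac * (np.sqrt(len(a)) - 1.0)
        w = l1_constrained_unit(a, c)
        assert np.linalg.norm(w) <= 1 + 1e-8
        assert np.abs(w).sum() <= c + 1e-6
        assert w @ a >= np.max(np.abs(a)) - 1e-6


def angle_oracle_rho(X, Z, t, step_deg=0.05):
    """Exhaustive oracle for p = q = 2: parameterise both unit weight
    vectors by angle at ``step_deg`` resolution, reject pairs violating the
    L1 budget, maximise the penalized-matrix-decomposition objective
    u'X'Zv over the feasible grid, and return the data correlation of the
    winning composites."""
    c = max(1.0, t * np.sqrt(2))
    angles = np.deg2rad(np.arange(0.0, 360.0, step_deg))
    dirs = np.column_stack([np.cos(angles), np.sin(angles)])
    dirs = dirs[np.abs(dirs).sum(axis=1) <= c + 1e-12]
    Xs = standardize_columns(X)
    Zs = standardize_columns(Z)
    M = Xs.T @ Zs
    vals = (dirs @ M) @ dirs.T  # objective for every (u-angle, v-angle) pair
    i, j = np.unravel_index(np.argmax(vals), vals.shape)
    u, v = dirs[i], dirs[j]
    return float(np.corrcoef(Xs @ u, Zs @ v)[0, 1])


class TestFitScca:
    def test_identical_single_columns_give_perfect_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((30, 1))
        fit = fit_scca(x, x.copy(), 1.0, 1.0)
        assert fit.rho == pytest.approx(1.0, abs=1e-10)
        assert abs(fit.u[0]) == pytest.approx(1.0)
        assert abs(fit.v[0]) == pytest.approx(1.0)

    def test_one_dimensional_reduction_equals_abs_pearson(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((60, 1))
        z = -0.4 * x + rng.standard_normal((60, 1))
        fit = fit_scca(x, z, 1.0, 1.0)
        r = np.corrcoef(x[:, 0], z[:, 0])[0, 1]
        assert fit.rho == pytest.approx(abs(r), abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_angle_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        latent = rng.standard_normal((n, 1))
        X = 0.5 * latent + rng.standard_normal((n, 2))
        Z = 0.5 * latent + rng.standard_normal((n, 2))
        fit = fit_scca(X, Z, 0.8, 0.8)
        oracle = angle_oracle_rho(X, Z, 0.8)
        assert fit.rho == pytest.approx(oracle, abs=1e-3)

    def test_objective_monotone_in_debug_mode(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 6))
        Z = rng.standard_normal((40, 9))
        fit = fit_scca(X, Z, 0.5, 0.5, check_monotone=True)
        path = np.array(fit.objective_path)
        assert np.all(np.diff(path) >= -1e-9)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((35, 4))
        Z = rng.standard_normal((35, 7))
        fit = fit_scca(X, Z, 0.7, 0.7)
        perm = rng.permutation(35)
        fit_p = fit_scca(X[perm], Z[perm], 0.7, 0.7)
        np.testing.assert_allclose(fit.u, fit_p.u, atol=1e-10)
        np.testing.assert_allclose(fit.v, fit_p.v, atol=1e-10)
        assert fit.rho == pytest.approx(fit_p.rho, abs=1e-10)

    def test_column_sign_flip_flips_only_that_weight(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((45, 3))
        Z = rng.standard_normal((45, 5))
        fit = fit_scca(X, Z, 1.0, 1.0)
        Z2 = Z.copy()
        Z2[:, 2] *= -1
        fit2 = fit_scca(X, Z2, 1.0, 1.0)
        expected_v = fit.v.copy()
        expected_v[2] *= -1
        np.testing.assert_allclose(fit2.v, expected_v, atol=1e-6)
        np.testing.assert_allclose(fit2.u, fit.u, atol=1e-6)

    def test_support_shrinks_as_penalty_tightens(self):
        rng = np.random.default_rng(5)
        mean_nnz = []
        datasets = [
            (rng.standard_normal((40, 5)), rng.standard_normal((40, 20))) for _ in range(100)
        ]
        for tz in (1.0, 0.7, 0.4, 0.1):
            nnz = [np.count_nonzero(fit_scca(X, Z, 0.8, tz).v) for X, Z in datasets]
            mean_nnz.append(np.mean(nnz))
        assert all(a >= b - 1e-12 for a, b in zip(mean_nnz, mean_nnz[1:]))

    def test_sign_convention_orients_clinical_weights_nonpositive(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((50, 4))
        Z = rng.standard_normal((50, 6))
        fit = fit_scca(X, Z, 0.6, 0.6)
        assert fit.u.sum() <= 1e-12

    def test_fit_invariants_hold(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((30, 11))
        Z = rng.standard_normal((30, 50))
        for tx, tz in [(0.1, 0.3), (0.5, 0.5), (1.0, 1.0)]:
            fit = fit_scca(X, Z, tx, tz)
            assert np.linalg.norm(fit.u) <= 1 + 1e-8
            assert np.linalg.norm(fit.v) <= 1 + 1e-8
            assert np.abs(fit.u).sum() <= max(1.0, tx * np.sqrt(11)) + 1e-6
            assert np.abs(fit.v).sum() <= max(1.0, tz * np.sqrt(50)) + 1e-6
            assert -1 <= fit.rho <= 1

    def test_tightest_clinical_penalty_selects_single_variable(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((60, 11))
        Z = rng.standard_normal((60, 50))
        fit = fit_scca(X, Z, 0.1, 0.5)
        assert np.count_nonzero(fit.u) == 1
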