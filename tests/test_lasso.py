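import warnings

import numpy as np
import pytest

from seeddeconv.errors import NonFiniteInput
from seeddeconv.lasso import (
    correct_z,
    fit_lasso,
    kkt_violation,
    select_by_strength,
    soft_threshold,
)

from conftest import grid_minimize_lasso, make_membership


def random_instance(rng, n_pools=8, n_families=3):
    """Small random binary-membership problem with distinct columns
    (duplicate membership columns make the minimizer non-unique)."""
    pools = [f"p{i}" for i in range(n_pools)]
    seeds = ["AAAAAA", "CCCCCC", "GGGGGG", "UUUUUU"][:n_families]
    assignments = {}
    used = set()
    for s in seeds:
        while True:
            size = rng.integers(1, n_pools + 1)
            members = frozenset(rng.choice(pools, size=size, replace=False))
            if members not in used:
                used.add(members)
                assignments[s] = list(members)
                break
    X = make_membership(assignments, pools)
    z = rng.normal(0, 2, size=n_pools)
    return z, X


class TestSolver:
    def test_single_family_lambda_zero_is_member_mean(self):
        pools = [f"p{i}" for i in range(5)]
        X = make_membership({"AAAAAA": ["p0", "p2", "p4"]}, pools)
        z = np.array([3.0, 9.9, 5.0, -7.7, 1.0])
        fit = fit_lasso(z, X, 0.0)
        np.testing.assert_allclose(fit.beta[0], np.mean([3.0, 5.0, 1.0]), atol=1e-12)

    def test_disjoint_families_match_soft_threshold_closed_form(self):
        pools = [f"p{i}" for i in range(6)]
        X = make_membership(
            {"AAAAAA": ["p0", "p1"], "CCCCCC": ["p2", "p3", "p4"]}, pools
        )
        z = np.array([2.0, 4.0, -1.0, -2.0, -3.0, 9.0])
        lam = 1.5
        fit = fit_lasso(z, X, lam)
        expected = [
            soft_threshold(2.0 + 4.0, lam / 2) / 2,
            soft_threshold(-1.0 - 2.0 - 3.0, lam / 2) / 3,
        ]
        np.testing.assert_allclose(fit.beta, expected, atol=1e-10)

    def test_zero_response_gives_zero_solution(self):
        pools = ["p0", "p1", "p2"]
        X = make_membership({"AAAAAA": ["p0", "p1"], "CCCCCC": ["p1", "p2"]}, pools)
        for lam in (0.0, 0.001, 5.0):
            fit = fit_lasso(np.zeros(3), X, lam)
            np.testing.assert_allclose(fit.beta, 0.0)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_dense_grid_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        z, X = random_instance(rng)
        lam = float(rng.choice([0.0, 0.001, 0.5, 2.0]))
        fit = fit_lasso(z, X, lam)
        oracle = grid_minimize_lasso(z, X.toarray().astype(float), lam)
        np.testing.assert_allclose(fit.beta, oracle, atol=1e-4)

    @pytest.mark.parametrize("trial", range(10))
    def test_kkt_conditions_hold_at_convergence(self, trial):
        rng = np.random.default_rng(200 + trial)
        z, X = random_instance(rng, n_pools=20, n_families=4)
        lam = float(rng.choice([0.001, 0.2, 1.0]))
        fit = fit_lasso(z, X, lam)
        assert fit.converged
        assert kkt_violation(fit, z, X) < 1e-4

    def test_objective_not_above_null_model(self):
        rng = np.random.default_rng(3)
        z, X = random_instance(rng, n_pools=30, n_families=4)
        fit = fit_lasso(z, X, 0.7)
        assert fit.objective(z, X) <= (z @ z) + 1e-9

    def test_objective_monotone_in_sweeps(self):
        rng = np.random.default_rng(4)
        z, X = random_instance(rng, n_pools=30, n_families=4)
        objs = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for k in range(1, 8):
                fit = fit_lasso(z, X, 0.3, max_iter=k)
                objs.append(fit.objective(z, X))
        assert all(a >= b - 1e-10 for a, b in zip(objs, objs[1:]))

    def test_huge_lambda_zeroes_everything(self):
        rng = np.random.default_rng(5)
        z, X = random_instance(rng, n_pools=20, n_families=3)
        np.testing.assert_allclose(fit_lasso(z, X, 1e9).beta, 0.0)

    def test_lambda_zero_full_rank_equals_least_squares(self):
        rng = np.random.default_rng(6)
        z, X = random_instance(rng, n_pools=30, n_families=4)
        fit = fit_lasso(z, X, 0.0, tol=1e-12)
        ls, *_ = np.linalg.lstsq(X.toarray().astype(float), z, rcond=None)
        np.testing.assert_allclose(fit.beta, ls, atol=1e-8)

    def test_solution_invariant_to_row_permutation(self):
        rng = np.random.default_rng(7)
        pools = [f"p{i}" for i in range(12)]
        assignments = {
            "AAAAAA": pools[:5],
            "CCCCCC": pools[3:9],
            "GGGGGG": pools[8:],
        }
        z = rng.normal(size=12)
        X1 = make_membership(assignments, pools)
        perm = rng.permutation(12)
        X2 = make_membership(assignments, [pools[i] for i in perm])
        fit1 = fit_lasso(z, X1, 0.1)
        fit2 = fit_lasso(z[perm], X2, 0.1)
        np.testing.assert_allclose(fit1.beta, fit2.beta, atol=1e-8)

    def test_matches_sklearn_under_penalty_rescaling(self):
        # sklearn minimizes (1/2n)||z-Xb||^2 + alpha|b|; ours is the
        # unscaled form, so alpha = lambda / (2n)
        from sklearn.linear_model import Lasso

        rng = np.random.default_rng(8)
        z, X = random_instance(rng, n_pools=40, n_families=4)
        lam = 3.0
        fit = fit_lasso(z, X, lam, tol=1e-10)
        sk = Lasso(alpha=lam / (2 * len(z)), fit_intercept=False, tol=1e-12)
        sk.fit(X.toarray().astype(float), z)
        np.testing.assert_allclose(fit.beta, sk.coef_, atol=1e-6)

    def test_nonfinite_input_rejected(self):
        X = make_membership({"AAAAAA": ["p0"]}, ["p0", "p1"])
        with pytest.raises(NonFiniteInput):
            fit_lasso(np.array([np.nan, 1.0]), X, 0.1)


class TestSelection:
    def make_fit(self, beta):
        from seeddeconv.lasso import LassoFit

        seeds = [f"SEED{i:02d}" for i in range(len(beta))]
        return LassoFit(
            seeds=seeds, beta=np.asarray(beta, float), lambda_=0.001,
            n_iter=1, converged=True, residuals=np.zeros(1), pool_ids=["p0"],
        )

    def test_strict_threshold(self):
        fit = self.make_fit([-2.3, 0.4, 1.01])
        assert select_by_strength(fit, 1.0) == {"SEED00", "SEED02"}

    def test_boundary_value_excluded(self):
        fit = self.make_fit([1.0, -1.0, 1.000001])
        assert select_by_strength(fit, 1.0) == {"SEED02"}

    def test_all_below_cutoff_gives_empty_set(self):
        assert select_by_strength(self.make_fit([0.2, -0.9]), 1.0) == set()

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            select_by_strength(self.make_fit([1.0]), 0.0)


class TestCorrection:
    def test_empty_significant_set_is_identity(self):
        pools = ["p0", "p1", "p2"]
        X = make_membership({"AAAAAA": ["p0", "p1"]}, pools)
        z = np.array([1.0, 2.0, 3.0])
        fit = fit_lasso(z, X, 0.0)
        np.testing.assert_array_equal(correct_z(z, X, fit, set()), z)

    def test_single_member_pool_shifts_by_beta(self):
        pools = ["p0", "p1"]
        X = make_membership({"AAAAAA": ["p0"]}, pools)
        z = np.array([4.0, 1.0])
        fit = fit_lasso(z, X, 0.0)
        y = correct_z(z, X, fit, {"AAAAAA"})
        np.testing.assert_allclose(y, [4.0 - fit.beta[0], 1.0])

    def test_mean_removed_effect_equals_beta_for_disjoint_families(self):
        rng = np.random.default_rng(9)
        pools = [f"p{i}" for i in range(30)]
        assignments = {"AAAAAA": pools[:10], "CCCCCC": pools[10:18]}
        X = make_membership(assignments, pools)
        z = rng.normal(size=30)
        fit = fit_lasso(z, X, 0.0)
        y = correct_z(z, X, fit, set(assignments))
        for j, seed in enumerate(X.seeds):
            members = [pools.index(p) for p in assignments[seed]]
            np.testing.assert_allclose((z - y)[members].mean(), fit.beta[j], atol=1e-9)

    def test_subtract_all_flag_gives_model_residual(self):
        rng = np.random.default_rng(10)
        pools = [f"p{i}" for i in range(12)]
        X = make_membership({"AAAAAA": pools[:6], "CCCCCC": pools[4:]}, pools)
        z = rng.normal(size=12)
        fit = fit_lasso(z, X, 0.01)
        np.testing.assert_allclose(
            correct_z(z, X, fit, subtract_all=True), fit.residuals, atol=1e-9
        )

    def test_overlapping_significant_families_corrected_additively(self):
        pools = ["p0", "p1", "p2", "p3"]
        X = make_membership({"AAAAAA": ["p0", "p1"], "CCCCCC": ["p0", "p2"]}, pools)
        z = np.array([5.0, 2.0, 3.0, 0.0])
        fit = fit_lasso(z, X, 0.001)
        y = correct_z(z, X, fit, {"AAAAAA", "CCCCCC"})
        np.testing.assert_allclose(y[0], z[0] - fit.beta[0] - fit.beta[1], atol=1e-9)
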