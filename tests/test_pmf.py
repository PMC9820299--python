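"""PMF solver: uncertainty rules, the weighted objective, factor recovery."""

import numpy as np
import pandas as pd
import pytest

import wqsource as wq
from wqsource.pmf import (
    build_uncertainty,
    contribution_matrix,
    factor_count_scan,
    fit_pmf,
    match_factors,
    matched_contribution_correlation,
    q_statistic,
)


class TestUncertainty:
    def test_measured_entry_combines_error_and_mdl(self):
        u = build_uncertainty(np.array([[1.0]]), mdl=0.02, error_fraction=0.1)
        assert u[0, 0] == pytest.approx(np.sqrt(0.1**2 + 0.01**2))

    def test_censored_entry_uses_five_sixths_mdl(self):
        u = build_uncertainty(
            np.array([[0.005]]), mdl=0.01, error_fraction=0.1,
            censored=np.array([[True]]),
        )
        assert u[0, 0] == pytest.approx(5.0 / 6.0 * 0.01)

    def test_zero_mdl_degenerates_to_fractional_error(self):
        x = np.array([[2.0, 4.0]])
        u = build_uncertainty(x, mdl=0.0, error_fraction=0.1)
        np.testing.assert_allclose(u, 0.1 * x)

    def test_all_zero_specification_rejected(self):
        with pytest.raises(ValueError):
            build_uncertainty(np.ones((2, 2)), mdl=0.0, error_fraction=0.0)


class TestQStatistic:
    def test_exact_factorization_gives_zero(self):
        G = np.abs(np.random.default_rng(0).normal(size=(6, 2)))
        F = np.abs(np.random.default_rng(1).normal(size=(2, 4)))
        X = G @ F
        assert q_statistic(X, np.ones_like(X), G, F) == 0.0

    def test_unit_uncertainty_equals_frobenius_norm(self):
        rng = np.random.default_rng(2)
        X = np.abs(rng.normal(size=(5, 3)))
        G = np.abs(rng.normal(size=(5, 2)))
        F = np.abs(rng.normal(size=(2, 3)))
        assert q_statistic(X, np.ones_like(X), G, F) == pytest.approx(
            np.linalg.norm(X - G @ F, "fro") ** 2
        )

    def test_two_by_two_hand_computation(self):
        X = np.array([[2.0, 1.0], [1.0, 3.0]])
        G = np.array([[1.0], [1.0]])
        F = np.array([[1.0, 1.0]])
        U = np.array([[0.5, 1.0], [1.0, 2.0]])
        # residuals: [[1, 0], [0, 2]] -> (1/0.5)^2 + (2/2)^2 = 5
        assert q_statistic(X, U, G, F) == pytest.approx(5.0)


def planted_problem(n=30, m=8, p=2, seed=0, noise=0.0):
    """Separable planted factorization: each source has exclusive species
    (exact zeros in the other profiles), which makes the noiseless solution
    unique up to permutation and scale."""
    rng = np.random.default_rng(seed)
    G = rng.gamma(2.0, 1.0, size=(n, p))
    F = rng.uniform(0.1, 1.0, size=(p, m))
    for j in range(p):
        others = [jj for jj in range(p) if jj != j]
        F[others, 2 * j : 2 * j + 2] = 0.0   # species exclusive to source j
        G[3 * j : 3 * j + 3, others] = 0.0   # samples where only source j is active
    X = G @ F
    if noise:
        X = X * rng.lognormal(0, noise, size=X.shape)
    # detection-limit-like floor so zero entries carry a finite uncertainty
    U = np.maximum(0.1 * X, 0.01 * X.mean())
    return X, U, G, F


class TestFitPMF:
    def test_noiseless_reaches_machine_level_q(self):
        X, U, G0, F0 = planted_problem(seed=3)
        res = fit_pmf(X, U, p=2, n_starts=4, seed=1)
        assert res.Q <= 1e-6
        assert res.converged

    def test_q_non_increasing_across_iterations(self):
        X, U, *_ = planted_problem(seed=4, noise=0.1)
        res = fit_pmf(X, U, p=2, n_starts=3, seed=2)
        hist = res.q_history
        assert all(b <= a + 1e-9 * max(1.0, a) for a, b in zip(hist, hist[1:]))

    def test_factors_are_nonnegative_and_canonical(self):
        X, U, *_ = planted_problem(seed=5, noise=0.05)
        res = fit_pmf(X, U, p=2, n_starts=3, seed=3)
        assert (res.G >= 0).all() and (res.F >= 0).all()
        np.testing.assert_allclose(res.F.sum(axis=1), 1.0, atol=1e-9)
        total = res.G.sum(axis=0) * res.F.sum(axis=1)
        assert np.all(np.diff(total) <= 1e-9)  # descending total mass

    def test_noiseless_rank2_recovers_true_contribution_shares(self):
        X, U, G0, F0 = planted_problem(n=40, seed=6)
        res = fit_pmf(X, U, p=2, n_starts=6, seed=4)
        c_est = contribution_matrix(res)
        c_true = contribution_matrix((G0, F0))
        perm = match_factors(c_est, c_true)
        np.testing.assert_allclose(c_est[perm], c_true, atol=1e-3)

    def test_best_of_starts_is_reported(self):
        X, U, *_ = planted_problem(seed=7, noise=0.2)
        res = fit_pmf(X, U, p=2, n_starts=5, seed=5)
        assert res.Q == pytest.approx(min(res.q_per_start))

    def test_invalid_factor_count_rejected(self):
        X, U, *_ = planted_problem()
        with pytest.raises(ValueError):
            fit_pmf(X, U, p=8, n_starts=1, seed=0)

    def test_negative_data_rejected(self):
        X, U, *_ = planted_problem()
        X[0, 0] = -1.0
        with pytest.raises(ValueError):
            fit_pmf(X, U, p=2, n_starts=1, seed=0)


class TestContributionMatrix:
    def test_single_factor_owns_everything(self):
        X, U, *_ = planted_problem(seed=8)
        res = fit_pmf(X, U, p=1, n_starts=2, seed=1)
        np.testing.assert_allclose(contribution_matrix(res), 1.0, atol=1e-12)

    def test_zero_loading_gives_zero_share(self):
        G = np.ones((4, 2))
        F = np.array([[1.0, 0.0], [1.0, 2.0]])
        c = contribution_matrix((G, F))
        assert c[0, 1] == 0.0

    def test_matches_elementwise_double_loop(self):
        rng = np.random.default_rng(9)
        G = rng.gamma(1.0, 1.0, size=(5, 3))
        F = rng.gamma(1.0, 1.0, size=(3, 4))
        c = contribution_matrix((G, F))
        for j in range(3):
            for i in range(4):
                num = sum(G[n, j] * F[j, i] for n in range(5))
                den = sum(G[n, jj] * F[jj, i] for n in range(5) for jj in range(3))
                assert c[j, i] == pytest.approx(num / den)

    def test_zero_mass_species_flagged_nan(self):
        G = np.ones((3, 2))
        F = np.array([[1.0, 0.0], [1.0, 0.0]])
        c = contribution_matrix((G, F))
        assert np.isnan(c[:, 1]).all()


class TestScanAndMatching:
    def test_factor_scan_reports_decreasing_q(self):
        X, U, *_ = planted_problem(n=40, m=6, p=3, seed=10, noise=0.05)
        scan = factor_count_scan(X, U, [1, 2, 3], n_starts=2, seed=0, max_iter=300)
        assert scan["Q"].is_monotonic_decreasing

    def test_matching_recovers_a_known_permutation(self):
        rng = np.random.default_rng(11)
        c_true = rng.dirichlet(np.full(3, 0.5), size=6).T  # 3 factors x 6 species
        perm = np.array([2, 0, 1])
        c_est = c_true[perm]
        back = match_factors(c_est, c_true)
        np.testing.assert_array_equal(c_est[back], c_true)
        assert matched_contribution_correlation(c_est, c_true) == pytest.approx(1.0)
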