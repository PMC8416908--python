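import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rgnb.data_model import CountMatrix, LabelVector
from rgnb.errors import DomainError
from rgnb.nb_core import (
    PHI_MIN,
    estimate_dispersion_raw,
    fit_beta,
    nb_log_pmf,
    sample_log_likelihood,
    shrink_dispersion_wl,
)
from rgnb.preprocessing import compute_class_means


def scipy_nb_logpmf(y, mu, phi):
    """Independent oracle: scipy's NB with n = 1/phi, p = 1/(1 + phi*mu)."""
    return stats.nbinom.logpmf(y, 1.0 / phi, 1.0 / (1.0 + phi * mu))


class TestNbLogPmf:
    def test_zero_count_closed_form(self):
        assert nb_log_pmf(0, 2.0, 0.5) == pytest.approx(-2.0 * math.log(2.0), abs=1e-12)
        for mu in (0.5, 3.0, 70.0):
            for phi in (0.05, 0.4, 2.0):
                assert nb_log_pmf(0, mu, phi) == pytest.approx(
                    -(1.0 / phi) * math.log1p(phi * mu), abs=1e-12
                )

    def test_poisson_limit(self):
        expected = 3 * math.log(2) - 2 - math.log(6)
        assert nb_log_pmf(3, 2.0, 1e-12) == pytest.approx(expected, abs=1e-6)

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 200, size=50)
        mu = rng.uniform(0.5, 100, size=50)
        phi = rng.uniform(0.01, 3.0, size=50)
        np.testing.assert_allclose(
            nb_log_pmf(y, mu, phi), scipy_nb_logpmf(y, mu, phi), atol=1e-10
        )

    def test_normalizes(self):
        y = np.arange(5001)
        total = np.exp(nb_log_pmf(y, 50.0, 0.8)).sum()
        assert 1 - 1e-6 <= total <= 1.0 + 1e-12

    def test_continuous_at_poisson_switch(self):
        from rgnb.nb_core import POISSON_SWITCH

        for y, mu in [(7, 13.0), (0, 2.0), (120, 90.0)]:
            below = nb_log_pmf(y, mu, POISSON_SWITCH)
            above = nb_log_pmf(y, mu, POISSON_SWITCH * (1 + 1e-9))
            assert abs(below - above) < 1e-6

    def test_stable_for_tiny_phi(self):
        # at phi = 1e-10 the exact NB differs from Poisson by O(phi*(y-mu)^2)
        for y, mu in [(7, 13.0), (120, 90.0), (0, 5.0)]:
            nb = nb_log_pmf(y, mu, 2e-10)  # just above the switch: NB branch
            pois = nb_log_pmf(y, mu, 0.0)
            assert abs(nb - pois) < 1e-6

    def test_huge_count_no_overflow(self):
        val = nb_log_pmf(10**9, 1e8, 0.5)
        assert np.isfinite(val)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            nb_log_pmf(1, 0.0, 0.5)
        with pytest.raises(DomainError):
            nb_log_pmf(1, 2.0, -0.1)
        with pytest.raises(DomainError):
            nb_log_pmf(1.5, 2.0, 0.5)


class TestSampleLogLikelihood:
    def test_single_gene(self):
        assert sample_log_likelihood([4], [2.0], [0.5]) == pytest.approx(
            float(nb_log_pmf(4, 2.0, 0.5))
        )

    def test_three_gene_term_by_term_oracle(self):
        y, mu, phi = [1, 0, 4], [2.0, 1.0, 5.0], [0.5, 0.5, 0.5]
        expected = sum(scipy_nb_logpmf(a, b, c) for a, b, c in zip(y, mu, phi))
        assert sample_log_likelihood(y, mu, phi) == pytest.approx(expected, abs=1e-10)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 40, size=12)
        mu = rng.uniform(1, 30, size=12)
        phi = rng.uniform(0.05, 1.0, size=12)
        perm = rng.permutation(12)
        assert sample_log_likelihood(y, mu, phi) == pytest.approx(
            sample_log_likelihood(y[perm], mu[perm], phi[perm]), rel=1e-14
        )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            sample_log_likelihood([1, 2], [1.0], [0.5])


def dataset_with_means(counts_arr, labels_list):
    G, n = counts_arr.shape
    cm = CountMatrix([f"g{i}" for i in range(G)], [f"s{i}" for i in range(n)], counts_arr)
    lv = LabelVector(cm.sample_ids, labels_list, sorted(set(labels_list)))
    return cm, compute_class_means(cm, lv)


class TestEstimateDispersionRaw:
    def test_grid_oracle_ten_samples(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(rng.gamma(2.0, 0.5 * 25.0, size=(1, 10)))
        cm, means = dataset_with_means(counts, ["a"] * 5 + ["b"] * 5)
        phi_hat, _ = estimate_dispersion_raw(cm, means)

        mu = means.mean_matrix(cm)
        grid = np.linspace(np.log(1e-6), np.log(1e3), 2000)
        lls = [np.sum(nb_log_pmf(cm.counts[0], mu[0], np.exp(g))) for g in grid]
        best = grid[int(np.argmax(lls))]
        step = grid[1] - grid[0]
        assert abs(np.log(phi_hat[0]) - best) <= step

    def test_consistency_simulation(self):
        # true phi = 0.5, mu = 30, n = 2000, means held at truth:
        # MLE within +-0.1 in >= 95/100 runs
        from rgnb.preprocessing import ClassMeans

        n = 2000
        half = n // 2
        means = ClassMeans(
            gene_ids=["g0"],
            class_set=["a", "b"],
            sample_ids=[f"s{i}" for i in range(n)],
            labels=["a"] * half + ["b"] * half,
            size_factors={"a": np.full(half, 1.0 / half),
                          "b": np.full(half, 1.0 / half)},
            lambdas={"a": np.array([30.0 * half]), "b": np.array([30.0 * half])},
            class_positions={"a": np.arange(half), "b": np.arange(half, n)},
        )
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            counts = rng.poisson(rng.gamma(2.0, 0.5 * 30.0, size=(1, n)))
            cm = CountMatrix(["g0"], means.sample_ids, counts)
            phi_hat, _ = estimate_dispersion_raw(cm, means)
            if abs(phi_hat[0] - 0.5) <= 0.1:
                hits += 1
        assert hits >= 95

    def test_poisson_data_hits_lower_bound(self):
        at_bound = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            counts = rng.poisson(25.0, size=(1, 500))
            cm, means = dataset_with_means(counts, ["a"] * 250 + ["b"] * 250)
            phi_hat, _ = estimate_dispersion_raw(cm, means)
            if phi_hat[0] <= PHI_MIN * 10:
                at_bound += 1
        assert at_bound > 10

    def test_tau2_positive(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(rng.gamma(2.0, 0.5 * 20.0, size=(5, 60)))
        cm, means = dataset_with_means(counts, ["a"] * 30 + ["b"] * 30)
        _, tau2 = estimate_dispersion_raw(cm, means)
        assert (tau2 > 0).all()


class TestShrinkDispersionWl:
    def test_all_equal_is_fixed_point(self):
        phi = np.full(6, 0.37)
        tau2 = np.full(6, 0.01)
        est = shrink_dispersion_wl(phi, tau2)
        assert est.phi0 == pytest.approx(0.37, abs=1e-14)
        np.testing.assert_allclose(est.phi_shrunk, 0.37, atol=1e-14)

    def test_alpha_zero_identity(self):
        phi = np.array([0.1, 0.5, 0.9])
        tau2 = np.array([0.01, 0.02, 0.03])
        est = shrink_dispersion_wl(phi, tau2, alpha=0.0)
        np.testing.assert_allclose(est.phi_shrunk, phi, atol=1e-15)

    def test_two_gene_hand_example(self):
        # phi = {0.2, 0.6}, tau2 = {0.01, 0.01}, tau0^2 = 0.03 (population
        # variance 0.04 minus mean tau2 0.01) -> alpha = 1/6, phi0 = 0.4,
        # shrunken first gene = (0.2/0.01 + (1/6)*80) / (1/0.01 + (1/6)*200)
        phi = np.array([0.2, 0.6])
        tau2 = np.array([0.01, 0.01])
        est = shrink_dispersion_wl(phi, tau2)
        assert est.tau02 == pytest.approx(0.03, abs=1e-12)
        assert est.alpha == pytest.approx(1.0 / 6.0, abs=1e-12)
        assert est.phi0 == pytest.approx(0.4, abs=1e-12)
        expected_1 = (0.2 / 0.01 + (1 / 6) * (0.2 / 0.01 + 0.6 / 0.01)) / (
            1 / 0.01 + (1 / 6) * (2 / 0.01)
        )
        expected_2 = (0.6 / 0.01 + (1 / 6) * (0.2 / 0.01 + 0.6 / 0.01)) / (
            1 / 0.01 + (1 / 6) * (2 / 0.01)
        )
        assert est.phi_shrunk[0] == pytest.approx(expected_1, abs=1e-12)
        assert est.phi_shrunk[1] == pytest.approx(expected_2, abs=1e-12)

    def test_single_gene_warns_and_passes_through(self):
        with pytest.warns(UserWarning):
            est = shrink_dispersion_wl(np.array([0.4]), np.array([0.01]))
        assert est.phi_shrunk[0] == pytest.approx(0.4)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_contraction_toward_common_value(self, seed):
        rng = np.random.default_rng(seed)
        G = rng.integers(2, 30)
        phi = rng.uniform(0.01, 2.0, size=G)
        tau2 = rng.uniform(1e-4, 0.1, size=G)
        est = shrink_dispersion_wl(phi, tau2)
        assert np.all(
            np.abs(est.phi_shrunk - est.phi0) <= np.abs(est.phi_raw - est.phi0) + 1e-12
        )

    def test_convex_combination_bounds(self):
        rng = np.random.default_rng(9)
        phi = rng.uniform(0.05, 1.5, size=10)
        tau2 = rng.uniform(1e-3, 0.05, size=10)
        est = shrink_dispersion_wl(phi, tau2)
        lo = np.minimum(est.phi_raw, est.phi0) - 1e-12
        hi = np.maximum(est.phi_raw, est.phi0) + 1e-12
        assert np.all((est.phi_shrunk >= lo) & (est.phi_shrunk <= hi))


class TestFitBeta:
    def test_intercept_only_mean_of_logs(self):
        X = np.ones((2, 1))
        mu = np.array([[math.e**2], [math.e**4]])
        fit = fit_beta(X, mu)
        assert fit.betas[0, 0] == pytest.approx(3.0, abs=1e-12)

    def test_exact_linear_recovery(self):
        rng = np.random.default_rng(4)
        X = np.column_stack([np.ones(20), rng.normal(size=(20, 2))])
        beta_true = np.array([[2.0, 0.5, -0.3], [1.0, -1.0, 0.2]])  # (G=2, p=3)
        mu = np.exp(X @ beta_true.T)
        fit = fit_beta(X, mu)
        np.testing.assert_allclose(fit.betas, beta_true, atol=1e-10)
        np.testing.assert_allclose(fit.rss, 0.0, atol=1e-16)

    def test_duplicated_column_minimum_norm_vs_ridge_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=10)
        X = np.column_stack([np.ones(10), x, x])  # rank-deficient
        mu = np.exp(1.0 + 0.8 * x)[:, None]
        fit = fit_beta(X, mu)
        # ridge-limit oracle in stable augmented form: min ||Xb-y||^2 + lam||b||^2
        lam = 1e-12
        X_aug = np.vstack([X, np.sqrt(lam) * np.eye(3)])
        y_aug = np.concatenate([np.log(mu)[:, 0], np.zeros(3)])
        ridge, *_ = np.linalg.lstsq(X_aug, y_aug, rcond=None)
        np.testing.assert_allclose(fit.betas[0], ridge, atol=1e-6)

    def test_nonpositive_mu_rejected(self):
        with pytest.raises(DomainError):
            fit_beta(np.ones((2, 1)), np.array([[1.0], [0.0]]))
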