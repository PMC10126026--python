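"""Closed-form coefficient checks against hand-derived values."""

import numpy as np
import pytest

from relicred import (EstimatorError, ItemResponseMatrix, cronbach_alpha, glb,
                      guttman_lambda2, guttman_lambda6, item_rest_correlation,
                      omega_from_params, sample_covariance)


class TestAlpha:
    def test_two_item(self, sigma2):
        assert cronbach_alpha(sigma2) == pytest.approx(2 / 3, abs=1e-12)

    def test_three_item(self, sigma3):
        assert cronbach_alpha(sigma3) == pytest.approx(0.75, abs=1e-12)

    def test_diagonal_is_zero(self):
        assert cronbach_alpha(np.diag([1.0, 2.0, 3.0])) == pytest.approx(0.0)

    def test_degenerate_total_variance(self):
        sigma = np.array([[1.0, -1.0], [-1.0, 1.0]])
        with pytest.raises(EstimatorError):
            cronbach_alpha(sigma)

    def test_asymmetric_rejected(self):
        with pytest.raises(EstimatorError):
            cronbach_alpha(np.array([[1.0, 0.5], [0.2, 1.0]]))


class TestLambda2:
    def test_two_item(self, sigma2):
        # (3 - 2 + 1) / 3
        assert guttman_lambda2(sigma2) == pytest.approx(2 / 3, abs=1e-12)

    def test_three_item(self, sigma3):
        # (6 - 3 + 1.5) / 6
        assert guttman_lambda2(sigma3) == pytest.approx(0.75, abs=1e-12)

    def test_diagonal_is_zero(self):
        assert guttman_lambda2(np.diag([1.0, 1.0, 4.0])) == pytest.approx(0.0)

    def test_at_least_alpha_random(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            k = rng.integers(2, 9)
            a = rng.normal(size=(k, k + 2))
            s = a @ a.T
            assert guttman_lambda2(s) >= cronbach_alpha(s) - 1e-12


class TestLambda6:
    def test_two_item(self, sigma2):
        # residual variance .75 per item; 1 - 1.5/3
        assert guttman_lambda6(sigma2) == pytest.approx(0.5, abs=1e-12)

    def test_three_item(self, sigma3):
        # inverse diagonal entries 1.5 each; 1 - 2/6
        assert guttman_lambda6(sigma3) == pytest.approx(2 / 3, abs=1e-12)

    def test_diagonal_is_zero(self):
        assert guttman_lambda6(np.diag([1.0, 2.0, 1.0])) == pytest.approx(0.0)

    def test_singular_raises(self):
        s = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(EstimatorError, match="singular"):
            guttman_lambda6(s)


class TestGlb:
    def test_two_item(self, sigma2):
        assert glb(sigma2) == pytest.approx(2 / 3, abs=1e-6)

    def test_three_item(self, sigma3):
        assert glb(sigma3) == pytest.approx(0.75, abs=1e-6)

    def test_diagonal_is_zero(self):
        assert glb(np.diag([1.0, 2.0])) == pytest.approx(0.0, abs=1e-6)

    def test_in_unit_interval_random(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a = rng.normal(size=(4, 6))
            val = glb(a @ a.T)
            assert 0.0 <= val <= 1.0

    def test_brute_force_grid_k2(self):
        """Lattice search over theta on a 0.01 grid agrees to 1e-2."""
        rng = np.random.default_rng(11)
        for _ in range(10):
            a = rng.normal(size=(2, 4))
            s = a @ a.T
            grid0 = np.arange(0.0, s[0, 0] + 1e-12, 0.01 * s[0, 0])
            grid1 = np.arange(0.0, s[1, 1] + 1e-12, 0.01 * s[1, 1])
            best = 0.0
            for t0 in grid0:
                for t1 in grid1:
                    m = s - np.diag([t0, t1])
                    if np.linalg.eigvalsh(m)[0] >= -1e-12:
                        best = max(best, t0 + t1)
            brute = 1.0 - best / s.sum()
            assert glb(s) == pytest.approx(brute, abs=1e-2)

    def test_not_psd_rejected(self):
        s = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(EstimatorError):
            glb(s)


class TestOrderingHierarchy:
    def test_alpha_lambda2_glb_on_1000_random_psd(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            k = int(rng.integers(2, 9))
            a = rng.normal(size=(k, k + 2))
            s = a @ a.T / (k + 2)
            al = cronbach_alpha(s)
            l2 = guttman_lambda2(s)
            g = glb(s)
            assert al <= l2 + 1e-9
            assert l2 <= g + 1e-6

    def test_parallel_items_all_equal(self):
        """Compound symmetry: alpha = lambda2 = glb = omega of the match."""
        for k, rho in [(3, 0.3), (5, 0.5), (4, 0.7)]:
            s = np.full((k, k), rho)
            np.fill_diagonal(s, 1.0)
            lam = np.full(k, np.sqrt(rho))
            psi = np.full(k, 1.0 - rho)
            om = omega_from_params(lam, psi, 1.0)
            assert cronbach_alpha(s) == pytest.approx(om, abs=1e-6)
            assert guttman_lambda2(s) == pytest.approx(om, abs=1e-6)
            assert glb(s) == pytest.approx(om, abs=1e-6)

    def test_simultaneous_scalar_invariance(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(4, 6))
        s = a @ a.T
        for fn in (cronbach_alpha, guttman_lambda2, guttman_lambda6, glb):
            assert fn(4.0 * s) == pytest.approx(fn(s), abs=1e-6)


class TestOmegaFromParams:
    def test_closed_form(self):
        lam = np.full(3, 0.70711)
        psi = np.full(3, 0.5)
        assert omega_from_params(lam, psi, 1.0) == pytest.approx(4.5 / 6.0,
                                                                 abs=1e-4)

    def test_zero_residuals_is_one(self):
        assert omega_from_params([0.5, 0.5], [0.0, 0.0]) == pytest.approx(1.0)

    def test_zero_loadings_is_zero(self):
        assert omega_from_params([0.0, 0.0], [1.0, 1.0]) == pytest.approx(0.0)

    def test_latent_variance_scaling(self):
        # phi = 4 doubles each effective loading
        direct = omega_from_params([0.5, 0.5, 0.5], [0.4, 0.4, 0.4], 4.0)
        scaled = omega_from_params([1.0, 1.0, 1.0], [0.4, 0.4, 0.4], 1.0)
        assert direct == pytest.approx(scaled, abs=1e-12)


class TestItemRestCorrelation:
    def test_two_items_equals_correlation(self, sigma2):
        assert item_rest_correlation(sigma2, 0) == pytest.approx(0.5)

    def test_three_item_compound(self, sigma3):
        assert item_rest_correlation(sigma3, 0) == pytest.approx(1 / np.sqrt(3),
                                                                 abs=1e-6)

    def test_diagonal_is_zero(self):
        assert item_rest_correlation(np.diag([1.0, 2.0, 1.0]), 1) == pytest.approx(0.0)

    def test_bounds(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            a = rng.normal(size=(4, 6))
            s = a @ a.T
            for i in range(4):
                assert -1.0 <= item_rest_correlation(s, i) <= 1.0


class TestSampleCovariance:
    def test_identical_rows_zero(self):
        data = ItemResponseMatrix.from_values([[1.0, 2.0], [1.0, 2.0]])
        assert np.allclose(sample_covariance(data), 0.0)

    def test_hand_computed(self):
        data = ItemResponseMatrix.from_values([[0.0, 0.0], [1.0, 1.0]])
        assert np.allclose(sample_covariance(data),
                           [[0.5, 0.5], [0.5, 0.5]])

    def test_brute_force_oracle(self):
        rows = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        data = ItemResponseMatrix.from_values(rows)
        n = rows.shape[0]
        mean = rows.mean(axis=0)
        expect = sum(np.outer(r - mean, r - mean) for r in rows) / (n - 1)
        assert np.allclose(sample_covariance(data), expect)

    def test_listwise_view(self):
        vals = np.array([[0.0, 0.0], [1.0, np.nan], [2.0, 2.0], [4.0, 4.0]])
        data = ItemResponseMatrix.from_values(vals)
        complete = np.array([[0.0, 0.0], [2.0, 2.0], [4.0, 4.0]])
        assert np.allclose(sample_covariance(data),
                           np.cov(complete, rowvar=False, ddof=1))
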