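import numpy as np
import pytest

from relicred import (FactorPrior, ItemResponseMatrix, McmcConfig,
                      bayesian_fit_measures, gibbs_factor_sampler,
                      make_two_factor, make_unidimensional, ppc_eigenvalues,
                      rhat, rhat_is_problematic, traceplot_data)
from relicred.diagnostics import simulate_eigenvalue_bands, _gaussian_loglik
from relicred.factor import FactorDraws, implied_covariance
from relicred.simulate import GeneratorSpec, two_factor_covariance


class TestRhat:
    def test_identical_chains(self):
        chain = np.arange(100.0)
        val = rhat(np.stack([chain, chain, chain]))
        assert val == pytest.approx(np.sqrt(99 / 100), abs=1e-12)

    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(1)
        val = rhat(rng.normal(size=(3, 10_000)))
        assert val == pytest.approx(1.0, abs=0.01)

    def test_separated_chains_formula_oracle(self):
        rng = np.random.default_rng(2)
        chains = np.stack([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
        val = rhat(chains)
        assert val > 1.1
        # brute-force the formula
        m, n = chains.shape
        w = np.mean([np.var(c, ddof=1) for c in chains])
        b = n * np.var([c.mean() for c in chains], ddof=1)
        expect = np.sqrt(((n - 1) / n * w + b / n) / w)
        assert val == pytest.approx(expect, abs=1e-12)

    def test_zero_within_variance_infinite(self):
        chains = np.array([[1.0, 1.0, 1.0], [2.0, 2.0, 2.0]])
        with pytest.warns(UserWarning):
            assert rhat(chains) == np.inf

    def test_problem_flag(self):
        assert rhat_is_problematic(1.2)
        assert not rhat_is_problematic(1.05)

    def test_needs_two_chains(self):
        with pytest.raises(ValueError):
            rhat(np.ones((1, 100)))


class TestTraceplotData:
    def test_shapes_default_layout(self):
        chains = np.random.default_rng(0).normal(size=(3, 950))
        series = traceplot_data(chains)
        assert len(series) == 3
        assert all(len(s["values"]) == 950 for s in series)

    def test_thinned_length(self):
        chains = np.zeros((3, 475))
        series = traceplot_data(chains)
        assert all(len(s["iterations"]) == 475 for s in series)

    def test_values_untransformed(self):
        chains = np.random.default_rng(1).normal(size=(2, 50))
        series = traceplot_data(chains)
        np.testing.assert_array_equal(series[1]["values"], chains[1])


def _degenerate_draws(lam, psi, phi=1.0, reps=200):
    k = len(lam)
    return FactorDraws(
        loadings=np.tile(np.asarray(lam, float), (1, reps, 1)),
        residual_variances=np.tile(np.asarray(psi, float), (1, reps, 1)),
        latent_variance=np.full((1, reps), phi),
        omega=np.full((1, reps), 0.5),
    )


class TestPpcEigenvalues:
    def test_well_specified_data_inside(self):
        spec = GeneratorSpec(n=500, k=5, target_omega=0.8, seed=60)
        data = make_unidimensional(spec)
        draws = gibbs_factor_sampler(
            data, FactorPrior(),
            McmcConfig(chains=1, iterations=450, burn_in=50), seed=61,
        )
        res = ppc_eigenvalues(data, draws, seed=61)
        assert res.inside.all()
        assert res.all_inside
        assert (res.band_lower <= res.band_upper).all()
        assert (np.diff(res.observed_eigenvalues) <= 1e-10).all()

    def test_two_factor_misfit_flags_second_eigenvalue(self):
        data = make_two_factor(n=500, k_per_block=3, between_corr=0.2, seed=62)
        draws = gibbs_factor_sampler(
            data, FactorPrior(),
            McmcConfig(chains=1, iterations=400, burn_in=100), seed=63,
        )
        res = ppc_eigenvalues(data, draws, seed=64)
        assert not res.inside[1]  # rank 2 outside its band

    def test_calibration_quick(self):
        """~95% of rank flags inside when bands come from the true model."""
        spec = GeneratorSpec(n=200, k=4, target_omega=0.75, seed=65)
        lam, psi, phi = spec.resolve()
        sigma = spec.population_covariance()
        implied = np.tile(sigma, (600, 1, 1))
        lower, upper = simulate_eigenvalue_bands(implied, 200, seed=66)
        rng = np.random.default_rng(67)
        hits = []
        for _ in range(100):
            x = rng.multivariate_normal(np.zeros(4), sigma, size=200)
            ev = np.linalg.eigvalsh(np.cov(x, rowvar=False))[::-1]
            hits.append((ev >= lower) & (ev <= upper))
        coverage = np.mean(hits)
        assert coverage == pytest.approx(0.95, abs=0.05)

    def test_n_reps_cap(self, tiny_data, small_mcmc):
        draws = gibbs_factor_sampler(tiny_data, FactorPrior(), small_mcmc,
                                     seed=68)
        with pytest.raises(ValueError):
            ppc_eigenvalues(tiny_data, draws, n_reps=10**6, seed=69)


class TestFitMeasures:
    def test_perfect_fit_saturated_k3(self):
        """k=3: the one-factor model is saturated; exact-fit draws give
        zero chi-square, zero BRMSEA and unit BCFI."""
        rng = np.random.default_rng(70)
        f = rng.normal(size=300)
        vals = np.outer(f, [0.8, 0.7, 0.6]) + rng.normal(0, 0.5, (300, 3))
        data = ItemResponseMatrix.from_values(vals)
        x = vals - vals.mean(axis=0)
        s = np.cov(x, rowvar=False, ddof=1)
        # Spearman solution reproducing S exactly
        l1 = np.sqrt(s[0, 1] * s[0, 2] / s[1, 2])
        l2 = np.sqrt(s[0, 1] * s[1, 2] / s[0, 2])
        l3 = np.sqrt(s[0, 2] * s[1, 2] / s[0, 1])
        lam = np.array([l1, l2, l3])
        psi = np.diag(s) - lam**2
        assert (psi > 0).all()
        draws = _degenerate_draws(lam, psi, 1.0, reps=100)
        fit = bayesian_fit_measures(data, draws, seed=71)
        assert fit.brmsea == pytest.approx(0.0, abs=1e-6)
        assert fit.p_brmsea_below == 1.0
        assert fit.bcfi == pytest.approx(1.0, abs=1e-6)
        assert fit.blr == pytest.approx(0.0, abs=1e-6)

    def test_formula_oracle_fixed_draws(self):
        """Deviance per draw equals a direct evaluation of the formulas."""
        rng = np.random.default_rng(72)
        vals = rng.multivariate_normal(np.zeros(4), np.eye(4) + 0.3, size=120)
        data = ItemResponseMatrix.from_values(vals)
        lam_set = [np.full(4, 0.5), np.full(4, 0.6), np.full(4, 0.4)]
        psi_set = [np.full(4, 0.8), np.full(4, 0.7), np.full(4, 0.9)]
        draws = FactorDraws(
            loadings=np.stack(lam_set)[None, :, :],
            residual_variances=np.stack(psi_set)[None, :, :],
            latent_variance=np.ones((1, 3)),
            omega=np.full((1, 3), 0.5),
        )
        fit = bayesian_fit_measures(data, draws, seed=73)
        x = vals - vals.mean(axis=0)
        s = np.cov(x, rowvar=False, ddof=1)
        ll_sat = _gaussian_loglik(x, s)
        devs = []
        for lam, psi in zip(lam_set, psi_set):
            sig = implied_covariance(lam, psi, 1.0)
            devs.append(2 * (ll_sat - _gaussian_loglik(x, sig)))
        dev_pm = 2 * (ll_sat - _gaussian_loglik(
            x, implied_covariance(np.mean(lam_set, axis=0),
                                  np.mean(psi_set, axis=0), 1.0)))
        pd_eff = np.mean(devs) - dev_pm
        pstar = 4 * 5 / 2
        expect = np.sqrt(np.maximum(np.array(devs) - pstar, 0)
                         / ((pstar - pd_eff) * 120))
        np.testing.assert_allclose(fit.brmsea_draws, expect, atol=1e-10)
        assert fit.blr == pytest.approx(dev_pm, abs=1e-10)

    def test_misfit_increases_brmsea(self):
        """Same fixed draws, data perturbed away from the model -> larger
        posterior-mean BRMSEA."""
        spec = GeneratorSpec(n=400, k=5, target_omega=0.8, seed=74)
        lam, psi, phi = spec.resolve()
        draws = _degenerate_draws(lam, psi, phi, reps=50)
        good = make_unidimensional(spec)
        fit_good = bayesian_fit_measures(good, draws, seed=75)
        # block misfit: items {0,1,2} and {3,4} correlate .6 within, .1 across
        bad_sigma = np.full((5, 5), 0.1)
        bad_sigma[:3, :3] = 0.6
        bad_sigma[3:, 3:] = 0.6
        np.fill_diagonal(bad_sigma, 1.0)
        from relicred import make_from_covariance
        bad = make_from_covariance(bad_sigma, 400, seed=76)
        fit_bad = bayesian_fit_measures(bad, draws, seed=77)
        assert fit_bad.brmsea >= fit_good.brmsea

    def test_probability_ranges(self, tiny_data, small_mcmc):
        draws = gibbs_factor_sampler(tiny_data, FactorPrior(), small_mcmc,
                                     seed=78)
        fit = bayesian_fit_measures(tiny_data, draws, seed=79)
        for p in (fit.p_brmsea_below, fit.p_bcfi_above, fit.p_btli_above):
            assert 0.0 <= p <= 1.0
        assert (fit.brmsea_draws >= 0).all()
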