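"""Inference-core tests: noise estimation, energies, Laplace marginals, priors."""

import math

import numpy as np
import pytest
from scipy import integrate
from scipy.optimize import minimize
from scipy.stats import norm

from fretbayes.data import FretDataset, SampleMeasurements
from fretbayes.likelihood import (
    NoiseEstimate,
    PriorSpec,
    SampleStats,
    _make_energy,
    energy_grid,
    estimate_noise,
    laplace_log_marginal,
    log_posterior,
    log_prior,
    profile_totals,
    sample_energy,
)
from fretbayes.spectral import ModelParams, predict_intensities


def noiseless_sample(D0, A0, params, kappa, n=5, sample_id="clean"):
    pred = predict_intensities(D0, A0, params, kappa)
    return SampleMeasurements(sample_id, np.tile(pred, (n, 1)))


class TestEstimateNoise:
    def test_identical_replicates_hit_floor(self):
        s = SampleMeasurements("s", np.tile([10.0, 10.0, 10.0], (3, 1)))
        nz = estimate_noise(s)
        assert nz.sigma_D == pytest.approx(1e-12 * 11.0)

    def test_simple_sd_formula(self):
        s = SampleMeasurements("s", np.column_stack([[9, 10, 11]] * 3))
        nz = estimate_noise(s)
        assert nz.sigma_D == pytest.approx(1.0)
        assert nz.sigma_F == pytest.approx(1.0)

    def test_noise_fraction_recovered_on_simulated_data(self, fig2_dataset):
        for s in fig2_dataset:
            nz = estimate_noise(s).as_array()
            mean = s.intensities.mean(axis=0)
            # 5% generating noise; sampling error at n=10 is wide.
            assert np.all(nz / mean > 0.015) and np.all(nz / mean < 0.12)

    def test_single_replicate_requires_explicit_sigma(self):
        s = SampleMeasurements("s", np.array([[1.0, 2.0, 3.0]]))
        with pytest.raises(ValueError, match="explicit"):
            estimate_noise(s)


class TestSampleEnergy:
    def test_matches_sum_of_normal_logpdfs(self, single_sample, kappa):
        params = ModelParams(2e-6, 0.3)
        noise = estimate_noise(single_sample)
        D0, A0 = 1.3e-6, 0.6e-6
        e = sample_energy(single_sample, D0, A0, params, kappa, noise)
        pred = predict_intensities(D0, A0, params, kappa)
        oracle = -sum(
            norm.logpdf(single_sample.intensities[:, ch], pred[ch], noise.as_array()[ch]).sum()
            for ch in range(3)
        )
        assert e == pytest.approx(oracle, rel=1e-10)

    def test_perfect_fit_leaves_only_normalisation(self, kappa):
        params = ModelParams(1e-6, 0.4)
        s = noiseless_sample(1e-6, 1e-6, params, kappa, n=4)
        sigma = NoiseEstimate(0.1, 0.2, 0.3)
        e = sample_energy(s, 1e-6, 1e-6, params, kappa, sigma)
        expected = 4 * sum(math.log(sig * math.sqrt(2 * math.pi)) for sig in sigma.as_array())
        assert e == pytest.approx(expected, rel=1e-12)

    def test_doubling_sigma_adds_counting_term(self, kappa):
        params = ModelParams(1e-6, 0.4)
        n = 4
        s = noiseless_sample(1e-6, 1e-6, params, kappa, n=n)
        e1 = sample_energy(s, 1e-6, 1e-6, params, kappa, NoiseEstimate(0.1, 0.2, 0.3))
        e2 = sample_energy(s, 1e-6, 1e-6, params, kappa, NoiseEstimate(0.2, 0.4, 0.6))
        assert e2 - e1 == pytest.approx(n * 3 * math.log(2), rel=1e-12)

    def test_negative_totals_rejected(self, single_sample, kappa):
        with pytest.raises(ValueError):
            sample_energy(single_sample, -1e-9, 1e-6, ModelParams(1e-6, 0.4), kappa)


class TestProfileTotals:
    def test_linear_case_recovers_generating_totals(self, kappa):
        # E_fr = 0: model is linear in the totals, minimum is unique.
        params = ModelParams(1e-6, 0.0)
        s = noiseless_sample(1.5e-6, 0.4e-6, params, kappa)
        d, a = profile_totals(s, params, kappa, noise=NoiseEstimate(1e-8, 1e-8, 1e-8))
        assert d == pytest.approx(1.5e-6, rel=1e-5)
        assert a == pytest.approx(0.4e-6, rel=1e-5)

    def test_noiseless_fret_case_self_consistent(self, kappa):
        params = ModelParams(1e-6, 0.4)
        s = noiseless_sample(1e-6, 1e-6, params, kappa)
        d, a = profile_totals(s, params, kappa, noise=NoiseEstimate(1e-8, 1e-8, 1e-8))
        assert d == pytest.approx(1e-6, rel=1e-4)
        assert a == pytest.approx(1e-6, rel=1e-4)

    def test_zero_data_gives_zero_totals(self, kappa):
        s = SampleMeasurements("z", np.zeros((4, 3)))
        d, a = profile_totals(s, ModelParams(1e-6, 0.4), kappa, noise=NoiseEstimate(1.0, 1.0, 1.0))
        assert abs(d) < 1e-10 and abs(a) < 1e-10

    def test_matches_scipy_nelder_mead(self, single_sample, kappa):
        # Dual-route check of the bespoke simplex implementation.
        params = ModelParams(2e-6, 0.55)
        stats = SampleStats(single_sample)
        energy = _make_energy(stats, params, kappa)
        d, a = profile_totals(stats, params, kappa)
        ref = minimize(
            lambda x: energy(x[0], x[1]),
            np.array(stats.moment_guess(kappa)),
            method="Nelder-Mead",
            options=dict(xatol=1e-10 * 1e-6, fatol=1e-12, maxiter=3000, maxfev=4000),
        )
        assert energy(d, a) == pytest.approx(ref.fun, abs=1e-7)


def quadrature_log_marginal(sample, params, kappa, noise, span=8.0):
    """Independent oracle: adaptive 2-D quadrature of exp(-energy).

    Integrates over a box spanning +-`span` posterior SDs around the
    profile optimum (SDs from the inverse Hessian of the Laplace fit).
    """
    fit = laplace_log_marginal(sample, params, kappa, noise)
    cov = np.linalg.inv(fit.hessian)
    sd = np.sqrt(np.abs(np.diag(cov)))
    e = _make_energy(SampleStats(sample, noise), params, kappa)
    shift = fit.E_min  # rescale for numerical stability of the integrand

    val, _ = integrate.dblquad(
        lambda a, d: math.exp(-(e(d, a) - shift)),
        fit.D0_star - span * sd[0],
        fit.D0_star + span * sd[0],
        lambda d: fit.A0_star - span * sd[1],
        lambda d: fit.A0_star + span * sd[1],
        epsabs=1e-12,
        epsrel=1e-10,
    )
    return math.log(val) - shift, fit


class TestLaplaceMarginal:
    def test_exact_for_linear_model(self, kappa):
        # E_fr = 0: energy exactly quadratic, Laplace = exact integral.
        params = ModelParams(1e-6, 0.0)
        rng = np.random.default_rng(5)
        pred = predict_intensities(1e-6, 0.8e-6, params, kappa)
        s = SampleMeasurements("lin", pred + rng.normal(0, 0.03 * pred, (6, 3)))
        noise = estimate_noise(s)
        oracle, fit = quadrature_log_marginal(s, params, kappa, noise, span=10.0)
        assert fit.log_marginal == pytest.approx(oracle, abs=1e-6)

    def test_close_to_quadrature_with_fret(self, kappa):
        params = ModelParams(1e-6, 0.4)
        rng = np.random.default_rng(6)
        pred = predict_intensities(1.2e-6, 0.9e-6, params, kappa)
        s = SampleMeasurements("nl", pred + rng.normal(0, 0.05 * pred, (8, 3)))
        noise = estimate_noise(s)
        oracle, fit = quadrature_log_marginal(s, params, kappa, noise)
        assert fit.log_marginal == pytest.approx(oracle, abs=0.05)

    def test_laplace_identity_holds(self, single_sample, kappa):
        fit = laplace_log_marginal(single_sample, ModelParams(1e-6, 0.4), kappa)
        det = np.linalg.det(fit.hessian)
        assert fit.log_marginal == pytest.approx(
            -fit.E_min + math.log(2 * math.pi) - 0.5 * math.log(det), rel=1e-12
        )
        assert np.all(np.linalg.eigvalsh(fit.hessian) > 0)

    def test_invariant_to_replicate_order(self, single_sample, kappa):
        params = ModelParams(1e-6, 0.4)
        noise = estimate_noise(single_sample)
        fit1 = laplace_log_marginal(single_sample, params, kappa, noise)
        perm = single_sample.intensities[::-1].copy()
        fit2 = laplace_log_marginal(
            SampleMeasurements("p", perm), params, kappa, noise
        )
        assert fit1.log_marginal == pytest.approx(fit2.log_marginal, rel=1e-9)


class TestPriors:
    def test_uniform_prior_constant_in_support(self):
        p = PriorSpec()
        vals = {p.log_density(lk, e) for lk, e in [(-11, 0.1), (-6, 0.5), (-3, 0.99)]}
        assert len(vals) == 1
        assert math.isfinite(vals.pop())

    def test_gaussian_efr_prior_density_gap(self):
        # Prior knowledge centred at 0.45 with SD 0.15.
        p = PriorSpec(efr_mean=0.45, efr_sd=0.15)
        gap = p.log_density(-6, 0.45) - p.log_density(-6, 0.3)
        expected = norm.logpdf(0.45, 0.45, 0.15) - norm.logpdf(0.3, 0.45, 0.15)
        assert gap == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("lk,e", [(-6, 1.2), (-6, -0.1), (-13, 0.5), (-1, 0.5)])
    def test_out_of_support(self, lk, e):
        assert PriorSpec().log_density(lk, e) == -math.inf

    def test_log_prior_wrapper(self):
        p = PriorSpec()
        assert log_prior(ModelParams(1e-6, 0.4), p) == p.log_density(-6.0, 0.4)


class TestLogPosterior:
    def test_single_sample_decomposition(self, single_sample, kappa):
        ds = FretDataset([single_sample])
        params = ModelParams(1e-6, 0.4)
        prior = PriorSpec()
        fit = laplace_log_marginal(single_sample, params, kappa)
        lp = log_posterior(ds, params, kappa, prior)
        assert lp == pytest.approx(log_prior(params, prior) + fit.log_marginal, rel=1e-9)

    def test_duplicated_sample_doubles_likelihood(self, single_sample, kappa):
        params = ModelParams(1e-6, 0.4)
        prior = PriorSpec()
        twin = SampleMeasurements("twin", single_sample.intensities.copy())
        lp1 = log_posterior(FretDataset([single_sample]), params, kappa, prior)
        lp2 = log_posterior(FretDataset([single_sample, twin]), params, kappa, prior)
        like1 = lp1 - log_prior(params, prior)
        like2 = lp2 - log_prior(params, prior)
        assert like2 == pytest.approx(2 * like1, rel=1e-9)

    def test_truth_beats_distant_kd(self, fig2_dataset, kappa):
        lp_true = log_posterior(fig2_dataset, ModelParams(1e-6, 0.4), kappa)
        lp_far = log_posterior(fig2_dataset, ModelParams(1e-4, 0.4), kappa)
        assert lp_true > lp_far


class TestEnergyGrid:
    def test_single_node_equals_log_posterior(self, single_sample, kappa):
        ds = FretDataset([single_sample])
        grid = energy_grid(ds, [-6.0], [0.4], kappa)
        assert grid.shape == (1, 1)
        assert grid[0, 0] == pytest.approx(
            -log_posterior(ds, ModelParams(1e-6, 0.4), kappa), rel=1e-9
        )

    def test_argmin_near_truth_on_benchmark(self, fig2_dataset, kappa):
        kd_grid = np.linspace(-8, -4, 9)  # 0.5-decade spacing
        efr_grid = np.linspace(0.1, 0.9, 9)
        surf = energy_grid(fig2_dataset, kd_grid, efr_grid, kappa)
        i, j = np.unravel_index(np.argmin(surf), surf.shape)
        assert abs(kd_grid[i] - (-6.0)) <= 0.5 + 1e-9
        assert abs(efr_grid[j] - 0.4) <= 0.1 + 1e-9

    def test_zero_efficiency_row_is_flat_in_kd(self, single_sample, kappa):
        ds = FretDataset([single_sample])
        surf = energy_grid(ds, np.linspace(-9, -3, 5), [0.0], kappa)
        assert np.ptp(surf[:, 0]) < 1e-6
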