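"""Calibration tests: absolute constants, extinction rule, marginals, MCMC."""

import math

import numpy as np
import pytest
from scipy import integrate

from fretbayes.calibration import (
    CalibrationDataset,
    ExtinctionRatio,
    _block_log_marginal_jeffreys,
    _construct_coefficients,
    calib_log_posterior,
    calibrate_absolute,
    calibrate_relative,
    fret_kappa_from_extinction,
)
from fretbayes.data import SampleMeasurements
from fretbayes.likelihood import SampleStats
from fretbayes.simulate import default_kappa
from fretbayes.spectral import KappaTable

#: Extinction ratios implied by the default kappa table (kF = kA * ratio).
DEFAULT_RATIOS = ExtinctionRatio(
    tuple(f / a for f, a in zip(default_kappa().kappa_F, default_kappa().kappa_A))
)


def block(coeffs, conc, n=10, r=0.0, seed=0, sample_id="b"):
    """Single-species calibration block: intensities = coeffs * conc + noise."""
    pred = np.asarray(coeffs, float) * conc
    rng = np.random.default_rng(seed)
    noise = rng.normal(size=(n, 3)) * (r * pred)[None, :]
    return SampleMeasurements(sample_id, pred[None, :] + noise)


def make_calib(kappa, efr_construct=0.35, concs=(1e-6, 0.8e-6, 0.5e-6), n=10, r=0.01, seed=0):
    a_construct = _construct_coefficients(kappa, efr_construct)
    return CalibrationDataset(
        donor_only=block(kappa.kappa_D, concs[0], n, r, seed, "donor_only"),
        acceptor_only=block(kappa.kappa_A, concs[1], n, r, seed + 1, "acceptor_only"),
        construct=block(a_construct, concs[2], n, r, seed + 2, "construct"),
    )


class TestAbsoluteCalibration:
    def test_noiseless_recovery_is_exact(self, kappa):
        res = calibrate_absolute(
            block(kappa.kappa_D, 1e-6, r=0.0, sample_id="d"),
            block(kappa.kappa_A, 2e-6, r=0.0, sample_id="a"),
            D0=1e-6,
            A0=2e-6,
        )
        np.testing.assert_allclose(res.kappa_D, kappa.kappa_D, rtol=1e-12)
        np.testing.assert_allclose(res.kappa_A, kappa.kappa_A, rtol=1e-12)

    def test_noisy_recovery_within_propagated_error(self, kappa):
        res = calibrate_absolute(
            block(kappa.kappa_D, 1e-6, n=50, r=0.05, seed=3, sample_id="d"),
            block(kappa.kappa_A, 1e-6, n=50, r=0.05, seed=4, sample_id="a"),
            D0=1e-6,
            A0=1e-6,
        )
        for est, sd, true in zip(res.kappa_D, res.sd_kappa_D, kappa.kappa_D):
            assert abs(est - true) < 3 * sd + 1e-15
        for est, sd, true in zip(res.kappa_A, res.sd_kappa_A, kappa.kappa_A):
            assert abs(est - true) < 3 * sd + 1e-15

    def test_zero_intensities_give_zero_kappa(self):
        z = SampleMeasurements("z", np.zeros((5, 3)))
        res = calibrate_absolute(z, z, D0=1e-6, A0=1e-6)
        assert res.kappa_D == (0.0, 0.0, 0.0)
        assert res.sd_kappa_D == (0.0, 0.0, 0.0)

    def test_nonpositive_concentration_rejected(self, kappa):
        d = block(kappa.kappa_D, 1e-6, sample_id="d")
        with pytest.raises(ValueError):
            calibrate_absolute(d, d, D0=0.0, A0=1e-6)


class TestExtinctionRule:
    def test_unit_ratio_copies_acceptor_constants(self, kappa):
        out = fret_kappa_from_extinction(kappa.kappa_A, ExtinctionRatio((1.0, 1.0, 1.0)))
        assert out == kappa.kappa_A

    def test_elementwise_product(self):
        out = fret_kappa_from_extinction((0.01, 0.75, 0.15), ExtinctionRatio((20.0, 0.1, 20.0)))
        np.testing.assert_allclose(out, (0.2, 0.075, 3.0))

    def test_round_trip_with_default_table(self, kappa):
        out = fret_kappa_from_extinction(kappa.kappa_A, DEFAULT_RATIOS)
        np.testing.assert_allclose(out, kappa.kappa_F, rtol=1e-12)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            ExtinctionRatio((1.0, 0.0, 1.0))


class TestBlockMarginal:
    def test_jeffreys_marginal_matches_quadrature(self, kappa):
        # Oracle: numerically integrate the sigma-marginalised density
        # over the block concentration.
        s = block(kappa.kappa_D, 1e-6, n=10, r=0.05, seed=7, sample_id="d")
        stats = SampleStats(s)
        a = np.asarray(kappa.kappa_D)
        n, ntot = stats.n, 3 * stats.n

        def log_m_sigma(c):
            r = stats.mean - a * c
            rss = stats.m2.sum() + n * (r * r).sum()
            return (
                math.lgamma(0.5 * ntot)
                - math.log(2.0)
                - 0.5 * ntot * math.log(math.pi * rss)
            )

        # Centre the quadrature window on the sharp concentration peak.
        S = n * float((a * a).sum())
        c_hat = float((a * stats.mean).sum()) / float((a * a).sum())
        resid = stats.mean - a * c_hat
        rss0 = float(stats.m2.sum() + n * (resid * resid).sum())
        width = math.sqrt(rss0 / (ntot * S))
        shift = log_m_sigma(c_hat)
        val, _ = integrate.quad(
            lambda c: math.exp(log_m_sigma(c) - shift),
            c_hat - 12 * width,
            c_hat + 12 * width,
            epsabs=1e-14,
        )
        oracle = math.log(val) + shift
        ours = _block_log_marginal_jeffreys(stats, a)
        # <= 1% discrepancy on the log scale.
        assert ours == pytest.approx(oracle, abs=0.01 * abs(oracle))

    def test_student_closed_form_agreement(self, kappa):
        # Exact integral: RSS(c) = RSS0 + S (c - c_hat)^2 integrates to a
        # Beta-function expression; Laplace must agree closely at 3n = 30.
        s = block(kappa.kappa_A, 8e-7, n=10, r=0.03, seed=8, sample_id="a")
        stats = SampleStats(s)
        a = np.asarray(kappa.kappa_A)
        n, ntot = stats.n, 3 * stats.n
        S = n * float((a * a).sum())
        c_hat = float((a * stats.mean).sum()) / float((a * a).sum())
        r = stats.mean - a * c_hat
        rss0 = float(stats.m2.sum() + n * (r * r).sum())
        log_exact = (
            math.lgamma(0.5 * ntot)
            - math.log(2.0)
            - 0.5 * ntot * math.log(math.pi)
            - 0.5 * (ntot - 1) * math.log(rss0)
            - 0.5 * math.log(S)
            + math.lgamma(0.5) + math.lgamma(0.5 * (ntot - 1)) - math.lgamma(0.5 * ntot)
        )
        ours = _block_log_marginal_jeffreys(stats, a)
        # The Gaussian (Laplace) kernel vs. the exact Student kernel differ
        # by log[B(1/2,(3n-1)/2)/sqrt(2*pi/3n)] ~= 0.026 at 3n = 30.
        assert ours == pytest.approx(log_exact, abs=0.05)


class TestCalibLogPosterior:
    def test_truth_beats_perturbed_kappa(self, kappa):
        calib = make_calib(kappa, r=0.0)
        lp_true = calib_log_posterior(calib, kappa, 0.35)
        perturbed = KappaTable(
            kappa.kappa_D,
            (kappa.kappa_A[0], 2 * kappa.kappa_A[1], kappa.kappa_A[2]),
            kappa.kappa_F,
        )
        lp_bad = calib_log_posterior(calib, perturbed, 0.35)
        assert lp_true > lp_bad

    def test_gauge_invariance_of_generated_data(self, kappa):
        # kappa * c with concentrations / c produces bit-identical blocks,
        # hence an identical posterior: the overall scale is unidentifiable.
        c = 3.7
        scaled = KappaTable(
            tuple(v * c for v in kappa.kappa_D),
            tuple(v * c for v in kappa.kappa_A),
            tuple(v * c for v in kappa.kappa_F),
        )
        concs = (1e-6, 0.8e-6, 0.5e-6)
        calib_a = make_calib(kappa, concs=concs, r=0.01, seed=5)
        calib_b = make_calib(scaled, concs=tuple(x / c for x in concs), r=0.01, seed=5)
        np.testing.assert_allclose(
            calib_a.donor_only.intensities, calib_b.donor_only.intensities, rtol=1e-12
        )
        lp_a = calib_log_posterior(calib_a, kappa, 0.35)
        lp_b = calib_log_posterior(calib_b, kappa, 0.35)
        # Equal up to float round-off of the rescaled products.
        assert lp_a == pytest.approx(lp_b, abs=1e-5)

    def test_gauge_must_be_fixed(self, kappa):
        calib = make_calib(kappa)
        off_gauge = KappaTable((2.0, 0.1, 0.4), kappa.kappa_A, kappa.kappa_F)
        with pytest.raises(ValueError, match="gauge"):
            calib_log_posterior(calib, off_gauge, 0.35)

    def test_out_of_support_efficiency(self, kappa):
        calib = make_calib(kappa)
        assert calib_log_posterior(calib, kappa, 1.2) == -math.inf


class TestRelativeCalibration:
    def test_construct_block_required(self, kappa):
        calib = CalibrationDataset(
            donor_only=block(kappa.kappa_D, 1e-6, sample_id="d"),
            acceptor_only=block(kappa.kappa_A, 1e-6, sample_id="a"),
            construct=None,
        )
        with pytest.raises(ValueError, match="construct"):
            calibrate_relative(calib, DEFAULT_RATIOS)

    def test_round_trip_recovers_ratios_and_efficiency(self, kappa):
        # Default kappa already has kappa_D[0] = 1 (the gauge).
        calib = make_calib(kappa, efr_construct=0.35, n=10, r=0.01, seed=12)
        res = calibrate_relative(calib, DEFAULT_RATIOS, n_steps=4000, seed=2)
        assert res.kappa_D[0] == 1.0
        for est, sd, true in zip(res.kappa_D[1:], res.sd_kappa_D[1:], kappa.kappa_D[1:]):
            assert abs(est - true) < max(4 * sd, 0.05 * true)
        for est, sd, true in zip(res.kappa_A, res.sd_kappa_A, kappa.kappa_A):
            assert abs(est - true) < max(4 * sd, 0.05 * true)
        assert abs(res.efr_construct - 0.35) < max(4 * res.sd_efr_construct, 0.03)
        assert "scaled" in res.scale_note
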