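"""Calibration of the kappa constants from single-species samples.

Absolute mode: when fluorophore concentrations are known, the donor
and acceptor constants follow directly from the channel means of
donor-only and acceptor-only samples.

Relative mode: without known concentrations, the six donor/acceptor
constants are identifiable only up to a common scale (rescaling every
kappa by c and every concentration by 1/c leaves all predictions
unchanged), so the donor-channel donor constant is fixed to unity and
the remaining five ratios -- plus the FRET efficiency of a tandem
donor-acceptor construct -- are sampled by MCMC.  Each calibration
block (donor-only, acceptor-only, construct) has exactly one unknown
concentration, which is Laplace-marginalised; the shared noise scale
sigma of a block is marginalised analytically under a Jeffreys 1/sigma
prior, yielding a Student-type marginal in the block's residual sum of
squares.

The FRET-sensitized constants are tied to the acceptor constants by
the excitation physics: sensitized emission is acceptor emission driven
by donor absorption, so ``kappa_F[i] = kappa_A[i] *
(eps_D[i]/eps_A[i])`` with the per-channel ratio of molar extinction
coefficients supplied by the user (from spectra or literature values).

Downstream caveat recorded in every relative result: Kd estimates made
with a relative kappa table are scaled by the unknown reference
constant.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from .data import SampleMeasurements
from .likelihood import SampleStats
from .mcmc import Chain, metropolis
from .spectral import KappaTable

__all__ = [
    "CalibrationDataset",
    "ExtinctionRatio",
    "CalibrationResult",
    "calibrate_absolute",
    "fret_kappa_from_extinction",
    "calib_log_posterior",
    "calibrate_relative",
]

_LOG_2PI = math.log(2.0 * math.pi)
#: log10 bounds on free kappa ratios in relative calibration.
_LOG10_KAPPA_BOUNDS = (-8.0, 4.0)


@dataclass
class CalibrationDataset:
    """Three-cube measurements of the three calibration sample types."""

    donor_only: SampleMeasurements
    acceptor_only: SampleMeasurements
    construct: Optional[SampleMeasurements] = None
    known_concentrations: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        for name in ("donor_only", "acceptor_only", "construct"):
            s = getattr(self, name)
            if s is not None and s.n < 2:
                raise ValueError(f"calibration block {name!r} needs n >= 2 replicates")


@dataclass(frozen=True)
class ExtinctionRatio:
    """Per-channel ratio of donor to acceptor molar extinction coefficients."""

    ratio: tuple[float, float, float]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.ratio)
        if len(vals) != 3 or any(not math.isfinite(v) or v <= 0 for v in vals):
            raise ValueError(f"extinction ratios must be positive and finite, got {vals}")
        object.__setattr__(self, "ratio", vals)


@dataclass
class CalibrationResult:
    """Inferred kappa constants with uncertainties.

    In relative mode ``kappa_D[0] == 1`` exactly (the gauge) and
    ``scale_note`` records that Kd estimates made with this table are
    scaled by the true value of the reference constant.
    """

    kappa_D: tuple[float, float, float]
    kappa_A: tuple[float, float, float]
    sd_kappa_D: tuple[float, float, float]
    sd_kappa_A: tuple[float, float, float]
    kappa_F: Optional[tuple[float, float, float]] = None
    sd_kappa_F: Optional[tuple[float, float, float]] = None
    efr_construct: Optional[float] = None
    sd_efr_construct: Optional[float] = None
    mode: str = "absolute"
    scale_note: str = ""
    chain: Optional[Chain] = field(default=None, repr=False)

    def kappa_table(self) -> KappaTable:
        if self.kappa_F is None:
            raise ValueError(
                "kappa_F not calibrated; derive it with fret_kappa_from_extinction first"
            )
        return KappaTable(self.kappa_D, self.kappa_A, self.kappa_F)


def calibrate_absolute(
    donor_only: SampleMeasurements,
    acceptor_only: SampleMeasurements,
    D0: float,
    A0: float,
) -> CalibrationResult:
    """Absolute donor/acceptor constants from known concentrations.

    ``kappa_D[i] = mean(I_i donor-only) / D0`` and analogously for the
    acceptor; the reported SD is the standard error of the channel mean
    divided by the concentration.
    """
    if not (D0 > 0 and A0 > 0):
        raise ValueError(f"known concentrations must be positive, got D0={D0!r}, A0={A0!r}")
    kd = donor_only.intensities.mean(axis=0) / D0
    ka = acceptor_only.intensities.mean(axis=0) / A0
    sd_kd = donor_only.intensities.std(axis=0, ddof=1) / math.sqrt(donor_only.n) / D0
    sd_ka = acceptor_only.intensities.std(axis=0, ddof=1) / math.sqrt(acceptor_only.n) / A0
    return CalibrationResult(
        kappa_D=tuple(kd),
        kappa_A=tuple(ka),
        sd_kappa_D=tuple(sd_kd),
        sd_kappa_A=tuple(sd_ka),
        mode="absolute",
        scale_note="absolute calibration: Kd estimates are on the true molar scale",
    )


def fret_kappa_from_extinction(
    kappa_A: tuple[float, float, float], ratio: ExtinctionRatio
) -> tuple[float, float, float]:
    """FRET-sensitized constants from acceptor constants.

    Sensitized emission shares the acceptor's quantum yield and
    detection factors but is driven by the donor's absorption, so each
    acceptor constant is rescaled by the per-channel donor:acceptor
    extinction ratio.
    """
    return tuple(float(a) * r for a, r in zip(kappa_A, ratio.ratio))


def _construct_coefficients(
    kappa: KappaTable, efr_construct: float
) -> np.ndarray:
    """Per-channel intensity per molar of construct concentration."""
    kd = np.asarray(kappa.kappa_D)
    ka = np.asarray(kappa.kappa_A)
    kf = np.asarray(kappa.kappa_F)
    return kd * (1.0 - efr_construct) + ka + kf * efr_construct


def _block_log_marginal_jeffreys(stats: SampleStats, a: np.ndarray) -> float:
    """Log marginal of one block: concentration Laplace, sigma Jeffreys.

    The block's predictions are ``a_i * c`` with a single unknown
    concentration c.  Integrating the Gaussian likelihood over sigma
    (Jeffreys prior 1/sigma, shared across the three channels) gives

        m(c) = Gamma(3n/2)/2 * (pi * RSS(c))^(-3n/2),

    and c is then integrated by a 1-D Laplace approximation of the
    energy E(c) = (3n/2) log RSS(c) around its minimiser, with the
    Hessian by central finite differences.
    """
    n = stats.n
    ntot = 3 * n
    mean, m2 = stats.mean, stats.m2

    def rss(c: float) -> float:
        # sum over channels of [m2 + n (mean - a c)^2]
        r = mean - a * c
        return float(m2.sum() + n * (r * r).sum())

    den = float((a * a).sum())
    if den <= 0:
        raise ValueError("degenerate calibration block: all coefficients are zero")
    c_hat = max(float((a * mean).sum()) / den, 0.0)
    r0 = rss(c_hat)
    if r0 <= 0:
        # Perfect fit with zero replicate scatter cannot occur for n >= 2
        # unless the data are degenerate; floor for safety.
        r0 = 1e-300

    def energy(c: float) -> float:
        return 0.5 * ntot * math.log(rss(c))

    h = max(1e-6 * abs(c_hat), 1e-12)
    e0 = energy(c_hat)
    curv = (energy(c_hat + h) - 2.0 * e0 + energy(c_hat - h)) / (h * h)
    if not (curv > 0 and math.isfinite(curv)):
        return -math.inf
    log_m_sigma = math.lgamma(0.5 * ntot) - math.log(2.0) - 0.5 * ntot * math.log(math.pi * r0)
    return log_m_sigma + 0.5 * _LOG_2PI - 0.5 * math.log(curv)


def _block_log_marginal_gaussian(stats: SampleStats, a: np.ndarray) -> float:
    """Variant with per-channel sigma plugged in from the replicate SDs.

    The energy is exactly quadratic in the block concentration, so the
    1-D Laplace integral is exact.
    """
    w = 2.0 * stats.half_weight  # n / sigma^2 per channel
    den = float((w * a * a).sum())
    if den <= 0:
        raise ValueError("degenerate calibration block: all coefficients are zero")
    c_hat = max(float((w * a * stats.mean).sum()) / den, 0.0)
    r = stats.mean - a * c_hat
    e_min = stats.base_energy + float((stats.half_weight * r * r).sum())
    return -e_min + 0.5 * _LOG_2PI - 0.5 * math.log(den)


def calib_log_posterior(
    calib_data: CalibrationDataset,
    kappa_candidate: KappaTable,
    efr_construct_candidate: float,
    sigma_mode: str = "jeffreys",
) -> float:
    """Log posterior of candidate kappa constants and construct efficiency.

    Sums per-block marginal likelihoods over the donor-only,
    acceptor-only and (when present) construct blocks.  Candidates
    outside the support (non-positive constants where data demand them,
    efficiency outside [0, 1]) score -inf.  ``sigma_mode`` selects the
    Jeffreys shared-sigma marginal (default) or plug-in per-channel
    sigma ("per_channel").
    """
    if abs(kappa_candidate.kappa_D[0] - 1.0) > 1e-9:
        raise ValueError(
            "relative calibration gauge requires kappa_D[0] == 1 "
            f"(got {kappa_candidate.kappa_D[0]!r})"
        )
    if not (0.0 <= efr_construct_candidate <= 1.0):
        return -math.inf
    if sigma_mode == "jeffreys":
        block_fn = _block_log_marginal_jeffreys
    elif sigma_mode == "per_channel":
        block_fn = _block_log_marginal_gaussian
    else:
        raise ValueError(f"unknown sigma_mode {sigma_mode!r}")

    blocks: list[tuple[SampleMeasurements, np.ndarray]] = [
        (calib_data.donor_only, np.asarray(kappa_candidate.kappa_D)),
        (calib_data.acceptor_only, np.asarray(kappa_candidate.kappa_A)),
    ]
    if calib_data.construct is not None:
        blocks.append(
            (
                calib_data.construct,
                _construct_coefficients(kappa_candidate, efr_construct_candidate),
            )
        )
    total = 0.0
    for sample, a in blocks:
        total += block_fn(SampleStats(sample), a)
        if total == -math.inf:
            return -math.inf
    return total


def _relative_state_to_kappa(x: np.ndarray, ratio: ExtinctionRatio) -> KappaTable:
    """Map the 6-D sampling state to a gauge-fixed kappa table.

    State layout: (log10 kD2, log10 kD3, log10 kA1, log10 kA2,
    log10 kA3, E'_fr); kappa_D[0] = 1 and kappa_F follows from the
    extinction-ratio rule.
    """
    kd = (1.0, 10.0 ** x[0], 10.0 ** x[1])
    ka = (10.0 ** x[2], 10.0 ** x[3], 10.0 ** x[4])
    kf = fret_kappa_from_extinction(ka, ratio)
    return KappaTable(kd, ka, kf)


def _relative_init(calib_data: CalibrationDataset) -> np.ndarray:
    """Heuristic start: channel-mean ratios for the kappa directions."""
    dm = np.maximum(calib_data.donor_only.intensities.mean(axis=0), 1e-12)
    am = np.maximum(calib_data.acceptor_only.intensities.mean(axis=0), 1e-12)
    kd_dir = dm / dm[0]
    ka_dir = am / am[1]  # acceptor brightest in its own channel
    return np.array(
        [
            math.log10(kd_dir[1]),
            math.log10(kd_dir[2]),
            math.log10(ka_dir[0]),
            0.0,  # kA2 scale: unknown without the construct; start at parity
            math.log10(ka_dir[2]),
            0.5,
        ]
    )


def calibrate_relative(
    calib_data: CalibrationDataset,
    extinction_ratio: ExtinctionRatio,
    n_steps: int = 6000,
    seed: int = 0,
    sigma_mode: str = "jeffreys",
    burn_in_frac: float = 0.25,
) -> CalibrationResult:
    """Sample relative kappa constants and construct efficiency by MCMC.

    Requires all three calibration blocks: without the construct the
    donor:acceptor brightness scale and the FRET constants are
    unidentifiable.  The chain state is (five log10 kappa ratios,
    E'_fr) with kappa_D[0] fixed to 1; the posterior is
    :func:`calib_log_posterior`.  The start is refined by Nelder-Mead
    before tuning and sampling.
    """
    if calib_data.construct is None:
        raise ValueError(
            "relative calibration requires a donor-acceptor construct block: "
            "without it the donor:acceptor scale and kappa_F are unidentifiable"
        )
    lo, hi = _LOG10_KAPPA_BOUNDS

    def logpost(x: np.ndarray, carry=None):
        if np.any(x[:5] < lo) or np.any(x[:5] > hi) or not (0.0 <= x[5] <= 1.0):
            return -math.inf, None
        kappa = _relative_state_to_kappa(x, extinction_ratio)
        return calib_log_posterior(calib_data, kappa, float(x[5]), sigma_mode), None

    x0 = _relative_init(calib_data)
    # Mode-seeking refinement before sampling (bounded by clipping).
    def neg(x):
        xc = x.copy()
        xc[:5] = np.clip(xc[:5], lo, hi)
        xc[5] = np.clip(xc[5], 0.0, 1.0)
        lp, _ = logpost(xc)
        return -lp if np.isfinite(lp) else 1e12

    res = minimize(neg, x0, method="Nelder-Mead", options={"maxiter": 4000, "fatol": 1e-8})
    x0 = res.x.copy()
    x0[:5] = np.clip(x0[:5], lo, hi)
    x0[5] = float(np.clip(x0[5], 1e-3, 1.0 - 1e-3))

    rng = np.random.default_rng(seed)
    sds = np.full(6, 0.02)
    sds[5] = 0.05
    # Block-wise pilot tuning of a common scale factor.
    lp0, _ = logpost(x0)
    if not np.isfinite(lp0):
        raise ValueError("calibration start has zero posterior; check the data")
    x, lp = x0, lp0
    for _ in range(30):
        states, lps, accepted, lp, _ = metropolis(logpost, x, sds, 100, rng, lp0=lp)
        x = states[-1]
        acc = float(accepted.mean())
        if 0.40 <= acc <= 0.60:
            break
        sds = sds * float(np.clip(math.exp(2.0 * (acc - 0.5)), 0.3, 2.5))
    states, lps, accepted, _, _ = metropolis(logpost, x, sds, n_steps, rng, lp0=lp)
    burn = int(burn_in_frac * n_steps)
    draws = states[burn:]
    if not (0.40 <= accepted.mean() <= 0.60):
        warnings.warn(
            f"relative calibration acceptance rate {accepted.mean():.0%} outside 40-60% band",
            RuntimeWarning,
            stacklevel=2,
        )

    kappa_draws = np.empty((draws.shape[0], 9))
    for i, xs in enumerate(draws):
        kt = _relative_state_to_kappa(xs, extinction_ratio)
        kappa_draws[i] = np.concatenate([kt.kappa_D, kt.kappa_A, kt.kappa_F])
    mean = kappa_draws.mean(axis=0)
    sd = kappa_draws.std(axis=0, ddof=1)
    efr_draws = draws[:, 5]
    chain = Chain(
        states=states,
        energies=-lps,
        accepted=accepted,
        seed=seed,
        init=x0,
        burn_in_index=burn,
    )
    return CalibrationResult(
        kappa_D=tuple(mean[0:3]),
        kappa_A=tuple(mean[3:6]),
        kappa_F=tuple(mean[6:9]),
        sd_kappa_D=tuple(sd[0:3]),
        sd_kappa_A=tuple(sd[3:6]),
        sd_kappa_F=tuple(sd[6:9]),
        efr_construct=float(efr_draws.mean()),
        sd_efr_construct=float(efr_draws.std(ddof=1)),
        mode="relative",
        scale_note=(
            "relative calibration: kappa_D[0] fixed to 1, so downstream Kd "
            "estimates are scaled by the true value of that reference constant"
        ),
        chain=chain,
    )
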