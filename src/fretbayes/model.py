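"""Model/Results API for fitting the binding model to three-cube data.

:class:`FretModel` holds a dataset, a kappa table and priors;
``fit()`` tunes proposal step sizes, runs several overdispersed
Metropolis-Hastings chains, detects burn-in, checks convergence and
returns a :class:`FretResults` carrying posterior summaries,
diagnostics and the raw chains.  :class:`ApparentFretModel` and
:class:`CalibrationModel` wrap the apparent-FRET and relative
calibration procedures in the same shape.
"""

from __future__ import annotations

import math
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .apparent import ApparentPrior, ApparentSummary, infer_apparent
from .calibration import (
    CalibrationDataset,
    CalibrationResult,
    ExtinctionRatio,
    calibrate_relative,
)
from .data import FretDataset
from .likelihood import (
    NoiseEstimate,
    PosteriorEvaluator,
    PriorSpec,
    energy_grid,
)
from .mcmc import (
    Chain,
    ConvergenceReport,
    PosteriorSummary,
    ProposalSpec,
    _tune_chain,
    check_convergence,
    detect_burn_in,
    metropolis,
    summarize,
)
from .spectral import KappaTable

__all__ = [
    "FretModel",
    "FretResults",
    "ApparentFretModel",
    "ApparentFretResults",
    "CalibrationModel",
]


class FretModel:
    """Bayesian binding model for a three-cube FRET dataset.

    Parameters
    ----------
    dataset : FretDataset
        Background-corrected replicate intensities per sample.
    kappa : KappaTable
        Calibrated photophysical constants (absolute or relative).
    prior : PriorSpec, optional
        Priors on (log10 Kd, E_fr); defaults to uniform E_fr on [0, 1]
        and uniform log10 Kd on [-12, -2].
    noise : sequence of NoiseEstimate, optional
        Explicit per-sample noise scales; estimated from replicate
        scatter when omitted.
    """

    def __init__(
        self,
        dataset: FretDataset,
        kappa: KappaTable,
        prior: Optional[PriorSpec] = None,
        noise: Optional[Sequence[NoiseEstimate]] = None,
    ):
        self.dataset = dataset
        self.kappa = kappa
        self.prior = prior if prior is not None else PriorSpec()
        self._evaluator = PosteriorEvaluator(dataset, kappa, self.prior, noise)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        kappa: KappaTable,
        prior: Optional[PriorSpec] = None,
    ) -> "FretModel":
        """Build from the wide measurements layout (sample_id, replicate, I_D, I_A, I_F)."""
        return cls(FretDataset.from_frame(df), kappa, prior)

    def log_posterior(self, Kd: float, E_fr: float) -> float:
        """Log posterior density at (Kd, E_fr); Kd in molar."""
        lp, _ = self._evaluator.logpost(math.log10(Kd), E_fr)
        return lp

    def energy_grid(self, kd_grid, efr_grid) -> np.ndarray:
        """Energy surface (-log posterior) over (log10 Kd, E_fr) grids."""
        return energy_grid(self.dataset, kd_grid, efr_grid, self.kappa, self.prior)

    def _seed_inits(
        self, chains: int, rng: np.random.Generator
    ) -> list[tuple[float, float]]:
        """Chain starts from a coarse posterior scan, jittered.

        The posterior is evaluated on a small (log10 Kd, E_fr) grid and
        each chain starts near one of the highest-posterior nodes.
        Starting the walks inside the typical set keeps the step-size
        tuning representative; raw prior draws can land in degenerate
        regions (e.g. the E_fr ~ 0 slab, where Kd is unidentifiable)
        whose locally-tuned steps mix poorly elsewhere.
        """
        lo, hi = self.prior.kd_log10_bounds
        lks = np.linspace(lo + 0.05 * (hi - lo), hi - 0.05 * (hi - lo), 6)
        efs = [0.15, 0.35, 0.55, 0.75, 0.95]
        if self.prior.efr_mean is not None:
            efs.append(float(np.clip(self.prior.efr_mean, 0.02, 0.98)))
        nodes: list[tuple[float, float]] = []
        lps: list[float] = []
        warm = None
        for lk in lks:
            for e in efs:
                lp, optima = self._evaluator.logpost(lk, e, warm=warm)
                if optima is not None:
                    warm = optima
                nodes.append((lk, e))
                lps.append(lp)
        order = np.argsort(lps)[::-1]
        inits = []
        for c in range(chains):
            lk, e = nodes[order[c % len(nodes)]]
            lk = float(np.clip(lk + rng.uniform(-0.3, 0.3), lo, hi))
            e = float(np.clip(e + rng.uniform(-0.05, 0.05), 0.01, 0.99))
            inits.append((lk, e))
        return inits

    def fit(
        self,
        chains: int = 3,
        steps: int = 20000,
        seed: Optional[int] = None,
        inits: Optional[Sequence[tuple[float, float]]] = None,
        proposal: Optional[ProposalSpec] = None,
        tune: bool = True,
    ) -> "FretResults":
        """Sample the posterior of (Kd, E_fr).

        Each chain gets its own substream of the master seed, a start
        near a distinct high-posterior node of a coarse scan (unless
        ``inits`` is given), a pilot tuning phase targeting 40-60%
        acceptance (frozen before recording), ``steps`` recorded steps
        and energy-trace burn-in detection.
        """
        if chains < 1:
            raise ValueError("need at least one chain")
        ss = np.random.SeedSequence(seed if seed is not None else 0)
        child = ss.spawn(2 * chains + 1)
        if inits is None:
            init_rng = np.random.default_rng(
                int(child[2 * chains].generate_state(1)[0] % (2**31))
            )
            inits = self._seed_inits(chains, init_rng)
        chain_list: list[Chain] = []
        tuned: list[ProposalSpec] = []
        for c in range(chains):
            init_seed = int(child[2 * c].generate_state(1)[0] % (2**31))
            run_seed = int(child[2 * c + 1].generate_state(1)[0] % (2**31))
            init = inits[c]
            if tune:
                spec, x, lp, carry = _tune_chain(
                    self._evaluator, init, init_seed, initial=proposal
                )
            else:
                if proposal is None:
                    raise ValueError("proposal must be given when tune=False")
                spec = proposal
                x = np.asarray(init, dtype=float)
                lp, carry = self._evaluator.logpost(x[0], x[1])
                if not np.isfinite(lp):
                    raise ValueError(f"initial state {init!r} has zero posterior")
            tuned.append(spec)
            states, lps, accepted, _, _ = metropolis(
                lambda z, cr: self._evaluator.logpost(z[0], z[1], warm=cr),
                x,
                spec.as_array(),
                steps,
                np.random.default_rng(run_seed),
                carry=carry,
                lp0=lp,
                explore_sds=spec.explore_array(),
                explore_prob=spec.explore_prob,
            )
            ch = Chain(
                states=states,
                energies=-lps,
                accepted=accepted,
                seed=run_seed,
                init=np.asarray(init, dtype=float),
            )
            detect_burn_in(ch)
            chain_list.append(ch)
        report = check_convergence(chain_list) if chains >= 2 else None
        if report is not None and not report.passed:
            warnings.warn(f"chains may not have converged: {report}", RuntimeWarning)
        truth = None
        cfg = self.dataset.config
        if cfg is not None:
            truth = (cfg.params.Kd, cfg.params.E_fr)
        summary = summarize(chain_list, truth=truth)
        return FretResults(self, chain_list, summary, report, tuned)


class FretResults:
    """Posterior sampling results for a fitted :class:`FretModel`."""

    def __init__(
        self,
        model: FretModel,
        chains: list[Chain],
        posterior: PosteriorSummary,
        convergence: Optional[ConvergenceReport],
        proposals: list[ProposalSpec],
    ):
        self.model = model
        self.chains = chains
        self.posterior = posterior
        self.convergence = convergence
        self.proposals = proposals

    @property
    def params(self) -> pd.Series:
        """Posterior means: Kd (molar, natural scale) and E_fr."""
        return pd.Series(
            {"Kd": self.posterior.kd.mean, "E_fr": self.posterior.efr.mean}
        )

    @property
    def sd(self) -> pd.Series:
        return pd.Series({"Kd": self.posterior.kd.sd, "E_fr": self.posterior.efr.sd})

    @property
    def cv(self) -> pd.Series:
        """Relative uncertainty: posterior SD / posterior mean."""
        return pd.Series({"Kd": self.posterior.kd.cv, "E_fr": self.posterior.efr.cv})

    @property
    def acceptance_rate(self) -> float:
        """Recorded-phase acceptance fraction pooled over chains."""
        acc = np.concatenate([c.accepted for c in self.chains])
        return float(acc.mean())

    def error(self, kd_true: float, efr_true: Optional[float] = None) -> pd.Series:
        """Recovery error vs. known truth.

        Kd error is log10(posterior-mean Kd / true Kd) (0 = perfect);
        E_fr error is the plain difference of means.
        """
        out = {"Kd_log10_error": math.log10(self.posterior.kd.mean / kd_true)}
        if efr_true is not None:
            out["E_fr_error"] = self.posterior.efr.mean - efr_true
        return pd.Series(out)

    def pooled_draws(self) -> pd.DataFrame:
        """Post-burn-in draws pooled across chains (natural-scale Kd)."""
        draws = np.concatenate([c.post_burn_in() for c in self.chains], axis=0)
        return pd.DataFrame({"Kd": 10.0 ** draws[:, 0], "E_fr": draws[:, 1]})

    def summary(self) -> str:
        """Human-readable fit report."""
        p = self.posterior
        lines = [
            "          Three-cube FRET binding model",
            "=" * 56,
            f"samples: {self.model.dataset.m}   chains: {len(self.chains)}   "
            f"recorded steps/chain: {self.chains[0].n_steps}",
            f"burn-in indices: {[c.burn_in_index for c in self.chains]}",
            f"pooled draws: {p.n_samples}   acceptance: {self.acceptance_rate:.1%}",
            "-" * 56,
            f"{'':>6} {'mean':>11} {'sd':>11} {'cv':>8} {'5%':>11} {'95%':>11}",
            f"{'Kd':>6} {p.kd.mean:>11.4g} {p.kd.sd:>11.4g} {p.kd.cv:>8.3f} "
            f"{p.kd.q05:>11.4g} {p.kd.q95:>11.4g}",
            f"{'E_fr':>6} {p.efr.mean:>11.4g} {p.efr.sd:>11.4g} {p.efr.cv:>8.3f} "
            f"{p.efr.q05:>11.4g} {p.efr.q95:>11.4g}",
        ]
        if self.convergence is not None:
            lines.append("-" * 56)
            lines.append(str(self.convergence))
        if p.error_log10_kd is not None:
            lines.append(
                f"vs. simulation truth: log10 Kd error = {p.error_log10_kd:+.4f}, "
                f"E_fr error = {p.error_efr:+.4f}"
            )
        return "\n".join(lines)

    def plot_posterior(self, axes=None):
        """Histograms of the pooled Kd (log axis) and E_fr draws."""
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(1, 2, figsize=(8, 3))
        draws = self.pooled_draws()
        axes[0].hist(np.log10(draws["Kd"]), bins=60, color="C0")
        axes[0].set_xlabel("log10 Kd (M)")
        axes[1].hist(draws["E_fr"], bins=60, color="C1")
        axes[1].set_xlabel("E_fr")
        for ax in axes:
            ax.set_ylabel("draws")
        return axes

    def __repr__(self) -> str:
        return (
            f"<FretResults Kd={self.posterior.kd.mean:.3g} M, "
            f"E_fr={self.posterior.efr.mean:.3g}, draws={self.posterior.n_samples}>"
        )


class ApparentFretModel:
    """Apparent-efficiency model: E_d and r_da without absolute concentrations."""

    def __init__(
        self,
        dataset: FretDataset,
        kappa: KappaTable,
        prior: Optional[ApparentPrior] = None,
    ):
        self.dataset = dataset
        self.kappa = kappa
        self.prior = prior if prior is not None else ApparentPrior()

    def fit(self, chains: int = 3, steps: int = 5000, seed: int = 0) -> "ApparentFretResults":
        chain_list, summary = infer_apparent(
            self.dataset,
            self.kappa,
            n_chains=chains,
            n_steps=steps,
            seed=seed,
            prior=self.prior,
        )
        return ApparentFretResults(self, chain_list, summary)


class ApparentFretResults:
    def __init__(self, model: ApparentFretModel, chains: list[Chain], summary: ApparentSummary):
        self.model = model
        self.chains = chains
        self.apparent = summary

    @property
    def params(self) -> pd.Series:
        return pd.Series(
            {
                "E_d": self.apparent.E_d.mean,
                "r_da": self.apparent.r_da.mean,
                "E_a": self.apparent.E_a.mean,
            }
        )

    def summary(self) -> str:
        s = self.apparent
        lines = [
            "        Apparent FRET quantities",
            "=" * 48,
            f"pooled draws: {s.n_samples}",
            f"{'':>6} {'mean':>10} {'sd':>10} {'5%':>10} {'95%':>10}",
        ]
        for name, ps in (("E_d", s.E_d), ("r_da", s.r_da), ("E_a", s.E_a)):
            lines.append(
                f"{name:>6} {ps.mean:>10.4g} {ps.sd:>10.4g} {ps.q05:>10.4g} {ps.q95:>10.4g}"
            )
        return "\n".join(lines)


class CalibrationModel:
    """Relative calibration of the kappa table from three sample types."""

    def __init__(self, data: CalibrationDataset, extinction_ratio: ExtinctionRatio):
        self.data = data
        self.extinction_ratio = extinction_ratio

    def fit(self, steps: int = 6000, seed: int = 0, sigma_mode: str = "jeffreys") -> CalibrationResult:
        return calibrate_relative(
            self.data,
            self.extinction_ratio,
            n_steps=steps,
            seed=seed,
            sigma_mode=sigma_mode,
        )
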