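# Methods

## Model and assumptions

The package models a bimolecular interaction D + A ⇌ DA with
dissociation constant `Kd` (molar). Assumptions inherited by every
analysis:

* all interacting molecules are fluorescently tagged, so "donor" and
  "acceptor" stand for the tagged proteins themselves;
* only 1:1 complexes form, and every complex has the same intrinsic
  FRET efficiency `E_fr` (the probability that exciting a donor in
  complex excites its acceptor);
* collisional FRET between free fluorophores is negligible;
* photobleaching, dark states and incomplete labelling are not
  modelled;
* measurement noise is Gaussian and independent across channels and
  replicates.

Given totals `(D0, A0)` per sample, the complex concentration is the
physically valid root of `DA² − (D0+A0+Kd)·DA + D0·A0 = 0`. The root
is evaluated as `DA = 2·D0·A0 / (b + √(b² − 4·D0·A0))` with
`b = D0+A0+Kd`: algebraically identical to the textbook smaller root
but free of subtractive cancellation when `Kd ≫ D0+A0`, the
weak-binding regime where concentration plateaus are studied.
Round-off negatives in the free concentrations are clamped to zero at
a relative tolerance of 1e-15.

Spectral mixing is linear: channel intensities are
`I = M · ([D],[A],[DA])ᵀ` with the complex column
`κ_D(1−E_fr) + κ_A + κ_F·E_fr`. The nine κ constants (intensity per
molar, channels ordered donor/acceptor/FRET) fold together
illumination, molar extinction, quantum yield and detection
sensitivity; the individual photophysical factors are never needed at
run time, which is why they are not stored separately. All
concentrations are molar internally; the CLI converts µM inputs on
read so that no 1e-6 factor can slip in silently.

## Likelihood, noise and marginalisation of the totals

Replicates are Gaussian around the forward-model prediction. Noise
scales σ are estimated per sample *and* per channel as the replicate
sample SD (ddof=1), floored at `1e-12·(|mean|+1)`; per-channel,
per-sample estimation matters because noise tracks signal and samples
differ up to 25-fold in concentration. Energies (negative log
likelihoods) keep all normalisation constants so that per-sample
marginals are absolute log likelihoods and sum across samples.

Each sample's unknown totals `(D0, A0)` are profiled and integrated
out by a Laplace approximation:

1. Nelder–Mead minimises the energy over `(D0, A0) ≥ 0` (negative
   trial values are clamped to zero inside the objective). Starts: a
   weighted least-squares moment guess (exact for `E_fr = 0`), the
   previous accepted proposal's optimum (warm start, which makes long
   MCMC runs fast), and 10× the moment guess; remaining starts are
   skipped once two agree to 1e-8 in energy. The simplex itself is a
   two-dimensional specialisation with standard coefficients
   (reflection 1, expansion 2, contraction 0.5, shrink 0.5),
   cross-validated against scipy's implementation in the test suite;
   the specialisation exists because this routine runs inside every
   MCMC proposal and dominates runtime.
2. The 2×2 Hessian comes from central finite differences with step
   `h = max(1e-5·x*, 1e-12 M)` per coordinate, applied to the
   *residual-only* energy (the additive normalisation constant is
   excluded from the differenced values). Both choices are dictated by
   float cancellation: differencing values that carry a large constant
   term, or using a much smaller step, injects ~1e-6 noise into
   log|H|, which the quadrature-oracle tests would reject.
3. `log P(data|Kd,E_fr) = −E_min + log 2π − ½ log|H|`, the Gaussian
   integral over the whole plane. For `E_fr = 0` the energy is exactly
   quadratic and this is exact; the test suite bounds the error
   against adaptive 2-D quadrature at ≤ 0.05 log units for FRET-active
   cases. A non-positive-definite Hessian marks the fit invalid and
   the MCMC proposal carrying it is rejected (never regularised, which
   would silently distort the marginal).

Energy evaluations use per-channel sufficient statistics
(count, mean, centred sum of squares), making each evaluation O(1) in
the replicate count.

## Priors

`log₁₀ Kd` gets a uniform prior on a bounded support, default
[−12, −2] (log₁₀ M). Boundedness is not cosmetic: when concentrations
sit far from Kd the likelihood plateaus and an unbounded flat prior in
log space would leave the posterior improper. `E_fr` is uniform on
[0, 1] by default; prior knowledge (e.g. from lifetime measurements)
enters as a Gaussian with user-supplied mean and SD truncated to
[0, 1]. The bundled example prior uses mean 0.45 and SD 0.15; the
value 0.15 is treated as a standard deviation, not a variance (a
variance of 0.15 would mean SD ≈ 0.39, incompatible with calling the
information "limited but useful").

## MCMC sampling

The sampler is Metropolis–Hastings on `(log₁₀ Kd, E_fr)`; Kd is
explored on the log scale because credible sets routinely span
decades. Proposals are symmetric about the current state, so support
violations are handled by the prior's −∞ without breaking detailed
balance.

The proposal kernel is a two-component Gaussian mixture: with
probability 0.9 a local step with tuned per-coordinate SDs, with
probability 0.1 a fixed wide "exploration" step (SD 1 decade in
log₁₀ Kd, 0.2 in E_fr). The wide component exists because this
posterior has two very different regimes. Near a well-identified mode
the coordinates are strongly correlated (a Kd–E_fr ridge) and the
tuned local steps are small; on concentration plateaus whole decades
of Kd are equally probable, and a walk restricted to locally-tuned
steps would need quadratically many steps to cross them — in testing,
chains tuned inside the degenerate `E_fr ≈ 0` slab (where Kd is
unidentifiable) stayed trapped there for entire runs. Exploration
proposals are simply rejected near a tight mode, costing a few percent
of acceptance.

Step-size tuning runs in pilot blocks of 100 steps, scaling the local
SDs by `exp(2(acc − 0.5))` (clipped) per block and freezing once a
block's acceptance lands inside 43–57% — slightly inside the nominal
40–60% target band so the recorded phase stays in band despite
block-to-block fluctuation — with at least 3 and at most 50 blocks
(≤ 5,000 pilot steps). Adaptation is frozen before any recorded
samples, preserving detailed balance. If the band is unreachable
(e.g. a flat target accepts everything) the closest-to-50% setting is
returned with a warning.

Chains start near distinct high-posterior nodes of a coarse
(6 × 5) posterior scan, jittered per chain, rather than from raw prior
draws: prior draws occasionally land in the `E_fr ≈ 0` slab and a
chain tuned there mixes poorly elsewhere. The scan costs ~30
posterior evaluations. Default runs use 3 chains × 20,000 recorded
steps (configurable; the bundled studies use shorter chains, see
below).

Burn-in is detected from the energy trace: the first index whose
100-step window mean lies within two window-SDs of the final-quarter
mean, capped at half the chain with a warning. Convergence requires
the Gelman–Rubin potential scale reduction factor below 1.1 on both
coordinates plus pairwise overlapping interquartile ranges; identical
chains report PSRF exactly 1 (estimates below 1 are sampling noise and
are clamped). Summaries pool post-burn-in draws across chains; Kd is
summarised on the natural scale with mean, SD, cv (= SD/mean) and
5/50/95 percentiles. When ground truth is known the Kd recovery error
is `log₁₀(⟨Kd⟩_posterior / Kd_true)` — zero for a perfect estimate and
symmetric on the scale Kd is explored on.

## Calibration of the κ constants

With known concentrations, donor-only and acceptor-only samples give
the six donor/acceptor constants directly (channel mean over
concentration; SD propagated as the standard error of the mean).
Without known concentrations the constants are identifiable only up to
a common scale — rescaling every κ by c and every concentration by 1/c
leaves all predictions unchanged — so the relative mode fixes
κ_D(donor channel) ≡ 1 and samples the remaining five ratios plus the
tandem construct's FRET efficiency E′_fr by MCMC over their logs
(bounds ±[−8, 4] in log₁₀). Every relative result carries the note
that downstream Kd estimates are scaled by the unknown reference
constant.

Each calibration block has exactly one unknown concentration, which is
integrated by a 1-D Laplace approximation with the same
finite-difference policy as the main model. The shared noise scale σ
of a block is marginalised analytically under a Jeffreys 1/σ prior
(default, assuming equal error across a block's three channels),
giving a Student-type marginal in the residual sum of squares; a
per-channel plug-in σ variant is exposed as `sigma_mode="per_channel"`.
The Laplace-vs-exact gap of the Student kernel,
`log[B(½,(3n−1)/2)/√(2π/3n)]` ≈ 0.026 at n = 10, is asserted in the
tests.

The FRET-sensitized constants are not free parameters: sensitized
emission is acceptor emission driven by donor absorption, so
`κ_F[i] = κ_A[i] · (ε_D[i]/ε_A[i])` with the per-channel
donor:acceptor extinction ratio supplied by the user (from excitation
spectra rescaling of literature extinction coefficients). The
construct block is mandatory in relative mode; without it the
donor:acceptor brightness scale and E′_fr are unidentifiable and the
fit refuses to run.

## Apparent FRET quantities

When only relative κ are available, the package infers the
instrument-independent apparent donor efficiency `E_d` (intrinsic
efficiency × fraction of donors in complex) and the ratio
`r_da = [D0]/[A0]`, with `E_a = E_d · r_da`. Under the
reparameterisation `[D0] = r_da[A0]`, `E_fr[DA] = E_d·r_da·[A0]` the
predictions are linear in [A0], so each sample's [A0] is profiled by
the closed-form weighted least-squares optimum (clamped at zero) and
integrated exactly as a 1-D Gaussian. `(E_d, log₁₀ r_da)` are sampled
by the same Metropolis machinery; r_da is sampled on the log scale
because donor- and acceptor-excess regimes should be symmetric. No
prior for r_da is canonical; the default is uniform in log₁₀ r_da on
[−3, 3].

## Simulator

The simulator generates replicate intensity triples from the forward
model plus Gaussian noise with SD `r ×` (that channel's noiseless mean
for that sample) — noise referenced per sample and per channel, not to
a grand mean, because noise tracks signal strength. Negative
simulated intensities are kept: the Gaussian likelihood is defined on
all reals and clamping would bias inference. The default κ table is

    κ_D = (1.0, 0.05, 0.2)   κ_A = (0.01, 0.75, 0.15)   κ_F = (0.01, 0.05, 0.75)

(intensity·M⁻¹; channels donor, acceptor, FRET), describing a pair
with substantial spectral overlap: own-channel constants largest,
donor and acceptor unequally bright, ~20% bleed-through/cross-talk
into the FRET channel, and small-but-nonzero acceptor contamination of
the donor channel. The bundled benchmark scenario is three cells at
0.2/1/5 µM equal donor and acceptor totals, Kd = 1 µM, E_fr = 0.4,
ten replicates per channel, 5% noise.

What the simulator does *not* emulate — and hence what passing tests
do not certify about real data: background-subtraction residuals and
image-quantification artefacts, shot (Poisson) or log-normal noise,
photobleaching during acquisition, incomplete labelling, cell-to-cell
κ variation, and non-1:1 stoichiometries. Recovery results here
certify the inference machinery, not the microscope.

## Problem sizes in the bundled studies and tests

The test suite runs the headline analysis at full scale (3 chains ×
20,000 recorded steps) once, and uses deliberately smaller problem
sizes elsewhere so the whole battery stays quick: plateau studies at
3 × 8,000 steps, replicate recovery studies at 10 datasets × 5,000
steps, and trend sweeps (noise, replicate count) at 4 datasets per
condition × 1,500 steps — large enough that the monotone cv trends and
near-zero mean error are unambiguous, as the tests assert. The
`experiment` runner defaults to 10 datasets per condition and is
configurable up to 50. Properties that would need very long chains to
resolve by sampling (e.g. the few-percent posterior-SD reduction from
the example E_fr prior) are instead verified on exact grid marginals,
with the MCMC checked against them at a Monte-Carlo tolerance.

## Known limitations

* The Laplace marginal assumes a single, well-curved energy minimum in
  `(D0, A0)`; it is exact for `E_fr = 0` and accurate to a few
  hundredths of a log unit in realistic FRET-active cases, but no
  multimodality detection is attempted.
* The `E_fr ≈ 0` slab (any Kd, no FRET) is a genuine part of the
  posterior under a uniform efficiency prior. The exploration kernel
  and scan-seeded starts keep chains from getting trapped there, but
  its narrow geometry means its posterior mass carries larger
  Monte-Carlo error than the rest of the space.
* σ estimates from n replicates are plugged in, not propagated; with
  very small n (≤ 3) the resulting credible intervals are somewhat
  optimistic. Fitting σ jointly is a possible extension, as is
  treating the κ constants as uncertain in the main fit.
* Exactly three spectral channels are supported; the mixing matrix
  generalises, the code does not.
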