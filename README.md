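# fretbayes

Bayesian inference of *in vivo* binding constants from three-cube FRET
intensity data.

## The problem

Förster resonance energy transfer (FRET) between a donor-tagged and an
acceptor-tagged protein reports on their physical interaction in living
cells, but the raw channel intensities confound everything a
quantitative biologist actually wants: the dissociation constant
`Kd = [D][A]/[DA]` of the interaction, the intrinsic FRET efficiency
`E_fr` of the complex, the unknown fluorophore concentrations in each
cell, spectral cross-talk and bleed-through, and measurement noise.
`fretbayes` separates these by fitting an explicit photophysical and
biochemical model and reporting full posterior distributions — so the
output is not just "Kd ≈ 1 µM" but how strongly the data constrain it,
including the honest answer "only a lower bound" when concentrations
were chosen badly.

It is aimed at quantitative cell biologists and modellers who have
background-corrected three-cube FRET intensities (donor, acceptor and
FRET channels) from cells or regions spanning a range of expression
levels, plus standard donor-only / acceptor-only / tandem-construct
calibration samples.

## The model

Free donor D, free acceptor A and complex DA at equilibrium:

    DA² − (D0 + A0 + Kd)·DA + D0·A0 = 0,   [D] = [D0] − [DA],  [A] = [A0] − [DA]

Predicted channel intensities are linear in the species concentrations,

    I = M(κ, E_fr) · ([D], [A], [DA])ᵀ,
    M[:, DA] = κ_D (1 − E_fr) + κ_A + κ_F E_fr,

where the nine κ constants map molar concentration to intensity per
channel and absorb illumination, extinction, quantum yield and detector
sensitivity (hence all cross-talk and bleed-through). Replicate
measurements are Gaussian around the prediction with per-sample,
per-channel noise scales estimated from the replicate scatter. The
unknown totals (D0, A0) of every sample are nuisance parameters,
removed by a Laplace approximation: Nelder–Mead finds the energy
minimum over (D0, A0) and the 2×2 Hessian gives the Gaussian integral

    log P(data | Kd, E_fr) = −E_min + log 2π − ½ log|H|.

The posterior of (log₁₀ Kd, E_fr) is then sampled by
Metropolis–Hastings with step sizes tuned to a 40–60% acceptance rate,
multiple chains, Gelman–Rubin convergence checks and burn-in removal.
Relative κ calibration (gauge κ_D1 ≡ 1), apparent quantities
(E_d, r_da, E_a) and a simulator for experiment design round out the
toolkit.

## Worked example

Simulate the benchmark experiment — three cells with equal donor and
acceptor totals of 0.2, 1 and 5 µM, true Kd = 1 µM, E_fr = 0.4, ten
measurements per cell per channel, 5% noise — and fit it:

```python
from fretbayes import FretModel, simulate

cfg = simulate.figure2_config(seed=11)
ds = simulate.simulate_dataset(cfg)
res = FretModel(ds, cfg.kappa).fit(chains=3, steps=8000, seed=1)
print(res.summary())
```

```
          Three-cube FRET binding model
========================================================
samples: 3   chains: 3   recorded steps/chain: 8000
burn-in indices: [0, 0, 0]
pooled draws: 24000   acceptance: 45.0%
--------------------------------------------------------
              mean          sd       cv          5%         95%
    Kd    1.02e-06   2.082e-07    0.204   7.133e-07   1.391e-06
  E_fr      0.4118     0.02975    0.072      0.3654      0.4626
--------------------------------------------------------
ConvergenceReport(PASS: PSRF(log10 Kd)=1.0012, PSRF(E_fr)=1.0003, IQR overlap=True)
vs. simulation truth: log10 Kd error = +0.0084, E_fr error = +0.0118
```

Reading the numbers: the posterior mean recovers the generating
Kd = 1 µM within 2% (`log10 Kd error` = log₁₀ of posterior-mean-Kd
over true Kd, 0 for a perfect estimate); the coefficient of variation
(`cv`, posterior SD over mean) says the data pin Kd to about ±20% and
E_fr to ±7%; the acceptance rate sits inside the 40–60% tuning band;
and the potential scale reduction factors near 1 confirm the three
independently started chains sample the same distribution.

The same workflow is available from the shell:

```bash
fretbayes simulate --kd 1 --efr 0.4 --d0 0.2,1,5 --a0 0.2,1,5 \
    --units uM --n 10 --noise 0.05 --seed 11 --out data.csv
fretbayes fit data.csv --chains 3 --steps 8000 --seed 1 --out-dir fit/
fretbayes grid data.csv --out energy.txt      # energy surface for contour plots
fretbayes experiment noise_sweep --out-dir study/   # replicate recovery studies
```

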