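# mixguts

Bayesian hybrid neural-ODE TKTD modelling of chemical-mixture survival
toxicity.

## The problem

Acute toxicity tests (OECD 203 style: 96 h of constant exposure, daily
survivor counts) are run substance by substance, but organisms in the
field meet *mixtures*. The classical null models — Concentration
Addition (CA), where components act as dilutions of one another, and
Independent Action (IA), where survival probabilities multiply — predict
most mixtures well, yet miss synergistic and antagonistic interactions.
`mixguts` is for ecotoxicologists and risk assessors who want to
(1) calibrate a mechanistic survival model on routine mixture data,
(2) predict survival for untested concentration ratios, times and
combinations with honest uncertainty, and (3) quantify how far a mixture
deviates from CA/IA expectations.

## The model

A chain of three components, calibrated jointly by MCMC:

1. **Toxicokinetics** — per substance *i*, the scaled internal
   concentration follows `dC_i/dt = kd_i (X_i(t) − C_i(t))` with constant
   water concentration `X_i` (solved in closed form).
2. **Damage bridge** — `C(t) ↦ D(t)`, a scalar latent damage. Either
   Damage Addition (`D = b + Σ a_i C_i`, label `n`), its exponential
   (`n_exp`), or 1–3 ReLU perceptron layers of width *n* feeding an
   exponential output (`nn_ReLU_n_exp`, …) that can express non-additive
   interaction surfaces. `*_split` variants additionally express the
   threshold median as the same function of per-substance medians.
3. **Toxicodynamics** — GUTS-IT (individual tolerance):
   `S(t) = exp(−hb·t) / (1 + (max_τ≤t D(τ)/α)^β)`, with log-logistic
   threshold distribution (median `α`, shape `β`) and background hazard
   `hb`. Counts are conditionally binomial between observations.

Priors follow routine TKTD practice (log-normal `kd`, `α`, `hb`;
normal(0, 0.5) network weights; log-uniform `β` on [10⁻², 10²]), with
`kd`/`α` optionally centred on single-substance calibrations. Fit
quality is compared by WAIC/NRMSE/SPPE and posterior predictive checks;
mixture interaction is scored by the Mean Penalized Deviation (MPD), the
uncertainty-penalized symmetric ratio between CA- or IA-expected and
model-predicted survival, classified at |MPD| ≥ 0.1 (weak) and ≥ 0.2
(strong). See `docs/methods.md` for the full account.

## Worked example

Simulate a synergistic binary mixture, calibrate a one-layer NN bridge,
and score its deviation from Concentration Addition:

```bash
mixguts simulate --pattern synergism --seed 34 --out syn.csv
mixguts deviation --data syn.csv --model nn_ReLU_n_exp --pair A,B \
    --chains 2 --iterations 2500 --warmup 1250 --seed 134 --out dev.csv
```

which prints

```
wrote 36 series (216 observations) to syn.csv
max R-hat = 1.0514, min ESS = 52
warning: convergence contract not met
CA: MPD = +0.758 (synergism-strong, 0 masked)
IA: MPD = +0.784 (synergism-strong, 0 masked)
```

`max R-hat`/`min ESS` are convergence diagnostics over *raw* parameters
(contract: R-hat < 1.05, ESS > 400); raw NN weights are
permutation-symmetric and mix slowly, so short chains trip the warning
even when the survival pushforward is stable — see `docs/methods.md`.
The MPD of +0.76 under CA means the calibrated surface predicts far
lower survival across the concentration grid than CA built from the
model's own single-substance margins: the generated synergism is
recovered and classified as strong (threshold 0.2). The same pipeline
on additive data (`--pattern additive`) yields |MPD| < 0.1 ("none"):
the statistic does not fabricate interactions. Library equivalents:
`generate_artificial_mixture`, `run_mcmc`, `deviation_analysis`.

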