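# Methods

## Model

`mixguts` models acute survival of aquatic organisms under constant
exposure to a mixture of `n` chemicals as a chain of three components.

**Toxicokinetics (TK).** Each substance `i` has a scaled internal
concentration `C_i(t)` following the one-compartment equation
`dC_i/dt = kd_i (X_i - C_i)` with constant water concentration `X_i` and
dominant rate constant `kd_i` (h⁻¹). Because exposure is constant the
solver uses the exact exponential solution; an adaptive RK45 integrator
(rtol 1e-8, atol 1e-10) is retained as an oracle and for future
time-variable exposure. The initial internal concentration is 0 at the
start of the test (organisms are unexposed beforehand).

**Damage bridge.** The vector `C(t)` is aggregated into a scalar latent
damage `D(t)` by one of six functions: a linear form (`n`), its
exponential (`n_exp`), or one to three `n x n` perceptron layers
(identity or ReLU activation) followed by an exponential output
(`nn_n_exp`, `nn_ReLU_n_exp`, `nn_ReLU_nn_ReLU_n_exp`,
`nn_ReLU_nn_ReLU_nn_ReLU_n_exp`). Layer width equals the number of
substances; there is no hidden-width knob. The exponential output keeps
`D > 0`; the plain `n` label may go negative, and non-positive damage is
treated as "no effect" downstream.

**Toxicodynamics (TD).** Survival follows the individual-tolerance
variant of the General Unified Threshold model of Survival (GUTS-IT):
each organism has a fixed threshold drawn from a log-logistic
distribution (median `alpha`, shape `beta`); with background hazard
`hb`,

    S(t) = exp(-hb t) / (1 + (Dmax(t)/alpha)^beta),

where `Dmax(t)` is the running maximum of damage.

**Initial condition.** Exponential-output bridges evaluate to
`exp(bias) > 0` at `C = 0`, while damage is zero at the start of the
test and `S(0) = 1`. We reconcile this by starting the running maximum
at zero: the bridge output at `t = 0` is excluded from `Dmax`, and
contributes from the first refinement step (1 h by default) onward.
This makes the baseline damage visible to the first observation
interval's likelihood, so calibration actively suppresses spurious
baseline kill — without it, a constant damage offset is invisible to
the conditional likelihood yet ruins unconditional predictions.

**Split-alpha variants.** For `*_split` labels the global threshold
median is expressed through per-substance medians,
`alpha = f(alpha_1, ..., alpha_n)` with `f` the damage bridge itself,
*sharing* its parameter values. Split is restricted to
exponential-output labels so the aggregated median stays positive.
Marginal `alpha_i` are constants, not functions of time.

**Observation model.** Survivor counts are conditionally binomial
between consecutive observations,
`n_k | n_{k-1} ~ Bin(n_{k-1}, S(t_k)/S(t_{k-1}))`. Its pointwise terms
(one per interval) feed WAIC and posterior predictive checks.

## Bayesian calibration

Positive parameters (`kd`, `hb`, `alpha`, `beta`) are sampled on the
log scale. Priors: `kd_i` and `alpha` log-normal — centred on
single-substance estimates with sd 0.5 when a marginal calibration is
supplied, otherwise weakly informative log-normal(log 1, 2); network
weights, biases and output coefficients normal(0, 0.5); `hb` log-normal
with sd 1 centred on the pooled control-group mortality rate per
fish-hour — a clean control only bounds the hazard from above, so zero
observed deaths enter as a half-death pseudo-count
(0.5/fish-hours ≈ 5e-4 h⁻¹ for one 10-fish 96-h control) rather than a
hard floor, with 1e-5 h⁻¹ as the absolute fallback when no control data
exist; `beta` log-uniform on [1e-2, 1e2].

The recommended workflow for mixture data mirrors routine TKTD
practice: calibrate each substance alone first (reduced model: identity
bridge, so the composition is exactly reduced GUTS-IT), then calibrate
the mixture model with `kd`/`alpha` priors centred on those marginal
estimates. Single-substance calibrations fix the bridge to the identity
(`a = 1`, `b = 0`) because with one substance the output coefficient
and the threshold median are scale-confounded.

**Sampler.** Each requested chain is an independent affine-invariant
ensemble (emcee) using differential-evolution moves (80% DE, 20%
snooker). Initialization matters for the ReLU bridges, whose posteriors
carry many local optima separated by kink surfaces: we (1) pre-screen a
prior-scale cloud and polish the best points with L-BFGS-B (batched
finite-difference gradients), and (2) for layered bridges alternate two
rounds of short scouting-ensemble runs with re-polishing of the best
visited point, which reliably climbs between ridge systems where direct
optimization stalls. Walkers start from the final mode jittered by a
diagonal-Laplace posterior scale (curvature-based, capped at the prior
scale). The post-warmup (steps x walkers) sample is thinned by striding
across steps and walkers down to exactly `iterations - warmup` draws
per chain, so the returned draws have low autocorrelation and the
familiar `chains x (iterations - warmup)` layout. Defaults are 3 chains
of 7500 iterations with 5000 warm-up.

Convergence contract: split rank-normalized R-hat < 1.05 and bulk
ESS > 400 for all parameters. The linear and reduced models meet the
contract easily at default settings; raw weights of multi-layer ReLU
bridges are non-identifiable (sign/permutation symmetry) and their raw
R-hat/ESS can remain poor even when fit quality and predictions are
stable — convergence for those is judged on pushforwards (WAIC terms,
predicted survival).

**Damage refinement.** Inside the likelihood, damage and its running
maximum are evaluated on the union of observation times and a regular
refinement grid (`refine_h`, default 1 h; the test-suite and acceptance
experiments use 2 h, which changes third-decimal survival values at
most for the kinetics involved).

## Goodness of fit

NRMSE (root-mean-square error over survivor counts, normalized by the
observed mean, posterior-mean predictions), SPPE (end-of-test observed
minus predicted count over the initial count), WAIC
(`-2 (lpd - p_waic)`, pointwise unit = one observation interval, sample
variance with denominator n-1), and PPC coverage (the percentage of
observations inside the equal-tailed 95% predictive interval of counts
simulated from the conditional binomial re-anchored at the previous
observed count). NRMSE and WAIC are comparative metrics; absolute
values are not interpreted.

## Mixture null models and deviation

For a binary mixture, Concentration Addition (CA) predicts the effect
level `X` solving `C_A/LC_X,A + C_B/LC_X,B = 1`; Independent Action
(IA) multiplies marginal survival probabilities. The Mean Penalized
Deviation pools, over a concentration-by-time grid,

    MPD = mean[ (benchmark - predicted) / (benchmark + predicted)
                * (1 - CI_width) ],

masking points whose 95% credible-interval width exceeds 0.5 entirely.
MPD lies in [-1, 1]; positive values mean the calibrated model predicts
more mortality than the null (synergism tendency). Classification:
|MPD| >= 0.1 weak, >= 0.2 strong, boundaries closed.

**Benchmark construction.** By default the CA and IA benchmarks are
built from the calibrated mixture model's *own* single-substance
predictions: `LC_X,i` comes from inverting the model's posterior-mean
survival at exposures with substance `i` alone (margins are evaluated
out to the largest total concentration on the grid so every cell's
effect level is reachable), and IA multiplies the model's marginal
survivals (divided once by the model's background survival so `hb` is
not double-counted). Benchmark and prediction then share calibration
error, and the MPD isolates the interaction structure of the fitted
surface: a strictly additive bridge scores MPD ≈ 0 by construction,
matching the theoretical alignment of Damage Addition with CA. We
initially built benchmarks from separate single-substance calibrations
instead; at realistic acute-test sizes (10 organisms per group, 7
levels per margin) the sampling noise of two independently estimated
surfaces, amplified by the symmetric ratio at low survival, produced
|MPD| up to ~0.3 on perfectly additive data — a false-positive rate
that defeats the statistic's purpose. The externally-calibrated
benchmark remains available (`marginals=` argument) for workflows with
authoritative single-substance studies.

The default deviation grid is 21 x 21 cells per pair, spanning zero to
each substance's maximum concentration within mixed exposures, at 4,
24, 48, 72 and 96 h.

Note that under IA, steep concentration-response curves (log-logistic
shape > 1) make additively-generated data score as synergistic; this is
a known property of the IA null, not a detection error, and is why CA
is the primary reference.

## Synthetic data

`generate_artificial_mixture` emulates a 96-h constant-exposure acute
test on a binary mixture: 7 total-concentration levels (geometric
series spanning LC5-LC95 of the additive reference at 96 h), 5 mixture
proportions (0, 0.25, 0.5, 0.75, 1), observations at 0, 4, 24, 48, 72,
96 h, 10 organisms per group, plus an unexposed control. Interaction is
induced by a Hewlett-type isobole exponent on potency-scaled internal
concentrations,

    D = [ (C_A/theta_A)^(1/lam) + (C_B/theta_B)^(1/lam) ]^lam,

with `lam = 1` additive (straight isoboles; exactly CA-consistent under
GUTS-IT), `lam = 2` synergistic, `lam = 0.5` antagonistic; both margins
are untouched by `lam`. Default truths: `kd = 0.3 h⁻¹` per substance,
potencies 1, `alpha = 1`, `beta = 3`, `hb = 0.001 h⁻¹` — unit-scale,
mid-steepness, mild background mortality. Counts are drawn through the
same conditional-binomial chain the likelihood assumes.

What the generator does **not** emulate: inter-organism heterogeneity
beyond the IT threshold, time-variable exposure, solvent/co-formulant
effects, immobility endpoints, or inter-study variability. Passing
tests demonstrate self-consistency of the inference machinery and
detectability of isobole-type interactions at OECD-like sample sizes —
not performance on real mixtures.

## Validation protocols

Random time-point and random time-series 90/10 splits (train fraction
rounded half-up; `t = 0` anchors never leave training under time-point
splitting since they carry no likelihood information), repeated with
fresh seeds; leave-pair-out removes exactly the series whose active
substances equal the pair (higher-order mixtures containing the pair
stay in training). Validation NRMSE uses unconditional posterior-mean
predicted counts (`n0 x E[S(t)]`) from the train-only fit.

## Problem sizes and numerical choices

The shipped test-suite and `scripts/acceptance.py` run the full
pipeline at deliberately desk-scale sizes: parameter recovery uses 20
(suite) or 8 (script) replicates at the reference 3 x 7500/5000 MCMC
protocol; model-comparison and deviation experiments use 2 chains with
2000-3000 iterations scaled to model dimension, and a 2-h damage
refinement grid. LC_X inversion brackets on log-concentration and
solves with Brent's method (relative tolerance ~1e-9); CA solves are
vectorized over a 400-point logit-spaced effect grid with interpolated
crossings (abs. error < 2e-3 in survival against the scalar solver).
Degenerate inputs: all-masked deviation grids raise
`InsufficientConfidenceError`; non-positive damage maxima map to "no
toxicant effect"; survival log-floors at exp(-1000) to keep impossible
draws finite.

## Known limitations

- Constant exposure only; the numerical TK path exists but the public
  API does not accept time-varying profiles.
- No GUTS-SD variant, no sublethal endpoints, no hierarchical pooling
  across studies.
- Ensemble MCMC on the 2- and 3-layer bridges mixes slowly in the raw
  parameter space; WAIC values for those models carry a few units of
  sampler noise at desk-scale settings, and WAIC gaps of that order
  between the linear and deep bridges on additive data are not
  meaningful.
- The isobole-exponent generator is one mechanism of non-additivity;
  rate-constant interactions (one substance altering another's
  elimination) produce different time signatures not represented here.
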