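"""Concentration-Addition / Independent-Action benchmarks and deviation scoring.

The two classical null models for mixture toxicity are built from
single-substance ("marginal") calibrations:

* CA treats components as dilutions of one another: the expected effect
  level X of a mixture solves sum_i C_i / LC_X,i = 1.
* IA multiplies component survival probabilities.

Deviation of the calibrated mixture model from a benchmark is summarized
by the Mean Penalized Deviation

    MPD = mean_i [ (benchmark_i - predicted_i) / (benchmark_i + predicted_i)
                   * (1 - uncertainty_i) ],

a symmetric ratio in [-1, 1], penalized by the width of the 95% credible
interval of the prediction; points whose uncertainty exceeds 0.5 are
excluded entirely. Positive MPD marks a synergism tendency (the model
predicts lower survival than the null), negative MPD antagonism.
Classification thresholds: |MPD| >= 0.1 weak, >= 0.2 strong.

Benchmarks are computed on the toxicant-induced survival and multiplied
once by a common background survival factor, so background mortality does
not enter the CA/IA comparison twice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .bayes import PosteriorSamples, survival_pushforward
from .errors import DomainError, InsufficientConfidenceError, UsageError

#: classification thresholds on |MPD| (closed boundaries).
WEAK_THRESHOLD = 0.1
STRONG_THRESHOLD = 0.2

#: CI-width level above which a deviation point is masked.
MASK_THRESHOLD = 0.5


@dataclass(frozen=True)
class MarginalModel:
    """Fixed-parameter single-substance reduced GUTS-IT model.

    Damage equals the scaled internal concentration (identity bridge),
    so survival is s(c, t) = exp(-hb t) / (1 + (c (1 - e^{-kd t}) / alpha)^beta).
    Typically built from the posterior medians of a marginal calibration.
    """

    kd: float
    alpha: float
    beta: float
    hb: float = 0.0

    def __post_init__(self):
        if self.kd <= 0 or self.alpha <= 0 or self.beta <= 0 or self.hb < 0:
            raise DomainError("require kd, alpha, beta > 0 and hb >= 0")

    def dmax(self, conc, t):
        return np.asarray(conc) * (1.0 - np.exp(-self.kd * np.asarray(t)))

    def survival_tox(self, conc, t):
        """Toxicant-only survival (background hazard excluded)."""
        d = self.dmax(conc, t)
        with np.errstate(over="ignore"):
            return 1.0 / (1.0 + (d / self.alpha) ** self.beta)

    def survival(self, conc, t):
        return np.exp(-self.hb * np.asarray(t)) * self.survival_tox(conc, t)

    def lc_closed_form(self, X: float, t: float) -> float:
        """Closed-form LC_X on toxicant-only survival (test oracle for lc_x)."""
        r = (X / 100.0) / (1.0 - X / 100.0)
        return self.alpha * r ** (1.0 / self.beta) / (
            1.0 - np.exp(-self.kd * t)
        )


def lc_x(model, X: float, t: float, bracket=(1e-12, 1e12)) -> float:
    """Concentration producing X% mortality at time t.

    ``model`` is either a :class:`MarginalModel` (its toxicant-only
    survival is inverted) or a callable ``s(conc, t)`` monotone
    non-increasing in ``conc``. Root-found by bracketing + Brent bisection
    to relative tolerance 1e-6.
    """
    if not 0 < X < 100:
        raise DomainError("X must be in (0, 100)")
    if isinstance(model, MarginalModel):
        surv: Callable = model.survival_tox
    elif callable(model):
        surv = model
    else:
        raise UsageError("model must be a MarginalModel or a callable s(c, t)")
    target = 1.0 - X / 100.0
    if surv(0.0, t) <= target:
        raise DomainError(
            f"effect {X}% not attainable: survival at zero concentration is "
            f"{surv(0.0, t):.6g} <= {target:.6g}"
        )

    def g(log_c):
        return surv(np.exp(log_c), t) - target

    lo, hi = np.log(bracket[0]), np.log(bracket[1])
    if g(hi) > 0:
        raise DomainError(
            f"effect {X}% not attainable within bracket {bracket}: "
            f"survival at c={bracket[1]:g} is {surv(bracket[1], t):.6g}"
        )
    log_root = brentq(g, lo, hi, xtol=1e-12, rtol=1e-9)
    return float(np.exp(log_root))


def _effect_grid(n: int = 400) -> np.ndarray:
    """Effect levels X densely covering (0, 100), logit-spaced."""
    u = np.linspace(logit(1e-6), logit(1.0 - 1e-6), n)
    return 100.0 * expit(u)


def ca_benchmark(
    marginals: Mapping[str, MarginalModel],
    concentrations: Mapping[str, float],
    t: float,
) -> float:
    """CA-expected toxicant survival of one mixture point.

    Solves sum_i C_i / LC_X,i(t) = 1 for the common effect level X by
    monotone bisection and returns 1 - X/100. All-zero concentrations
    return 1.
    """
    active = {s: c for s, c in concentrations.items() if c > 0}
    if not active:
        return 1.0
    missing = set(active) - set(marginals)
    if missing:
        raise UsageError(f"no marginal model for substances: {sorted(missing)}")

    def total(X):
        return sum(
            c / lc_x(marginals[s], X, t) for s, c in active.items()
        ) - 1.0

    lo, hi = 1e-7, 100.0 - 1e-7
    if total(lo) <= 0:  # mixture too dilute for even a tiny common effect
        return 1.0
    if total(hi) >= 0:  # beyond the resolvable effect range
        return 0.0
    X = brentq(total, lo, hi, xtol=1e-10, rtol=1e-9)
    return 1.0 - X / 100.0


def _ca_solve(inv_lc: np.ndarray, C: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Solve sum_i C_i / LC_X,i = 1 on a discretized effect grid.

    inv_lc: (n, nX) reciprocal lethal concentrations on the effect grid X
    (percent); C: (G, n) concentrations. Returns CA-expected survival
    1 - X*/100 per grid row (1 where no common effect level is reached).
    """
    S = C @ inv_lc  # (G, nX) total toxic-unit sum, decreasing in X
    out = np.ones(C.shape[0])
    crossed = S[:, 0] > 1.0  # a common effect level exists above X_min
    # interpolate log S against logit(X/100) at the S = 1 crossing
    u = logit(X / 100.0)
    with np.errstate(divide="ignore"):
        logS = np.log(S[crossed])
    for row, ls in zip(np.nonzero(crossed)[0], logS):
        k = np.searchsorted(-ls, 0.0)  # first index with log S <= 0
        if k >= len(u):
            out[row] = 0.0
            continue
        if k == 0:
            out[row] = 1.0 - X[0] / 100.0
            continue
        w = ls[k - 1] / (ls[k - 1] - ls[k])
        ustar = u[k - 1] + w * (u[k] - u[k - 1])
        out[row] = 1.0 - expit(ustar)
    return out


def ca_benchmark_grid(
    marginals: Sequence[MarginalModel],
    C: np.ndarray,
    t: float,
    n_effect: int = 400,
) -> np.ndarray:
    """Vectorized CA benchmark for a (G, n) concentration grid at time t.

    Uses the closed-form marginal LC_X on a dense effect grid and
    interpolates the crossing of sum_i C_i / LC_X,i = 1.
    """
    C = np.atleast_2d(np.asarray(C, dtype=float))
    X = _effect_grid(n_effect)
    inv_lc = np.array(
        [1.0 / np.array([m.lc_closed_form(x, t) for x in X])
         for m in marginals]
    )  # (n, nX)
    return _ca_solve(inv_lc, C, X)


def _inverse_lc_from_curve(conc: np.ndarray, s: np.ndarray,
                           X: np.ndarray) -> np.ndarray:
    """Reciprocal LC_X from a discrete marginal survival curve.

    The curve is made non-increasing (running minimum) before inversion;
    effect levels beyond the curve's reach get LC = inf (zero reciprocal),
    effect levels below the first positive concentration extrapolate
    between 0 and the first grid point.
    """
    s_mono = np.minimum.accumulate(s)
    target = 1.0 - X / 100.0
    # np.interp needs increasing x: flip the monotone-decreasing curve
    lc = np.interp(target[::-1], s_mono[::-1], conc[::-1],
                   left=np.nan, right=0.0)[::-1]
    inv = np.zeros_like(lc)
    beyond = np.isnan(lc)  # effect deeper than the curve reaches: LC = inf
    background = ~beyond & (lc <= 0)  # effect within background mortality
    mid = ~beyond & ~background
    inv[mid] = 1.0 / lc[mid]
    inv[background] = 1e12
    return inv


def ia_benchmark(marginal_survivals) -> float:
    """IA-expected survival: the product of marginal survival probabilities."""
    s = np.asarray(marginal_survivals, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise DomainError("marginal survivals must lie in [0, 1]")
    return float(np.prod(s))


@dataclass(frozen=True)
class DeviationPoint:
    """One grid point entering the MPD: benchmark vs predicted survival."""

    benchmark: float
    predicted: float
    uncertainty: float

    def __post_init__(self):
        if not 0 <= self.uncertainty <= 1:
            raise DomainError("uncertainty (CI width) must be in [0, 1]")

    @property
    def masked(self) -> bool:
        return self.uncertainty > MASK_THRESHOLD

    @property
    def term(self) -> float:
        denom = self.benchmark + self.predicted
        if denom <= 0:
            raise DomainError("benchmark + predicted must be > 0")
        return ((self.benchmark - self.predicted) / denom
                * (1.0 - self.uncertainty))


@dataclass
class DeviationResult:
    pair: tuple[str, ...]
    hypothesis: str  # "CA" | "IA"
    mpd: float
    n_points_used: int
    n_points_masked: int
    classification: str

    def to_row(self) -> dict:
        return {
            "pair": "-".join(self.pair),
            "hypothesis": self.hypothesis,
            "mpd": self.mpd,
            "n_used": self.n_points_used,
            "n_masked": self.n_points_masked,
            "classification": self.classification,
        }


def classify_interaction(mpd: float) -> str:
    if not -1.0 <= mpd <= 1.0:
        raise DomainError("MPD must lie in [-1, 1]")
    if mpd >= STRONG_THRESHOLD:
        return "synergism-strong"
    if mpd >= WEAK_THRESHOLD:
        return "synergism-weak"
    if mpd <= -STRONG_THRESHOLD:
        return "antagonism-strong"
    if mpd <= -WEAK_THRESHOLD:
        return "antagonism-weak"
    return "none"


def mean_penalized_deviation(
    points: Sequence[DeviationPoint],
    pair: tuple[str, ...] = (),
    hypothesis: str = "CA",
) -> DeviationResult:
    """Aggregate deviation points into an MPD and interaction class.

    Masked points (CI width > 0.5) are excluded; if every point is masked
    the model gave no reliable prediction anywhere and an
    InsufficientConfidenceError is raised.
    """
    used = [p for p in points if not p.masked]
    if not used:
        raise InsufficientConfidenceError(
            "all deviation points exceeded the 50% uncertainty mask"
        )
    mpd = float(np.mean([p.term for p in used]))
    return DeviationResult(
        pair=tuple(pair),
        hypothesis=hypothesis,
        mpd=mpd,
        n_points_used=len(used),
        n_points_masked=len(points) - len(used),
        classification=classify_interaction(mpd),
    )


def fit_marginal_models(
    dataset,
    chains: int = 2,
    iterations: int = 2000,
    warmup: int = 1000,
    seed: int = 0,
    refine_h: float = 1.0,
) -> dict[str, MarginalModel]:
    """Calibrate a reduced single-substance model for every substance.

    Each marginal fit uses the control series plus the series exposing
    that substance alone, with the identity bridge (the composition then
    reduces to standard reduced GUTS-IT). Returns posterior-median
    parameter sets, the inputs to CA/IA benchmarks and to
    single-substance-informed priors for mixture calibrations.
    """
    from .bayes import run_mcmc
    from .data_model import RunConfig

    out = {}
    for k, sub in enumerate(dataset.substances):
        sub_data = dataset.restricted([sub])
        cfg = RunConfig(
            model_label="n", chains=chains, iterations=iterations,
            warmup=warmup, seed=seed + 17 * k + 1,
        )
        samples = run_mcmc(
            sub_data, cfg, fix_bridge_identity=True, refine_h=refine_h
        )
        med = samples.median_params()
        out[sub] = MarginalModel(
            kd=med[f"kd_{sub}"], alpha=med["alpha"],
            beta=med["beta"], hb=med["hb"],
        )
    return out


def marginal_estimates(marginals: Mapping[str, MarginalModel]) -> dict:
    """Marginal fits in the form build_priors expects for informed priors."""
    return {
        sub: {"kd": m.kd, "alpha": m.alpha} for sub, m in marginals.items()
    }


def deviation_analysis(
    samples: PosteriorSamples,
    pair: tuple[str, str],
    conc_max: Mapping[str, float],
    hypothesis: str = "CA",
    times: Sequence[float] = (4.0, 24.0, 48.0, 72.0, 96.0),
    n_grid: int = 21,
    max_draws: int = 300,
    floor: float = 1e-9,
    marginals: Mapping[str, MarginalModel] | None = None,
) -> DeviationResult:
    """Full CA/IA deviation workflow for one binary mixture.

    The calibrated mixture model supplies the predicted survival (posterior
    mean) and its 95% CI width on an n_grid x n_grid concentration grid at
    the given times. The CA/IA benchmark is constructed from the same
    calibrated model's own single-substance predictions — the lethal
    concentrations LC_X,i (CA) or marginal survival probabilities (IA) come
    from the model evaluated with one substance at a time — so the MPD
    isolates the interaction structure of the fitted surface and shared
    calibration error cancels. Passing ``marginals`` (fixed-parameter
    single-substance fits) switches the benchmark to those external
    marginal models instead.
    """
    if hypothesis not in ("CA", "IA"):
        raise UsageError("hypothesis must be 'CA' or 'IA'")
    subs = samples.layout.substances
    if set(pair) - set(subs):
        raise UsageError(f"pair {pair} not registered in the calibration")
    axes = [np.linspace(0.0, conc_max[s], n_grid) for s in pair]
    AA, BB = np.meshgrid(axes[0], axes[1], indexing="ij")
    grid_pair = np.column_stack([AA.ravel(), BB.ravel()])  # (G, 2)
    X = np.zeros((grid_pair.shape[0], len(subs)))
    for k, s in enumerate(pair):
        X[:, subs.index(s)] = grid_pair[:, k]

    times = np.asarray(times, dtype=float)
    draws = survival_pushforward(samples, X, times, max_draws=max_draws)
    predicted = draws.mean(axis=0)  # (G, T)
    width = (np.quantile(draws, 0.975, axis=0)
             - np.quantile(draws, 0.025, axis=0))

    # cell (i, j) of the grid corresponds to axes[0][i], axes[1][j]
    ii, jj = np.unravel_index(np.arange(grid_pair.shape[0]),
                              (n_grid, n_grid))
    if marginals is None:
        # marginal survival curves predicted by the mixture model itself,
        # evaluated out to the largest total concentration on the grid so
        # the CA solve can reach every cell's effect level
        c_total = float(sum(conc_max[s] for s in pair))
        marg_axis = np.linspace(0.0, c_total, 2 * n_grid - 1)
        marg_mean = []
        for k, s in enumerate(pair):
            Xm = np.zeros((len(marg_axis), len(subs)))
            Xm[:, subs.index(s)] = marg_axis
            md = survival_pushforward(samples, Xm, times,
                                      max_draws=max_draws)
            marg_mean.append(md.mean(axis=0))  # (len(marg_axis), T)
        X_eff = _effect_grid()
        # model background survival, to avoid counting it once per margin
        s0 = survival_pushforward(
            samples, np.zeros((1, len(subs))), times, max_draws=max_draws
        ).mean(axis=0)[0]  # (T,)
        bench = np.empty_like(predicted)
        for ti in range(len(times)):
            if hypothesis == "IA":
                sa = np.interp(axes[0], marg_axis, marg_mean[0][:, ti])
                sb = np.interp(axes[1], marg_axis, marg_mean[1][:, ti])
                bench[:, ti] = (sa[ii] * sb[jj]
                                / max(float(s0[ti]), floor))
            else:
                inv_lc = np.vstack(
                    [_inverse_lc_from_curve(marg_axis, marg_mean[k][:, ti],
                                            X_eff)
                     for k in range(2)]
                )
                bench[:, ti] = _ca_solve(inv_lc, grid_pair, X_eff)
    else:
        m_pair = [marginals[s] for s in pair]
        hb_bar = float(np.mean([m.hb for m in m_pair]))
        bench = np.empty_like(predicted)
        for ti, t in enumerate(times):
            background = np.exp(-hb_bar * t)
            if hypothesis == "CA":
                bench[:, ti] = (
                    ca_benchmark_grid(m_pair, grid_pair, t) * background
                )
            else:
                s_marg = np.column_stack(
                    [m.survival_tox(grid_pair[:, k], t)
                     for k, m in enumerate(m_pair)]
                )
                bench[:, ti] = s_marg.prod(axis=1) * background

    points = []
    for ti in range(len(times)):
        for g in range(grid_pair.shape[0]):
            points.append(
                DeviationPoint(
                    benchmark=max(float(bench[g, ti]), floor),
                    predicted=max(float(predicted[g, ti]), floor),
                    uncertainty=min(float(width[g, ti]), 1.0),
                )
            )
    return mean_penalized_deviation(points, pair=pair, hypothesis=hypothesis)


def deviation_table(results: Sequence[DeviationResult]) -> pd.DataFrame:
    """Machine-readable deviation summary, one row per (pair, hypothesis)."""
    return pd.DataFrame([r.to_row() for r in results])
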