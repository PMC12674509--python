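"""GUTS-IT toxicodynamics: damage -> survival probability -> count likelihood.

Under the individual-tolerance (IT) assumption every organism carries a
fixed damage threshold drawn from a log-logistic distribution with median
``alpha`` and shape ``beta``; an organism dies as soon as the running
maximum of damage exceeds its threshold. Together with a background hazard
``hb`` the survival probability is

    S(t) = exp(-hb t) * (1 - F(max_{0<=tau<=t} D(tau)))
         = exp(-hb t) / (1 + (Dmax(t)/alpha)^beta),

with the convention that a non-positive running maximum produces no
toxicant effect (the limit Dmax -> 0+).

The observation model is the standard conditional binomial between
consecutive observation times: n_k | n_{k-1} ~ Binomial(n_{k-1},
S(t_k)/S(t_{k-1})). Its pointwise decomposition (one term per observation
interval) is retained for WAIC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, xlog1py, xlogy

from .bridge import DamageTrajectory
from .data_model import SurvivalTimeSeries
from .errors import DomainError, ValidationError


@dataclass(frozen=True)
class TDParams:
    """GUTS-IT toxicodynamic parameters.

    hb: background hazard (per hour, >= 0); alpha: median of the threshold
    distribution (damage units, > 0); beta: shape (> 0). ``marginal_alphas``
    carries the per-substance alpha_i of split variants (the effective
    alpha is then computed by the bridge, not stored here).
    """

    hb: float
    alpha: float
    beta: float
    marginal_alphas: tuple[float, ...] | None = None

    def __post_init__(self):
        if not np.isfinite(self.hb) or self.hb < 0:
            raise DomainError(f"hb must be >= 0, got {self.hb}")
        if not np.isfinite(self.alpha) or self.alpha <= 0:
            raise DomainError(f"alpha must be > 0, got {self.alpha}")
        if not np.isfinite(self.beta) or self.beta <= 0:
            raise DomainError(f"beta must be > 0, got {self.beta}")


@dataclass
class SurvivalCurve:
    times: np.ndarray
    s: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if self.times.shape != self.s.shape:
            raise DomainError("times and s must have the same shape")

    def at(self, times) -> np.ndarray:
        """Survival at a subset of the curve's own grid points."""
        idx = np.searchsorted(self.times, times)
        if not np.allclose(self.times[idx], times):
            raise DomainError("requested times are not on the curve grid")
        return self.s[idx]


def log_threshold_factor(dmax: np.ndarray, alpha, beta) -> np.ndarray:
    """log of 1/(1 + (Dmax/alpha)^beta), with Dmax <= 0 mapped to 0."""
    dmax, alpha, beta = np.broadcast_arrays(
        np.asarray(dmax, dtype=float),
        np.asarray(alpha, dtype=float),
        np.asarray(beta, dtype=float),
    )
    out = np.zeros(dmax.shape)
    pos = dmax > 0
    with np.errstate(over="ignore", divide="ignore"):
        # dmax/alpha may under/overflow at extreme draws; logaddexp keeps
        # the resulting +-inf exponents exact (factor 1 or 0)
        out[pos] = -np.logaddexp(
            0.0, beta[pos] * np.log(dmax[pos] / alpha[pos])
        )
    return out


def effective_running_max(times, values) -> np.ndarray:
    """Running damage maximum honouring the initial condition D(t=0) = 0.

    Exponential-output bridges evaluate to exp(bias) > 0 at zero internal
    concentration, but damage is zero at the start of the experiment and
    S(0) = 1; the threshold maximum therefore starts at zero and
    accumulates damage only for tau > 0. (If the grid does not start at
    t = 0 the first value is included as usual.)
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times[0] == 0.0:
        values = np.concatenate([[-np.inf], values[1:]])
    return np.maximum.accumulate(values)


def survival_probability(damage: DamageTrajectory, td: TDParams) -> SurvivalCurve:
    """Survival curve implied by a damage trajectory under GUTS-IT."""
    dmax = effective_running_max(damage.times, damage.values)
    log_s = -td.hb * damage.times + log_threshold_factor(
        dmax, td.alpha, td.beta
    )
    return SurvivalCurve(damage.times, np.exp(log_s))


def conditional_binomial_loglik(
    series: SurvivalTimeSeries, curve: SurvivalCurve
) -> tuple[float, np.ndarray]:
    """Conditional-binomial log-likelihood of observed survivor counts.

    Returns (total, pointwise) where ``pointwise`` holds one term per
    observation interval (t_{k-1}, t_k]; they sum exactly to the total.
    """
    s = curve.at(series.times)
    n = series.n_surviving
    if np.any(np.diff(n) > 0):
        raise ValidationError(
            f"series {series.series_id!r}: increasing survivor counts"
        )
    p = s[1:] / s[:-1]
    if np.any(p > 1 + 1e-12) or np.any(p < -1e-12):
        raise DomainError(
            "conditional survival probability outside [0, 1] beyond tolerance"
        )
    p = np.clip(p, 0.0, 1.0)
    prev, curr = n[:-1], n[1:]
    log_coeff = gammaln(prev + 1) - gammaln(curr + 1) - gammaln(prev - curr + 1)
    pointwise = log_coeff + xlogy(curr, p) + xlog1py(prev - curr, -p)
    return float(pointwise.sum()), pointwise


def simulate_survivors(
    curve: SurvivalCurve, n0: int, seed=None
) -> np.ndarray:
    """Forward-simulate survivor counts by sequential conditional binomials."""
    if n0 < 1:
        raise DomainError("n0 must be >= 1")
    rng = np.random.default_rng(seed)
    s = curve.s
    counts = np.empty(len(s), dtype=int)
    counts[0] = n0
    for k in range(1, len(s)):
        p = s[k] / s[k - 1] if s[k - 1] > 0 else 0.0
        counts[k] = rng.binomial(counts[k - 1], min(max(p, 0.0), 1.0))
    return counts
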