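"""Goodness-of-fit criteria: NRMSE, SPPE, WAIC and posterior predictive checks.

NRMSE and WAIC are relative metrics: they compare models calibrated on the
same data set and their absolute values are not interpreted in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .bayes import PosteriorSamples, survival_pushforward
from .data_model import MixtureDataset, SurvivalTimeSeries
from .errors import DomainError, UsageError


@dataclass
class GofReport:
    """One calibration's goodness-of-fit summary (one row per model/dataset)."""

    nrmse: float
    sppe: dict[str, float]  # per series
    waic: float
    lpd: float
    p_waic: float
    ppc_coverage_pct: float

    def to_row(self) -> dict:
        return {
            "nrmse": self.nrmse,
            "waic": self.waic,
            "lpd": self.lpd,
            "p_waic": self.p_waic,
            "ppc_coverage_pct": self.ppc_coverage_pct,
            "sppe_mean": float(np.mean(list(self.sppe.values()))),
        }


def nrmse(y_obs, y_pred) -> float:
    """Root-mean-square error normalized by the observed mean."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape or y_obs.size == 0:
        raise DomainError("y_obs and y_pred must be equal-length, non-empty")
    m = y_obs.mean()
    if m <= 0:
        raise DomainError("mean of y_obs must be > 0")
    return float(np.sqrt(np.mean((y_obs - y_pred) ** 2)) / m)


def sppe(series: SurvivalTimeSeries, y_pred) -> float:
    """Survival-probability prediction error at the end of the test.

    (observed - predicted survivor count at the final time) divided by the
    observed initial count; positive values mean mortality was
    under-predicted.
    """
    y_pred = np.asarray(y_pred, dtype=float)
    if len(series.times) < 2 or y_pred.shape != series.times.shape:
        raise DomainError("y_pred must align with a series of >= 2 points")
    n0 = series.n_surviving[0]
    if n0 <= 0:
        raise DomainError("initial count must be > 0")
    return float((series.n_surviving[-1] - y_pred[-1]) / n0)


def waic(pointwise_loglik: np.ndarray) -> tuple[float, float, float]:
    """Widely applicable information criterion from a (draws, obs) matrix.

    Returns (waic, lpd, p_waic) with lpd the sum over observations of the
    log posterior-mean density and p_waic the sum of posterior variances of
    the log-densities (sample variance, denominator n-1);
    waic = -2 (lpd - p_waic), deviance scale.
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise UsageError("need a (draws >= 2, observations) log-lik matrix")
    if not np.all(np.isfinite(ll)):
        raise DomainError("pointwise log-likelihood contains non-finite entries")
    n_draws = ll.shape[0]
    lpd = float(np.sum(logsumexp(ll, axis=0) - np.log(n_draws)))
    p_w = float(np.sum(np.var(ll, axis=0, ddof=1)))
    return -2.0 * (lpd - p_w), lpd, p_w


def posterior_mean_counts(samples: PosteriorSamples,
                          max_draws: int = 400) -> dict[str, np.ndarray]:
    """Posterior-mean predicted survivor counts per series at its own times.

    Predictions are unconditional on the observed trajectory: count(t) =
    n0 * E[S(t)], the quantity used for NRMSE and SPPE.
    """
    dataset = samples.core.dataset
    out = {}
    for s in dataset.series:
        X = np.array([[s.concentration_of(sub)
                       for sub in dataset.substances]])
        draws = survival_pushforward(samples, X, s.times, max_draws=max_draws)
        out[s.series_id] = s.n0 * draws.mean(axis=0)[0]
    return out


def ppc_coverage(dataset: MixtureDataset, samples: PosteriorSamples,
                 max_draws: int = 500, seed: int = 0) -> float:
    """Percentage of observations inside their 95% posterior predictive interval.

    For each observation interval the predictive survivor count is
    simulated from the conditional binomial re-anchored at the previous
    observed count, one simulation per posterior draw; the interval is the
    equal-tailed 2.5-97.5% quantile range of those counts.
    """
    core = samples.core
    if core.dataset is not dataset and core.dataset.mixture_keys() != dataset.mixture_keys():
        raise UsageError("samples were not calibrated on this dataset")
    flat = samples.flat(natural=False)
    take = np.unique(
        np.linspace(0, flat.shape[0] - 1,
                    min(max_draws, flat.shape[0])).astype(int)
    )
    logp = np.empty((len(take), core.n_intervals))
    for start in range(0, len(take), 256):
        sel = take[start:start + 256]
        nat = core.layout.unpack(flat[sel])
        logp[start:start + len(sel)] = np.minimum(
            core.conditional_logp(nat), 0.0
        )
    rng = np.random.default_rng(seed)
    sim = rng.binomial(
        core.nprev.astype(int)[None, :], np.exp(logp)
    )
    lo = np.quantile(sim, 0.025, axis=0)
    hi = np.quantile(sim, 0.975, axis=0)
    inside = (core.ncurr >= lo) & (core.ncurr <= hi)
    return float(100.0 * inside.mean())


def gof_report(samples: PosteriorSamples, max_draws: int = 400,
               seed: int = 0) -> GofReport:
    """Assemble the full goodness-of-fit report for one calibration."""
    dataset = samples.core.dataset
    pred = posterior_mean_counts(samples, max_draws=max_draws)
    y_obs = np.concatenate([s.n_surviving for s in dataset.series])
    y_pred = np.concatenate([pred[s.series_id] for s in dataset.series])
    w, lpd, p_w = waic(samples.pointwise)
    return GofReport(
        nrmse=nrmse(y_obs, y_pred),
        sppe={s.series_id: sppe(s, pred[s.series_id])
              for s in dataset.series},
        waic=w,
        lpd=lpd,
        p_waic=p_w,
        ppc_coverage_pct=ppc_coverage(dataset, samples,
                                      max_draws=max_draws, seed=seed),
    )
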