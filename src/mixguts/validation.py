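"""Calibration/validation protocols: data splitting, cross-validation,
leave-pair-out validation and prediction-surface experiments."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .bayes import PosteriorSamples, predict_surface, run_mcmc
from .data_model import MixtureDataset, RunConfig, SurvivalTimeSeries
from .errors import MCMCError, UsageError
from .gof import nrmse


@dataclass
class SplitPlan:
    """How to divide a dataset into calibration and validation subsets."""

    strategy: str = "random-time-series"
    train_fraction: float = 0.9
    repeats: int = 5
    seed: int = 0
    pair: tuple[str, str] | None = None

    def __post_init__(self):
        if self.strategy not in (
            "random-time-point", "random-time-series", "leave-pair-out"
        ):
            raise UsageError(f"unknown split strategy {self.strategy!r}")
        if not 0 < self.train_fraction < 1:
            raise UsageError("train_fraction must be in (0, 1)")
        if self.repeats < 1:
            raise UsageError("repeats must be >= 1")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_random_timepoints(
    dataset: MixtureDataset, plan: SplitPlan, repeat: int = 0
) -> tuple[MixtureDataset, pd.DataFrame]:
    """Randomly hold out individual observations (series, time) pairs.

    The train fraction applies to the total observation count (rounded
    half-up). The t=0 anchor of every series always stays in train: it
    carries no likelihood information and anchors the conditional-binomial
    chain. Returns the training dataset and a long-format table of the
    held-out observations.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([plan.seed, repeat, 1])
    )
    points = [
        (s.series_id, k)
        for s in dataset.series
        for k in range(len(s.times))
    ]
    n_total = len(points)
    n_train = _round_half_up(plan.train_fraction * n_total)
    eligible = [(sid, k) for sid, k in points if k > 0]
    n_val = n_total - n_train
    if n_val > len(eligible):
        raise UsageError("not enough non-anchor points to hold out")
    chosen = rng.choice(len(eligible), size=n_val, replace=False)
    held = {eligible[i] for i in chosen}
    by_series: dict[str, SurvivalTimeSeries] = {
        s.series_id: s for s in dataset.series
    }
    train_series, val_rows = [], []
    for s in dataset.series:
        keep = [k for k in range(len(s.times))
                if (s.series_id, k) not in held]
        out = [k for k in range(len(s.times)) if (s.series_id, k) in held]
        train_series.append(
            SurvivalTimeSeries(
                series_id=s.series_id,
                study_id=s.study_id,
                times=s.times[keep],
                n_surviving=s.n_surviving[keep],
                exposures=s.exposures,
            )
        )
        for k in out:
            val_rows.append(
                {
                    "series_id": s.series_id,
                    "time_h": s.times[k],
                    "n_surviving": int(s.n_surviving[k]),
                    "n0": s.n0,
                }
            )
    train = MixtureDataset(series=train_series, substances=dataset.substances)
    validation = pd.DataFrame(
        val_rows, columns=["series_id", "time_h", "n_surviving", "n0"]
    )
    return train, validation


def split_random_timeseries(
    dataset: MixtureDataset, plan: SplitPlan, repeat: int = 0
) -> tuple[MixtureDataset, MixtureDataset]:
    """Randomly hold out whole time series at the same train fraction."""
    rng = np.random.default_rng(
        np.random.SeedSequence([plan.seed, repeat, 2])
    )
    ids = [s.series_id for s in dataset.series]
    n_train = _round_half_up(plan.train_fraction * len(ids))
    perm = rng.permutation(len(ids))
    train_ids = {ids[i] for i in perm[:n_train]}
    train = dataset.subset([i for i in ids if i in train_ids])
    val = dataset.subset([i for i in ids if i not in train_ids])
    return train, val


def leave_pair_out(
    dataset: MixtureDataset, pair: Sequence[str]
) -> tuple[MixtureDataset, MixtureDataset]:
    """Hold out every series whose active substances are exactly the pair.

    Higher-order mixtures containing the pair remain in training; the
    validation subset is the exact binary mixture only.
    """
    key = frozenset(pair)
    if len(key) != 2:
        raise UsageError("pair must contain two distinct substances")
    val_ids = [
        s.series_id for s in dataset.series if s.mixture_key == key
    ]
    if not val_ids:
        raise UsageError(
            f"dataset has no series with exact mixture {sorted(key)}"
        )
    val_set = set(val_ids)
    train = dataset.subset(
        [s.series_id for s in dataset.series if s.series_id not in val_set]
    )
    return train, dataset.subset(val_ids)


def _validation_nrmse_series(
    samples: PosteriorSamples, validation: MixtureDataset, max_draws: int = 300
) -> float:
    """Out-of-sample NRMSE on whole held-out series (counts vs n0 * mean S)."""
    subs = samples.layout.substances
    obs, pred = [], []
    for s in validation.series:
        X = np.array([[s.concentration_of(sub) for sub in subs]])
        surf = predict_surface(samples, X, s.times, max_draws=max_draws)
        obs.append(s.n_surviving.astype(float))
        pred.append(s.n0 * surf.mean[0])
    return nrmse(np.concatenate(obs), np.concatenate(pred))


def _validation_nrmse_points(
    samples: PosteriorSamples, validation: pd.DataFrame,
    dataset: MixtureDataset, max_draws: int = 300
) -> float:
    subs = samples.layout.substances
    by_id = {s.series_id: s for s in dataset.series}
    obs, pred = [], []
    for sid, g in validation.groupby("series_id"):
        s = by_id[sid]
        X = np.array([[s.concentration_of(sub) for sub in subs]])
        times = g["time_h"].to_numpy(dtype=float)
        surf = predict_surface(samples, X, times, max_draws=max_draws)
        obs.append(g["n_surviving"].to_numpy(dtype=float))
        pred.append(s.n0 * surf.mean[0])
    return nrmse(np.concatenate(obs), np.concatenate(pred))


def cross_validate(
    dataset: MixtureDataset,
    models: Sequence[str],
    plan: SplitPlan,
    config: RunConfig,
) -> pd.DataFrame:
    """Repeated split/calibrate/validate over a list of bridge models.

    Returns one row per (model, repeat) with the validation NRMSE between
    observed survivor counts and posterior-mean predictions from the
    train-only fit (no re-anchoring on validation observations). A failed
    calibration flags the row and the run continues.
    """
    rows = []
    for rep in range(plan.repeats):
        if plan.strategy == "random-time-point":
            train, validation = split_random_timepoints(dataset, plan, rep)
        elif plan.strategy == "random-time-series":
            train, validation = split_random_timeseries(dataset, plan, rep)
        else:
            raise UsageError("use leave_pair_out() for the pair strategy")
        for mi, model in enumerate(models):
            cfg = RunConfig(
                model_label=model,
                chains=config.chains,
                iterations=config.iterations,
                warmup=config.warmup,
                seed=int(
                    np.random.SeedSequence(
                        [config.seed, rep, mi]
                    ).generate_state(1)[0] % (2**31)
                ),
                prior_overrides=config.prior_overrides,
            )
            row = {"model": model, "repeat": rep, "strategy": plan.strategy}
            try:
                samples = run_mcmc(train, cfg)
                if plan.strategy == "random-time-point":
                    row["nrmse"] = _validation_nrmse_points(
                        samples, validation, dataset
                    )
                else:
                    row["nrmse"] = _validation_nrmse_series(
                        samples, validation
                    )
                row["failed"] = False
            except MCMCError as exc:
                row["nrmse"] = np.nan
                row["failed"] = True
                row["message"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)


def prediction_surface_experiment(
    samples: PosteriorSamples,
    pair: tuple[str, str],
    conc_grid: dict[str, np.ndarray],
    times: Sequence[float],
    max_draws: int = 300,
    isocline_levels: Sequence[float] = (0.25, 0.5, 0.75),
):
    """Mean-survival and CI-width surfaces over a binary concentration grid.

    Returns a dict time -> PredictionSurface (grid flattened row-major over
    the pair's axes) plus isocline contours extracted at the requested
    survival levels.
    """
    subs = samples.layout.substances
    if set(pair) - set(subs):
        raise UsageError(f"pair {pair} not registered")
    ax_a = np.asarray(conc_grid[pair[0]], dtype=float)
    ax_b = np.asarray(conc_grid[pair[1]], dtype=float)
    AA, BB = np.meshgrid(ax_a, ax_b, indexing="ij")
    X = np.zeros((AA.size, len(subs)))
    X[:, subs.index(pair[0])] = AA.ravel()
    X[:, subs.index(pair[1])] = BB.ravel()
    surf = predict_surface(samples, X, np.asarray(times, dtype=float),
                           max_draws=max_draws)
    isoclines = {}
    for ti, t in enumerate(surf.times):
        grid_mean = surf.mean[:, ti].reshape(len(ax_a), len(ax_b))
        level_curves = {}
        for lev in isocline_levels:
            # crossing of the survival level along each row of the grid
            pts = []
            for i, row in enumerate(grid_mean):
                below = np.nonzero(row <= lev)[0]
                if below.size and below[0] > 0:
                    j = below[0]
                    w = (row[j - 1] - lev) / (row[j - 1] - row[j])
                    pts.append(
                        (ax_a[i], ax_b[j - 1] + w * (ax_b[j] - ax_b[j - 1]))
                    )
            level_curves[lev] = np.array(pts)
        isoclines[float(t)] = level_curves
    return {"surface": surf, "isoclines": isoclines,
            "axes": {pair[0]: ax_a, pair[1]: ax_b}}
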