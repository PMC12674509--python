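"""Bayesian calibration engine: priors, MCMC, diagnostics, posterior prediction.

Parameterization. Positive parameters (kd, hb, alpha(s), beta) are sampled
on the log scale, so their normal priors are log-normal in natural space
and the uniform prior on log(beta) is a log-uniform. Neural-network
weights, biases and output coefficients are sampled directly with
normal(0, 0.5) priors.

Sampler. Each requested chain is an independent affine-invariant ensemble
(emcee) initialized near a posterior mode and advanced for ``iterations``
ensemble steps; the first ``warmup`` steps are discarded and the remaining
(steps x walkers) sample is thinned down to exactly
``iterations - warmup`` draws per chain by striding across steps and
walkers, which leaves draws with very low autocorrelation. Convergence is
judged with the split-R-hat and ESS diagnostics (contract: R-hat < 1.05,
ESS > 400).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import SimpleNamespace
from typing import Mapping

import emcee
import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .bridge import _N_LAYERS, bridge_function
from .data_model import MixtureDataset, RunConfig, split_label
from .errors import ConfigurationError, MCMCError, UsageError
from .survival import log_threshold_factor

HB_FLOOR = 1e-5  # per hour; hb prior location when controls show no deaths

# ---------------------------------------------------------------------------
# Parameter layout


@dataclass
class ParamLayout:
    """Mapping between named model parameters and the flat sampled vector."""

    model_label: str
    substances: tuple[str, ...]
    fix_bridge_identity: bool
    names: tuple[str, ...]
    transforms: tuple[str, ...]  # "log" | "id", aligned with names

    def __post_init__(self):
        self.base_label, self.split = split_label(self.model_label)
        self.index = {name: i for i, name in enumerate(self.names)}

    @property
    def ndim(self) -> int:
        return len(self.names)

    def slice_of(self, names) -> np.ndarray:
        return np.array([self.index[n] for n in names], dtype=int)

    def to_natural(self, U: np.ndarray) -> np.ndarray:
        """Transform sampled-space draws (..., ndim) to natural space."""
        nat = np.array(U, dtype=float)
        for i, tr in enumerate(self.transforms):
            if tr == "log":
                nat[..., i] = np.exp(nat[..., i])
        return nat

    def unpack(self, U: np.ndarray) -> SimpleNamespace:
        """Split a (B, ndim) sampled-space batch into natural parameter blocks.

        Returns kd (B, n); weights/biases lists per layer; output a (B, n)
        and bias b (B,); hb, alpha, beta (B,). For split variants ``alpha``
        is the effective alpha aggregated from the marginal alpha_i by the
        bridge function itself (shared parameter values); the marginals are
        exposed as ``alphas``.
        """
        U = np.atleast_2d(U)
        B = U.shape[0]
        n = len(self.substances)
        idx = self.index

        kd = np.exp(U[:, [idx[f"kd_{s}"] for s in self.substances]])
        weights, biases = [], []
        if self.fix_bridge_identity:
            a = np.ones((B, n))
            b = np.zeros(B)
        else:
            for k in range(1, _N_LAYERS[self.base_label] + 1):
                W = U[:, [idx[f"W{k}_{i}_{j}"]
                          for i in range(1, n + 1)
                          for j in range(1, n + 1)]].reshape(B, n, n)
                bk = U[:, [idx[f"b{k}_{i}"] for i in range(1, n + 1)]]
                weights.append(W)
                biases.append(bk)
            a = U[:, [idx[f"a_{i}"] for i in range(1, n + 1)]]
            b = (U[:, idx["b"]] if self.base_label in ("n", "n_exp")
                 else np.zeros(B))
        hb = np.exp(U[:, idx["hb"]])
        beta = np.exp(U[:, idx["beta"]])
        if self.split:
            alphas = np.exp(
                U[:, [idx[f"alpha_{s}"] for s in self.substances]]
            )
            alpha = bridge_function(
                self.base_label, alphas, weights, biases, a, b
            )
            # a misbehaving draw could aggregate to a non-positive alpha
            # only for the plain n label, which split_label already rejects
        else:
            alphas = None
            alpha = np.exp(U[:, idx["alpha"]])
        return SimpleNamespace(
            kd=kd, weights=weights, biases=biases, a=a, b=b,
            hb=hb, alpha=alpha, alphas=alphas, beta=beta,
        )


def build_layout(
    model_label: str,
    substances: tuple[str, ...],
    fix_bridge_identity: bool = False,
) -> ParamLayout:
    base, is_split = split_label(model_label)
    if fix_bridge_identity and base != "n":
        raise UsageError("fix_bridge_identity is defined for the n label only")
    n = len(substances)
    names: list[str] = [f"kd_{s}" for s in substances]
    transforms: list[str] = ["log"] * n
    if not fix_bridge_identity:
        for k in range(1, _N_LAYERS[base] + 1):
            for i in range(1, n + 1):
                for j in range(1, n + 1):
                    names.append(f"W{k}_{i}_{j}")
            for i in range(1, n + 1):
                names.append(f"b{k}_{i}")
        names += [f"a_{i}" for i in range(1, n + 1)]
        if base in ("n", "n_exp"):
            names.append("b")
        transforms += ["id"] * (len(names) - len(transforms))
    names.append("hb")
    transforms.append("log")
    if is_split:
        names += [f"alpha_{s}" for s in substances]
        transforms += ["log"] * n
    else:
        names.append("alpha")
        transforms.append("log")
    names.append("beta")
    transforms.append("log")
    return ParamLayout(
        model_label=model_label,
        substances=tuple(substances),
        fix_bridge_identity=fix_bridge_identity,
        names=tuple(names),
        transforms=tuple(transforms),
    )


# ---------------------------------------------------------------------------
# Priors


@dataclass
class PriorSet:
    """Per-parameter prior descriptors in sampled space.

    Entries are ``("normal", loc, scale)`` or ``("uniform", lo, hi)``;
    for log-transformed parameters they describe the prior of the log,
    i.e. log-normal / log-uniform priors in natural space.
    """

    priors: dict[str, tuple] = field(default_factory=dict)

    def __post_init__(self):
        for name, p in self.priors.items():
            if p[0] == "normal" and p[2] <= 0:
                raise ConfigurationError(f"prior scale for {name!r} must be > 0")
            if p[0] == "uniform" and p[2] <= p[1]:
                raise ConfigurationError(f"empty uniform range for {name!r}")
            if p[0] not in ("normal", "uniform"):
                raise ConfigurationError(f"unknown prior kind {p[0]!r}")

    def arrays(self, layout: ParamLayout):
        """(is_normal mask, p1, p2) aligned with the layout order."""
        missing = [n for n in layout.names if n not in self.priors]
        if missing:
            raise ConfigurationError(f"no prior for parameters: {missing}")
        kinds = np.array(
            [self.priors[n][0] == "normal" for n in layout.names]
        )
        p1 = np.array([self.priors[n][1] for n in layout.names])
        p2 = np.array([self.priors[n][2] for n in layout.names])
        return kinds, p1, p2


def pooled_control_mortality_rate(dataset: MixtureDataset) -> float:
    """Pooled per-hour control mortality, floored at ``HB_FLOOR``.

    Estimated as total control deaths divided by total fish-hours at risk
    (survivor-weighted trapezoid over observation intervals). A clean
    control carries only an upper bound on the hazard, so zero deaths are
    replaced by a half-death pseudo-count rather than a hard floor —
    0.5/960 fish-hours ~ 5e-4 h^-1 for a 10-fish 96-h control — keeping
    the prior consistent with the information the control actually holds.
    """
    deaths = 0.0
    fish_hours = 0.0
    for s in dataset.control_series():
        deaths += s.n_surviving[0] - s.n_surviving[-1]
        mid = 0.5 * (s.n_surviving[:-1] + s.n_surviving[1:])
        fish_hours += float(np.sum(mid * np.diff(s.times)))
    if fish_hours <= 0:
        return HB_FLOOR
    return max(max(deaths, 0.5) / fish_hours, HB_FLOOR)


def build_priors(
    model_label: str,
    dataset: MixtureDataset,
    single_substance_estimates: Mapping[str, Mapping[str, float]] | None = None,
    overrides: Mapping[str, tuple] | None = None,
    fix_bridge_identity: bool = False,
) -> PriorSet:
    """Construct the prior set for a model/dataset combination.

    kd and alpha priors are centred on single-substance estimates when
    supplied (sd 0.5 on the log scale) and otherwise fall back to the
    weakly-informative log-normal(log 1, 2). The hb prior location comes
    from the pooled control-group mortality rate; NN weights/biases and
    output coefficients get normal(0, 0.5); beta is log-uniform on
    [1e-2, 1e2].
    """
    if len(dataset) == 0:
        raise UsageError("cannot build priors from an empty dataset")
    est = single_substance_estimates or {}
    layout = build_layout(
        model_label, dataset.substances, fix_bridge_identity
    )
    hb_loc = float(np.log(pooled_control_mortality_rate(dataset)))
    priors: dict[str, tuple] = {}
    for name in layout.names:
        if name.startswith("kd_"):
            sub = name[3:]
            if sub in est and "kd" in est[sub]:
                priors[name] = ("normal", float(np.log(est[sub]["kd"])), 0.5)
            else:
                priors[name] = ("normal", 0.0, 2.0)
        elif name.startswith("alpha_"):
            sub = name[6:]
            if sub in est and "alpha" in est[sub]:
                priors[name] = ("normal", float(np.log(est[sub]["alpha"])), 0.5)
            else:
                priors[name] = ("normal", 0.0, 2.0)
        elif name == "alpha":
            priors[name] = ("normal", 0.0, 2.0)
        elif name == "hb":
            priors[name] = ("normal", hb_loc, 1.0)
        elif name == "beta":
            priors[name] = ("uniform", float(np.log(1e-2)), float(np.log(1e2)))
        else:  # NN weights, biases, output coefficients and bias
            priors[name] = ("normal", 0.0, 0.5)
    if overrides:
        for name, p in overrides.items():
            if name not in priors:
                raise ConfigurationError(f"override for unknown parameter {name!r}")
            priors[name] = tuple(p)
    return PriorSet(priors)


# ---------------------------------------------------------------------------
# Likelihood core


class LikelihoodCore:
    """Precomputed arrays for fast batched likelihood evaluation.

    The damage trajectory is evaluated on the union of all observation
    times and an hourly refinement grid, so the running maximum of
    non-monotone (ReLU) bridges is resolved below the observation scale.
    """

    def __init__(self, dataset: MixtureDataset, layout: ParamLayout,
                 refine_h: float = 1.0):
        self.dataset = dataset
        self.layout = layout
        obs_times = np.unique(np.concatenate([s.times for s in dataset.series]))
        tmax = obs_times.max() if obs_times.size else 0.0
        grid = np.unique(np.concatenate(
            [obs_times, np.arange(0.0, tmax + refine_h / 2, refine_h)]
        ))
        self.grid = grid
        self.X = dataset.exposure_matrix()  # (S, n)
        # flattened observation intervals
        sidx, gprev, gcurr, nprev, ncurr, dt = [], [], [], [], [], []
        self.interval_series: list[str] = []
        for si, s in enumerate(dataset.series):
            gi = np.searchsorted(grid, s.times)
            for k in range(1, len(s.times)):
                sidx.append(si)
                gprev.append(gi[k - 1])
                gcurr.append(gi[k])
                nprev.append(s.n_surviving[k - 1])
                ncurr.append(s.n_surviving[k])
                dt.append(s.times[k] - s.times[k - 1])
                self.interval_series.append(s.series_id)
        self.sidx = np.array(sidx, dtype=int)
        self.gprev = np.array(gprev, dtype=int)
        self.gcurr = np.array(gcurr, dtype=int)
        self.nprev = np.array(nprev, dtype=float)
        self.ncurr = np.array(ncurr, dtype=float)
        self.dt = np.array(dt, dtype=float)
        from scipy.special import gammaln

        self.log_coeff = (
            gammaln(self.nprev + 1)
            - gammaln(self.ncurr + 1)
            - gammaln(self.nprev - self.ncurr + 1)
        )

    @property
    def n_intervals(self) -> int:
        return len(self.sidx)

    def log_survival_grid(self, nat: SimpleNamespace,
                          X: np.ndarray | None = None,
                          grid: np.ndarray | None = None) -> np.ndarray:
        """log S(t) on (B, S, T) for a batch of natural parameter blocks."""
        X = self.X if X is None else X
        grid = self.grid if grid is None else grid
        # internal concentrations: (B, S, T, n)
        C = X[None, :, None, :] * (
            1.0 - np.exp(-nat.kd[:, None, None, :] * grid[None, None, :, None])
        )
        weights = [W[:, None, None] for W in nat.weights]
        biases = [bk[:, None, None] for bk in nat.biases]
        D = bridge_function(
            self.layout.base_label, C, weights, biases,
            nat.a[:, None, None, :], nat.b[:, None, None],
        )
        # initial condition D(t=0) = 0: the threshold maximum excludes the
        # t = 0 bridge output (exp-output bridges are positive there)
        if grid[0] == 0.0:
            D = D.copy()
            D[..., 0] = -np.inf
        dmax = np.maximum.accumulate(D, axis=-1)
        log_tox = log_threshold_factor(
            dmax, nat.alpha[:, None, None], nat.beta[:, None, None]
        )
        log_s = -nat.hb[:, None, None] * grid[None, None, :] + log_tox
        # floor keeps impossible-survival draws at a huge-but-finite penalty
        # instead of producing inf - inf in the conditional ratios
        return np.maximum(log_s, -1e3)

    def conditional_logp(self, nat: SimpleNamespace) -> np.ndarray:
        """log conditional survival probability per interval, (B, I)."""
        log_s = self.log_survival_grid(nat)
        return (log_s[:, self.sidx, self.gcurr]
                - log_s[:, self.sidx, self.gprev])

    def pointwise_loglik(self, nat: SimpleNamespace) -> np.ndarray:
        """Pointwise conditional-binomial log-likelihood terms, (B, I)."""
        logp = np.minimum(self.conditional_logp(nat), 0.0)
        deaths = self.nprev - self.ncurr
        with np.errstate(divide="ignore", invalid="ignore"):
            log1mp = np.log(-np.expm1(logp))  # log(1 - p), p = exp(logp)
            dead_term = np.where(deaths > 0, deaths * log1mp, 0.0)
        return self.log_coeff + self.ncurr * logp + dead_term

    def loglik(self, U: np.ndarray) -> np.ndarray:
        nat = self.layout.unpack(U)
        return self.pointwise_loglik(nat).sum(axis=1)


def make_log_posterior(core: LikelihoodCore, priors: PriorSet):
    layout = core.layout
    kinds, p1, p2 = priors.arrays(layout)
    norm = kinds
    unif = ~kinds

    def log_posterior(U: np.ndarray) -> np.ndarray:
        U = np.atleast_2d(np.asarray(U, dtype=float))
        lp = np.zeros(U.shape[0])
        z = (U[:, norm] - p1[norm]) / p2[norm]
        lp -= 0.5 * np.sum(z * z, axis=1)
        if unif.any():
            inside = np.all(
                (U[:, unif] >= p1[unif]) & (U[:, unif] <= p2[unif]), axis=1
            )
            lp[~inside] = -np.inf
        ok = np.isfinite(lp)
        if ok.any():
            lp[ok] += core.loglik(U[ok])
        return lp

    return log_posterior


# ---------------------------------------------------------------------------
# Posterior container


@dataclass
class PosteriorSamples:
    """MCMC draws with chain structure plus pointwise log-likelihoods."""

    layout: ParamLayout
    priors: PriorSet
    config: RunConfig
    draws: np.ndarray  # (chains, n_draws, ndim), sampled space
    pointwise: np.ndarray  # (chains * n_draws, n_intervals)
    core: LikelihoodCore

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return self.layout.names

    @property
    def n_total(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    def flat(self, natural: bool = True) -> np.ndarray:
        U = self.draws.reshape(-1, self.layout.ndim)
        return self.layout.to_natural(U) if natural else U

    def natural_draws(self) -> dict[str, np.ndarray]:
        flat = self.flat(natural=True)
        return {n: flat[:, i] for i, n in enumerate(self.layout.names)}

    def median_params(self) -> dict[str, float]:
        return {k: float(np.median(v)) for k, v in self.natural_draws().items()}

    def credible_interval(self, name: str, level: float = 0.95):
        v = self.natural_draws()[name]
        half = (1.0 - level) / 2
        return tuple(np.quantile(v, [half, 1.0 - half]))

    def to_long_frame(self) -> pd.DataFrame:
        """Long table (chain, iteration, parameter, value), natural space."""
        chains, n_draws, d = self.draws.shape
        nat = self.layout.to_natural(self.draws)
        rows = {
            "chain": np.repeat(np.arange(chains), n_draws * d),
            "iteration": np.tile(np.repeat(np.arange(n_draws), d), chains),
            "parameter": np.tile(np.array(self.layout.names), chains * n_draws),
            "value": nat.reshape(-1),
        }
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        nat = self.natural_draws()
        rows = []
        for name in self.layout.names:
            v = nat[name]
            rows.append(
                {
                    "parameter": name,
                    "median": np.median(v),
                    "mean": np.mean(v),
                    "q2.5": np.quantile(v, 0.025),
                    "q97.5": np.quantile(v, 0.975),
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# MAP + MCMC


def _bounds_for(layout, priors):
    kinds, p1, p2 = priors.arrays(layout)
    bounds = []
    for k in range(layout.ndim):
        if kinds[k]:
            bounds.append((p1[k] - 6 * p2[k], p1[k] + 6 * p2[k]))
        else:
            span = p2[k] - p1[k]
            bounds.append((p1[k] + 1e-9 * span, p2[k] - 1e-9 * span))
    return bounds


def _polish(log_post, x0, bounds, maxiter=300):
    """L-BFGS-B ascent with a batched finite-difference gradient."""

    def neg(x):
        return -float(log_post(x[None, :])[0])

    def neg_grad(x):
        h = 1e-6 * np.maximum(1.0, np.abs(x))
        pts = np.vstack([x[None, :], x[None, :] + np.diag(h)])
        vals = -log_post(pts)
        with np.errstate(invalid="ignore"):
            return (vals[1:] - vals[0]) / h

    res = minimize(
        neg, x0, jac=neg_grad, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": maxiter},
    )
    return res.x, float(res.fun)


def _map_estimate(log_post, layout, priors, rng, n_restarts=6,
                  n_screen=512, maxiter=300):
    """Posterior mode via multi-start L-BFGS-B.

    Candidate starts are pre-screened by a single vectorized evaluation of
    a prior-scale cloud (ReLU bridges have many poor local modes); the
    gradient is a batched finite difference.
    """
    kinds, p1, p2 = priors.arrays(layout)
    d = layout.ndim
    bounds = _bounds_for(layout, priors)
    cloud = np.where(
        kinds[None, :],
        p1 + p2 * rng.standard_normal((n_screen, d)) * 0.5,
        p1 + (p2 - p1) * rng.uniform(0.05, 0.95, (n_screen, d)),
    )
    vals = np.concatenate(
        [log_post(cloud[i:i + 128]) for i in range(0, n_screen, 128)]
    )
    order = np.argsort(-vals)
    starts = cloud[order[:n_restarts]]

    best_x, best_f = None, np.inf
    for x0 in starts:
        if not np.isfinite(log_post(x0[None, :])[0]):
            continue
        x, f = _polish(log_post, x0, bounds, maxiter)
        if f < best_f:
            best_x, best_f = x, f
    if best_x is None:
        raise MCMCError("could not find a finite-posterior starting point")
    return best_x


def _clip_uniform(p0, layout, priors):
    kinds, p1, p2 = priors.arrays(layout)
    unif = ~kinds
    if unif.any():
        lo, hi = p1[unif], p2[unif]
        span = hi - lo
        p0[:, unif] = np.clip(p0[:, unif], lo + 1e-6 * span,
                              hi - 1e-6 * span)
    return p0


def _refine_map(log_post, x_map, layout, priors, rng, moves,
                n_walkers, rounds=2, pre_steps=500):
    """Alternate short exploratory ensemble runs with mode polishing.

    ReLU bridge posteriors carry many local optima separated by kink
    surfaces; direct optimization routinely stalls far below the dominant
    mode. Letting a scouting ensemble wander from the current optimum and
    re-polishing its best point climbs between ridge systems reliably.
    """
    d = layout.ndim
    best_x = x_map
    best_f = -float(log_post(x_map[None, :])[0])
    bounds = _bounds_for(layout, priors)
    for _ in range(rounds):
        sd = _laplace_scales(log_post, best_x, layout, priors)
        p0 = best_x[None, :] + sd * rng.standard_normal((n_walkers, d))
        p0 = _clip_uniform(p0, layout, priors)
        scout = emcee.EnsembleSampler(
            n_walkers, d, log_post, vectorize=True, moves=moves
        )
        scout.random_state = np.random.RandomState(
            int(rng.integers(2**31))
        ).get_state()
        scout.run_mcmc(p0, pre_steps, skip_initial_state_check=True)
        lpc = scout.get_log_prob()
        i, j = np.unravel_index(np.argmax(lpc), lpc.shape)
        x, f = _polish(log_post, scout.get_chain()[i, j], bounds)
        if f < best_f:
            best_x, best_f = x, f
    return best_x


def _laplace_scales(log_post, x_map, layout, priors):
    """Per-parameter posterior scale from a diagonal Laplace approximation.

    Second differences of the log-posterior at the mode give curvature;
    flat or non-concave directions (ReLU kinks, weak identification) fall
    back to the prior scale, which also caps the result.
    """
    kinds, p1, p2 = priors.arrays(layout)
    prior_scale = np.where(kinds, p2, (p2 - p1) / 4)
    d = layout.ndim
    h = 1e-3 * np.maximum(1.0, np.abs(x_map))
    pts = np.vstack(
        [x_map[None, :], x_map[None, :] + np.diag(h),
         x_map[None, :] - np.diag(h)]
    )
    vals = log_post(pts)
    curv = -(vals[1:d + 1] - 2 * vals[0] + vals[d + 1:]) / h**2
    with np.errstate(divide="ignore", invalid="ignore"):
        sd = 1.0 / np.sqrt(curv)
    sd = np.where(np.isfinite(sd) & (sd > 0), sd, prior_scale)
    return np.minimum(sd, prior_scale)


def run_mcmc(
    dataset: MixtureDataset,
    config: RunConfig,
    priors: PriorSet | None = None,
    fix_bridge_identity: bool = False,
    single_substance_estimates=None,
    refine_h: float = 1.0,
) -> PosteriorSamples:
    """Calibrate a bridge model on a dataset; returns posterior draws.

    Deterministic for a fixed config seed. Each chain is an independent
    ensemble; the returned draws satisfy
    draws.shape == (chains, iterations - warmup, ndim).
    """
    layout = build_layout(
        config.model_label, dataset.substances, fix_bridge_identity
    )
    if priors is None:
        priors = build_priors(
            config.model_label,
            dataset,
            single_substance_estimates=single_substance_estimates,
            overrides=config.prior_overrides,
            fix_bridge_identity=fix_bridge_identity,
        )
    core = LikelihoodCore(dataset, layout, refine_h=refine_h)
    log_post = make_log_posterior(core, priors)
    d = layout.ndim
    n_walkers = max(2 * d + 2, 16)
    n_walkers += n_walkers % 2
    n_draws = config.iterations - config.warmup
    moves = [
        (emcee.moves.DEMove(), 0.8),
        (emcee.moves.DESnookerMove(), 0.2),
    ]
    master = np.random.SeedSequence(config.seed)
    map_seq, *chain_seeds = master.spawn(config.chains + 1)
    map_rng = np.random.default_rng(map_seq)
    x_map = _map_estimate(log_post, layout, priors, map_rng)
    has_layers = _N_LAYERS[layout.base_label] > 0 and not fix_bridge_identity
    if has_layers:
        x_map = _refine_map(
            log_post, x_map, layout, priors, map_rng, moves, n_walkers,
            rounds=2, pre_steps=min(500, max(100, config.warmup // 4)),
        )
    init_scale = _laplace_scales(log_post, x_map, layout, priors)
    all_draws = np.empty((config.chains, n_draws, d))
    for c, seq in enumerate(chain_seeds):
        rng = np.random.default_rng(seq)
        p0 = x_map[None, :] + init_scale * rng.standard_normal(
            (n_walkers, d)
        )
        p0 = _clip_uniform(p0, layout, priors)
        sampler = emcee.EnsembleSampler(
            n_walkers, d, log_post, vectorize=True, moves=moves,
        )
        sampler.random_state = np.random.RandomState(
            int(seq.generate_state(1)[0]) % (2**31)
        ).get_state()
        try:
            sampler.run_mcmc(
                p0, config.iterations, skip_initial_state_check=True,
                progress=False,
            )
        except Exception as exc:  # pragma: no cover - defensive
            raise MCMCError(f"sampler failed: {exc}") from exc
        chain = sampler.get_chain()  # (iterations, n_walkers, d)
        post = chain[config.warmup:]
        steps = np.arange(n_draws)
        all_draws[c] = post[steps, steps % n_walkers, :]

    flat = all_draws.reshape(-1, d)
    pointwise = np.empty((flat.shape[0], core.n_intervals))
    for start in range(0, flat.shape[0], 512):
        block = flat[start:start + 512]
        pointwise[start:start + block.shape[0]] = core.pointwise_loglik(
            layout.unpack(block)
        )
    return PosteriorSamples(
        layout=layout, priors=priors, config=config,
        draws=all_draws, pointwise=pointwise, core=core,
    )


# ---------------------------------------------------------------------------
# Diagnostics


def _to_inference_dict(samples: PosteriorSamples) -> dict[str, np.ndarray]:
    return {
        name: samples.draws[:, :, i]
        for i, name in enumerate(samples.layout.names)
    }


def gelman_rubin(samples: PosteriorSamples) -> dict[str, float]:
    """Split-chain potential scale reduction (R-hat) per parameter."""
    if samples.draws.shape[0] < 2:
        raise UsageError("R-hat needs at least two chains")
    import arviz as az

    rhat = az.rhat(az.from_dict(posterior=_to_inference_dict(samples)))
    return {k: float(rhat[k].values) for k in samples.layout.names}


def effective_sample_size(samples: PosteriorSamples) -> dict[str, float]:
    """Bulk effective sample size per parameter (autocorrelation-based)."""
    if samples.draws.shape[0] < 2:
        raise UsageError("ESS needs at least two chains")
    import arviz as az

    ess = az.ess(az.from_dict(posterior=_to_inference_dict(samples)))
    return {k: float(ess[k].values) for k in samples.layout.names}


# ---------------------------------------------------------------------------
# Posterior prediction


@dataclass
class PredictionSurface:
    """Pushforward survival summaries on a concentration x time grid."""

    substances: tuple[str, ...]
    conc: np.ndarray  # (G, n) exposure grid
    times: np.ndarray  # (T,)
    mean: np.ndarray  # (G, T)
    lower: np.ndarray  # 2.5% quantile
    upper: np.ndarray  # 97.5% quantile

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in range(self.conc.shape[0]):
            for t in range(len(self.times)):
                row = {
                    f"conc_{s}": self.conc[g, j]
                    for j, s in enumerate(self.substances)
                }
                row.update(
                    time_h=self.times[t],
                    mean=self.mean[g, t],
                    lower=self.lower[g, t],
                    upper=self.upper[g, t],
                    width=self.width[g, t],
                )
                rows.append(row)
        return pd.DataFrame(rows)


def survival_pushforward(
    samples: PosteriorSamples,
    X: np.ndarray,
    times,
    max_draws: int = 400,
) -> np.ndarray:
    """Posterior survival draws (n_draws_used, G, T) for an exposure grid.

    Draws are subsampled deterministically (evenly spaced through the
    chain-stacked sample) to bound memory and compute.
    """
    layout = samples.layout
    X = np.atleast_2d(np.asarray(X, dtype=float))
    times = np.asarray(times, dtype=float)
    order = np.argsort(times)
    sorted_times = times[order]
    grid = np.unique(np.concatenate(
        [sorted_times, np.arange(0.0, sorted_times.max() + 0.5, 1.0)]
    ))
    tidx = np.searchsorted(grid, sorted_times)
    flat = samples.flat(natural=False)
    take = np.unique(
        np.linspace(0, flat.shape[0] - 1, min(max_draws, flat.shape[0]))
        .astype(int)
    )
    out = np.empty((len(take), X.shape[0], len(times)))
    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))
    for start in range(0, len(take), 64):
        sel = take[start:start + 64]
        nat = layout.unpack(flat[sel])
        log_s = samples.core.log_survival_grid(nat, X=X, grid=grid)
        out[start:start + len(sel)] = np.exp(log_s[:, :, tidx][:, :, inv])
    return out


def posterior_predict(
    samples: PosteriorSamples,
    scenario: Mapping[str, float],
    times,
    max_draws: int = 400,
) -> PredictionSurface:
    """Predicted survival with 95% credible band for one exposure scenario."""
    subs = samples.layout.substances
    unknown = set(scenario) - set(subs)
    if unknown:
        raise UsageError(f"unregistered substances in scenario: {sorted(unknown)}")
    X = np.array([[scenario.get(s, 0.0) for s in subs]])
    return predict_surface(samples, X, times, max_draws=max_draws)


def predict_surface(
    samples: PosteriorSamples,
    X: np.ndarray,
    times,
    max_draws: int = 400,
) -> PredictionSurface:
    times = np.asarray(times, dtype=float)
    draws = survival_pushforward(samples, X, times, max_draws=max_draws)
    return PredictionSurface(
        substances=samples.layout.substances,
        conc=np.atleast_2d(X),
        times=times,
        mean=draws.mean(axis=0),
        lower=np.quantile(draws, 0.025, axis=0),
        upper=np.quantile(draws, 0.975, axis=0),
    )
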