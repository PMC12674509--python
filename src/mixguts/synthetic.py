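"""Synthetic survival data generators.

Two generators are provided:

* :func:`generate_artificial_mixture` builds binary-mixture designs with a
  controlled interaction pattern. The interaction mechanism is a
  Hewlett-type isobole exponent lambda acting on potency-scaled internal
  concentrations,

      D(t) = [ (C_A(t)/theta_A)^{1/lambda} + (C_B(t)/theta_B)^{1/lambda} ]^lambda,

  which reduces to Damage Addition (straight isoboles) at lambda = 1,
  bows the isoboles outward (antagonism, less-than-additive damage) for
  lambda < 1 and inward (synergism) for lambda > 1, while leaving both
  single-substance margins untouched.

* :func:`generate_guts_dataset` forward-simulates any TK -> bridge -> TD
  configuration of the package itself (parameter-recovery fixtures).

Both draw survivor counts through the sequential conditional-binomial
observation model and are reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from .bridge import BridgeSpec, evaluate_bridge
from .data_model import ExposureProfile, MixtureDataset, SurvivalTimeSeries
from .errors import DomainError
from .survival import (
    SurvivalCurve,
    TDParams,
    effective_running_max,
    log_threshold_factor,
    simulate_survivors,
)
from .tk import TKParams

PATTERN_LAMBDA = {"additive": 1.0, "antagonism": 0.5, "synergism": 2.0}

DEFAULT_TIMES = (0.0, 4.0, 24.0, 48.0, 72.0, 96.0)
DEFAULT_PROPORTIONS = (0.0, 0.25, 0.5, 0.75, 1.0)


def _default_levels(td: TDParams, kd: float, t_end: float,
                    n_levels: int = 7) -> tuple[float, ...]:
    """Geometric concentration series spanning LC5-LC95 of the additive
    reference (single equivalent substance, theta = 1) at test end."""
    eq = 1.0 - np.exp(-kd * t_end)
    lo = td.alpha * (0.05 / 0.95) ** (1.0 / td.beta) / eq
    hi = td.alpha * (0.95 / 0.05) ** (1.0 / td.beta) / eq
    return tuple(np.geomspace(lo, hi, n_levels))


@dataclass
class ArtificialDesign:
    """Design of an artificial binary-mixture experiment.

    Defaults emulate a 96-h constant-exposure acute test: 7 total
    concentration levels spanning low to high mortality, 5 mixture
    proportions (including both single-substance rays), daily-style
    observation times and 10 organisms per group, plus one unexposed
    control group.
    """

    pattern: str = "additive"
    isobole_exponent: float | None = None  # default set from pattern
    substances: tuple[str, str] = ("A", "B")
    kd: tuple[float, float] = (0.3, 0.3)
    potency: tuple[float, float] = (1.0, 1.0)
    td_truth: TDParams = field(
        default_factory=lambda: TDParams(hb=0.001, alpha=1.0, beta=3.0)
    )
    levels: tuple[float, ...] | None = None
    proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    times: tuple[float, ...] = DEFAULT_TIMES
    n0: int = 10
    include_control: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.pattern not in PATTERN_LAMBDA:
            raise DomainError(
                f"pattern must be one of {sorted(PATTERN_LAMBDA)}"
            )
        if self.isobole_exponent is None:
            self.isobole_exponent = PATTERN_LAMBDA[self.pattern]
        if self.isobole_exponent <= 0:
            raise DomainError("isobole exponent lambda must be > 0")
        if (self.pattern == "additive") != (self.isobole_exponent == 1.0):
            raise DomainError("lambda = 1 if and only if pattern is additive")
        if any(not 0 <= p <= 1 for p in self.proportions):
            raise DomainError("proportions must lie in [0, 1]")
        if self.levels is None:
            self.levels = _default_levels(
                self.td_truth, min(self.kd), max(self.times)
            )
        if any(lv <= 0 for lv in self.levels):
            raise DomainError("levels must be > 0")

    def truth_document(self) -> dict:
        return {
            "pattern": self.pattern,
            "isobole_exponent": float(self.isobole_exponent),
            "substances": list(self.substances),
            "kd": [float(k) for k in self.kd],
            "potency": [float(p) for p in self.potency],
            "hb": float(self.td_truth.hb),
            "alpha": float(self.td_truth.alpha),
            "beta": float(self.td_truth.beta),
            "levels": [float(lv) for lv in self.levels],
            "proportions": [float(p) for p in self.proportions],
            "times": [float(t) for t in self.times],
            "n0": int(self.n0),
            "seed": int(self.seed),
        }


def isobole_damage(CA, CB, theta_a, theta_b, lam) -> np.ndarray:
    """Hewlett-type aggregate damage of two potency-scaled concentrations."""
    if lam <= 0:
        raise DomainError("lambda must be > 0")
    xa = np.asarray(CA, dtype=float) / theta_a
    xb = np.asarray(CB, dtype=float) / theta_b
    return (xa ** (1.0 / lam) + xb ** (1.0 / lam)) ** lam


def _survival_curve_from_damage(times, damage, td: TDParams) -> SurvivalCurve:
    dmax = effective_running_max(times, damage)
    log_s = -td.hb * np.asarray(times) + log_threshold_factor(
        dmax, td.alpha, td.beta
    )
    return SurvivalCurve(np.asarray(times, dtype=float), np.exp(log_s))


def generate_artificial_mixture(design: ArtificialDesign) -> MixtureDataset:
    """Simulate a binary-mixture dataset with the designed interaction."""
    rng = np.random.default_rng(design.seed)
    times = np.asarray(design.times, dtype=float)
    sub_a, sub_b = design.substances
    kd_a, kd_b = design.kd
    series = []
    if design.include_control:
        curve = _survival_curve_from_damage(
            times, np.zeros_like(times), design.td_truth
        )
        counts = simulate_survivors(curve, design.n0, rng)
        series.append(
            SurvivalTimeSeries(
                series_id="control",
                study_id=design.pattern,
                times=times,
                n_surviving=counts,
                exposures=(),
            )
        )
    for li, level in enumerate(design.levels):
        for pi, p in enumerate(design.proportions):
            xa, xb = level * p, level * (1.0 - p)
            Ca = xa * (1.0 - np.exp(-kd_a * times))
            Cb = xb * (1.0 - np.exp(-kd_b * times))
            D = isobole_damage(
                Ca, Cb, *design.potency, design.isobole_exponent
            )
            curve = _survival_curve_from_damage(times, D, design.td_truth)
            counts = simulate_survivors(curve, design.n0, rng)
            exposures = tuple(
                ExposureProfile(s, x)
                for s, x in ((sub_a, xa), (sub_b, xb))
                if x > 0
            )
            series.append(
                SurvivalTimeSeries(
                    series_id=f"L{li + 1}_p{int(round(100 * p))}",
                    study_id=design.pattern,
                    times=times,
                    n_surviving=counts,
                    exposures=exposures,
                )
            )
    return MixtureDataset(series=series, substances=design.substances)


def write_truth_sidecar(design: ArtificialDesign, path) -> None:
    """Record the generating parameters next to an emitted survival table."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(design.truth_document(), fh, sort_keys=False)


def expected_survival_curve(
    design: ArtificialDesign, level: float, proportion: float
) -> SurvivalCurve:
    """Noise-free survival curve of one design cell (for oracle checks)."""
    times = np.asarray(design.times, dtype=float)
    xa, xb = level * proportion, level * (1.0 - proportion)
    Ca = xa * (1.0 - np.exp(-design.kd[0] * times))
    Cb = xb * (1.0 - np.exp(-design.kd[1] * times))
    D = isobole_damage(Ca, Cb, *design.potency, design.isobole_exponent)
    return _survival_curve_from_damage(times, D, design.td_truth)


def generate_guts_dataset(
    tk: TKParams,
    spec: BridgeSpec,
    td: TDParams,
    exposures: Sequence[dict],
    times: Sequence[float] = DEFAULT_TIMES,
    n0: int = 10,
    seed: int = 0,
    include_control: bool = True,
    substances: tuple[str, ...] | None = None,
) -> MixtureDataset:
    """Forward-simulate survival data through the package's own model chain.

    ``exposures`` is a list of {substance: concentration} mappings, one
    series per entry. Damage flows through the given bridge spec and the
    GUTS-IT survival model; counts come from sequential conditional
    binomials.
    """
    rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    if substances is None:
        subs: list[str] = []
        for e in exposures:
            for s in e:
                if s not in subs:
                    subs.append(s)
        substances = tuple(subs)
    if len(substances) != spec.n_substances:
        raise DomainError(
            "bridge spec width does not match the number of substances"
        )
    # refine the grid so non-monotone bridges are maximized adequately
    grid = np.unique(np.concatenate(
        [times, np.arange(0.0, times.max() + 0.5, 1.0)]
    ))
    tidx = np.searchsorted(grid, times)
    series = []
    if include_control:
        curve = _survival_curve_from_damage(
            times, np.zeros_like(times), td
        )
        series.append(
            SurvivalTimeSeries(
                series_id="control",
                study_id="simulated",
                times=times,
                n_surviving=simulate_survivors(curve, n0, rng),
                exposures=(),
            )
        )
    for k, exposure in enumerate(exposures):
        C = np.column_stack(
            [
                exposure.get(s, 0.0)
                * (1.0 - np.exp(-tk.kd.get(s, 1.0) * grid))
                for s in substances
            ]
        )
        damage = evaluate_bridge(spec, grid, C)
        dmax = effective_running_max(grid, damage.values)
        curve_grid = np.exp(
            -td.hb * grid + log_threshold_factor(dmax, td.alpha, td.beta)
        )
        curve = SurvivalCurve(times, curve_grid[tidx])
        series.append(
            SurvivalTimeSeries(
                series_id=f"s{k + 1}",
                study_id="simulated",
                times=times,
                n_surviving=simulate_survivors(curve, n0, rng),
                exposures=tuple(
                    ExposureProfile(s, c) for s, c in exposure.items() if c > 0
                ),
            )
        )
    return MixtureDataset(series=series, substances=substances)
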