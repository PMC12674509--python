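"""One-compartment toxicokinetics.

For each substance i the scaled internal concentration C_i(t) follows

    dC_i/dt = kd_i * (X_i(t) - C_i(t)),

with X_i the (constant) water concentration and kd_i the dominant
toxicokinetic rate constant. Because exposure is constant over time the
solver uses the exponential closed form

    C(t) = X + (c0 - X) * exp(-kd * (t - t0)),

which is exact; an adaptive Runge-Kutta fallback is retained for future
time-variable exposure and doubles as the test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp

from .data_model import ExposureProfile, SurvivalTimeSeries
from .errors import ConfigurationError, DomainError


@dataclass(frozen=True)
class TKParams:
    """Per-substance dominant rate constants kd (per hour), all > 0."""

    kd: Mapping[str, float]

    def __post_init__(self):
        for sub, k in self.kd.items():
            if not np.isfinite(k) or k <= 0:
                raise DomainError(f"kd for {sub!r} must be > 0, got {k}")


@dataclass
class ConcentrationTrajectory:
    substance_id: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise DomainError("times and values must have the same shape")


def _check_grid(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise DomainError("time grid must be a non-empty 1-D array")
    if times[0] < 0 or np.any(np.diff(times) <= 0):
        raise DomainError("time grid must be non-negative, strictly increasing")
    return times


def solve_internal_concentration(
    exposure: ExposureProfile,
    kd: float,
    times,
    c0: float = 0.0,
) -> ConcentrationTrajectory:
    """Exact solution of the one-compartment TK ODE on a time grid.

    The trajectory approaches the water concentration monotonically and is
    bounded between ``c0`` and the exposure concentration.
    """
    times = _check_grid(times)
    if not np.isfinite(kd) or kd <= 0:
        raise DomainError(f"kd must be > 0, got {kd}")
    X = exposure.concentration
    values = X + (c0 - X) * np.exp(-kd * (times - times[0]))
    return ConcentrationTrajectory(exposure.substance_id, times, values)


def solve_internal_concentration_numeric(
    exposure: ExposureProfile,
    kd: float,
    times,
    c0: float = 0.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> ConcentrationTrajectory:
    """Adaptive Runge-Kutta integration of the TK ODE (reference solver)."""
    times = _check_grid(times)
    if kd <= 0:
        raise DomainError(f"kd must be > 0, got {kd}")
    X = exposure.concentration

    def rhs(t, c):
        return kd * (X - c)

    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        [c0],
        t_eval=times,
        rtol=rtol,
        atol=atol,
        method="RK45",
    )
    if not sol.success:  # pragma: no cover - defensive
        raise DomainError(f"ODE integration failed: {sol.message}")
    return ConcentrationTrajectory(exposure.substance_id, times, sol.y[0])


def solve_mixture_tk(
    series: SurvivalTimeSeries,
    params: TKParams,
    times,
    substances: tuple[str, ...] | None = None,
) -> list[ConcentrationTrajectory]:
    """Solve the TK ODE for every registered substance of a series.

    Substances absent from the series (concentration 0) yield all-zero
    trajectories; an exposed substance without a kd entry is a
    configuration error.
    """
    times = _check_grid(times)
    if substances is None:
        substances = tuple(e.substance_id for e in series.exposures)
    out = []
    for sub in substances:
        conc = series.concentration_of(sub)
        if conc > 0 and sub not in params.kd:
            raise ConfigurationError(
                f"no kd for exposed substance {sub!r} in series "
                f"{series.series_id!r}"
            )
        if conc == 0:
            out.append(
                ConcentrationTrajectory(sub, times, np.zeros_like(times))
            )
        else:
            out.append(
                solve_internal_concentration(
                    ExposureProfile(sub, conc), params.kd[sub], times
                )
            )
    return out


def internal_concentration_matrix(
    X: np.ndarray, kd: np.ndarray, times: np.ndarray
) -> np.ndarray:
    """Batched closed-form TK for constant exposures, c0 = 0.

    X: (..., n) constant exposures; kd: (..., n) rates broadcastable
    against X; times: (T,). Returns C of shape (..., T, n).
    """
    times = np.asarray(times, dtype=float)
    X = np.asarray(X, dtype=float)
    kd = np.asarray(kd, dtype=float)
    decay = np.exp(-kd[..., None, :] * times[:, None])  # (..., T, n)
    return X[..., None, :] * (1.0 - decay)
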