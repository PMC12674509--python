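"""Core domain types: exposure profiles, survival time series, data sets, run configuration.

The package models standard acute fish toxicity designs (OECD 203 style):
organisms are exposed to a constant water concentration of one or more
active ingredients and the number of survivors is recorded at a small set
of observation times (typically daily over 96 h).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError

#: Bridge labels supported for calibration (optionally suffixed "_split").
BRIDGE_LABELS = (
    "n",
    "n_exp",
    "nn_n_exp",
    "nn_ReLU_n_exp",
    "nn_ReLU_nn_ReLU_n_exp",
    "nn_ReLU_nn_ReLU_nn_ReLU_n_exp",
)

#: Labels accepted by RunConfig / the CLI, including split variants.
MODEL_LABELS = BRIDGE_LABELS + tuple(
    lab + "_split" for lab in BRIDGE_LABELS if lab != "n"
)


def split_label(model_label: str) -> tuple[str, bool]:
    """Split an optional ``_split`` suffix off a model label.

    Returns ``(base_label, is_split)`` and validates the base label.
    """
    if model_label.endswith("_split"):
        base, is_split = model_label[: -len("_split")], True
    else:
        base, is_split = model_label, False
    if base not in BRIDGE_LABELS:
        raise ConfigurationError(f"unknown bridge label: {model_label!r}")
    if is_split and base == "n":
        raise ConfigurationError(
            "split-alpha requires an exponential-output bridge; "
            "label 'n' cannot guarantee a positive effective alpha"
        )
    return base, is_split


@dataclass(frozen=True)
class ExposureProfile:
    """Constant water exposure of one substance.

    Exposure concentrations are constant over time, matching the
    constant-exposure acute test design the package targets.
    """

    substance_id: str
    concentration: float

    def __post_init__(self):
        if not self.substance_id:
            raise ValidationError("substance_id must be non-empty")
        if not np.isfinite(self.concentration) or self.concentration < 0:
            raise ValidationError(
                f"concentration for {self.substance_id!r} must be finite "
                f"and >= 0, got {self.concentration}"
            )


@dataclass
class SurvivalTimeSeries:
    """One survival time series under a fixed (possibly mixed) exposure.

    ``times`` are hours since exposure start (first element 0, strictly
    increasing); ``n_surviving`` are the survivor counts observed at those
    times and must be non-increasing. ``exposures`` carries one
    ExposureProfile per substance present; substances absent from the
    mapping are implicitly at concentration 0.
    """

    series_id: str
    study_id: str
    times: np.ndarray
    n_surviving: np.ndarray
    exposures: tuple[ExposureProfile, ...]

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.n_surviving = np.asarray(self.n_surviving, dtype=int)
        if self.times.ndim != 1 or self.times.size == 0:
            raise ValidationError(f"series {self.series_id!r}: empty time grid")
        if len(self.times) != len(self.n_surviving):
            raise ValidationError(
                f"series {self.series_id!r}: times and n_surviving lengths differ"
            )
        if self.times[0] < 0 or np.any(np.diff(self.times) <= 0):
            raise ValidationError(
                f"series {self.series_id!r}: times must be non-negative and "
                "strictly increasing"
            )
        if np.any(self.n_surviving < 0):
            raise ValidationError(
                f"series {self.series_id!r}: negative survivor count"
            )
        if np.any(np.diff(self.n_surviving) > 0):
            raise ValidationError(
                f"series {self.series_id!r}: survivor counts increase over time"
            )
        if self.n_surviving[0] < 1:
            raise ValidationError(
                f"series {self.series_id!r}: initial count must be >= 1"
            )
        ids = [e.substance_id for e in self.exposures]
        if len(set(ids)) != len(ids):
            raise ValidationError(
                f"series {self.series_id!r}: duplicate substance in exposures"
            )
        self.exposures = tuple(self.exposures)

    @property
    def n0(self) -> int:
        return int(self.n_surviving[0])

    def concentration_of(self, substance_id: str) -> float:
        for e in self.exposures:
            if e.substance_id == substance_id:
                return e.concentration
        return 0.0

    @property
    def mixture_key(self) -> frozenset[str]:
        """Set of substances actually present (concentration > 0)."""
        return frozenset(
            e.substance_id for e in self.exposures if e.concentration > 0
        )


@dataclass
class MixtureDataset:
    """A collection of survival time series over a registry of substances."""

    series: list[SurvivalTimeSeries]
    substances: tuple[str, ...]

    def __post_init__(self):
        self.substances = tuple(self.substances)
        if len(set(self.substances)) != len(self.substances):
            raise ValidationError("duplicate substance in registry")
        registry = set(self.substances)
        for s in self.series:
            unknown = {e.substance_id for e in s.exposures} - registry
            if unknown:
                raise ValidationError(
                    f"series {s.series_id!r}: substances {sorted(unknown)} "
                    "not in the dataset registry"
                )
        ids = [s.series_id for s in self.series]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate series_id in dataset")

    def __len__(self) -> int:
        return len(self.series)

    @property
    def n_observations(self) -> int:
        """Total number of survival data points across all series."""
        return int(sum(len(s.times) for s in self.series))

    def mixture_keys(self) -> dict[str, frozenset[str]]:
        return {s.series_id: s.mixture_key for s in self.series}

    def exposure_matrix(self) -> np.ndarray:
        """(n_series, n_substances) matrix of constant concentrations."""
        X = np.zeros((len(self.series), len(self.substances)))
        for i, s in enumerate(self.series):
            for j, sub in enumerate(self.substances):
                X[i, j] = s.concentration_of(sub)
        return X

    def subset(self, series_ids: Sequence[str]) -> "MixtureDataset":
        keep = set(series_ids)
        return MixtureDataset(
            series=[s for s in self.series if s.series_id in keep],
            substances=self.substances,
        )

    def restricted(self, substances: Sequence[str]) -> "MixtureDataset":
        """Sub-dataset of series whose active substances all lie in ``substances``.

        The registry is narrowed accordingly; useful for extracting the
        single-substance (plus control) portion used by marginal fits.
        """
        keep = tuple(substances)
        keep_set = set(keep)
        series = []
        for s in self.series:
            if s.mixture_key <= keep_set:
                series.append(
                    SurvivalTimeSeries(
                        series_id=s.series_id,
                        study_id=s.study_id,
                        times=s.times,
                        n_surviving=s.n_surviving,
                        exposures=tuple(
                            e for e in s.exposures
                            if e.substance_id in keep_set
                        ),
                    )
                )
        return MixtureDataset(series=series, substances=keep)

    def control_series(self) -> list[SurvivalTimeSeries]:
        """Series with no substance present (all concentrations 0)."""
        return [s for s in self.series if not s.mixture_key]


@dataclass
class RunConfig:
    """MCMC run configuration.

    Defaults follow the reference calibration protocol: three chains of
    7500 iterations each, the first 5000 discarded as warm-up.
    """

    model_label: str
    chains: int = 3
    iterations: int = 7500
    warmup: int = 5000
    seed: int = 0
    prior_overrides: Mapping[str, tuple] = field(default_factory=dict)

    def __post_init__(self):
        split_label(self.model_label)  # validates
        if self.chains < 1:
            raise ConfigurationError("chains must be >= 1")
        if self.iterations < 1 or not (0 < self.warmup < self.iterations):
            raise ConfigurationError("need 0 < warmup < iterations")
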