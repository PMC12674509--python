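"""Readers and writers for the package's delimited-text formats.

Canonical survival-table layout (long in observations, wide in substances):

    series_id,study_id,time_h,n_surviving,conc_<substanceA>,conc_<substanceB>,...

one row per observation, comma-separated, "." decimal, UTF-8, header row
mandatory. Concentrations are constant within a series; absent substance
columns mean concentration 0.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .data_model import (
    ExposureProfile,
    MixtureDataset,
    RunConfig,
    SurvivalTimeSeries,
)
from .errors import FormatError, ValidationError

_REQUIRED = ("series_id", "study_id", "time_h", "n_surviving")
_CONC_PREFIX = "conc_"


def read_survival_table(path, format: str = "csv") -> MixtureDataset:
    """Read a survival table into a validated :class:`MixtureDataset`.

    Rows are grouped by ``series_id`` and sorted by time; substances are
    registered in column order. Any invariant violation (non-monotone
    survivor counts, negative concentration) raises, with the offending
    series named — no silent row dropping.
    """
    sep = {"csv": ",", "tsv": "\t"}.get(format)
    if sep is None:
        raise FormatError(f"unknown table format {format!r}")
    df = pd.read_csv(path, sep=sep)
    return dataset_from_frame(df)


def dataset_from_frame(df: pd.DataFrame) -> MixtureDataset:
    """Build a MixtureDataset from an in-memory long-format table."""
    for col in _REQUIRED:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    conc_cols = [c for c in df.columns if c.startswith(_CONC_PREFIX)]
    substances = tuple(c[len(_CONC_PREFIX):] for c in conc_cols)
    series = []
    for sid, g in df.groupby("series_id", sort=False):
        g = g.sort_values("time_h")
        study = str(g["study_id"].iloc[0])
        exposures = []
        for sub, col in zip(substances, conc_cols):
            vals = g[col].to_numpy(dtype=float)
            if not np.allclose(vals, vals[0], rtol=0, atol=0):
                raise ValidationError(
                    f"series {sid!r}: concentration of {sub!r} is not "
                    "constant over time"
                )
            if vals[0] > 0:
                exposures.append(ExposureProfile(sub, float(vals[0])))
            elif vals[0] < 0:
                raise ValidationError(
                    f"series {sid!r}: negative concentration for {sub!r}"
                )
        series.append(
            SurvivalTimeSeries(
                series_id=str(sid),
                study_id=study,
                times=g["time_h"].to_numpy(dtype=float),
                n_surviving=g["n_surviving"].to_numpy(dtype=int),
                exposures=tuple(exposures),
            )
        )
    return MixtureDataset(series=series, substances=substances)


def dataset_to_frame(dataset: MixtureDataset) -> pd.DataFrame:
    rows = []
    for s in dataset.series:
        conc = {
            _CONC_PREFIX + sub: s.concentration_of(sub)
            for sub in dataset.substances
        }
        for t, n in zip(s.times, s.n_surviving):
            rows.append(
                {
                    "series_id": s.series_id,
                    "study_id": s.study_id,
                    "time_h": t,
                    "n_surviving": int(n),
                    **conc,
                }
            )
    cols = list(_REQUIRED) + [_CONC_PREFIX + sub for sub in dataset.substances]
    return pd.DataFrame(rows, columns=cols)


def write_survival_table(dataset: MixtureDataset, path) -> None:
    """Write a dataset; round-trips exactly through :func:`read_survival_table`.

    Counts are written as integers; concentrations and times with 17
    significant digits (lossless for float64).
    """
    df = dataset_to_frame(dataset)
    df.to_csv(path, index=False, float_format="%.17g")


def read_config(path) -> RunConfig:
    """Read a flat key-value run-configuration document (YAML)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise FormatError("config must be a flat key-value mapping")
    return RunConfig(**raw)


def write_config(config: RunConfig, path) -> None:
    doc = {
        "model_label": config.model_label,
        "chains": config.chains,
        "iterations": config.iterations,
        "warmup": config.warmup,
        "seed": config.seed,
    }
    if config.prior_overrides:
        doc["prior_overrides"] = {
            k: list(v) for k, v in config.prior_overrides.items()
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")
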