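import numpy as np
import pytest

from mixguts import (
    BridgeSpec,
    ExposureProfile,
    MixtureDataset,
    RunConfig,
    SurvivalTimeSeries,
    TDParams,
    TKParams,
    run_mcmc,
)
from mixguts.synthetic import generate_guts_dataset


def make_series(series_id="s1", times=(0, 24, 48, 72, 96),
                counts=(10, 10, 9, 7, 7), exposures=(("A", 0.5),)):
    return SurvivalTimeSeries(
        series_id=series_id,
        study_id="study",
        times=np.asarray(times, dtype=float),
        n_surviving=np.asarray(counts, dtype=int),
        exposures=tuple(ExposureProfile(s, c) for s, c in exposures),
    )


@pytest.fixture
def one_series_dataset():
    return MixtureDataset(series=[make_series()], substances=("A",))


@pytest.fixture(scope="session")
def single_substance_dataset():
    """Forward-simulated reduced GUTS-IT data: 6 concentrations + control."""
    spec = BridgeSpec(label="n", n_substances=1,
                      output_coeffs=[1.0], output_bias=0.0)
    levels = np.geomspace(0.374, 2.668, 6)
    return generate_guts_dataset(
        TKParams({"A": 0.3}), spec, TDParams(hb=0.001, alpha=1.0, beta=3.0),
        [{"A": float(c)} for c in levels], seed=42,
    )


@pytest.fixture(scope="session")
def single_substance_fit(single_substance_dataset):
    """One shared reduced-model calibration reused by several test modules."""
    cfg = RunConfig(model_label="n", chains=3, iterations=3000,
                    warmup=1500, seed=7)
    return run_mcmc(single_substance_dataset, cfg,
                    fix_bridge_identity=True, refine_h=2.0)
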