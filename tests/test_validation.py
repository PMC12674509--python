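import numpy as np
import pytest

from mixguts import (
    BridgeSpec,
    MixtureDataset,
    SplitPlan,
    TDParams,
    TKParams,
    generate_guts_dataset,
    leave_pair_out,
    split_random_timepoints,
    split_random_timeseries,
)
from mixguts.errors import UsageError

from conftest import make_series


@pytest.fixture(scope="module")
def three_substance_dataset():
    """All seven mixture groups of three substances: A,B,C,AB,AC,BC,ABC."""
    spec = BridgeSpec(label="n", n_substances=3,
                      output_coeffs=[1.0] * 3, output_bias=0.0)
    tk = TKParams({s: 0.3 for s in "ABC"})
    td = TDParams(hb=0.001, alpha=1.0, beta=3.0)
    groups = [
        {"A": 1.0}, {"B": 1.0}, {"C": 1.0},
        {"A": 0.5, "B": 0.5}, {"A": 0.5, "C": 0.5}, {"B": 0.5, "C": 0.5},
        {"A": 0.4, "B": 0.4, "C": 0.4},
    ]
    exposures = [g for g in groups for _ in range(2)]  # 2 series per group
    return generate_guts_dataset(
        tk, spec, td, exposures, seed=13, substances=("A", "B", "C"),
    )


class TestTimepointSplit:
    def test_exact_fraction_and_partition(self, three_substance_dataset):
        plan = SplitPlan(strategy="random-time-point", seed=5)
        train, val = split_random_timepoints(three_substance_dataset, plan)
        n_total = three_substance_dataset.n_observations
        assert train.n_observations == round(0.9 * n_total)
        assert train.n_observations + len(val) == n_total

    def test_anchors_never_held_out(self, three_substance_dataset):
        plan = SplitPlan(strategy="random-time-point", seed=5)
        _, val = split_random_timepoints(three_substance_dataset, plan)
        assert (val["time_h"] > 0).all()

    def test_deterministic_per_seed(self, three_substance_dataset):
        plan = SplitPlan(strategy="random-time-point", seed=5)
        _, v1 = split_random_timepoints(three_substance_dataset, plan)
        _, v2 = split_random_timepoints(three_substance_dataset, plan)
        assert v1.equals(v2)


class TestTimeseriesSplit:
    def test_nine_one_for_ten_series(self):
        series = [make_series(series_id=f"s{k}") for k in range(10)]
        ds = MixtureDataset(series=series, substances=("A",))
        train, val = split_random_timeseries(ds, SplitPlan(seed=1))
        assert len(train) == 9 and len(val) == 1

    def test_rounding_half_up_on_paper_sized_dataset(self):
        series = [make_series(series_id=f"s{k}") for k in range(244)]
        ds = MixtureDataset(series=series, substances=("A",))
        train, val = split_random_timeseries(ds, SplitPlan(seed=1))
        assert len(train) == 220 and len(val) == 24

    def test_disjoint_and_exhaustive(self, three_substance_dataset):
        train, val = split_random_timeseries(
            three_substance_dataset, SplitPlan(seed=2)
        )
        ids_train = {s.series_id for s in train.series}
        ids_val = {s.series_id for s in val.series}
        assert not ids_train & ids_val
        assert ids_train | ids_val == {
            s.series_id for s in three_substance_dataset.series
        }


class TestLeavePairOut:
    def test_worked_example_exact_pair_only(self, three_substance_dataset):
        train, val = leave_pair_out(three_substance_dataset, ("A", "B"))
        assert all(s.mixture_key == frozenset("AB") for s in val.series)
        train_keys = {frozenset(k) for k in
                      (s.mixture_key for s in train.series)}
        # singles, the other pairs, and the triple all stay in training
        for expect in ["A", "B", "C", "AC", "BC", "ABC"]:
            assert frozenset(expect) in train_keys
        assert frozenset("AB") not in train_keys
        assert len(train) + len(val) == len(three_substance_dataset)

    def test_relabelled_pair(self, three_substance_dataset):
        _, val = leave_pair_out(three_substance_dataset, ("A", "C"))
        assert all(s.mixture_key == frozenset("AC") for s in val.series)

    def test_absent_pair_raises(self, three_substance_dataset):
        ds = three_substance_dataset
        only_singles = ds.subset(
            [s.series_id for s in ds.series if len(s.mixture_key) <= 1]
        )
        with pytest.raises(UsageError):
            leave_pair_out(only_singles, ("A", "B"))


def test_prediction_surface_experiment_properties():
    """Mean-survival surfaces: certain survival at t=0, monotone decay
    along concentration rays for the additive bridge, widths in [0,1]."""
    from mixguts import (
        ArtificialDesign,
        RunConfig,
        generate_artificial_mixture,
        prediction_surface_experiment,
    )
    from mixguts.bayes import run_mcmc

    data = generate_artificial_mixture(
        ArtificialDesign(pattern="additive", seed=6)
    )
    cfg = RunConfig(model_label="n", chains=2, iterations=600, warmup=300,
                    seed=9)
    samples = run_mcmc(data, cfg, refine_h=4.0)
    grid = {"A": np.linspace(0, 2.0, 9), "B": np.linspace(0, 2.0, 9)}
    out = prediction_surface_experiment(
        samples, ("A", "B"), grid, times=[0.0, 48.0, 96.0], max_draws=100
    )
    surf = out["surface"]
    np.testing.assert_allclose(surf.mean[:, 0], 1.0)
    np.testing.assert_allclose(surf.width[:, 0], 0.0, atol=1e-12)
    assert np.all((surf.width >= 0) & (surf.width <= 1))
    means = surf.mean[:, 2].reshape(9, 9)
    assert np.all(np.diff(means, axis=0) <= 1e-6)  # more A, less survival
    assert np.all(np.diff(means, axis=1) <= 1e-6)
    curve = out["isoclines"][96.0][0.5]
    assert curve.size  # the 50% isocline crosses the tested range


def test_timeseries_cv_scores_below_timepoint_cv():
    """Whole-series validation yields lower mean NRMSE than time-point
    validation (its held-out sets include the exactly-predicted t=0
    anchors); asserted on the mean over three generation seeds."""
    from mixguts import ArtificialDesign, RunConfig, cross_validate, generate_artificial_mixture

    tp, ts = [], []
    for seed in (1, 2, 3):
        data = generate_artificial_mixture(
            ArtificialDesign(pattern="additive", seed=seed)
        )
        cfg = RunConfig(model_label="n", chains=2, iterations=800,
                        warmup=400, seed=seed)
        for strategy, acc in (("random-time-point", tp),
                              ("random-time-series", ts)):
            plan = SplitPlan(strategy=strategy, repeats=2, seed=seed)
            table = cross_validate(data, ["n"], plan, cfg)
            acc.extend(table["nrmse"].tolist())
    assert np.mean(ts) < np.mean(tp)


def test_plan_validation():
    with pytest.raises(UsageError):
        SplitPlan(strategy="bogus")
    with pytest.raises(UsageError):
        SplitPlan(train_fraction=1.0)
    with pytest.raises(UsageError):
        SplitPlan(repeats=0)
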