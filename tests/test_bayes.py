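from types import SimpleNamespace

import numpy as np
import pytest

from mixguts import (
    MixtureDataset,
    RunConfig,
    build_priors,
    effective_sample_size,
    gelman_rubin,
    posterior_predict,
    run_mcmc,
)
from mixguts.bayes import build_layout, pooled_control_mortality_rate
from mixguts.errors import UsageError

from conftest import make_series


def fake_samples(draws):
    """Minimal stand-in carrying chains x draws x 1 parameter ('x')."""
    draws = np.asarray(draws, dtype=float)[:, :, None]
    return SimpleNamespace(draws=draws, layout=SimpleNamespace(names=("x",)))


class TestPriors:
    def test_parameter_enumeration_linear_model(self, one_series_dataset):
        ds = MixtureDataset(
            series=[make_series(exposures=(("A", 0.5), ("B", 0.2)))],
            substances=("A", "B"),
        )
        priors = build_priors("n", ds)
        assert set(priors.priors) == {
            "kd_A", "kd_B", "a_1", "a_2", "b", "hb", "alpha", "beta"
        }

    def test_nn_weights_get_half_sd_normals(self):
        ds = MixtureDataset(
            series=[make_series(exposures=(("A", 0.5), ("B", 0.2)))],
            substances=("A", "B"),
        )
        priors = build_priors("nn_ReLU_n_exp", ds)
        nn_names = [n for n in priors.priors
                    if n[0] in "Wab" and n not in ("alpha", "beta")]
        assert len(nn_names) == 8  # W1 (4) + b1 (2) + output coeffs (2)
        for n in ["W1_1_1", "W1_2_2", "b1_1", "a_1", "a_2"]:
            assert priors.priors[n] == ("normal", 0.0, 0.5)
        assert priors.priors["beta"] == (
            "uniform", pytest.approx(np.log(1e-2)), pytest.approx(np.log(1e2))
        )

    def test_control_with_no_deaths_uses_pseudocount_rate(self):
        ds = MixtureDataset(
            series=[make_series(counts=(10,) * 5, exposures=())],
            substances=("A",),
        )
        # half a death over 10 fish x 96 h of exposure
        expected = 0.5 / (10 * 96)
        assert pooled_control_mortality_rate(ds) == pytest.approx(expected)
        priors = build_priors("n", ds)
        assert priors.priors["hb"] == ("normal",
                                       pytest.approx(np.log(expected)), 1.0)

    def test_no_control_series_floors_hb(self):
        ds = MixtureDataset(series=[make_series()], substances=("A",))
        assert pooled_control_mortality_rate(ds) == 1e-5

    def test_informed_priors_centre_on_estimates(self, one_series_dataset):
        priors = build_priors(
            "n", one_series_dataset,
            single_substance_estimates={"A": {"kd": 0.25, "alpha": 2.0}},
        )
        assert priors.priors["kd_A"] == ("normal",
                                         pytest.approx(np.log(0.25)), 0.5)
        assert priors.priors["alpha"][1] == pytest.approx(0.0)  # pooled default

    def test_split_layout_has_marginal_alphas(self):
        layout = build_layout("nn_ReLU_n_exp_split", ("A", "B"))
        assert "alpha_A" in layout.names and "alpha_B" in layout.names
        assert "alpha" not in layout.names


class TestDiagnostics:
    def test_identical_stationary_chains_near_one(self):
        rng = np.random.default_rng(0)
        chain = rng.standard_normal(4000)
        s = fake_samples([chain, chain])
        assert gelman_rubin(s)["x"] == pytest.approx(1.0, abs=2e-3)

    def test_iid_chains_converged_and_full_ess(self):
        rng = np.random.default_rng(1)
        s = fake_samples(rng.standard_normal((3, 2000)))
        assert gelman_rubin(s)["x"] < 1.01
        ess = effective_sample_size(s)["x"]
        assert ess == pytest.approx(6000, rel=0.15)

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.0, 0.05, 1000)
        b = rng.normal(10.0, 0.05, 1000)
        # rank-normalized split R-hat saturates below the classic statistic
        # but must flag the divergence far beyond the 1.05 contract
        assert gelman_rubin(fake_samples([a, b]))["x"] > 1.5

    def test_ar1_ess_ratio(self):
        rng = np.random.default_rng(3)
        chains = []
        for _ in range(2):
            eps = rng.standard_normal(20_000)
            x = np.empty_like(eps)
            x[0] = eps[0]
            for t in range(1, len(eps)):
                x[t] = 0.9 * x[t - 1] + eps[t]
            chains.append(x)
        ess = effective_sample_size(fake_samples(chains))["x"]
        expected = 40_000 * (1 - 0.9) / (1 + 0.9)
        assert ess == pytest.approx(expected, rel=0.3)

    def test_single_chain_rejected(self):
        s = fake_samples(np.zeros((1, 100)))
        with pytest.raises(UsageError):
            gelman_rubin(s)
        with pytest.raises(UsageError):
            effective_sample_size(s)


class TestRunMcmc:
    def test_reproducible_draws(self, single_substance_dataset):
        cfg = RunConfig(model_label="n", chains=2, iterations=300,
                        warmup=150, seed=11)
        a = run_mcmc(single_substance_dataset, cfg,
                     fix_bridge_identity=True, refine_h=4.0)
        b = run_mcmc(single_substance_dataset, cfg,
                     fix_bridge_identity=True, refine_h=4.0)
        np.testing.assert_array_equal(a.draws, b.draws)
        assert a.draws.shape == (2, 150, 4)

    def test_degenerate_all_alive_concentrates_hb_near_zero(self):
        series = [
            make_series(series_id=f"c{k}", counts=(10,) * 5, exposures=())
            for k in range(5)
        ]
        ds = MixtureDataset(series=series, substances=("A",))
        cfg = RunConfig(model_label="n", chains=2, iterations=800,
                        warmup=400, seed=3)
        samples = run_mcmc(ds, cfg, fix_bridge_identity=True, refine_h=4.0)
        hb = samples.natural_draws()["hb"]
        assert np.quantile(hb, 0.95) < 0.01

    def test_diagnostics_contract_on_packaged_example(
        self, single_substance_fit
    ):
        rhat = gelman_rubin(single_substance_fit)
        ess = effective_sample_size(single_substance_fit)
        assert max(rhat.values()) < 1.05
        assert min(ess.values()) > 400

    def test_posterior_predict_surface_properties(self, single_substance_fit):
        surf = posterior_predict(
            single_substance_fit, {"A": 1.0}, [0.0, 24.0, 96.0]
        )
        assert surf.mean[0, 0] == pytest.approx(1.0)
        assert surf.width[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diff(surf.mean[0]) <= 1e-9)
        assert np.all(surf.lower <= surf.mean + 1e-12)
        assert np.all(surf.mean <= surf.upper + 1e-12)
        assert np.all((surf.width >= 0) & (surf.width <= 1))
        with pytest.raises(UsageError):
            posterior_predict(single_substance_fit, {"Z": 1.0}, [0.0, 24.0])

    def test_split_alpha_variant_calibrates(self):
        from mixguts import ArtificialDesign, generate_artificial_mixture

        data = generate_artificial_mixture(
            ArtificialDesign(pattern="additive", seed=8)
        )
        cfg = RunConfig(model_label="n_exp_split", chains=2, iterations=500,
                        warmup=250, seed=4)
        samples = run_mcmc(data, cfg, refine_h=4.0)
        names = samples.parameter_names
        assert "alpha_A" in names and "alpha_B" in names
        assert "alpha" not in names
        marg = samples.natural_draws()
        assert np.all(marg["alpha_A"] > 0) and np.all(marg["alpha_B"] > 0)
        surf = posterior_predict(samples, {"A": 0.5, "B": 0.5},
                                 [0.0, 48.0, 96.0], max_draws=100)
        assert np.all(np.diff(surf.mean[0]) <= 1e-9)

    def test_long_frame_export_shape(self, single_substance_fit):
        df = single_substance_fit.to_long_frame()
        chains, n_draws, d = single_substance_fit.draws.shape
        assert len(df) == chains * n_draws * d
        assert set(df.columns) == {"chain", "iteration", "parameter", "value"}
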