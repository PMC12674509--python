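import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mixguts import (
    BridgeSpec,
    SurvivalCurve,
    TDParams,
    conditional_binomial_loglik,
    evaluate_bridge,
    simulate_survivors,
    survival_probability,
)
from mixguts.bridge import DamageTrajectory
from mixguts.errors import DomainError, ValidationError

from conftest import make_series


def constant_damage(value, times=(0.0, 24.0, 48.0, 72.0, 96.0)):
    vals = np.full(len(times), float(value))
    return DamageTrajectory.from_values(np.asarray(times), vals)


class TestSurvivalProbability:
    def test_median_threshold_gives_half(self):
        td = TDParams(hb=0.0, alpha=2.0, beta=3.0)
        curve = survival_probability(constant_damage(2.0), td)
        assert curve.s[0] == pytest.approx(1.0)  # D(0) excluded
        np.testing.assert_allclose(curve.s[1:], 0.5)

    def test_background_only(self):
        td = TDParams(hb=0.01, alpha=1.0, beta=2.0)
        curve = survival_probability(constant_damage(0.0), td)
        assert curve.s[-1] == pytest.approx(np.exp(-0.96), rel=1e-12)
        assert curve.s[-1] == pytest.approx(0.38289, abs=1e-5)

    def test_steep_shape_is_step_function(self):
        sharp = TDParams(hb=0.0, alpha=1.0, beta=400.0)
        below = survival_probability(constant_damage(0.9), sharp)
        above = survival_probability(constant_damage(1.1), sharp)
        assert below.s[-1] == pytest.approx(1.0, abs=1e-10)
        assert above.s[-1] == pytest.approx(0.0, abs=1e-10)

    def test_negative_damage_clamped_to_no_effect(self):
        td = TDParams(hb=0.0, alpha=1.0, beta=3.0)
        curve = survival_probability(constant_damage(-2.0), td)
        np.testing.assert_allclose(curve.s, 1.0)

    def test_parameter_domain(self):
        with pytest.raises(DomainError):
            TDParams(hb=0.0, alpha=-1.0, beta=2.0)
        with pytest.raises(DomainError):
            TDParams(hb=0.0, alpha=1.0, beta=0.0)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        dmax=st.floats(0.0, 20.0),
        alpha=st.floats(0.1, 10.0),
        beta=st.floats(0.1, 20.0),
        hb=st.floats(0.0, 0.05),
    )
    def test_monotonicity_properties(self, dmax, alpha, beta, hb):
        times = np.array([0.0, 24.0, 48.0, 96.0])
        td = TDParams(hb=hb, alpha=alpha, beta=beta)
        s = survival_probability(constant_damage(dmax, times), td).s
        assert np.all(np.diff(s) <= 1e-12)  # non-increasing in time
        assert np.all((0 <= s) & (s <= 1))
        # decreasing in damage, increasing in alpha
        s_hi = survival_probability(constant_damage(dmax + 1, times), td).s
        assert np.all(s_hi <= s + 1e-12)
        td_hi = TDParams(hb=hb, alpha=alpha * 2, beta=beta)
        s_a = survival_probability(constant_damage(dmax, times), td_hi).s
        assert np.all(s_a >= s - 1e-12)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_composition_matches_reduced_guts_brute_force(self, seed):
        """TK -> identity bridge -> TD equals direct reduced GUTS-IT."""
        rng = np.random.default_rng(seed)
        kd = rng.uniform(0.01, 1.0)
        conc = rng.uniform(0.1, 5.0)
        td = TDParams(hb=rng.uniform(0, 0.01), alpha=rng.uniform(0.2, 5.0),
                      beta=rng.uniform(0.5, 10.0))
        times = np.linspace(0.0, 96.0, 9)
        C = (conc * (1 - np.exp(-kd * times)))[:, None]
        spec = BridgeSpec(label="n", n_substances=1,
                          output_coeffs=[1.0], output_bias=0.0)
        s_pkg = survival_probability(evaluate_bridge(spec, times, C), td).s
        # independent brute force: monotone C, so Dmax(t) = C(t) for t > 0
        s_ref = np.exp(-td.hb * times) / (
            1.0 + (C[:, 0] / td.alpha) ** td.beta
        )
        s_ref[0] = 1.0
        np.testing.assert_allclose(s_pkg, s_ref, rtol=1e-10)


class TestConditionalBinomial:
    def test_certain_survival_gives_zero(self):
        series = make_series(counts=(10, 10, 10, 10, 10))
        curve = SurvivalCurve(series.times, np.ones(5))
        total, pointwise = conditional_binomial_loglik(series, curve)
        assert total == 0.0 and np.all(pointwise == 0.0)

    def test_hand_computed_binomial(self):
        series = make_series(times=(0.0, 24.0), counts=(10, 5))
        curve = SurvivalCurve(series.times, np.array([1.0, 0.5]))
        total, _ = conditional_binomial_loglik(series, curve)
        assert total == pytest.approx(np.log(252 * 0.5**10), rel=1e-12)
        assert total == pytest.approx(-1.4020, abs=1e-4)

    def test_pointwise_terms_sum_to_total(self):
        series = make_series()
        s = np.array([1.0, 0.95, 0.8, 0.6, 0.55])
        total, pointwise = conditional_binomial_loglik(
            series, SurvivalCurve(series.times, s)
        )
        assert total == pytest.approx(pointwise.sum(), rel=1e-15)

    def test_telescoping_under_inserted_observation(self):
        series = make_series(times=(0, 24, 96), counts=(10, 8, 8))
        s3 = np.array([1.0, 0.8, 0.7])
        t1, _ = conditional_binomial_loglik(
            series, SurvivalCurve(series.times, s3)
        )
        # insert an extra time with no deaths and interpolated survival s
        series4 = make_series(times=(0, 24, 48, 96), counts=(10, 8, 8, 8))
        s4 = np.array([1.0, 0.8, 0.75, 0.7])
        t2, _ = conditional_binomial_loglik(
            series4, SurvivalCurve(series4.times, s4)
        )
        assert t2 == pytest.approx(t1, rel=1e-12)

    def test_ratio_above_one_raises(self):
        series = make_series(times=(0.0, 24.0), counts=(10, 10))
        with pytest.raises(DomainError):
            conditional_binomial_loglik(
                series, SurvivalCurve(series.times, np.array([0.5, 0.8]))
            )


class TestSimulateSurvivors:
    def test_certain_survival_and_absorbing_death(self):
        times = np.arange(0.0, 5.0)
        ones = SurvivalCurve(times, np.ones(5))
        assert np.all(simulate_survivors(ones, 10, seed=0) == 10)
        dead = SurvivalCurve(times, np.array([1.0, 0.5, 0.2, 0.05, 0.0]))
        out = simulate_survivors(dead, 10, seed=0)
        assert out[-1] == 0 and np.all(np.diff(out) <= 0)

    def test_reproducible_and_unbiased(self):
        times = np.array([0.0, 96.0])
        curve = SurvivalCurve(times, np.array([1.0, 0.4]))
        a = simulate_survivors(curve, 10, seed=123)
        b = simulate_survivors(curve, 10, seed=123)
        np.testing.assert_array_equal(a, b)
        rng = np.random.default_rng(7)
        finals = [simulate_survivors(curve, 10, rng)[-1]
                  for _ in range(10_000)]
        assert np.mean(finals) == pytest.approx(4.0, abs=0.05)
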