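"""One-way tornado analysis and Monte Carlo PSA behaviour."""

import numpy as np
import pandas as pd
import pytest

from glaucoma_ce.markov import DiseaseState, Strategy
from glaucoma_ce.sensitivity import (
    PSAConfig,
    _beta_params,
    _draw,
    _gamma_params,
    _param_rng,
    ceac,
    dsa_frame,
    one_way_dsa,
    parameter_values,
    psa,
)

M = DiseaseState.MODERATE


@pytest.fixture(scope="module")
def effect_model(base_model):
    return base_model


@pytest.fixture(scope="module")
def null_model(base_model):
    """Zero-effect strategy and free reference surgery: increments reduce to
    the discounted one-off intervention cost."""
    null = Strategy(name="null", extra_iop_reduction=0.0, intervention_cost=638.42)
    return base_model.with_inputs(strategies=[null], reference_cost=0.0)


class TestMomentMatching:
    def test_beta_hand_oracle(self):
        a, b = _beta_params(0.75, 0.23)
        assert a == pytest.approx(1.9083175803402646, abs=1e-12)
        assert b == pytest.approx(0.6361058601134215, abs=1e-12)

    def test_beta_infeasible_sd_shrunk_with_warning(self):
        with pytest.warns(UserWarning, match="shrunk"):
            a, b = _beta_params(0.9, 0.5)
        assert a > 0 and b > 0

    def test_gamma_moments_recovered(self):
        shape, scale = _gamma_params(356.13, 183.41)
        assert shape * scale == pytest.approx(356.13)
        assert np.sqrt(shape) * scale == pytest.approx(183.41)

    @pytest.mark.parametrize(
        "family, mean, sd",
        [("beta", 0.75, 0.1), ("gamma", 300.0, 80.0), ("normal", 2.8, 1.3)],
    )
    def test_draw_means_converge(self, family, mean, sd):
        rng = np.random.default_rng(0)
        x = _draw(family, mean, sd, 20_000, rng)
        assert x.mean() == pytest.approx(mean, abs=3 * sd / np.sqrt(20_000))

    def test_zero_sd_is_degenerate(self):
        x = _draw("beta", 0.75, 0.0, 5, np.random.default_rng(0))
        assert np.all(x == 0.75)


class TestOneWayDSA:
    def test_early_stage_payoffs_do_not_move_the_icer(self, effect_model):
        # the effect only changes occupancy from the moderate stage onward,
        # so early-stage payoffs hit both arms identically
        res = one_way_dsa(effect_model, "two_tmbs", M, parameters=["cost_early", "utility_early"])
        base = effect_model.compare("two_tmbs", M).icer
        for r in res:
            assert r.spread <= 1e-6 * base

    def test_intervention_cost_scales_increment_linearly(self, null_model):
        base = null_model.compare("null", M)
        res = one_way_dsa(null_model, "null", M, parameters=["intervention_cost"])[0]
        # zero effect: inc_qaly = 0, so scenarios are dominated (no ICER) ...
        assert res.low_icer is None and res.high_icer is None
        # ... but the cost increment itself is exactly linear in the one-off cost
        from glaucoma_ce.sensitivity import _apply_overrides

        up = _apply_overrides(null_model, "null", {"intervention_cost": 638.42 * 1.2})
        assert up.compare("null", M).inc_cost == pytest.approx(1.2 * base.inc_cost, rel=1e-9)

    def test_ranked_by_spread_descending(self, effect_model):
        res = one_way_dsa(effect_model, "two_tmbs", M)
        spreads = [r.spread for r in res if not np.isnan(r.spread)]
        assert spreads == sorted(spreads, reverse=True)

    def test_out_of_domain_perturbation_warns(self, effect_model):
        with pytest.warns(UserWarning, match="clamped"):
            one_way_dsa(effect_model, "two_tmbs", M, parameters=["utility_early"])

    def test_frame_has_expected_columns(self, effect_model):
        df = dsa_frame(one_way_dsa(effect_model, "two_tmbs", M, parameters=["cost_moderate"]))
        assert set(df.columns) >= {"parameter", "low_icer", "high_icer", "spread"}


class TestPSA:
    def test_same_seed_bitwise_identical(self, effect_model):
        cfg = PSAConfig(n_iterations=50, seed=7)
        a = psa(effect_model, "two_tmbs", M, cfg).samples
        b = psa(effect_model, "two_tmbs", M, cfg).samples
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self, effect_model):
        a = psa(effect_model, "two_tmbs", M, PSAConfig(n_iterations=20, seed=1)).samples
        b = psa(effect_model, "two_tmbs", M, PSAConfig(n_iterations=20, seed=2)).samples
        assert not np.allclose(a["inc_qaly"], b["inc_qaly"])

    def test_degenerate_distributions_reproduce_deterministic_result(self, effect_model):
        # strip every dispersion: each iteration must equal the base case
        strat = effect_model.strategies["two_tmbs"]
        from dataclasses import replace

        model = effect_model.with_inputs(strategies=[replace(strat, extra_iop_sd=0.0)])
        for st in DiseaseState:
            if st == DiseaseState.DEAD:
                continue
            model = model.with_inputs(payoffs=model.payoffs.replace(st, utility_sd=0.0, annual_cost_sd=0.0))
        cfg = PSAConfig(n_iterations=10, seed=3, transition_sd_fraction=0.0)
        res = psa(model, "two_tmbs", M, cfg)
        det = res.deterministic
        assert np.allclose(res.samples["inc_cost"], det.inc_cost)
        assert np.allclose(res.samples["inc_qaly"], det.inc_qaly)

    def test_parameter_streams_independent_of_registration_order(self):
        # the same name always yields the same stream under one master seed
        a = _param_rng(42, "utility_moderate").random(5)
        b = _param_rng(42, "utility_moderate").random(5)
        c = _param_rng(42, "utility_advanced").random(5)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_fraction_cost_effective_matches_ceac_at_threshold(self, effect_model):
        res = psa(effect_model, "two_tmbs", M, PSAConfig(n_iterations=100, seed=5))
        curve = res.ceac([res.config.wtp_threshold])
        assert res.fraction_cost_effective() == pytest.approx(curve["probability"].iloc[0])


class TestCEAC:
    def samples(self, inc_cost, inc_qaly):
        return pd.DataFrame({"inc_cost": inc_cost, "inc_qaly": inc_qaly})

    def test_zero_threshold_with_positive_costs(self):
        s = self.samples([10.0, 20.0], [0.1, 0.2])
        assert ceac(s, [0.0])["probability"].iloc[0] == 0.0

    def test_huge_threshold_with_positive_gains(self):
        s = self.samples([10.0, 20.0], [0.1, 0.2])
        assert ceac(s, [1e12])["probability"].iloc[0] == 1.0

    def test_probability_half_at_median_icer(self):
        rng = np.random.default_rng(11)
        inc_q = np.full(1001, 0.01)
        inc_c = rng.gamma(5.0, 50.0, size=1001)
        icers = inc_c / inc_q
        s = self.samples(inc_c, inc_q)
        prob = ceac(s, [float(np.median(icers))])["probability"].iloc[0]
        assert prob == pytest.approx(0.5, abs=0.01)

    def test_monotone_when_all_gains_positive(self):
        rng = np.random.default_rng(3)
        s = self.samples(rng.normal(200, 100, 500), rng.uniform(0.001, 0.02, 500))
        grid = np.linspace(0, 100_000, 21)
        probs = ceac(s, grid)["probability"].to_numpy()
        assert np.all(np.diff(probs) >= 0)

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            ceac(self.samples([], []), [0.0])


class TestParameterRegistry:
    def test_base_values_reflect_model_inputs(self, effect_model):
        vals = parameter_values(effect_model, "two_tmbs")
        assert vals["p_progress_moderate"] == pytest.approx(0.124)
        assert vals["utility_blind"] == 0.46
        assert vals["intervention_cost"] == pytest.approx(937.34)
        assert vals["extra_iop_reduction"] == pytest.approx(2.8)
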