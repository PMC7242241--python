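"""Cohort dynamics: probability conversions, transition matrices, traces."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glaucoma_ce.economics import accumulate
from glaucoma_ce.markov import (
    CohortConfig,
    DiseaseState,
    Strategy,
    TransitionModel,
    annual_to_five_year,
    build_transition_matrix,
    five_year_to_annual,
    mixed_mortality,
    progression_multiplier,
    run_cohort,
)

from conftest import constant_mortality_table, microsimulate

E, M, A, B, D = DiseaseState


class TestProbabilityConversion:
    @pytest.mark.parametrize("p5, expected", [(0.0, 0.0), (1.0, 1.0), (0.36, 0.08538989614534731)])
    def test_five_year_to_annual(self, p5, expected):
        assert five_year_to_annual(p5) == pytest.approx(expected, abs=1e-12)

    @given(p=st.floats(min_value=0.0, max_value=0.999))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_round_trip(self, p):
        assert annual_to_five_year(five_year_to_annual(p)) == pytest.approx(p, abs=1e-9)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            five_year_to_annual(1.2)


class TestProgressionMultiplier:
    def test_identity_at_zero_effect(self):
        assert progression_multiplier(0.124, 0.0) == 0.124

    def test_zero_probability_stays_zero(self):
        assert progression_multiplier(0.0, 3.0) == 0.0

    def test_rate_transform_oracle(self):
        # independently derived: r = -ln(1-0.124); r' = r*(1-0.0031)^2.8
        assert progression_multiplier(0.124, 2.8) == pytest.approx(0.12299558580953651, abs=1e-12)

    def test_multiplier_never_raises_probability(self):
        for extra in (0.5, 1.0, 2.8, 5.0):
            assert progression_multiplier(0.2, extra) < 0.2

    def test_linear_mode_clamps_with_warning(self):
        with pytest.warns(UserWarning):
            assert progression_multiplier(0.3, 400.0, mode="linear") == 0.0

    def test_linear_mode_matches_rate_scaling(self):
        p, extra = 0.124, 2.0
        r = -math.log1p(-p)
        expected = 1 - math.exp(-r * (1 - 0.0031 * extra))
        assert progression_multiplier(p, extra, mode="linear") == pytest.approx(expected)


class TestMortality:
    def test_pure_female_cohort(self, life_table):
        assert mixed_mortality(70, 1.0, life_table) == life_table.q(70, "female")

    def test_equal_sexes_mix_invariant(self):
        lt = constant_mortality_table(0.02)
        for frac in (0.0, 0.3, 1.0):
            assert mixed_mortality(70, frac, lt) == pytest.approx(0.02)

    def test_weighted_mean(self):
        lt = constant_mortality_table(0.0)
        lt = lt.__class__(ages=lt.ages, q_female=np.full_like(lt.q_female, 0.01), q_male=np.full_like(lt.q_male, 0.02))
        assert mixed_mortality(70, 0.442, lt) == pytest.approx(0.01558)

    def test_beyond_terminal_age_dies(self, life_table):
        assert mixed_mortality(life_table.terminal_age + 1, 0.5, life_table) == 1.0


class TestTransitionMatrix:
    def test_published_early_row_without_mortality(self, transitions):
        lt = constant_mortality_table(0.0)
        m = build_transition_matrix(70, transitions, lt, CohortConfig())
        assert m[E] == pytest.approx([0.915, 0.085, 0, 0, 0])
        assert m[M] == pytest.approx([0, 0.876, 0.124, 0, 0])
        assert m[A] == pytest.approx([0, 0, 0.814, 0.186, 0])

    def test_zero_progression_zero_mortality_is_identity(self):
        tm = TransitionModel(p_progress={E: 0.0, M: 0.0, A: 0.0})
        m = build_transition_matrix(70, tm, constant_mortality_table(0.0), CohortConfig())
        assert np.allclose(m, np.eye(5))

    def test_certain_death_maps_everything_to_dead(self, transitions):
        m = build_transition_matrix(70, transitions, constant_mortality_table(1.0), CohortConfig())
        assert np.allclose(m[:, D], 1.0)

    def test_rows_stochastic_and_no_backward_flow(self, transitions, life_table):
        m = build_transition_matrix(75, transitions, life_table, CohortConfig())
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(np.tril(m, k=-1), 0.0)  # strictly forward

    def test_strategy_slows_application_stage_and_later(self, transitions, life_table):
        strat = Strategy(name="s", extra_iop_reduction=2.8, application_stage=M)
        base = build_transition_matrix(70, transitions, life_table, CohortConfig())
        treated = build_transition_matrix(70, transitions, life_table, CohortConfig(), strat)
        assert treated[E, M] == base[E, M]  # pre-application stage untouched
        assert treated[M, A] < base[M, A]
        assert treated[A, B] < base[A, B]


class TestCohortTrace:
    def test_single_cycle_matches_matrix_product(self, transitions):
        lt = constant_mortality_table(0.0)
        cfg = CohortConfig(start_age=63, max_age=64)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # horizon capped deliberately
            trace = run_cohort(None, transitions, lt, cfg)
        assert trace.occupancy[1] == pytest.approx([0.915, 0.085, 0, 0, 0])

    def test_certain_death_extinguishes_in_one_cycle(self, transitions):
        trace = run_cohort(None, transitions, constant_mortality_table(1.0), CohortConfig())
        assert trace.occupancy[1, D] == 1.0
        assert trace.n_cycles == 2

    def test_zero_progression_zero_mortality_constant_trace(self):
        tm = TransitionModel(p_progress={E: 0.0, M: 0.0, A: 0.0})
        with pytest.warns(UserWarning, match="capped"):
            trace = run_cohort(None, tm, constant_mortality_table(0.0, terminal_death=False), CohortConfig())
        assert np.all(trace.occupancy[:, E] == 1.0)

    def test_rows_sum_to_one_and_death_monotone(self, transitions, life_table):
        trace = run_cohort(None, transitions, life_table, CohortConfig())
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(np.diff(trace.occupancy[:, D]) >= -1e-12)

    def test_intervention_entry_mass_accounting(self, transitions, life_table):
        strat = Strategy(name="s", extra_iop_reduction=1.0, application_stage=M)
        trace = run_cohort(strat, transitions, life_table, CohortConfig())
        # nobody starts in moderate; total arrivals can never exceed the cohort
        assert trace.entry_fraction[0] == 0.0
        assert 0.0 < trace.entry_fraction.sum() <= 1.0

    def test_zero_coefficient_reproduces_reference_exactly(self, transitions, life_table):
        cfg = CohortConfig()
        null = Strategy(name="null", extra_iop_reduction=2.8, vf_coefficient=0.0)
        ref = run_cohort(None, transitions, life_table, cfg)
        out = run_cohort(null, transitions, life_table, cfg)
        assert np.array_equal(out.occupancy, ref.occupancy)

    def test_qalys_monotone_in_effect(self, transitions, life_table, payoffs):
        cfg = CohortConfig()
        prev = -np.inf
        for extra in np.linspace(0.0, 5.0, 6):
            strat = Strategy(name="s", extra_iop_reduction=float(extra))
            _, qaly = accumulate(run_cohort(strat, transitions, life_table, cfg), payoffs)
            assert qaly >= prev - 1e-12
            prev = qaly

    def test_effect_keeps_cohort_longer_in_pre_advanced_stages(self, transitions, life_table):
        cfg = CohortConfig()
        ref = run_cohort(None, transitions, life_table, cfg)
        strat = Strategy(name="s", extra_iop_reduction=3.0, application_stage=M)
        out = run_cohort(strat, transitions, life_table, cfg)
        n = min(ref.n_cycles, out.n_cycles)
        assert out.occupancy[:n, [E, M]].sum() >= ref.occupancy[:n, [E, M]].sum()

    def test_microsimulation_agrees_with_cohort_trace(self, transitions, life_table):
        cfg = CohortConfig()
        strat = Strategy(name="s", extra_iop_reduction=2.8, application_stage=M)
        trace = run_cohort(strat, transitions, life_table, cfg)
        n_ind = 5000
        micro = microsimulate(strat, transitions, life_table, cfg, n_ind, seed=20190101)
        n = min(len(micro), trace.n_cycles)
        p = trace.occupancy[:n]
        se = np.sqrt(p * (1 - p) / n_ind)
        diff = np.abs(micro[:n] - p)
        # Monte Carlo error: the bulk inside 2 SE, every cell inside 3 SE
        # (deviations are serially correlated along a trajectory)
        assert (diff <= 2 * se + 1e-3).mean() >= 0.90
        assert np.all(diff <= 3 * se + 1e-3)

    def test_discounted_life_years_match_annuity(self, life_table, payoffs):
        # no disease progression: the model is a pure survival annuity
        tm = TransitionModel(p_progress={E: 0.0, M: 0.0, A: 0.0})
        cfg = CohortConfig()
        trace = run_cohort(None, tm, life_table, cfg)
        from glaucoma_ce.economics import PayoffTable, StagePayoff

        unit = PayoffTable(
            [StagePayoff(s, 1.0, 0.0) for s in (E, M, A, B)] + [StagePayoff(D, 0.0, 0.0)]
        )
        _, ly = accumulate(trace, unit, rate=0.03)
        # closed form: sum_t df(t) * S(t) over the life table
        surv, total = 1.0, 0.0
        for t in range(trace.n_cycles):
            df = 1.0 if t == 0 else (1.03) ** (-t)
            total += df * surv
            surv *= 1.0 - mixed_mortality(cfg.start_age + t, cfg.female_fraction, life_table)
        assert ly == pytest.approx(total, abs=1e-9)


class TestTransitionModelValidation:
    def test_pairs_must_sum_to_one(self):
        with pytest.raises(ValueError):
            TransitionModel.from_stay_progress({"early": (0.9, 0.2), "moderate": (0.9, 0.1), "advanced": (0.9, 0.1)})

    def test_fixture_round_trip(self, transitions):
        assert transitions.p_progress[E] == pytest.approx(0.085)
        assert transitions.p_stay(A) == pytest.approx(0.814)
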