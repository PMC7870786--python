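import dataclasses
import math

import numpy as np
import pytest

from psmcea import (
    ModelSettings,
    NGSConfig,
    StrategyConfig,
    SurvivalDistribution,
    adjusted_survival,
    build_trace,
    nns,
    screening_cost,
)
from psmcea.engine import WEEKS_PER_MONTH, WEEKS_PER_YEAR
from psmcea.exceptions import ConfigError, ExtrapolationError, ParameterDomainError
from conftest import random_strategy


EXP_REF = SurvivalDistribution("exponential", {"rate": 0.1})


class TestAdjustedSurvival:
    def test_identity_when_hr_one_and_same_curve(self):
        t = np.linspace(0, 60, 200)
        out = adjusted_survival(EXP_REF, EXP_REF, hr=1.0, cutoff=18.0, t=t)
        np.testing.assert_allclose(out, np.exp(-0.1 * t), rtol=1e-12)

    def test_continuity_at_cutoff(self):
        own = SurvivalDistribution("weibull", {"shape": 1.4, "scale": 12.0})
        below = adjusted_survival(own, EXP_REF, hr=0.5, cutoff=18.0, t=18.0)
        above = adjusted_survival(own, EXP_REF, hr=0.5, cutoff=18.0, t=18.0 + 1e-9)
        assert below == pytest.approx(float(np.exp(-((18.0 / 12.0) ** 1.4))), rel=1e-12)
        assert above == pytest.approx(below, abs=1e-9)

    def test_closed_form_carry_forward(self):
        # own = reference exponential: S(18) * exp(-hr * rate * (t - 18))
        out = adjusted_survival(EXP_REF, EXP_REF, hr=0.34, cutoff=18.0, t=24.0)
        expected = math.exp(-0.1 * 18.0) * math.exp(-0.34 * 0.1 * 6.0)
        assert out == pytest.approx(expected, abs=1e-10)

    def test_zero_reference_survival_raises(self):
        dead = SurvivalDistribution("exponential", {"rate": 50.0})
        with pytest.raises(ExtrapolationError):
            adjusted_survival(EXP_REF, dead, hr=0.5, cutoff=18.0, t=24.0)

    def test_nonpositive_hr_rejected(self):
        with pytest.raises(ParameterDomainError):
            adjusted_survival(EXP_REF, EXP_REF, hr=0.0, cutoff=18.0, t=24.0)


class TestScreening:
    def test_nns_published_prevalence(self):
        assert nns(0.18) == 5.6

    def test_nns_trivial(self):
        assert nns(1.0) == 1.0

    def test_nns_rounding_convention(self):
        assert nns(0.28) == 3.6  # 3.571 -> 3.6

    def test_nns_domain(self):
        with pytest.raises(ParameterDomainError):
            nns(0.0)
        with pytest.raises(ParameterDomainError):
            nns(1.5)

    def test_flat_mode(self):
        assert screening_cost(5800.0, 0.18, "flat") == 5800.0

    def test_per_screened_full_prevalence(self):
        assert screening_cost(5800.0, 1.0, "per_screened") == 5800.0

    def test_per_screened_uses_one_decimal_nns(self):
        assert screening_cost(5800.0, 0.18, "per_screened") == pytest.approx(5800.0 * 5.6)


def _bare_strategy(pfs, os_, **overrides):
    kwargs = dict(
        name="s",
        pfs_model=pfs,
        os_model=os_,
        weekly_drug_cost=0.0,
        p_subsequent_active=0.0,
        subsequent_mix=(),
        subsequent_duration_months=0.0,
        supportive_care_cost_per_day=0.0,
        followup_cost_per_week=0.0,
        terminal_cost=0.0,
    )
    kwargs.update(overrides)
    return StrategyConfig(**kwargs)


class TestBuildTrace:
    def test_partition_identity_random_configs(self):
        rng = np.random.default_rng(17)
        settings = ModelSettings(horizon_weeks=260)
        for _ in range(100):
            strat = random_strategy(rng)
            trace = build_trace(strat, settings)
            np.testing.assert_allclose(
                trace.p_pfd + trace.p_pd + trace.p_dead, 1.0, atol=1e-9
            )
            assert np.all(np.diff(trace.p_dead) >= -1e-12)
            assert np.all(trace.p_pfd >= -1e-12)
            assert np.all(trace.p_pd >= -1e-12)

    def test_totals_equal_column_sums(self):
        rng = np.random.default_rng(23)
        strat = random_strategy(rng)
        trace = build_trace(strat, ModelSettings(horizon_weeks=104))
        assert trace.total_cost == pytest.approx(float(trace.cost.sum()), rel=1e-12)
        assert trace.total_qalys == pytest.approx(float(trace.qaly.sum()), rel=1e-12)

    def test_degenerate_reduction_qalys_equal_lys_equal_auc(self):
        pfs = SurvivalDistribution("exponential", {"rate": 0.2})
        os_ = SurvivalDistribution("exponential", {"rate": 0.1})
        strat = _bare_strategy(pfs, os_)
        settings = ModelSettings(
            horizon_weeks=520, annual_discount=0.0, u_pfd=1.0, u_pd=1.0
        )
        trace = build_trace(strat, settings)
        # independent Riemann AUC of the OS curve over cycle starts
        t_weeks = np.arange(520.0)
        auc = float(np.sum(np.exp(-0.1 * t_weeks / WEEKS_PER_MONTH))) / WEEKS_PER_YEAR
        assert trace.total_qalys == pytest.approx(trace.total_lys, rel=1e-12)
        assert trace.total_lys == pytest.approx(auc, rel=1e-9)
        assert trace.total_cost == 0.0

    def test_exponential_mean_survival(self):
        # rate 0.5/year -> mean 2 years; horizon 40/r years
        rate_per_month = 0.5 / 12.0
        os_ = SurvivalDistribution("exponential", {"rate": rate_per_month})
        strat = _bare_strategy(os_, os_)
        settings = ModelSettings(
            horizon_weeks=80 * WEEKS_PER_YEAR, annual_discount=0.0, u_pfd=1.0, u_pd=1.0
        )
        trace = build_trace(strat, settings)
        assert trace.total_lys == pytest.approx(2.0, rel=0.01)

    def test_drug_cost_monotonicity(self):
        rng = np.random.default_rng(31)
        strat = random_strategy(rng)
        settings = ModelSettings(horizon_weeks=260)
        lo = build_trace(dataclasses.replace(strat, weekly_drug_cost=100.0), settings)
        hi = build_trace(dataclasses.replace(strat, weekly_drug_cost=200.0), settings)
        assert hi.total_cost > lo.total_cost

    def test_ngs_additivity(self):
        rng = np.random.default_rng(37)
        strat = random_strategy(rng)
        settings = ModelSettings(horizon_weeks=260)
        without = build_trace(strat, settings)
        ngs = NGSConfig(test_cost=5800.0, prevalence=0.18, mode="flat")
        with_ngs = build_trace(dataclasses.replace(strat, ngs=ngs), settings)
        assert with_ngs.total_cost - without.total_cost == pytest.approx(
            screening_cost(5800.0, 0.18, "flat"), abs=1e-9
        )

    def test_cycle_halving_stability(self):
        pfs = SurvivalDistribution("exponential", {"rate": 0.15})
        os_ = SurvivalDistribution("exponential", {"rate": 0.08})
        strat = _bare_strategy(
            pfs, os_, weekly_drug_cost=1000.0, followup_cost_per_week=146.0
        )
        full = build_trace(strat, ModelSettings(horizon_weeks=520, cycle_length_weeks=1.0))
        half = build_trace(strat, ModelSettings(horizon_weeks=520, cycle_length_weeks=0.5))
        assert half.total_cost == pytest.approx(full.total_cost, rel=0.01)
        assert half.total_qalys == pytest.approx(full.total_qalys, rel=0.01)

    def test_half_cycle_correction_flag(self):
        pfs = SurvivalDistribution("exponential", {"rate": 0.15})
        os_ = SurvivalDistribution("exponential", {"rate": 0.08})
        strat = _bare_strategy(pfs, os_, weekly_drug_cost=500.0)
        plain = build_trace(strat, ModelSettings(horizon_weeks=260))
        hcc = build_trace(strat, ModelSettings(horizon_weeks=260, half_cycle_correction=True))
        assert hcc.total_qalys < plain.total_qalys  # midpoint below cycle-start occupancy
        np.testing.assert_allclose(hcc.p_pfd + hcc.p_pd + hcc.p_dead, 1.0, atol=1e-9)

    def test_hr_extrapolation_lowers_tail_with_favorable_hr(self, model_a):
        trace_with = build_trace(model_a.intervention, model_a.settings,
                                 reference=model_a.reference)
        no_cut = dataclasses.replace(model_a.intervention, extrapolation_cutoffs=None)
        trace_without = build_trace(no_cut, model_a.settings)
        assert trace_with.total_lys != pytest.approx(trace_without.total_lys, rel=1e-6)

    def test_ae_costs_and_disutility_land_in_first_cycle(self, model_a):
        from psmcea.simulate import make_fixture_config

        zero = make_fixture_config("A", ae_profile="zero")
        test = make_fixture_config("A", ae_profile="test")
        tz = build_trace(zero.intervention, zero.settings, reference=zero.reference)
        tt = build_trace(test.intervention, test.settings, reference=test.reference)
        # only cycle-0 accruals differ
        np.testing.assert_allclose(tz.cost[1:], tt.cost[1:], rtol=1e-12)
        np.testing.assert_allclose(tz.qaly[1:], tt.qaly[1:], rtol=1e-12)
        assert tt.cost[0] > tz.cost[0]
        assert tt.qaly[0] < tz.qaly[0]


class TestConfigValidation:
    def test_bad_subsequent_mix_sum(self):
        from psmcea import SubsequentRegimen

        pfs = SurvivalDistribution("exponential", {"rate": 0.1})
        with pytest.raises(ConfigError):
            _bare_strategy(pfs, pfs, subsequent_mix=(SubsequentRegimen("x", 0.5, 100.0),))

    def test_bad_utilities(self):
        with pytest.raises(ConfigError):
            ModelSettings(u_pfd=1.2)

    def test_negative_discount(self):
        with pytest.raises(ConfigError):
            ModelSettings(annual_discount=-0.01)

    def test_bad_prevalence(self):
        with pytest.raises(ConfigError):
            NGSConfig(prevalence=0.0)

    def test_bad_screening_mode(self):
        with pytest.raises(ConfigError):
            NGSConfig(mode="bulk")

    def test_horizon_shorter_than_cycle(self):
        with pytest.raises(ConfigError):
            ModelSettings(horizon_weeks=0.5, cycle_length_weeks=1.0)
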