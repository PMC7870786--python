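import math

import numpy as np
import pytest
from scipy import integrate, stats

from psmcea import (
    FitResult,
    SurvivalDistribution,
    fit_mle,
    hazard_at,
    select_best,
    survival_at,
)
from psmcea.exceptions import (
    NonIdentifiableError,
    ParameterDomainError,
    SelectionError,
    TimeDomainError,
)
from psmcea.survival import inverse_survival

GRID = np.linspace(0.0, 60.0, 1000)

WELL_BEHAVED = [
    SurvivalDistribution("exponential", {"rate": 0.1}),
    SurvivalDistribution("weibull", {"shape": 1.8, "scale": 10.0}),
    SurvivalDistribution("gamma", {"shape": 2.1689, "rate": 0.1485}),
    SurvivalDistribution("lognormal", {"meanlog": 2.0, "sdlog": 0.7}),
    SurvivalDistribution("loglogistic", {"shape": 2.383, "scale": 2.889}),
    SurvivalDistribution("gompertz", {"shape": 0.06804, "rate": 0.01423}),
    SurvivalDistribution("generalized_gamma", {"shape": 2.0, "power": 1.2, "scale": 6.0}),
    SurvivalDistribution(
        "mixture_cure", {"theta": 0.097, "shape": 2.383, "scale": 2.889},
        base_family="loglogistic",
    ),
    SurvivalDistribution(
        "nonmixture_cure", {"theta": 0.223, "meanlog": 1.206, "sdlog": 0.633},
        base_family="lognormal",
    ),
    # spline equivalent to weibull(1.4, scale e): lnH = 1.4*ln t - 1.4
    SurvivalDistribution(
        "rp_spline",
        {"gamma0": -1.4, "gamma1": 1.4, "gamma2": 0.0, "gamma3": 0.0},
        knots=(-1.0, 0.5, 1.5, 3.0),
    ),
]


class TestSurvivalAt:
    @pytest.mark.parametrize("dist", WELL_BEHAVED, ids=lambda d: d.family)
    def test_s0_is_one(self, dist):
        assert survival_at(dist, 0.0) == 1.0

    @pytest.mark.parametrize("dist", WELL_BEHAVED, ids=lambda d: d.family)
    def test_monotone_and_bounded_on_grid(self, dist):
        s = survival_at(dist, GRID)
        assert np.all((s >= 0) & (s <= 1))
        assert np.all(np.diff(s) <= 1e-12)

    def test_mixture_cure_asymptote(self):
        dist = SurvivalDistribution(
            "mixture_cure", {"theta": 0.097, "shape": 2.383, "scale": 2.889},
            base_family="loglogistic",
        )
        assert survival_at(dist, 1e9) == pytest.approx(0.097, abs=1e-9)

    def test_gamma_vs_quadrature(self):
        # independent oracle: integrate the density from t to infinity
        dist = SurvivalDistribution("gamma", {"shape": 2.1689, "rate": 0.1485})
        expected, _ = integrate.quad(
            lambda u: stats.gamma.pdf(u, 2.1689, scale=1 / 0.1485), 12.0, np.inf
        )
        assert survival_at(dist, 12.0) == pytest.approx(expected, abs=1e-8)

    def test_negative_time_rejected(self):
        dist = SurvivalDistribution("exponential", {"rate": 0.1})
        with pytest.raises(TimeDomainError):
            survival_at(dist, -1.0)

    @pytest.mark.parametrize(
        "family,params,kwargs",
        [
            ("exponential", {"rate": -0.1}, {}),
            ("weibull", {"shape": 0.0, "scale": 5.0}, {}),
            ("mixture_cure", {"theta": 1.3, "rate": 0.1}, {"base_family": "exponential"}),
            ("mixture_cure", {"theta": -0.1, "rate": 0.1}, {"base_family": "exponential"}),
        ],
    )
    def test_invalid_params_rejected(self, family, params, kwargs):
        with pytest.raises(ParameterDomainError):
            SurvivalDistribution(family, params, **kwargs)

    def test_scale_on_log_reinterprets_scale(self):
        nat = SurvivalDistribution("loglogistic", {"shape": 2.0, "scale": math.exp(2.889)})
        on_log = SurvivalDistribution(
            "loglogistic", {"shape": 2.0, "scale": 2.889}, scale_on_log=True
        )
        assert survival_at(on_log, 7.4) == pytest.approx(survival_at(nat, 7.4), rel=1e-12)


class TestHazardAt:
    def test_exponential_constant(self):
        dist = SurvivalDistribution("exponential", {"rate": 0.37})
        for t in (0.1, 1.0, 42.0):
            assert hazard_at(dist, t) == pytest.approx(0.37, rel=1e-12)

    def test_weibull_shape_one_reduces_to_exponential(self):
        dist = SurvivalDistribution("weibull", {"shape": 1.0, "scale": 8.0})
        assert hazard_at(dist, 3.0) == pytest.approx(1 / 8.0, rel=1e-12)
        assert hazard_at(dist, 17.0) == pytest.approx(1 / 8.0, rel=1e-12)

    def test_gompertz_closed_form_and_finite_difference(self):
        a, b = 0.08, 0.02
        dist = SurvivalDistribution("gompertz", {"shape": a, "rate": b})
        for t in (0.5, 5.0, 20.0):
            assert hazard_at(dist, t) == pytest.approx(b * math.exp(a * t), rel=1e-10)
            # finite-difference oracle on -ln S
            eps = 1e-5
            fd = (
                -math.log(survival_at(dist, t + eps)) + math.log(survival_at(dist, t - eps))
            ) / (2 * eps)
            assert hazard_at(dist, t) == pytest.approx(fd, abs=1e-6)

    @pytest.mark.parametrize("dist", WELL_BEHAVED, ids=lambda d: d.family)
    def test_consistency_with_survival(self, dist):
        # exp(-int_0^t h) must reproduce S(t)
        for t in (2.0, 9.0):
            integral, _ = integrate.quad(
                lambda u: hazard_at(dist, u), 1e-9, t, limit=200
            )
            assert math.exp(-integral) == pytest.approx(
                survival_at(dist, t), abs=1e-6
            )

    def test_consistency_random_draws(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            dist = SurvivalDistribution(
                "weibull", {"shape": rng.uniform(0.8, 2.5), "scale": rng.uniform(2, 20)}
            )
            t = rng.uniform(0.5, 30)
            integral, _ = integrate.quad(lambda u: hazard_at(dist, u), 1e-12, t, limit=200)
            assert math.exp(-integral) == pytest.approx(survival_at(dist, t), abs=1e-6)


class TestInverseSurvival:
    @pytest.mark.parametrize("dist", WELL_BEHAVED, ids=lambda d: d.family)
    def test_round_trip(self, dist):
        for u in (0.9, 0.5, 0.3):
            t = inverse_survival(dist, u)
            if np.isfinite(t):
                assert survival_at(dist, t) == pytest.approx(u, abs=1e-6)

    def test_cure_plateau_is_infinite(self):
        dist = SurvivalDistribution(
            "mixture_cure", {"theta": 0.3, "rate": 0.2}, base_family="exponential"
        )
        assert np.isinf(inverse_survival(dist, 0.25))


class TestFitMLE:
    def test_exponential_recovery(self, exp_ipd):
        obs, ev = exp_ipd
        fit = fit_mle("exponential", (obs, ev))
        assert fit.converged
        assert fit.distribution.params["rate"] == pytest.approx(0.1, rel=0.05)

    def test_mixture_cure_theta_recovery(self):
        rng = np.random.default_rng(3)
        truth = SurvivalDistribution(
            "mixture_cure", {"theta": 0.2, "shape": 1.5, "scale": 8.0},
            base_family="weibull",
        )
        t = inverse_survival(truth, rng.uniform(size=5000))
        obs = np.minimum(t, 60.0)
        ev = (t <= 60.0).astype(int)
        fit = fit_mle("mixture_cure", (obs, ev), base_family="weibull")
        assert fit.converged
        assert abs(fit.distribution.params["theta"] - 0.2) <= 0.05

    def test_all_censored_is_non_identifiable(self):
        with pytest.raises(NonIdentifiableError):
            fit_mle("exponential", (np.full(50, 10.0), np.zeros(50, dtype=int)))

    def test_empty_is_rejected(self):
        with pytest.raises(NonIdentifiableError):
            fit_mle("exponential", (np.array([]), np.array([])))

    def test_cure_requires_base_family(self, exp_ipd):
        with pytest.raises(ParameterDomainError):
            fit_mle("mixture_cure", exp_ipd)

    def test_bias_shrinks_with_n(self):
        biases = {}
        for n in (500, 5000):
            rng = np.random.default_rng(11)
            t = rng.weibull(1.6, n) * 9.0
            c = rng.uniform(0, 40, n)
            fit = fit_mle("weibull", (np.minimum(t, c), (t <= c).astype(int)), n_starts=1)
            biases[n] = abs(fit.distribution.params["shape"] - 1.6)
        assert biases[5000] < biases[500]

    def test_rp_spline_fits_weibull_data(self, exp_ipd):
        obs, ev = exp_ipd
        fit = fit_mle("rp_spline", (obs, ev))
        assert fit.converged
        # exponential data: spline loglik should at least match exponential's
        fit_exp = fit_mle("exponential", (obs, ev), n_starts=1)
        assert fit.loglik >= fit_exp.loglik - 1.0


class TestSelectBest:
    def _fit(self, aic, n_params, family="exponential", converged=True):
        loglik = (2 * n_params - aic) / 2
        return FitResult(
            distribution=SurvivalDistribution(family, {"rate": 0.1})
            if family == "exponential"
            else SurvivalDistribution("weibull", {"shape": 1.0, "scale": 1.0}),
            loglik=loglik,
            n_params=n_params,
            aic=aic,
            converged=converged,
        )

    def test_argmin(self):
        fits = [self._fit(100.0, 2), self._fit(98.2, 2, "weibull"), self._fit(105.1, 2)]
        assert select_best(fits).aic == 98.2

    def test_tie_prefers_fewer_params(self):
        fits = [self._fit(100.0, 3, "weibull"), self._fit(100.0, 2)]
        assert select_best(fits).n_params == 2

    def test_no_converged_raises(self):
        with pytest.raises(SelectionError):
            select_best([self._fit(100.0, 2, converged=False)])

    def test_aic_identity(self, exp_ipd):
        fit = fit_mle("weibull", exp_ipd, n_starts=1)
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik, abs=1e-12)
        assert fit.n_params == 2

    def test_aic_family_recovery_rate(self):
        # data from weibull(shape 1.8): weibull should beat exponential >= 80%
        wins = 0
        n_reps = 200
        for rep in range(n_reps):
            rng = np.random.default_rng(1000 + rep)
            t = rng.weibull(1.8, 1000) * 10.0
            c = rng.uniform(0, 30, 1000)
            obs, ev = np.minimum(t, c), (t <= c).astype(int)
            fits = [
                fit_mle("weibull", (obs, ev), n_starts=1),
                fit_mle("exponential", (obs, ev), n_starts=1),
            ]
            wins += select_best(fits).distribution.family == "weibull"
        assert wins / n_reps >= 0.80


class TestSerialization:
    @pytest.mark.parametrize("dist", WELL_BEHAVED, ids=lambda d: d.family)
    def test_dict_round_trip(self, dist):
        clone = SurvivalDistribution.from_dict(dist.to_dict())
        assert clone == dist
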