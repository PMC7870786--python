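import numpy as np
import pytest

from psmcea import (
    ModelSettings,
    ScenarioModel,
    StrategyConfig,
    SubsequentRegimen,
    SurvivalDistribution,
    make_fixture_config,
)


def random_distribution(rng: np.random.Generator) -> SurvivalDistribution:
    """A random well-behaved survival law (for trace property tests)."""
    fam = rng.choice(["exponential", "weibull", "gamma", "lognormal", "loglogistic", "gompertz"])
    if fam == "exponential":
        params = {"rate": rng.uniform(0.02, 0.3)}
    elif fam == "weibull":
        params = {"shape": rng.uniform(0.7, 2.5), "scale": rng.uniform(3, 20)}
    elif fam == "gamma":
        params = {"shape": rng.uniform(0.8, 3.0), "rate": rng.uniform(0.05, 0.4)}
    elif fam == "lognormal":
        params = {"meanlog": rng.uniform(0.5, 2.5), "sdlog": rng.uniform(0.3, 1.2)}
    elif fam == "loglogistic":
        params = {"shape": rng.uniform(1.0, 3.0), "scale": rng.uniform(3, 20)}
    else:
        params = {"shape": rng.uniform(0.01, 0.15), "rate": rng.uniform(0.02, 0.2)}
    return SurvivalDistribution(fam, params, time_unit="months")


def random_strategy(rng: np.random.Generator, name: str = "arm") -> StrategyConfig:
    """A random valid strategy configuration."""
    pfs = random_distribution(rng)
    os_ = random_distribution(rng)
    return StrategyConfig(
        name=name,
        pfs_model=pfs,
        os_model=os_,
        weekly_drug_cost=rng.uniform(0, 3000),
        p_subsequent_active=rng.uniform(0, 1),
        subsequent_mix=(
            SubsequentRegimen("x", 0.6, rng.uniform(0, 10_000)),
            SubsequentRegimen("y", 0.4, rng.uniform(0, 10_000)),
        ),
        subsequent_duration_months=rng.uniform(0, 12),
        supportive_care_cost_per_day=rng.uniform(0, 400),
        followup_cost_per_week=rng.uniform(0, 300),
        terminal_cost=rng.uniform(0, 50_000),
    )


@pytest.fixture(scope="session")
def model_a() -> ScenarioModel:
    return make_fixture_config("A")


@pytest.fixture(scope="session")
def model_b() -> ScenarioModel:
    return make_fixture_config("B")


@pytest.fixture()
def short_settings() -> ModelSettings:
    return ModelSettings(horizon_weeks=260.0)


@pytest.fixture()
def exp_ipd():
    """Simulated exponential IPD: n=5000, rate 0.1/month, ~20% censoring."""
    rng = np.random.default_rng(42)
    t = rng.exponential(10.0, 5000)
    c = rng.uniform(0, 55, 5000)
    obs = np.minimum(t, c)
    ev = (t <= c).astype(int)
    return obs, ev
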