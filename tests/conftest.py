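import dataclasses

import pytest
from hypothesis import HealthCheck, settings as hyp_settings

import lungscreen as ls
from lungscreen.parameters import DistributionSpec

hyp_settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
hyp_settings.load_profile("default")


@pytest.fixture(scope="session")
def params() -> ls.ParameterSet:
    return ls.default_parameters()


@pytest.fixture(scope="session")
def settings() -> ls.EvaluationSettings:
    return ls.EvaluationSettings()


@pytest.fixture(scope="session")
def strategies(params):
    return {s.name: s for s in ls.default_strategies()}


@pytest.fixture(scope="session")
def all_fixed_params(params) -> ls.ParameterSet:
    """The default set with every PSA distribution degenerate (fixed)."""
    return ls.ParameterSet(
        {
            p.name: dataclasses.replace(p, dist=DistributionSpec("fixed"))
            for p in params
        }
    )
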