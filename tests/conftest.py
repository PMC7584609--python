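import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mcsdesign.constraint_engine import GrowthCondition
from mcsdesign.synthetic_data import ToyCouplingParams, make_toy_coupled_model, toy_condition


@pytest.fixture
def toy():
    """Smallest strongly-couplable network (one NADH sink) + ground truth."""
    params = ToyCouplingParams(n_extra_nadh_sinks=0, uptake=6.3)
    model, ground_truth = make_toy_coupled_model(params)
    return model, ground_truth, toy_condition(params)


@pytest.fixture
def toy_model(toy):
    return toy[0]


@pytest.fixture
def toy_cond(toy) -> GrowthCondition:
    return toy[2]
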