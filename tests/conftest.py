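import pytest

from avarescue import (
    ExcavationSpec,
    GeneratorParams,
    SurvivalModelSpec,
)
from avarescue.synthetic import depth_sampler


@pytest.fixture(scope="session")
def survival_model():
    return SurvivalModelSpec()


@pytest.fixture(scope="session")
def excavation_spec():
    return ExcavationSpec()


@pytest.fixture(scope="session")
def generator_params():
    return GeneratorParams()


@pytest.fixture(scope="session")
def default_depth_sampler(generator_params):
    return depth_sampler(generator_params)
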