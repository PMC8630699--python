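import numpy as np
import pytest

from melcea import ModelConfig, SurvivalSpec, load_parameters


@pytest.fixture(scope="session")
def pset():
    return load_parameters()


@pytest.fixture(scope="session")
def cfg():
    return ModelConfig()


@pytest.fixture(scope="session")
def os_spec():
    return SurvivalSpec("loglogistic", (0.03916796, 1.52458))


@pytest.fixture(scope="session")
def pfs_spec():
    return SurvivalSpec("loglogistic", (0.1380415, 1.922389))


@pytest.fixture(scope="session")
def all_family_specs():
    """One representative, well-behaved spec per family (times in months)."""
    return [
        SurvivalSpec("exponential", (0.08,)),
        SurvivalSpec("weibull", (1.4, 12.0)),
        SurvivalSpec("lognormal", (2.2, 0.9)),
        SurvivalSpec("loglogistic", (0.03916796, 1.52458)),
        SurvivalSpec("gompertz", (0.05, 0.04)),
        SurvivalSpec("generalized_gamma", (2.0, 0.8, 0.5)),
    ]
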