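"""Shared fixtures.

The expensive model fits are session-scoped: the noisy five-condition
experiment (the study's full design) and the noiseless three-temperature
recovery problem are each generated and fitted once, then reused by the
estimation and acceptance tests.
"""

import numpy as np
import pytest

from capsuledry import (
    FitConfig,
    fit_constant,
    fit_variable,
)
from capsuledry.synthetic import GeneratorConfig, generate_drying_experiment


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig()


@pytest.fixture(scope="session")
def noisy_curves(default_config):
    """Five-condition synthetic experiment at the default noise (CV 5 %)."""
    return generate_drying_experiment(default_config)


@pytest.fixture(scope="session")
def variable_fit_noisy(noisy_curves):
    return fit_variable(noisy_curves)


@pytest.fixture(scope="session")
def constant_fit_noisy(noisy_curves):
    return fit_constant(noisy_curves)


@pytest.fixture(scope="session")
def noiseless_config():
    cfg = GeneratorConfig(noise_cv=0.0)
    cfg.conditions = [c for c in cfg.conditions if c.relative_humidity == 60.0]
    return cfg


@pytest.fixture(scope="session")
def noiseless_curves(noiseless_config):
    """Three temperatures (35/40/45 degC at RH 60 %), no measurement noise."""
    return generate_drying_experiment(noiseless_config)


@pytest.fixture(scope="session")
def variable_fit_noiseless(noiseless_curves):
    return fit_variable(noiseless_curves)


@pytest.fixture(scope="session")
def constant_fit_noiseless(noiseless_curves):
    return fit_constant(noiseless_curves)
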