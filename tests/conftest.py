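"""Shared fixtures: a tiny variable inventory and cohort for fast tests."""

import numpy as np
import pytest

from gazerel.config import SimConfig
from gazerel.simulate import generate_cohort, true_relevance

TINY_COUNTS = {
    "vitals": 3,
    "ventilator": 2,
    "labs": 4,
    "medications": 3,
    "procedures": 1,
    "cultures": 1,
    "intake_output": 1,
    "demographics": 6,
    "diagnosis": 1,
}


@pytest.fixture
def tiny_config() -> SimConfig:
    return SimConfig(n_cases=8, seed=7, variable_counts=dict(TINY_COUNTS))


@pytest.fixture
def tiny_cohort(tiny_config):
    cases, model = generate_cohort(tiny_config)
    return cases, model


@pytest.fixture
def tiny_session(tiny_config, tiny_cohort):
    from gazerel.simulate import simulate_session

    cases, model = tiny_cohort
    relevance = true_relevance(cases[0], model)
    return cases[0], simulate_session(cases[0], relevance, tiny_config, seed=42)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
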