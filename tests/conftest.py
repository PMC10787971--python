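"""Shared fixtures: frozen-seed synthetic cohorts and their cause-specific views."""

import numpy as np
import pytest

from bayesaft.data_model import Cause, cause_specific_view
from bayesaft import synthetic_data as sd

try:  # hypothesis is optional at runtime but present in the test environment
    from hypothesis import settings, HealthCheck

    settings.register_profile(
        "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
    )
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def fixtures():
    return sd.standard_fixtures()


@pytest.fixture(scope="session")
def tiny(fixtures):
    return fixtures["tiny_n20"]


@pytest.fixture(scope="session")
def n800(fixtures):
    return fixtures["weibull_truth_n800"]


@pytest.fixture(scope="session")
def n800_hf_view(n800):
    return cause_specific_view(n800.cohort, Cause.HF)


@pytest.fixture(scope="session")
def tiny_hf_view(tiny):
    return cause_specific_view(tiny.cohort, Cause.HF)


@pytest.fixture(scope="session")
def rashf(fixtures):
    return fixtures["rashf_like"]
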