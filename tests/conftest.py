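"""Shared fixtures.

The tuned closed-loop simulations are expensive (a few minutes), so the
reference/stenosis pair is computed once per session and shared by the
integration and acceptance tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from coroflow.config import reference_config
from coroflow.engine import run_scenario_pair

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def scenario_pair():
    """Tuned reference simulation and the aortic-stenosis case."""
    return run_scenario_pair(reference_config())


@pytest.fixture(scope="session")
def reference_beat(scenario_pair):
    return scenario_pair["reference"].record


@pytest.fixture(scope="session")
def stenosis_beat(scenario_pair):
    return scenario_pair["aortic_stenosis"].record


@pytest.fixture()
def rng():
    return np.random.default_rng(17)
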