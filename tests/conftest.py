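import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from growthzones import (
    ContinuationSettings,
    NondimParams,
    build_diagram,
    generate_scenarios,
)


@pytest.fixture(scope="session")
def symmetric_params():
    """A symmetric two-zone regime with the full orb/monopolar/bipolar structure."""
    return NondimParams(0.1, 20.0, (0.5, 0.5))


@pytest.fixture(scope="session")
def symmetric_diagram(symmetric_params):
    return build_diagram(symmetric_params, (0.05, 2.5))


@pytest.fixture(scope="session")
def wt_scenario():
    return generate_scenarios("wt")[0]


@pytest.fixture(scope="session")
def wt_diagram(wt_scenario):
    return build_diagram(wt_scenario.params, wt_scenario.suggested_l_range)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20120927)
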