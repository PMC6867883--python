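import random

import pytest

from castsim import agents, engine, problems
from castsim.io import make_fixtures


@pytest.fixture
def rng():
    return random.Random(12345)


@pytest.fixture(scope="session")
def small_bank():
    # 14 items per (domain, level) cell
    return problems.generate_bank(98, 98, seed=7)


@pytest.fixture
def default_agent():
    return agents.AgentParams()


@pytest.fixture(scope="session")
def fixtures():
    return make_fixtures(seed=0)


@pytest.fixture(scope="session")
def study_designs():
    return {s: engine.build_design(s) for s in engine.STUDIES}
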