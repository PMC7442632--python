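import pytest

from panworld.agent_policies import (
    Action,
    Policy,
    generate_fixture_session,
)
from panworld.sim_engine import _Session
from panworld.world_config import make_treatment_config


class ScriptedPolicy(Policy):
    """Test helper: delegates each decision to a user-supplied function."""

    def __init__(self, fn):
        self.fn = fn

    def decide(self, obs):
        return self.fn(obs)


def scripted(fn) -> ScriptedPolicy:
    return ScriptedPolicy(fn)


def idle_forever(obs):
    return Action.idle()


@pytest.fixture
def chimp_config():
    return make_treatment_config("chimpanzee")


@pytest.fixture
def bonobo_config():
    return make_treatment_config("bonobo")


def primed_session(config, policies, seed=0, day=0):
    """A _Session with day state primed but the clock not yet advanced."""
    sess = _Session(config, policies, seed)
    sess.start_day(day)
    return sess


@pytest.fixture(scope="session")
def chimp_fixture_log():
    """One full synthetic chimpanzee-treatment session (expensive; shared)."""
    return generate_fixture_session("chimpanzee", "split_grove_frugivores", seed=1)


@pytest.fixture(scope="session")
def bonobo_fixture_log():
    """One full synthetic bonobo-treatment session (expensive; shared)."""
    return generate_fixture_session("bonobo", "herd_grazers", seed=1)
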