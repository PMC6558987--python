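import pytest

from beemaze.apparatus import ArmState, LightStimulus, OdorStimulus
from beemaze.beesim import BeeParams
from beemaze.protocol import TestConfigSpec, schedule_session

BLUE = ArmState(light=LightStimulus.blue())
GREEN = ArmState(light=LightStimulus.green())
UV = ArmState(light=LightStimulus.uv())
LIMONENE = ArmState(odor=OdorStimulus("limonene"))
LINALOOL = ArmState(odor=OdorStimulus("linalool"))


@pytest.fixture(scope="session")
def blue():
    return BLUE


@pytest.fixture(scope="session")
def green():
    return GREEN


@pytest.fixture(scope="session")
def color_test():
    """Spontaneous blue-vs-green choice test (blue as CS+)."""
    return TestConfigSpec("spontaneous", (("CS+", BLUE), ("CS-", GREEN)))


@pytest.fixture(scope="session")
def nt4_schedule(color_test):
    """The standard paired session: Nt=4, one spontaneous test (670 s)."""
    return schedule_session(4, [color_test], cs_plus=BLUE, cs_minus=GREEN)


@pytest.fixture(scope="session")
def nt4_log(nt4_schedule):
    """One deterministic simulated session log (seed 42)."""
    from beemaze.beesim import simulate_bee

    return simulate_bee(nt4_schedule, BeeParams(), seed=42)
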