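import pytest

from tapcog import (
    DEFAULT_CONFIG,
    RespondentProfile,
    generate_battery,
)


@pytest.fixture(scope="session")
def config():
    return DEFAULT_CONFIG


@pytest.fixture(scope="session")
def battery(config):
    return generate_battery(config, seed=7)


@pytest.fixture()
def perfect_profile():
    """No lapses, no errors, no noise behaviors: every trial correct."""
    return RespondentProfile(
        lapse_rate=0.0,
        commission_rate=0.0,
        vr_hit_rate=1.0,
        vr_false_alarm_rate=0.0,
        double_tap_rate=0.0,
        anticipation_rate=0.0,
        seed=11,
    )
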