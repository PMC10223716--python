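from dataclasses import replace

import pytest

from cstrtwin import make_scenario


def _shorten(cfg, hold_s=600.0, duration_s=4 * 3600.0, shutdown_at_s=None):
    """Scale a scenario's hold/duration down for fast closed-loop tests."""
    cfg.control.hold_duration_s = hold_s
    cfg.scenario = replace(
        cfg.scenario, duration_s=duration_s, shutdown_at_s=shutdown_at_s
    )
    return cfg


@pytest.fixture
def shorten():
    return _shorten


@pytest.fixture
def short_run4():
    """Run-4 style PID scenario with a 10 min hold and 4 h horizon."""
    return _shorten(make_scenario(4, seed=0))


@pytest.fixture
def short_run4_manual():
    cfg = _shorten(make_scenario(4, seed=0))
    cfg.control.mode = "manual"
    cfg.scenario.faults = "clamp"
    return cfg
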