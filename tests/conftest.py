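import pytest

from buccalsim.params import default_params
from buccalsim.experiments import run_behavior

BEHAVIORS = ("bite", "swallow_unloaded", "swallow_loaded", "reject")


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def behavior_runs(params):
    """One 20 s simulation per behavior, shared across the whole suite."""
    out = {}
    for b in BEHAVIORS:
        traj, metrics = run_behavior(b, params, duration=20.0)
        out[b] = (traj, metrics)
    return out
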