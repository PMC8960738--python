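import numpy as np
import pytest
from hypothesis import settings

from pigatria import ModelParameters, resting_state, simulate_cell

settings.register_profile("default", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def rest(params):
    """Quiescent steady state (20 s unstimulated equilibration, cached)."""
    return resting_state(params)


@pytest.fixture(scope="session")
def paced_trace(params, rest):
    """Three beats at 1 Hz from rest; the last beat is rate-adapted."""
    stim_times = [1.0, 1001.0, 2001.0]
    tr = simulate_cell(params, rest, duration=3000.0,
                       stim_times=stim_times, stim_amplitude=70.0,
                       stim_duration=1.0, record_every=0.2)
    tr.stim_times = tuple(stim_times)
    return tr


@pytest.fixture(scope="session")
def cable_run(params):
    """Single stimulated plane wave on a 3 cm cable (probes at 1 and 2 cm)."""
    from pigatria.tissue import run_cable
    return run_cable(3.0, params, duration=90.0,
                     probe_positions_cm=(1.0, 2.0))


@pytest.fixture(scope="session")
def restitution_table(params, rest):
    """Restitution across the experimental pacing frequencies (plus 5 Hz)."""
    from pigatria.protocols import run_restitution
    return run_restitution([0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0], params,
                           state=rest)
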