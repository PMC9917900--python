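import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from cardiosync import SimParams, simulate_monolayer
from cardiosync.video_io import Trace


@pytest.fixture(scope="session")
def small_sync_sim():
    """A small fully synchronized monolayer (120 bpm) with its truth."""
    params = SimParams(
        height=96, width=96, n_frames=300, frame_interval=0.05,
        rate_bpm=120.0, cell_size=16, seed=11,
    )
    calcium, motion, truth = simulate_monolayer(params)
    return params, calcium, motion, truth


def make_trace(values, dt=0.05, region_id=0):
    return Trace(np.asarray(values, dtype=float), dt, region_id)


@pytest.fixture
def trace_factory():
    return make_trace
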