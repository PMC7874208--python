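import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vsrkit import StimulusProtocol, TailTrace, phenotype_preset, simulate_trace

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def protocol():
    """The standard single-recording protocol (0.53 Hz, 30 fps, 1280 frames)."""
    return StimulusProtocol()


@pytest.fixture
def short_protocol():
    """A 6-cycle recording for anything that renders frames."""
    return StimulusProtocol(frames_per_recording=6 * StimulusProtocol().frames_per_cycle)


@pytest.fixture
def wt_trace(protocol):
    return simulate_trace(phenotype_preset("wild_type", startle_rate=0.0, seed=11), protocol)


@pytest.fixture
def null_trace(protocol):
    return simulate_trace(phenotype_preset("mechanotransduction_null", seed=12), protocol)


def make_trace(angles, fps=30.0, black_every=None, epochs=None):
    """Hand-build a TailTrace with black frames at a fixed spacing."""
    angles = np.asarray(angles, dtype=float)
    n = len(angles)
    blacks = np.arange(0, n, black_every) if black_every else np.empty(0, dtype=int)
    valid = np.ones(n, dtype=bool)
    valid[blacks] = False
    return TailTrace(
        angles=angles, fps=fps, black_frames=blacks, valid=valid, epochs=epochs
    )
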