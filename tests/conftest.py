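import numpy as np
import pytest

from qeeg.synth import ContinuousSpec, StageProfile, generate_recording


@pytest.fixture(scope="session")
def three_stage_record():
    """A compact three-stage record: 2 min isoelectric, 10 min burst
    suppression at a constant 10 bursts/min, 3 min continuous background."""
    profile = StageProfile(
        isoelectric_end=120.0,
        bs_end=720.0,
        burst_rate=((0.0, 10.0), (1.0, 10.0)),
    )
    continuous = ContinuousSpec(band_fractions=(0.65, 0.15, 0.10, 0.10))
    return generate_recording(profile, continuous, fs=300.0, duration=900.0, seed=42)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20130312)
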