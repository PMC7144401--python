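import numpy as np
import pytest

from somnostat import (
    Recording,
    SimulationConfig,
    Stage,
    StageSequence,
    simulate_vigilance_trajectory,
    synthesize_recording,
)
from somnostat.simulate import DEFAULT_MONTAGE


@pytest.fixture
def montage():
    return dict(DEFAULT_MONTAGE)


@pytest.fixture
def make_recording(montage):
    """Recording factory from a channels x samples array (default 200 Hz)."""

    def build(data, sfreq=200.0):
        return Recording(
            data=data,
            sfreq=sfreq,
            channels=tuple(montage),
            regions=montage,
        )

    return build


@pytest.fixture
def silent_recording(make_recording):
    """All-zero 70-second recording (13 channels at 200 Hz)."""
    return make_recording(np.zeros((13, 70 * 200)))


def constant_sequence(stage, n=1200, mask=None):
    return StageSequence.from_labels([stage] * n, artifact_mask=mask)


@pytest.fixture
def small_config():
    """Reduced-scale simulation: 2-minute recordings, 5 per group."""
    return SimulationConfig(
        group_sizes={"HC": 5, "OB": 5, "DEP": 5, "OBDEP": 5},
        duration=120,
        seed=0,
    )


@pytest.fixture
def staged_pair():
    """A default-SNR synthetic recording and its ground-truth labels."""
    config = SimulationConfig()
    truth = simulate_vigilance_trajectory(config, trait=0.5, seed=11)
    recording = synthesize_recording(truth, config, seed=12)
    return recording, truth
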