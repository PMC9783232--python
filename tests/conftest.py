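import numpy as np
import pytest

from ropetrack.audio_io import AudioSignal, PipelineConfig
from ropetrack.synthetic_scenes import DomainLabel, JumpSceneSpec, synth_jump_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def fast_config():
    """8 kHz config for breath-clip tests (halves synthesis cost)."""
    return PipelineConfig(sample_rate=8000)


@pytest.fixture
def clean_scene():
    """A 30 dB, 40-jump scene with its ground truth."""
    spec = JumpSceneSpec(
        duration=22.0,
        n_jumps=40,
        base_period=0.5,
        period_jitter=0.02,
        snr_db=30.0,
        domain=DomainLabel(0),
        seed=7,
    )
    return synth_jump_scene(spec)


def tone(freq, duration=1.0, sample_rate=16_000, amp=0.5):
    t = np.arange(int(duration * sample_rate)) / sample_rate
    return AudioSignal(samples=amp * np.sin(2 * np.pi * freq * t), sample_rate=sample_rate)
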