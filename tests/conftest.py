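from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from oculearn import StimulusSpec, TrueState, synthesize_eye_trace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_clean_trace(
    gain: float = 0.8,
    phase: float = 0.0,
    frequency: float = 1.0,
    duration: float = 45.0,
    rate: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Synthetic trace with no saccades and (by default) no noise."""
    spec = StimulusSpec(frequency, 10.0)
    state = TrueState(gain=gain, phase=phase, noise_sd=noise_sd)
    return synthesize_eye_trace(
        spec, state, [], duration=duration, rate=rate, seed=seed, position_noise_sd=0.0
    )
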