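import numpy as np
import pytest

from flagsync import synthetic
from flagsync.stokeslet import ForceModulation


@pytest.fixture(scope="session")
def modulation_profile():
    """The measured single-cell force modulation used as the default drive."""
    return ForceModulation(A0=1076.0, A1=0.56, T=1.0 / 33.0)


@pytest.fixture(scope="session")
def piv_movie(modulation_profile):
    """Short noisy modulated-Stokeslet movie (3 beats at ~1 kHz)."""
    cfg = synthetic.SyntheticConfig(seed=1, frame_rate=990.0,
                                    duration=3 * modulation_profile.T,
                                    noise={"piv": 0.05},
                                    grid_extent=120.0, grid_spacing=6.0)
    return synthetic.generate_piv_frames(cfg, force_profile=modulation_profile)


@pytest.fixture(scope="session")
def beat_movie():
    """One full period of the synthetic beating flagellum."""
    model = synthetic.BeatModel()
    cfg = synthetic.SyntheticConfig(seed=0, frame_rate=1000.0,
                                    duration=model.period)
    frames, truth = synthetic.generate_waveforms(cfg, model)
    return frames, truth, model


@pytest.fixture(scope="session")
def locked_pair():
    """A 60 s locked noisy pair at L = 0.85 with stored ground truth."""
    params = synthetic.adler_params_at_separation(0.016, L=0.85)
    cfg = synthetic.SyntheticConfig(seed=3, duration=60.0)
    return synthetic.generate_pair_phases(cfg, params, L=0.85), params
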