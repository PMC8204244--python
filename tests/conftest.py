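import numpy as np
import pytest

from bcgbeat import SimConfig, design_bandpass, apply_bandpass, simulate_recording

FS = 250.0


@pytest.fixture(scope="session")
def clean_sim():
    """60 s at 60 bpm with mild jitter and 10% noise, plus ground truth."""
    cfg = SimConfig(duration_s=60.0, fs=FS, mean_hr_bpm=60.0, rr_jitter_sd_s=0.02,
                    noise_sd=0.10, seed=7)
    return simulate_recording(cfg)


@pytest.fixture(scope="session")
def filtered_clean_sim(clean_sim):
    rec, truth = clean_sim
    return apply_bandpass(rec, design_bandpass(fs=rec.fs)), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
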