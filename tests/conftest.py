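"""Shared fixtures: synthetic signals are generated once per session where
they are expensive (the full IP pipeline dominates)."""

import numpy as np
import pytest
from hypothesis import settings

import pulmosense as ps

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def quiet_train():
    """A 300 s steady breath train at 20 bpm with 5 % noise, plus truth."""
    params = ps.BreathTrainParams(duration_s=300.0, rr_mean_bpm=20.0,
                                  noise_sd_ohm=0.05, seed=20)
    series, truth = ps.make_breath_train(params)
    return params, series, truth


@pytest.fixture(scope="session")
def quiet_result(quiet_train):
    """Full pipeline output on the quiet train."""
    _, series, _ = quiet_train
    return ps.process_ip_channel(series)


@pytest.fixture(scope="session")
def csr_signal():
    """A 240 s Cheyne-Stokes train (five 48 s cycles, 25 % apnea)."""
    params = ps.BreathTrainParams(duration_s=240.0, rr_mean_bpm=22.0, seed=11)
    series, truth = ps.make_breath_train(params)
    csr = ps.CSRParams(cycle_length_s=48.0, apnea_fraction=0.25, n_cycles=5)
    mod, mod_truth = ps.apply_csr_envelope(series, truth, csr)
    return csr, mod, mod_truth


@pytest.fixture(scope="session")
def small_session():
    """A short full multimodal session with audio and ground truth."""
    return ps.simulate_session(subject="T01", tag="admission", seed=5,
                               duration_s=120.0, include_audio=True,
                               audio_duration_s=40.0, n_crackles=6)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
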