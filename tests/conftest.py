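"""Shared fixtures: small synthetic subjects reused across test modules."""

import numpy as np
import pytest

import mstates as ms


@pytest.fixture(scope="session")
def montage65():
    return ms.make_montage(65, seed=7)


@pytest.fixture(scope="session")
def templates4(montage65):
    return ms.make_templates(montage65, 4, seed=1)


@pytest.fixture(scope="session")
def small_subject(montage65, templates4):
    """One 20 s subject at 500 Hz with noise and artifacts."""
    cfg = ms.SimulationConfig(duration=20.0, seed=5)
    truth = ms.sample_state_sequence(cfg)
    rec, truth = ms.render_eeg(truth.labels, templates4, cfg, montage65)
    rec = ms.inject_artifacts(rec, cfg, truth)
    return rec, truth, cfg


@pytest.fixture(scope="session")
def preprocessed_subject(small_subject):
    rec, truth, cfg = small_subject
    return ms.preprocess(rec), truth, cfg


@pytest.fixture(scope="session")
def noisefree_subject(montage65, templates4):
    """A 12 s subject rendered directly at 125 Hz with zero noise."""
    cfg = ms.SimulationConfig(sampling_rate=125.0, duration=12.0, seed=9)
    truth = ms.sample_state_sequence(cfg)
    rec, truth = ms.render_eeg(
        truth.labels, templates4, cfg, montage65, noise_scale=0.0
    )
    return rec, truth, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
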