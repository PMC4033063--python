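"""Shared fixtures: one synthetic subject generated once per session."""

import numpy as np
import pytest

import synergait as sg


@pytest.fixture(scope="session")
def model():
    return sg.default_ground_truth()


@pytest.fixture(scope="session")
def default_config():
    return sg.SimulationConfig(seed=42)


@pytest.fixture(scope="session")
def subject(default_config):
    """Default-variability synthetic subject (seed 42)."""
    return sg.generate_subject(default_config)


@pytest.fixture(scope="session")
def cycle_set(subject):
    cs = sg.preprocess_recording(subject)
    cs.ground_truth = subject.ground_truth
    return cs


@pytest.fixture(scope="session")
def noiseless_config():
    """All step-to-step variability switched off."""
    return sg.SimulationConfig(seed=42, gain_cv=0.0, timing_jitter_sd=0.0,
                               envelope_noise_sd=0.0, cycle_duration_cv=0.0)


@pytest.fixture(scope="session")
def noiseless_cycle_set(noiseless_config):
    rec = sg.generate_subject(noiseless_config)
    cs = sg.preprocess_recording(rec)
    cs.ground_truth = rec.ground_truth
    return cs


@pytest.fixture(scope="session")
def ideal_cycle_set(model, noiseless_config):
    """Identical envelope cycles taken straight from the generative model,
    bypassing raw-signal synthesis and its envelope-estimation ripple."""
    env, _ = sg.generate_cycle_envelopes(model, noiseless_config)
    cs = sg.StepCycleSet(cycles=env, muscle_names=model.muscle_names,
                         boundaries=np.arange(41) * 2200, fs=2000.0)
    cs.ground_truth = model
    return cs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
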