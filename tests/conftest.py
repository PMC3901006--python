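"""Shared fixtures: synthetic sessions at the reference study conditions.

The default session mirrors the distributed VSDI dataset's design (6
conditions x 10 trials + 20 blanks, 110 Hz, heartbeat-triggered) at a
16 x 16 downscaled field of view.  Session-scoped fixtures are reused
across test modules to keep the suite fast.
"""

from __future__ import annotations

import datetime

import numpy as np
import pytest

from vsdikit.data_model import TrialMeta, TrialStack
from vsdikit.synth import SynthConfig, generate_session
from vsdikit import session as sess


@pytest.fixture(scope="session")
def default_config() -> SynthConfig:
    return SynthConfig(seed=1)


@pytest.fixture(scope="session")
def default_session(default_config):
    """(trials, ground truth) at the reference noisy study conditions."""
    return generate_session(default_config)


@pytest.fixture(scope="session")
def noiseless_session():
    """Pure-response session: every noise component disabled."""
    cfg = SynthConfig(seed=3, noise_sd=0.0, bleach_amplitude=0.0,
                      heartbeat_amplitude=0.0, heartbeat_phase_jitter=0.0)
    return cfg, generate_session(cfg)


@pytest.fixture(scope="session")
def fitted_default_session(default_config, default_session):
    """Noise estimate, design matrix and per-trial GLM fits for the default session."""
    trials, truth = default_session
    noise = sess.estimate_noise(trials)
    design = sess.build_session_design(
        default_config.T, default_config.sampling_rate,
        default_config.onset_frame, noise)
    fits = sess.fit_session(trials, design)
    return noise, design, fits


def make_meta(trial: int = 1, cond: int = 1, exp: int = 1) -> TrialMeta:
    return TrialMeta(
        session_date=datetime.date(2024, 1, 15),
        experiment_number=exp,
        trial_number=trial,
        condition_code=cond,
    )


@pytest.fixture
def small_stack() -> TrialStack:
    """Deterministic 4 x 4 x 12 stack around a 1000-count baseline."""
    rng = np.random.default_rng(7)
    data = 1000.0 + 50.0 * rng.standard_normal((4, 4, 12))
    return TrialStack(data=data, sampling_rate=100.0, onset_frame=3,
                      meta=make_meta())
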