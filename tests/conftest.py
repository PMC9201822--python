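"""Shared fixtures: small, fast synthetic sessions and epoch sets."""

from __future__ import annotations

import numpy as np
import pytest

from oddball_eeg.montage import CHANNELS
from oddball_eeg.preprocess import EpochSet
from oddball_eeg.presets import study_presets
from oddball_eeg.simulate import (ContinuousRecording, NoiseConfig,
                                  SessionConfig, SubjectProfile,
                                  build_schedule, simulate_session,
                                  synthesize_recording)


@pytest.fixture(scope="session")
def study_session_cfg() -> SessionConfig:
    return SessionConfig()


@pytest.fixture(scope="session")
def small_session_cfg() -> SessionConfig:
    """120 trials of 2 s (stimulus after 0.5 s) — fast to synthesize."""
    return SessionConfig(n_blocks=1, trials_per_block=120,
                        trial_duration_s=2.0, deviant_fraction=2.0 / 3.0,
                        inter_trial_gap_s=(0.3, 0.5), stimulus_delay_s=0.5)


@pytest.fixture(scope="session")
def unit_profile() -> SubjectProfile:
    """Canonical subject: no variability, default noise."""
    return SubjectProfile(subject_id="U", latency_jitter_sd_ms=0.0,
                          trial_amplitude_jitter_sd=0.0)


@pytest.fixture(scope="session")
def clean_profile() -> SubjectProfile:
    """Noise-free deterministic subject."""
    return SubjectProfile(subject_id="C", latency_jitter_sd_ms=0.0,
                          trial_amplitude_jitter_sd=0.0, noise_level=0.0,
                          blink_rate_per_min=0.0)


@pytest.fixture(scope="session")
def visual_presets():
    return study_presets("visual_only")


@pytest.fixture(scope="session")
def small_noisy_session(small_session_cfg, unit_profile, visual_presets):
    """One noisy small session (shared across tests; treat as read-only)."""
    return simulate_session(small_session_cfg, visual_presets, unit_profile,
                            seed=42)


def make_epochset(epochs: np.ndarray, labels: list[str],
                  channel_names: list[str] | None = None,
                  fs: float = 250.0,
                  window_s: tuple[float, float] = (-0.5, 1.0)) -> EpochSet:
    chans = channel_names or CHANNELS[:epochs.shape[1]]
    return EpochSet(epochs=epochs, channel_names=list(chans),
                    sampling_rate=fs, window_s=window_s, labels=labels)


@pytest.fixture
def epochset_factory():
    return make_epochset
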