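"""Shared fixtures: small synthetic cohorts sized for fast unit tests."""

from __future__ import annotations

import numpy as np
import pytest

from medeeg import EEGRecording, SimConfig, generate_cohort


@pytest.fixture(scope="session")
def unit_cfg() -> SimConfig:
    """Tiny cohort: enough subjects for the selection rule, short sessions."""
    return SimConfig(n_subjects=6, n_sessions_per_task=1, n_channels=8,
                     duration=16.0, n_sources=4, n_oscillators=2, seed=11)


@pytest.fixture(scope="session")
def unit_cohort(unit_cfg) -> list[EEGRecording]:
    return generate_cohort(unit_cfg)


@pytest.fixture(scope="session")
def study_cfg() -> SimConfig:
    """Desk-scale study conditions: 12 subjects, shorter/leaner sessions."""
    return SimConfig(n_subjects=12, n_sessions_per_task=2, n_channels=12,
                     duration=40.0, seed=7)


def make_recording(data: np.ndarray, fs: float = 128.0,
                   task: str = "NONMED") -> EEGRecording:
    return EEGRecording(subject_id="T01", task=task, session_index=1,
                        data=data, fs=fs)
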