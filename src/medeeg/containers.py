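"""Core in-memory containers shared across the pipeline.

An :class:`EEGRecording` is one session of one subject (channels x samples,
microvolts).  An :class:`EpochArray` is the segmented, labelled view used by
feature extraction and classification.  A :class:`FeatureTable` is the final
epochs x features matrix handed to the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Task labels. The two meditation conditions are loving-kindness meditation
#: directed at oneself / at others; NONMED is the non-meditation baseline.
LKM_SELF = "LKM_SELF"
LKM_OTHER = "LKM_OTHER"
NONMED = "NONMED"
TASKS = (LKM_SELF, LKM_OTHER, NONMED)
MEDITATION_TASKS = (LKM_SELF, LKM_OTHER)


@dataclass
class EEGRecording:
    """One EEG session: ``data`` is channels x samples in microvolts."""

    subject_id: str
    task: str
    session_index: int
    data: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(
                f"non-finite samples in recording "
                f"({self.subject_id}, {self.task}, {self.session_index})"
            )
        if self.task not in TASKS:
            raise ValueError(f"unknown task label {self.task!r}")
        if not self.channel_names:
            self.channel_names = [f"ch{i:02d}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length does not match data rows")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.fs

    @property
    def is_meditation(self) -> bool:
        return self.task in MEDITATION_TASKS

    def key(self) -> tuple[str, str, int]:
        return (self.subject_id, self.task, self.session_index)


@dataclass
class EpochArray:
    """Segmented epochs: ``data`` is epochs x channels x samples.

    ``labels`` holds the per-epoch class (meditation=1, non-meditation=0);
    ``source`` carries one (subject_id, task, session_index) provenance tuple
    per epoch so that train/test leakage can be asserted downstream.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    source: list[tuple[str, str, int]]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (epochs x channels x samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length does not match epoch count")
        if len(self.source) != self.data.shape[0]:
            raise ValueError("source length does not match epoch count")
        if self.labels.size and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 (non-meditation) or 1 (meditation)")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def __len__(self) -> int:
        return self.n_epochs


def concatenate_epochs(arrays: list[EpochArray]) -> EpochArray:
    """Pool several epoch arrays (same fs, channel count) into one."""
    if not arrays:
        raise ValueError("no epoch arrays to concatenate")
    fs = arrays[0].fs
    n_ch = arrays[0].n_channels
    for a in arrays:
        if a.fs != fs or a.n_channels != n_ch:
            raise ValueError("epoch arrays disagree on fs or channel count")
    data = np.concatenate([a.data for a in arrays], axis=0)
    labels = np.concatenate([a.labels for a in arrays])
    source: list[tuple[str, str, int]] = []
    for a in arrays:
        source.extend(a.source)
    return EpochArray(data=data, labels=labels, fs=fs, source=source)


@dataclass
class FeatureTable:
    """Epochs x features matrix aligned with per-epoch labels."""

    X: np.ndarray
    labels: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (epochs x features)")
        if self.X.shape[0] != len(self.labels):
            raise ValueError("row count does not match labels")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length does not match columns")
        if self.X.size and not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite feature values")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def __len__(self) -> int:
        return self.X.shape[0]
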