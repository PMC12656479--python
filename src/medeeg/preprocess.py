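"""Band-pass filtering and fixed-length overlapping epoching.

The analysis band of interest is theta+alpha (4-13 Hz); epochs are 2 s with
1 s overlap.  The filter is a zero-phase (forward-backward) FIR band-pass
designed so that one octave outside the band the attenuation exceeds 40 dB
while the passband ripple stays within 1 dB.  Recordings are assumed long
relative to the filter (>= 10 s); edge handling is the filter routine's
default odd reflection padding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .containers import EEGRecording, EpochArray, MEDITATION_TASKS

#: theta + alpha analysis band in Hz
DEFAULT_BAND = (4.0, 13.0)


@dataclass(frozen=True)
class EpochingParams:
    epoch_length: float = 2.0
    overlap: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.overlap < self.epoch_length):
            raise ValueError("need 0 <= overlap < epoch_length")


def _design_bandpass(low: float, high: float, fs: float, n_samples: int) -> np.ndarray:
    # Transition width: half an octave on each side keeps the one-octave
    # points well inside the stopband for a Hamming-window design (~53 dB).
    trans = min(low * (2 ** 0.5 - 1), (high - low) / 2)
    numtaps = int(math.ceil(3.3 * fs / trans))
    # filtfilt needs 3 * numtaps of padding headroom
    numtaps = min(numtaps, max(3, (n_samples - 1) // 3))
    if numtaps % 2 == 0:
        numtaps += 1
    return signal.firwin(numtaps, [low, high], pass_zero=False, fs=fs,
                         window="hamming")


def bandpass(recording: EEGRecording, low: float = DEFAULT_BAND[0],
             high: float = DEFAULT_BAND[1]) -> EEGRecording:
    """Zero-phase FIR band-pass; returns a new recording of the same shape."""
    if not (0 < low < high < recording.fs / 2):
        raise ValueError(
            f"band ({low}, {high}) Hz must lie inside (0, {recording.fs / 2}) Hz"
        )
    taps = _design_bandpass(low, high, recording.fs, recording.n_samples)
    filtered = signal.filtfilt(taps, [1.0], recording.data, axis=-1)
    return EEGRecording(
        subject_id=recording.subject_id, task=recording.task,
        session_index=recording.session_index, data=filtered,
        fs=recording.fs, channel_names=list(recording.channel_names),
    )


def n_epochs_expected(duration: float, params: EpochingParams) -> int:
    """Closed-form epoch count: floor((T - L) / (L - O)) + 1."""
    step = params.epoch_length - params.overlap
    return int(math.floor((duration - params.epoch_length) / step + 1e-9)) + 1


def epoch(recording: EEGRecording,
          params: EpochingParams = EpochingParams()) -> EpochArray:
    """Segment a recording into labelled, overlapping fixed-length epochs.

    Fractional sample counts are floored so no epoch reads past the signal
    end.  Every epoch inherits the recording's class label (meditation=1).
    """
    if recording.duration < params.epoch_length:
        raise ValueError(
            f"recording {recording.key()} is shorter "
            f"({recording.duration:g} s) than one epoch ({params.epoch_length:g} s)"
        )
    ep_len = int(math.floor(params.epoch_length * recording.fs + 1e-9))
    step = int(math.floor((params.epoch_length - params.overlap) * recording.fs + 1e-9))
    if step < 1:
        raise ValueError("overlap too close to epoch_length at this fs")
    n = recording.n_samples
    starts = range(0, n - ep_len + 1, step)
    data = np.stack([recording.data[:, s:s + ep_len] for s in starts])
    label = 1 if recording.task in MEDITATION_TASKS else 0
    n_ep = data.shape[0]
    return EpochArray(
        data=data,
        labels=np.full(n_ep, label),
        fs=recording.fs,
        source=[recording.key()] * n_ep,
    )


def filter_and_epoch(recording: EEGRecording,
               band: tuple[float, float] = DEFAULT_BAND,
               params: EpochingParams = EpochingParams()) -> EpochArray:
    """Convenience chain: band-pass to ``band`` then epoch."""
    return epoch(bandpass(recording, *band), params)
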