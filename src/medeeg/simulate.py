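"""Synthetic multi-subject, multi-session EEG cohorts.

The forward model is deliberately the simplest mechanism that produces a
band-limited, spatially structured class difference that both CSP and STFT
features can exploit:

* per subject, a fixed random mixing matrix with orthonormal columns maps a
  small set of latent sources to channels; the matrix perturbs a shared
  cohort-level template (``topography_variability`` sets how far), because
  subject-independent classification presupposes that the meditation
  band-power effect has a broadly consistent scalp topography across people
  while individual head geometry still shifts it;
* the latent sources are ``n_oscillators`` narrow-band oscillators
  (alternating theta 4-8 Hz and alpha 8-13 Hz band-limited noise, each with
  a small 1/f admixture) plus pure 1/f background sources;
* during meditation tasks the oscillators' *power* is scaled by (1 + e_s)
  where e_s ~ Normal(effect_mean, effect_sd_subject) truncated at 0 and
  drawn once per subject — this subject-level heterogeneity is what makes
  cross-subject transfer hard when effect_sd_subject is large; background
  sources are unaffected, so meditation both raises 4-13 Hz power and
  redistributes it spatially toward the oscillator topographies;
* one log-normal jitter per session scales every source amplitude
  (whole-head gain drift);
* white sensor noise is added so that total oscillatory source power over
  sensor-noise power equals ``noise_snr``.

Seeding: one global seed drives a per-subject ``numpy.random.SeedSequence``
spawn; each subject's sequence spawns one child per (task, session).  Subsets
of a cohort are therefore reproducible independently of how much of the
cohort is generated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .containers import EEGRecording, MEDITATION_TASKS, TASKS

THETA_BAND = (4.0, 8.0)
ALPHA_BAND = (8.0, 13.0)

# baseline channel-signal scale in microvolts RMS (cosmetic; the pipeline is
# scale-invariant except for EDF quantization)
_BASE_UV = 10.0


@dataclass
class SimConfig:
    """Study-condition defaults: 12 subjects x 3 tasks x 5 sessions.

    ``effect_mean`` is the dimensionless multiplicative band-power increase of
    meditation over non-meditation in the affected sources (0.5 means x1.5).
    ``effect_sd_subject`` controls between-subject heterogeneity of that
    effect and hence cross-subject transfer difficulty. ``noise_snr`` is the
    ratio of total oscillatory source power to white sensor-noise power.
    """

    n_subjects: int = 12
    n_sessions_per_task: int = 5
    tasks: tuple[str, ...] = TASKS
    n_channels: int = 22
    fs: float = 128.0
    duration: float = 120.0
    effect_mean: float = 0.5
    effect_sd_subject: float = 0.25
    session_jitter_sd: float = 0.05
    noise_snr: float = 3.0
    n_sources: int = 6
    n_oscillators: int = 4
    topography_variability: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_sessions_per_task < 1:
            raise ValueError("subject and session counts must be >= 1")
        if self.n_channels < 1 or self.n_sources < 1:
            raise ValueError("channel and source counts must be >= 1")
        if self.fs < 64:
            raise ValueError("fs must be >= 64 Hz")
        n_samp = self.duration * self.fs
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ValueError("duration x fs must be an integer sample count")
        if self.effect_mean < 0:
            raise ValueError("effect_mean must be >= 0")
        if self.noise_snr <= 0:
            raise ValueError("noise_snr must be positive")
        unknown = set(self.tasks) - set(TASKS)
        if unknown:
            raise ValueError(f"unknown tasks: {sorted(unknown)}")
        if self.n_sources > self.n_channels:
            raise ValueError("n_sources cannot exceed n_channels")
        if not (1 <= self.n_oscillators <= self.n_sources):
            raise ValueError("need 1 <= n_oscillators <= n_sources")
        if self.topography_variability < 0:
            raise ValueError("topography_variability must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    @property
    def n_recordings(self) -> int:
        return self.n_subjects * len(self.tasks) * self.n_sessions_per_task


def _expected_rms(amp: np.ndarray, n: int) -> float:
    """Expected RMS of irfft(amp * rfft(white noise)) of length n.

    Interior rfft bins of real white noise carry two real degrees of freedom,
    the DC and Nyquist bins one each.
    """
    weights = np.full(len(amp), 2.0)
    weights[0] = 1.0
    if n % 2 == 0:
        weights[-1] = 1.0
    return float(np.sqrt(np.sum(weights * amp**2) / n))


def _shaped_noise(rng: np.random.Generator, n: int,
                  amp: np.ndarray) -> np.ndarray:
    """Gaussian noise with spectral amplitude ``amp``, unit *expected* RMS.

    Normalizing by the expected rather than the realized RMS keeps the
    natural session-to-session power fluctuation of a stationary process —
    without it, every session would have bit-exact identical power and null
    comparisons between sessions become artificially conservative.
    """
    spec = np.fft.rfft(rng.standard_normal(n)) * amp
    return np.fft.irfft(spec, n=n) / _expected_rms(amp, n)


def _narrowband_noise(rng: np.random.Generator, n: int, fs: float,
                      band: tuple[float, float]) -> np.ndarray:
    """Band-limited Gaussian noise (FFT masking), unit expected RMS."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = ((freqs >= band[0]) & (freqs <= band[1])).astype(float)
    return _shaped_noise(rng, n, amp)


def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """1/f (power ~ 1/f) background noise, unit expected RMS."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    nz = freqs > 0
    amp[nz] = 1.0 / np.sqrt(freqs[nz])
    return _shaped_noise(rng, n, amp)


def _orthonormalize(m: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(m)
    # fix the QR sign ambiguity for reproducibility across BLAS builds
    return q * np.sign(np.diag(r))


def _cohort_template(cfg: SimConfig) -> np.ndarray:
    """Shared effect topography: one orthonormal mixing template per cohort."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7E4]))
    return _orthonormalize(rng.standard_normal((cfg.n_channels, cfg.n_sources)))


def _subject_params(cfg: SimConfig, template: np.ndarray,
                    ss: np.random.SeedSequence):
    """Fixed per-subject structure: mixing matrix, effect size, source bands."""
    rng = np.random.default_rng(ss)
    # subject mixing = orthonormalized perturbation of the cohort template
    g = rng.standard_normal((cfg.n_channels, cfg.n_sources))
    q = _orthonormalize(template + cfg.topography_variability * g)
    effect = max(0.0, rng.normal(cfg.effect_mean, cfg.effect_sd_subject))
    # alternate theta/alpha oscillators so both bands carry the effect;
    # remaining sources are pure 1/f background (band None)
    bands = [(THETA_BAND if k % 2 == 0 else ALPHA_BAND)
             if k < cfg.n_oscillators else None
             for k in range(cfg.n_sources)]
    return q, effect, bands


def _session_signal(cfg: SimConfig, mixing: np.ndarray, effect: float,
                    bands: list, meditation: bool,
                    ss: np.random.SeedSequence) -> np.ndarray:
    rng = np.random.default_rng(ss)
    n = cfg.n_samples
    gain = np.sqrt(1.0 + effect) if meditation else 1.0
    # one log-normal amplitude jitter per session: whole-head gain drifts
    # (impedance, vigilance) scale all sources together
    jitter = float(np.exp(rng.normal(0.0, cfg.session_jitter_sd)))
    sources = np.empty((cfg.n_sources, n))
    for k, band in enumerate(bands):
        if band is not None:
            osc = _narrowband_noise(rng, n, cfg.fs, band) * gain
            sources[k] = jitter * (osc + 0.3 * _pink_noise(rng, n, cfg.fs))
        else:
            sources[k] = jitter * _pink_noise(rng, n, cfg.fs)
    clean = mixing @ sources
    # sensor noise calibrated against the nominal *baseline* source power
    # (oscillators ~1.09 each, backgrounds 1), independent of the session's
    # meditation gain so the effect also shows in broadband SNR
    source_power = 1.09 * cfg.n_oscillators + (cfg.n_sources - cfg.n_oscillators)
    noise_sd = np.sqrt(source_power / cfg.noise_snr / cfg.n_channels)
    noisy = clean + noise_sd * rng.standard_normal(clean.shape)
    return _BASE_UV * noisy


def generate_recording(cfg: SimConfig, subject: int, task: str,
                       session_index: int) -> EEGRecording:
    """Generate a single session reproducibly from the cohort seed.

    Seed splitting: ``SeedSequence(seed).spawn(n_subjects)`` gives one
    sequence per subject; its first spawned child fixes subject-level
    structure, and child ``1 + task_rank * n_sessions + (session_index - 1)``
    drives that session's noise draws.
    """
    if not (0 <= subject < cfg.n_subjects):
        raise ValueError("subject index out of range")
    if task not in cfg.tasks:
        raise ValueError(f"task {task!r} not in config tasks")
    if not (1 <= session_index <= cfg.n_sessions_per_task):
        raise ValueError("session_index out of range")
    subj_ss = np.random.SeedSequence(cfg.seed).spawn(cfg.n_subjects)[subject]
    n_children = 1 + len(cfg.tasks) * cfg.n_sessions_per_task
    children = subj_ss.spawn(n_children)
    template = _cohort_template(cfg)
    mixing, effect, bands = _subject_params(cfg, template, children[0])
    t_rank = cfg.tasks.index(task)
    child = children[1 + t_rank * cfg.n_sessions_per_task + (session_index - 1)]
    data = _session_signal(cfg, mixing, effect, bands,
                           meditation=task in MEDITATION_TASKS, ss=child)
    return EEGRecording(
        subject_id=f"S{subject + 1:02d}", task=task,
        session_index=session_index, data=data, fs=cfg.fs,
    )


def generate_cohort(cfg: SimConfig) -> list[EEGRecording]:
    """Generate the full cohort: n_subjects x |tasks| x n_sessions recordings."""
    out = []
    for subject in range(cfg.n_subjects):
        for task in cfg.tasks:
            for session in range(1, cfg.n_sessions_per_task + 1):
                out.append(generate_recording(cfg, subject, task, session))
    return out


def subject_effects(cfg: SimConfig) -> np.ndarray:
    """The realized per-subject meditation effects (for diagnostics/tests)."""
    effects = np.empty(cfg.n_subjects)
    template = _cohort_template(cfg)
    for subject, ss in enumerate(np.random.SeedSequence(cfg.seed).spawn(cfg.n_subjects)):
        _, effects[subject], _ = _subject_params(cfg, template, ss.spawn(1)[0])
    return effects


def band_power(recording: EEGRecording, band: tuple[float, float]) -> np.ndarray:
    """Mean periodogram power inside ``band``, one value per channel.

    Quadratic in signal scale (scaling the signal by c multiplies every band
    power by c^2) and linear in signal power.
    """
    low, high = band
    if not (0 < low < high):
        raise ValueError("band must satisfy 0 < low < high")
    if high >= recording.fs / 2:
        raise ValueError("band upper edge must be below Nyquist")
    freqs, psd = signal.periodogram(recording.data, fs=recording.fs, axis=-1)
    mask = (freqs >= low) & (freqs <= high)
    if not mask.any():
        raise ValueError("band contains no frequency bins")
    return psd[:, mask].mean(axis=-1)
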