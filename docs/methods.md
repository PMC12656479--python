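# Methods

## The synthetic cohort model

The generator (`medeeg.simulate`) produces multi-subject, multi-session EEG
whose meditation/non-meditation difference is a theta+alpha band-power
effect with subject-specific spatial topography — the minimal forward model
under which both spatial (CSP) and spectral (STFT) features carry signal.

**Sources.** Each session is a linear mixture of `n_sources` latent
sources: `n_oscillators` narrow-band oscillators (alternating theta 4–8 Hz
and alpha 8–13 Hz band-limited Gaussian noise, each with a 0.3× 1/f
admixture) and pure 1/f background sources.  All stochastic components are
normalized to unit *expected* RMS rather than realized RMS, so the natural
session-to-session power fluctuation of a stationary process is preserved;
normalizing to realized power would make every session's power bit-identical
and render null comparisons between sessions artificially conservative.

**Effect.** During meditation tasks the oscillators (only) are amplitude-
scaled by √(1 + e_s), i.e. their power by (1 + e_s), where
e_s ~ Normal(effect_mean, effect_sd_subject) clipped at 0 is drawn once per
subject.  Because background sources are unaffected, meditation both raises
total 4–13 Hz power and redistributes it toward the oscillator
topographies, giving CSP a genuine spatial contrast.  `effect_sd_subject`
is the heterogeneity knob: subjects with e_s ≈ 0 are unclassifiable by any
subject-independent decoder, which is what produces the wide bottom-50 % /
top-50 % accuracy split.

**Topography.** One orthonormal mixing template (channels × sources) is
drawn per cohort; each subject's mixing matrix is the re-orthonormalized
template plus `topography_variability` × Gaussian noise.  Subject-
independent decoding presupposes a broadly consistent effect topography
across people, so the default deviation is mild (0.01).  This knob trades
realism against transferability steeply: CSP in particular amplifies
tiny subject-specific directions through whitening, and values ≳0.05
collapse cross-subject CSP transfer toward (and via subject reuse between
the two task draws, below) chance.

**Session and sensor noise.** Each session's sources share one log-normal
amplitude jitter (`session_jitter_sd`, default 0.05) — whole-head gain
drift; a per-source jitter would corrupt the spatial covariance structure
and make CSP learn session identity.  White sensor noise is added at
`noise_snr` (default 3) relative to the *nominal baseline* source power, so
that the meditation gain also changes broadband SNR rather than being
normalized away.

**Seeding.** `SeedSequence(seed)` spawns one stream per subject; the
subject stream's first child fixes subject-level structure and one further
child drives each (task, session).  Any single session can be regenerated
bit-identically in isolation (`generate_recording`).

**Defaults = study conditions.** 12 subjects × 3 tasks × 5 sessions,
128 Hz, 120 s, 22 channels (configurable; the source recordings' rate,
duration and retained channel count are not public, so these are working
values, not claims about the real data), effect 0.5 ± 0.25.

## Preprocessing

Zero-phase FIR band-pass (Hamming-window design, forward–backward
`filtfilt`), transition width half an octave per edge so that one octave
outside the band attenuation exceeds 40 dB; taps are capped at a third of
the signal length for short recordings.  Epoching is 2 s with 1 s overlap;
fractional sample counts floor so no epoch reads past the signal end; epoch
count = floor((T − L)/(L − O)) + 1.  The 4–13 Hz analysis restriction is
applied as a second band-pass before feature extraction.

## Features

* CSP: per-epoch covariances are trace-normalized before class averaging;
  the composite covariance is whitened by eigendecomposition; optional
  diagonal shrinkage (fixed 1e−6 ridge) engages automatically when its
  condition number exceeds 1e10.  Filter signs are fixed by making each
  row's largest-magnitude coefficient positive.  Default m = 3 pairs → 6
  features.
* STFT: 1 s Hann windows, 50 % overlap, per-band summed power averaged over
  windows and over 4 contiguous channel groups (anatomical grouping is
  impossible without a montage), log-transformed.  Bands use the half-open
  convention low ≤ f < high so theta and alpha do not share the 8 Hz bin
  and white noise reproduces the 4:5 bandwidth ratio.  2 bands × 4 groups →
  8 features.
* Fusion: 6 + 8 = 14 features, the cap.  If inputs exceed the cap, all CSP
  columns are kept and STFT columns are ranked by training-set variance
  (label-free, deterministic, ties broken by column index).

## Classifier

scikit-learn `MLPClassifier` behind a thin surface: hidden layers (20, 20),
logistic activations, adam at 1e−3, at most 500 epochs, early stopping on a
10 % validation split.  The early-stopping patience is 50 iterations: with
logistic activations the first ~10 adam iterations are a plateau, and a
short patience aborts training at chance level.  Features are standardized
with training-set mean/SD stored in the model; prediction is an explicit
forward pass through the stored weights (deterministic, save/load-able to a
single `.npz`), with P = 0.5 ties resolved to the non-meditation class.
Accuracy is epoch-level over the pooled epochs of the held-out pair — the
only unit that yields non-integer per-test accuracies.

## Evaluation design

`select_experiment` draws 5 subjects per task (independently for the two
tasks, so a subject may serve meditation in one draw and non-meditation in
the other — this is faithful to the study and is a real source of
below-chance transfer when classifiers latch onto subject identity), one
session per chosen subject, and pairs the draws by a random permutation.
`enumerate_splits` produces all (t+1)-subsets × held-out rotations:
30/20/5 splits for t = 2/3/4.  Within a split, CSP filters, the STFT
fusion ranking and standardization are fitted on pooled training epochs
only (leakage is assertable through per-epoch provenance tags).  The same
selection is reused across the three pipelines of a cell so pipeline
columns are comparable per experiment.  Seeds derive as
master → (task, train size, experiment) → pipeline → split, all documented
in `design.py`; a full study is reproducible result-for-result.

## Statistics

* Summaries: mean ± SD over all tests; the sorted sample is split at the
  midpoint (odd counts: the extra element joins the bottom half — the
  published counts are all even, so this never affects replication).
* Paired t-tests: classical paired t on per-cell all-tests means, two-sided
  p, df = n − 1 (= 5 for six cells).
* Dip: Hartigan's statistic via the iterative greatest-convex-minorant /
  least-concave-majorant algorithm, validated against an exact
  linear-programming minimization over piecewise-linear unimodal CDFs for
  n ≤ 8 (`tests/_dip_oracle.py`).  The bootstrap p-value resamples
  uniform(0,1) — the least-favourable unimodal null — with a seeded
  generator, n_boot = 2000 by default.

## Desk-scale study sizes

The full 9900-test design at study-scale sessions takes CPU-hours; the test
suite, the acceptance script and the examples therefore run a documented
desk scale chosen once: 12 subjects (kept at the study value — smaller
pools sharply increase subject reuse between the task draws and bias null
accuracy below chance), 2 sessions per task, 60 s sessions, 12 channels,
2 experiments per cell (4 for the heterogeneity split).  Under these
conditions the simulator reproduces the study's phenomenology: chance-level
means without an effect, ≈60 % means with a ≈30-point bottom/top-50 % gap
under heterogeneous effects (published analogue: 62.3 % with 46.0/78.3),
and >85 % fused-pipeline accuracy under a strong homogeneous effect.

## What the simulation does and does not show

The generator emulates band-limited, spatially structured effects with
subject heterogeneity, session jitter, 1/f background and sensor noise.  It
does not emulate eye/muscle artifacts, non-stationarity within sessions,
electrode montage geometry, volume-conduction physics, or the manual
cleaning chain applied to real recordings — synthetic data are born clean.
Passing tests therefore validate the pipeline's mechanics and its
sensitivity/calibration properties, not real-data accuracy levels; the
published accuracies are anchored only through their printed-value
arithmetic (table means and t-tests), which the package reproduces exactly.

## Known limitations

* EDF export is 16-bit with per-channel physical ranges; round-trip error
  is bounded by one quantization step but it is not bit-exact (the internal
  `.npy` container is).
* BrainVision support is read-only and validated on self-written fixtures.
* The dip test's bootstrap is exchangeable but not studentized; for the
  small n of per-cell summaries its power is limited.
* With `topography_variability` well above its default, CSP transfer
  degrades realistically but the strong-effect recovery guarantees in the
  acceptance checks no longer hold; the default is part of the package's
  study conditions.
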