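# Full study configuration: every key mirrors a library default, so an empty
# file runs the same study.  CLI flags (--seed, --scale, --out) override.

sim:
  n_subjects: 12            # participants in the cohort
  n_sessions_per_task: 5    # sessions per participant per mental task
  tasks: [LKM_SELF, LKM_OTHER, NONMED]
  n_channels: 22            # scalp channels after dimensionality reduction
  fs: 128.0                 # Hz
  duration: 120.0           # seconds per session
  effect_mean: 0.5          # meditation band-power increase (0.5 = x1.5)
  effect_sd_subject: 0.25   # between-subject SD of the effect
  session_jitter_sd: 0.05   # log-normal whole-head amplitude jitter per session
  noise_snr: 3.0            # oscillatory source power / sensor-noise power
  n_sources: 6              # latent sources mixed to channels
  n_oscillators: 4          # theta/alpha oscillators among the sources
  topography_variability: 0.01  # subject deviation from the shared topography
  seed: 0

band: [4.0, 13.0]           # theta + alpha analysis band, Hz

epoching:
  epoch_length: 2.0         # seconds
  overlap: 1.0              # seconds

features:
  n_csp_pairs: 3            # 2m = 6 CSP features
  stft_bands: [[4.0, 8.0], [8.0, 13.0]]
  stft_window: 1.0          # seconds, Hann taper
  stft_overlap: 0.5         # fraction
  stft_groups: 4            # contiguous channel groups -> 8 STFT features
  cap: 14                   # fused feature ceiling

mlp:
  hidden_layers: [20, 20]
  max_epochs: 500
  learning_rate: 0.001
  early_stopping: true
  validation_fraction: 0.1
  patience: 50

design:
  n_experiments: 30         # random 5-pair selections per cell
  train_sizes: [2, 3, 4]
  meditation_tasks: [LKM_SELF, LKM_OTHER]
  pipelines: [CSP, STFT, CSP_STFT]
  master_seed: 0
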