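"""Generate a small synthetic meditation/non-meditation EEG cohort and
verify that the injected theta+alpha band-power effect is present.

A cohort is a pool of sessions: each of the subjects contributes sessions
for LKM-Self, LKM-Others and a non-meditation baseline.  During meditation
the simulator scales the oscillatory sources' power by (1 + effect), so the
4-13 Hz channel band power of meditation sessions should exceed the
non-meditation ones by roughly that factor.
"""

import numpy as np

from medeeg import SimConfig, band_power, generate_cohort

cfg = SimConfig(n_subjects=6, n_sessions_per_task=2, n_channels=12,
                duration=30.0, effect_mean=0.5, effect_sd_subject=0.0, seed=1)
cohort = generate_cohort(cfg)
print(f"generated {len(cohort)} sessions "
      f"({cfg.n_subjects} subjects x {len(cfg.tasks)} tasks x "
      f"{cfg.n_sessions_per_task} sessions)")

med = [band_power(r, (4, 13)).mean() for r in cohort if r.is_meditation]
non = [band_power(r, (4, 13)).mean() for r in cohort if not r.is_meditation]
ratio = np.mean(med) / np.mean(non)
print(f"meditation / non-meditation 4-13 Hz band-power ratio: {ratio:.2f}")
print("with effect_mean=0.5 the oscillator power rises x1.5; diluted by the")
print("1/f background and sensor noise the channel-level ratio lands around "
      "1.3-1.5.")
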