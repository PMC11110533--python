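"""Generate a small synthetic cohort and inspect its structure.

Each subject carries a 10 min fasting block and a 60 min post-load block
of dual-wavelength intensity over 21 channels, plus fingertip reference
glucose every 5 min and the full generative ground truth.
"""
import numpy as np

import fnirsglu as fg

config = fg.SyntheticConfig(n_subjects=3, rng_seed=7)
cohort = fg.generate_cohort(config)

sub = cohort.subjects[0]
print(f"subjects: {len(cohort)}")
print(f"fasting intensity shape (T, channels, wavelengths): "
      f"{sub.fasting.intensity.shape}")
print(f"glucose intensity shape: {sub.glucose.intensity.shape}")
print(f"reference glucose samples per subject: {len(sub.glucose_refs)}")

truth = sub.truth
coupled = np.flatnonzero(truth.betas > 0) + 1
print(f"coupled channels: {coupled.tolist()} "
      f"(beta = {truth.betas.max():.3f} uM per mmol/L)")
print(f"glucose curve: fasting {truth.fasting_level:.2f} mmol/L, "
      f"peak {truth.glucose.max():.2f} mmol/L at "
      f"t = {truth.times[np.argmax(truth.glucose)]:.0f} s")
print(f"injected motion artifacts: {len(truth.events)}")
# The peak above the fasting level is the planted glucose excursion that
# the coupled channels' HbO must track through the whole analysis chain.
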