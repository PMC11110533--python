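"""Preprocess one subject and compare the recovered HbO with ground truth.

The chain is: channel pruning -> optical density (referenced to the
fasting baseline) -> motion-artifact detection -> wavelet correction ->
0.1 Hz low-pass -> MBLL inversion -> CBSI.
"""
import numpy as np

import fnirsglu as fg

config = fg.SyntheticConfig(n_subjects=1, rng_seed=3)
sub = fg.generate_cohort(config).subjects[0]

hemo = fg.run_preprocessing(sub.session())
print("stages run:", " -> ".join(hemo.provenance["stages"]))
print("channels pruned:", hemo.provenance["counts"]["channels_pruned"])
print(f"motion-flagged fraction: "
      f"{hemo.provenance['counts']['motion_flagged_fraction']:.4f}")

# the planted signal is the glucose-coupled HbO trend beta*(G - G_fast)
trend = sub.truth.glucose - sub.truth.fasting_level
for c in (7, 1):  # one coupled, one uncoupled channel
    r = np.corrcoef(hemo.dhbo[:, c - 1], trend)[0, 1]
    kind = "coupled" if sub.truth.betas[c - 1] > 0 else "uncoupled"
    print(f"channel {c:2d} ({kind:9s}): corr(recovered dHbO, glucose trend)"
          f" = {r:.3f}")
# The coupled channel's recovered HbO tracks the glucose excursion through
# the whole chain; the uncoupled channel contains only filtered
# physiological noise, uncorrelated with the trend.
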