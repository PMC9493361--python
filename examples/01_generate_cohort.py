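"""Generate a small synthetic EEG-fNIRS cohort and export it to disk.

Builds three subjects of paired resting-state recordings with known ground
truth (planted edge-performance correlations), writes EDF + SNIRF + a
performance table, and prints what was planted.
"""

import numpy as np

from neurocpm import CohortSpec, generate_cohort
from neurocpm.formats import save_cohort

spec = CohortSpec(n_subjects=3, duration_s=60.0, effect_r=0.8, seed=7)
subjects, truth = generate_cohort(spec)

out = save_cohort(subjects, truth, "scratch/example_cohort")
print(f"cohort written to {out}/")
for sub in subjects:
    print(f"  {sub.subject_id}: EEG {sub.eeg.data.shape} @ {sub.eeg.fs} Hz, "
          f"fNIRS {sub.fnirs.data.shape} @ {sub.fnirs.fs} Hz, "
          f"performance {sub.performance:.1f}%")

print("\nplanted edge weights (rows = subjects; these correlate with "
      "performance at effect_r = 0.8 in large cohorts):")
for (mod, i, j), w in truth.planted_edge_targets.items():
    print(f"  {mod} edge ({i},{j}): {np.round(w, 3)}")
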