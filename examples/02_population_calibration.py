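"""Latin-hypercube population of atrial ionic profiles, calibrated.

Samples 60 profiles with every conductance varied up to +/-50%, filters
them by action-potential biomarker windows at 1 Hz, and prints the
acceptance statistics and a reproducible subset.
"""

import atriatrials as at

pop = at.sample_population(60, seed=7)
accepted, report = at.calibrate_population(pop, n_beats=3)
print(f"sampled {len(pop)} profiles; accepted {len(accepted)} "
      f"({100 * len(accepted) / len(pop):.0f}%)")
rejected = report[~report.accepted]
if len(rejected):
    print("rejection reasons:")
    print(rejected.reasons.value_counts().to_string())

subset = at.select_subset(accepted, min(10, len(accepted)), seed=1)
print("\nrepresentative subset:", [p.profile_id for p in subset])
print("\nEach accepted profile is one virtual patient's atrial"
      " electrophysiology; the windows exclude only non-physiological"
      " extremes, keeping both sinus-rhythm-like and AF-remodelled cells.")
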