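"""Synthetic low-voltage-area (LVA) substrates of controlled extent.

Builds a parcellated atrial sheet and voltage maps at two of the study's
target LVA extents, printing the realized left-atrial and posterior-wall
fractions and the LVA patch statistics.
"""

import atriatrials as at
from atriatrials.synthetic_substrate import (POSTERIOR_LABELS, patch_areas,
                                             segment_fractions)

sheet = at.build_sheet((160, 120), dx=0.5)
print(f"sheet: {sheet.nx} x {sheet.ny} nodes at {sheet.dx} mm "
      f"({sheet.nx * sheet.dx / 10:.0f} x {sheet.ny * sheet.dx / 10:.0f} cm), "
      "13 LA segments + RA proxy")

for target, scale in [(0.222, 4.0), (0.576, 8.0)]:
    at.generate_voltage_map(sheet, at.LVAPattern(target, patch_scale_mm=scale,
                                                 seed=3))
    areas = patch_areas(sheet)
    print(f"\ntarget LA fraction {target:.1%} (patch scale {scale} mm):")
    print(f"  realized LA {at.lva_fraction(sheet, 'la'):.1%}, "
          f"posterior wall {at.lva_fraction(sheet, POSTERIOR_LABELS):.1%}, "
          f"{len(areas)} patches, mean {areas.mean():.0f} mm^2")

print("\nPer-segment report for the last map:")
print(segment_fractions(sheet).to_string(index=False))
print("\nBipolar voltage < 0.5 mV marks LVA; the RA proxy is always healthy,"
      "\nisolating the role of left-atrial structural remodelling.")
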