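# Default calibration windows for accepting sampled ionic profiles.
# Biomarkers are measured at 1 Hz pacing on the last paced beat.  The windows
# deliberately span both sinus-rhythm and AF-remodelled atrial phenotypes:
# they exclude only non-physiological extremes of the +/-50% conductance
# space, not the AF-prone profiles the study depends on.  Units: apd90 ms,
# rmp mV, amplitude mV.
ranges:
  apd90: [120.0, 450.0]
  rmp: [-90.0, -70.0]
  amplitude: [85.0, 135.0]
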