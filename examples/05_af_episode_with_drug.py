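"""A full AF episode: spiral-wave induction, drug administration, pseudo-ECG.

Runs one AF-prone virtual atria (high I_K1/I_to/I_NaK, low I_CaL) on a
22% -LVA substrate: six spiral re-entries are imposed, the episode runs to a
2.5 s desk-scale horizon, and a flecainide dose is administered in a second
run 0.75 s in.  Prints sustenance, the lead-V1 dominant frequency and the
drug outcome.  Takes a few minutes on one core.
"""

import atriatrials as at

# substrate and conductivity calibrated for an 80 cm/s bulk CV on this grid
sigma, cv = at.calibrate_conductivity(80.0, at.ConductanceScaling(),
                                      at.desk_params(5.0))
params = at.desk_params(sigma)
print(f"calibrated bulk conductivity: {sigma:.2f} mS/cm (CV {cv:.1f} cm/s)")

sheet = at.build_sheet((160, 120), dx=0.5)
at.generate_voltage_map(sheet, at.LVAPattern(0.222, patch_scale_mm=4.0, seed=7))
profile = at.ConductanceScaling(g_K1=1.5, g_to=1.5, g_NaK=1.5, g_CaL=0.5,
                                profile_id="af-prone")

init = at.init_spirals(sheet, at.SpiralInitSpec.default(sheet), profile)
electrodes = at.default_electrodes(sheet)

control = at.run_episode(sheet, params, profile, init[:2], horizon=2500.0,
                         electrodes=electrodes, sample_rate_hz=500.0)
print(f"control episode: sustained={control.sustained}")
if control.sustained:
    leads = at.episode_leads(control)
    df = at.dominant_frequency(leads.lead("V1")[250:], leads.fs)
    print(f"lead V1 dominant frequency: {df:.1f} Hz (fibrillatory f-waves)")

drug = at.get_drug("flecainide", "2uM", "ina70")
treated = at.run_episode(sheet, params, profile, init[:2], horizon=2500.0,
                         drug_event=at.DrugEvent(drug, time_ms=750.0))
outcome = "terminated AF" if not treated.sustained else "AF persisted"
print(f"{drug.label} at 750 ms: {outcome}"
      + (f" (termination at {treated.termination_time:.0f} ms)"
         if not treated.sustained else ""))
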