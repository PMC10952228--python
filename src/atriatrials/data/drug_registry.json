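{
  "description": "Fractional ionic-current block of the 12 anti-arrhythmic treatments (pore-block models). Currents not listed are unblocked.",
  "treatments": [
    {"name": "amiodarone", "dose": "1.5uM", "variant": "acute",
     "block": {"I_Kr": 0.40, "I_Ks": 0.30, "I_CaL": 0.30, "I_NCX": 0.30, "I_Na": 0.20}},
    {"name": "amiodarone", "dose": "3.0uM", "variant": "acute",
     "block": {"I_Kr": 0.65, "I_to": 0.30, "I_K1": 0.20, "I_Ks": 0.50, "I_CaL": 0.65, "I_NaK": 0.10, "I_NCX": 0.50, "I_Na": 0.40}},
    {"name": "amiodarone", "dose": "3.0uM", "variant": "chronic-a",
     "block": {"I_Kr": 0.65, "I_to": 0.30, "I_K1": 0.20, "I_Ks": 0.50, "I_CaL": 0.0, "I_NaK": 0.10, "I_NCX": 0.50, "I_Na": 0.40}},
    {"name": "amiodarone", "dose": "3.0uM", "variant": "chronic-b",
     "block": {"I_Kr": 0.65, "I_to": 0.30, "I_K1": 0.40, "I_Ks": 0.50, "I_CaL": 0.0, "I_NaK": 0.25, "I_NCX": 0.50, "I_Na": 0.40}},
    {"name": "amiodarone", "dose": "3.0uM", "variant": "chronic-c",
     "block": {"I_Kr": 0.65, "I_to": 0.30, "I_K1": 0.50, "I_Ks": 0.50, "I_CaL": 0.0, "I_NaK": 0.25, "I_NCX": 0.50, "I_Na": 0.40}},
    {"name": "flecainide", "dose": "1uM", "variant": "standard",
     "block": {"I_Kr": 0.30, "I_Na": 0.40}},
    {"name": "flecainide", "dose": "2uM", "variant": "ina60",
     "block": {"I_Kur": 0.30, "I_Kr": 0.60, "I_to": 0.15, "I_CaL": 0.10, "I_Na": 0.60}},
    {"name": "flecainide", "dose": "2uM", "variant": "ina70",
     "block": {"I_Kur": 0.30, "I_Kr": 0.60, "I_to": 0.15, "I_CaL": 0.10, "I_Na": 0.70}},
    {"name": "vernakalant", "dose": "10uM", "variant": "standard",
     "block": {"I_Kur": 0.40, "I_Kr": 0.30, "I_to": 0.40, "I_Na": 0.10}},
    {"name": "vernakalant", "dose": "30uM", "variant": "standard",
     "block": {"I_Kur": 0.70, "I_Kr": 0.60, "I_to": 0.60, "I_CaL": 0.20, "I_Na": 0.30}},
    {"name": "digoxin", "dose": "5nM", "variant": "standard",
     "block": {"I_Kr": 0.40, "I_NaK": 0.30}},
    {"name": "digoxin", "dose": "10nM", "variant": "standard",
     "block": {"I_Kr": 0.50, "I_NaK": 0.60}}
  ]
}
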