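# atriatrials

In-silico atrial-fibrillation (AF) drug trials at desk scale, for
computational electrophysiologists who want to study how a patient's ionic
current make-up and the extent of left-atrial low-voltage areas (LVA)
jointly decide whether AF sustains and which anti-arrhythmic drug works.

Clinically, anti-arrhythmic drug choice for AF is largely trial-and-error.
Simulation cohorts suggest the decisive patient features are the inward
currents — L-type Ca²⁺ (I_CaL) and fast Na⁺ (I_Na) — together with the
LVA burden: AF sustains in atria with short refractoriness and high
excitability (low I_CaL, high I_K1/I_to/I_NaK), large LVA push fast drivers
into the healthy right atrium while small patchy LVA anchor rotors at their
borders, and the drug that terminates AF tracks the inward-current profile
(flecainide for down-regulated I_Na; for up-regulated I_Na, vernakalant
when I_CaL is high, amiodarone when it is low). This package implements
that entire pipeline as a self-contained, testable artifact.

## What is inside

- **`cell_population`** — the Courtemanche–Ramirez–Nattel (CRN) human
  atrial action-potential model with 12 scalable conductances; Latin
  hypercube populations (±50% density variation), biomarker calibration,
  and an S1–S2 effective-refractory-period (ERP) protocol that captures
  post-repolarization refractoriness.
- **`synthetic_substrate`** — 2-D atrial sheets: 13 left-atrial segments
  (1–4 = posterior wall) plus a healthy right-atrial proxy; Gaussian-field
  LVA patterns hitting target extents exactly (bipolar voltage < 0.5 mV).
- **`tissue_sim`** — anisotropic monodomain solver (numba) with LVA
  remodelling (30% slower, 8:1 anisotropy, I_CaL/I_Na/I_K1 down-regulated),
  conduction-velocity calibration to 80 cm/s, six imposed spiral-wave
  re-entries, drug administration mid-episode, sustenance classification.
- **`drug_library`** — 12 pore-block treatments (vernakalant, amiodarone
  acute/chronic, flecainide, digoxin at clinical concentrations), applied
  as multiplicative conductance block; trial efficacy accounting.
- **`ecg_analysis`** — 8-lead pseudo-ECG (infinite-conductor dipole-layer
  integral) and five fibrillatory biomarkers: dominant frequency,
  organization index, spectral entropy, sample entropy, relative harmonic
  energy.
- **`frequency_maps`** — per-node dominant-frequency maps, 10th/90th
  percentile discretization, cross-episode high-frequency density maps.
- **`trial_stats`** — cohort assembly, sustenance/drug-response grouping,
  Wilcoxon rank-sum comparisons (exact on small samples), and the
  inward-current treatment-stratification rule.

The monodomain model is dVm/dt = ∇·(D∇Vm) − I_ion(Vm, y)/Cm with CRN
kinetics per node; drugs multiply each targeted maximal conductance g_X by
(1 − block_X). See `docs/methods.md` for the full model account, numerical
choices and limitations.

## A worked example

```python
import atriatrials as at

baseline = at.ConductanceScaling()
prone = baseline.scaled(g_CaL=0.5, g_K1=1.5, g_to=1.5, g_NaK=1.5,
                        profile_id="af-prone")
for p in (baseline, prone):
    bm = at.compute_biomarkers(p, pacing_cl=1000.0, n_beats=4)
    print(p.profile_id, round(bm.rmp, 1), round(bm.apd90), round(bm.erp))
```

prints

```
baseline -80.9 298 320
af-prone -84.0 128 130
```

— the AF-remodelled cell rests ~3 mV more negative and repolarizes in 128
ms instead of 298 ms, with the ERP tracking it; this is the short
refractoriness that lets re-entry persist in tissue. Applying drugs to a
profile and re-measuring (`examples/04_drugs_and_refractoriness.py`):

```
flecainide:1uM:standard      shift     +35 ms
flecainide:2uM:ina60         shift     +90 ms
flecainide:2uM:ina70         shift    +inf ms   (complete block)
digoxin:5nM:standard         shift     +60 ms
digoxin:10nM:standard        shift    +105 ms
```

ERP prolongation grows with the blocked I_Na or I_NaK fraction — the
mechanism behind dose-ordered termination efficacy. The `examples/`
directory walks through every capability one script at a time, from
single cells (`01`) up to a full AF episode with mid-episode flecainide
administration and the pseudo-ECG dominant frequency (`05`), frequency
maps of a rotor (`06`), and cohort statistics (`07`).

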