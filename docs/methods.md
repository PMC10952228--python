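# Methods

`atriatrials` is a desk-scale in-silico trial pipeline for atrial
fibrillation (AF) pharmacology. It combines five model layers: a population
of human atrial cardiomyocyte models with ionic-current variability, a
synthetic low-voltage-area (LVA) substrate generator, a 2-D monodomain
solver with spiral-wave AF induction and pore-block drug administration,
pseudo-ECG/frequency-map analysis, and cohort-level nonparametric
statistics with a treatment-stratification rule. This note documents the
models, the numerical choices, and what the desk-scale reduction does and
does not preserve.

## Cellular electrophysiology

The membrane model is the Courtemanche–Ramirez–Nattel (CRN) human atrial
action potential: 21 states (voltage, 15 gates, intracellular Na+/K+/Ca2+
and two sarcoplasmic-reticulum Ca2+ compartments), with baseline parameters
taken verbatim from the published model. Twelve maximal conductances and
fluxes are scalable by dimensionless factors (baseline = 1):

| factor | current | CRN baseline |
|---|---|---|
| g_Na | fast Na+ | 7.8 nS/pF |
| g_K1 | inward rectifier K+ | 0.09 nS/pF |
| g_to | transient outward K+ | 0.1652 nS/pF |
| g_Kur | ultrarapid delayed rectifier | 0.005 + 0.05/(1+exp(−(V−15)/13)) nS/pF |
| g_Kr | rapid delayed rectifier | 0.029411765 nS/pF |
| g_Ks | slow delayed rectifier | 0.12941176 nS/pF |
| g_CaL | L-type Ca2+ | 0.12375 nS/pF |
| g_NaK | Na+/K+ pump | 0.59933874 pA/pF |
| g_NCX | Na+/Ca2+ exchanger | 1600 pA/pF |
| g_rel / g_leak / g_up | SR release / leak / uptake | 30 ms⁻¹ / 0.005 mM·ms⁻¹ / 0.005 mM·ms⁻¹ |

An absolute current density is always `factor x baseline` (the table is the
conversion key when densities are reported in S/mF ≡ nS/pF).

Integration is Rush–Larsen for all gates and forward Euler for voltage and
concentrations, dt = 0.02 ms for single cells (0.005 ms when maximum
accuracy is wanted; the scheme is first-order and converges smoothly). A
fully independent re-implementation of the equations (plain-Python RHS on
scipy's stiff LSODA solver) lives in the test suite as an oracle; at 1 Hz
pacing the two agree to < 0.1 mV RMS over an action potential and < 1 ms in
APD90.

**Populations.** Profiles are drawn by Latin hypercube sampling, each factor
stratified over [0.5, 1.5] (densities varied up to ±50%). Calibration
accepts profiles whose 1 Hz biomarkers fall in shipped windows (APD90
120–450 ms, RMP −90…−70 mV, amplitude 85–135 mV). The windows are
deliberately wide — they span sinus-rhythm and AF-remodelled phenotypes and
exclude only non-physiological extremes; users can override them with their
own experimental ranges. A fixed-seed random subset provides the working
cohort.

**ERP protocol.** Refractoriness is measured by capture, not APD: an S1
train of 8 beats at CL 600 ms, then an S2 whose coupling interval is
bisected to 5 ms resolution; capture requires recovery below −40 mV at S2
onset and an overshooting response. Measuring by capture includes
post-repolarization refractoriness, which is what makes Na+-channel block
prolong ERP far beyond APD. A profile that loses S2 capture entirely under
drug is flagged "complete block" (shift = +inf). One caveat documented
here: with 65% I_Kr and 50% I_Ks block (acute amiodarone 3 µM), the slow
S1 rate makes K+-block APD prolongation dominate the I_CaL-block
shortening (reverse rate dependence), giving a small positive median shift
where fast-rate measurements would give ~0 or negative; the 1.5 µM acute
dose shows the expected negative shift.

## Synthetic LVA substrates

The substrate is a rectangular sheet (node-centred, row-major): the left
60% of columns is the left-atrial (LA) zone, parcellated into 13 fixed
rectangular segments with segments 1–4 forming the posterior-wall stripe;
the right 40% is a structurally-healthy right-atrial (RA) proxy. This
two-zone reduction keeps the one anatomical asymmetry the study's mechanism
needs — LVA confined to the LA, healthy RA — while dropping true atrial
geometry. Fiber angles are a smooth deterministic field (default: a gentle
0.35 rad sinusoidal rotation, 40 mm wavelength).

LVA patterns are Gaussian-smoothed white-noise fields thresholded at the
quantile that realizes the target LA fraction (posterior and non-posterior
LA thresholded separately when a posterior target is given); the smoothing
length is the patch scale, so small/patchy and large/confluent regimes are
both reachable. Bipolar voltage is mapped so LVA nodes fall strictly below
the 0.5 mV binarization threshold and healthy nodes above it; the RA proxy
is always ≥ 0.5 mV. Quantile thresholding makes the realized fraction exact
to grid discreteness (well inside ±2 percentage points).

What the generator does **not** emulate: real scar topology and transmural
structure, border-zone gradients (LVA is uniform, matching the modelling
choice it reproduces), registration to a patient anatomy, and
shape/size variability. Conclusions from these substrates are mechanistic
and directional, not patient-specific.

## Monodomain tissue model

dVm/dt = ∇·(D∇Vm) − I_ion − I_stim on the sheet, with
D = σ/(χ·Cm) (χ = 1400 cm⁻¹, Cm = 1 µF/cm²) and an anisotropic tensor
aligned with the fiber field (bulk conductivity anisotropy 4:1). Inside
LVA: conductivity ×0.70, anisotropy 8:1, and multiplicative ionic
down-regulation on top of the profile's factors — g_CaL ×0.5, g_Na ×0.6,
g_K1 ×0.5 by default (a ×0.4 g_Na variant is available as the
`lva_scheme="50-60-50"` switch, since both reductions appear in the source
modelling literature).

**Numerics.** Explicit 9-point anisotropic diffusion stencil
(flux-conservative in the axial terms, centred mixed terms, no-flux
boundaries by mirroring, Dxy zeroed on the boundary ring), Rush–Larsen
gates via voltage-indexed lookup tables (0.02 mV resolution), forward Euler
voltage/concentrations, Nernst potentials refreshed every 25 steps. An
a-priori stability check enforces dt ≤ dx²/4D. Default resolution dx =
0.15 mm, dt = 0.01 ms: at the 80 cm/s operating point CV changes 2.0% on
dx-halving and 0.9% on dt-halving, and CV scales as √σ within 5%.

**Conduction-velocity calibration.** Longitudinal conductivity is bisected
until a planar wave in a fiber-aligned strand travels at the target 80 cm/s
(tolerance 2%). Calibration is always done at the grid the simulation will
use, so the bulk CV target holds exactly where it matters.

**Desk-scale cohort grid.** Whole-cohort AF simulations use an 8 × 6 cm
sheet (160 × 120 nodes, dx = 0.5 mm, dt = 0.05 ms) with σ calibrated at
that grid (≈ 4.95 mS/cm). The coarse grid under-resolves the depolarization
front, which would bias CV if σ were carried over from a fine grid;
calibrating at the working grid absorbs that error into σ. Episode horizons
are 2.5 s with drug administration 0.75 s in — the same 2:5 split of
pre-drug to post-drug observation as a 7 s episode with administration at
2 s, scaled to desk cost. The sustenance rule is: an episode is sustained
iff some node activates within the final 250 ms of the horizon; earlier
silence of 250 ms terminates the run (activations are upstroke crossings of
−40 mV with a 40 ms dead time).

**AF induction.** Six spiral re-entries are imposed as initial conditions,
three per zone, adjacent re-entries counter-rotating. The phase-distribution
method assigns each node a state from a single-cell limit cycle: the sheet
is partitioned into territories by nearest core (within each zone), and the
phase is chirality × atan2 about the territory's core. The library cycle
length is the fastest cycle the profile captures 1:1 (tried at 200, 250,
300, 400, 500 ms), so short-refractoriness profiles start with AF-like
short wavelengths while long-APD profiles get physiological (and therefore
fragile) re-entries — no per-profile hand-tuning. Territory seams are
deliberate discontinuities; they seed the secondary wavelets that make the
initial condition fibrillation-like. Phase-singularity bookkeeping
(winding numbers on 2 × 2 plaquettes, seam plaquettes excluded) confirms
exactly the six imposed defects with the requested chiralities at t = 0.

## Drug models

Treatments are simple pore-block models: each targeted current's factor is
multiplied by (1 − block), applied instantaneously at the administration
time; block fractions are fixed (no rate or state dependence — the model's
stated limitation) and compose commutatively with LVA remodelling. The
registry ships 12 treatments (vernakalant 10/30 µM; amiodarone 1.5 µM
acute, 3 µM acute, and three 3 µM chronic sub-variants a/b/c with
progressive I_K1 20/40/50% and I_NaK 10/25/25% block and no I_CaL block;
flecainide 1 µM and 2 µM at 60% or 70% I_Na block, the higher level
reflecting block observed at fibrillatory rates; digoxin 5/10 nM) as a
checksum-validated JSON file. Efficacy is the percentage of
control-sustained episodes rendered non-sustained by the drug.

## ECG and frequency analysis

The pseudo-ECG treats the sheet as a current source in an infinite
homogeneous conductor: φ(e) ∝ −∫ ∇Vm·∇(1/r) dA, evaluated with
central-difference gradients at nine fixed virtual electrodes 50–80 mm off
the sheet (three limb proxies and V1–V6), from which leads I, II and V1–V6
are formed against the Wilson terminal. Geometry is a documented
convention, not a torso model. Two consequences worth knowing: the
potential of this in-plane dipole layer is even under reflection across the
sheet plane (it flips sign across a wavefront instead), and a compact
depolarized region decays as r⁻³ in the far field because its bounding
dipole loop has no net moment.

Per-lead biomarkers: dominant frequency DF (Welch PSD, Hann, 4 s segments
or the signal length if shorter, 50% overlap, band 3–15 Hz), organization
index OI (power within ±0.5 Hz of DF and its first two harmonics over
in-band power), normalized Shannon spectral entropy, sample entropy (m = 2,
r = 0.2·SD, Chebyshev, self-matches excluded, computed at 250 Hz), and
relative harmonic energy (harmonics excluding the DF peak, over in-band
power). OI/SE/RHE formula variants are documented defaults from the
fibrillatory-wave analysis literature.

Per-node DF maps use the inverse mean activation cycle length (≥ 4
activations required for validity; invalid nodes are flagged, never zeroed)
— equivalent to the spectral estimate for the near-periodic activations of
sustained AF and much cheaper than storing full voltage histories. Each
sustained episode's map is discretized at its own 10th/90th percentiles
(low ⇔ DF ≤ p10, high ⇔ DF ≥ p90, all-equal maps are all-mid), and
high-frequency categories are summed across episodes of one substrate into
density maps.

## Trial statistics

The cohort table is (profile × substrate × treatment) with control rows for
every treated row. Sustenance groups cut the per-profile sustained-substrate
fraction at 25%/75%; drug-response groups at 100% / >50% / ≤50%.
Two-group comparisons report Kolmogorov–Smirnov normality, the two-sided
Wilcoxon rank-sum p (exact by enumeration-equivalent computation when both
n ≤ 10 without ties, asymptotic otherwise; two all-tied groups return
p = 1 by convention), medians with linear-interpolation quartiles, and the
rank-biserial effect size. Raw p-values are the default (two significance
tiers, 0.05 and 0.001); a Benjamini–Hochberg helper is provided but not
applied. The stratification rule is: I_Na not up-regulated (factor ≤ 1 +
dead-band) → flecainide; otherwise vernakalant if I_CaL ≥ 1 − dead-band,
else amiodarone. The dead-band default is 0 (baseline is the boundary; ties
resolve to flecainide for I_Na and to the high branch for I_CaL).

## What desk scale shows — and what it cannot

The package's tests and acceptance checks are parameter-exact where the
source numbers are exact (drug registry, LVA remodelling factors, CV
target), oracle-exact where an independent implementation exists (CRN
traces, sample entropy, rank-sum), and directional where the original
evidence is cohort-scale 3-D simulation: AF-prone vs AF-resistant
sustenance, I_K1-driven DF elevation, dose-ordered ERP shifts, rotor cores
as low-DF regions, and RA-concentrated high-frequency density under large
LVA. An 8 × 6 cm two-zone sheet cannot reproduce cohort efficacy
percentages, anatomical driver locations, or ECG morphology; those require
the full bi-atrial anatomy and the original patient voltage maps. Episode
counts and grid sizes here were chosen to make the full pipeline run on a
single CPU core in minutes; all directional claims were designed to be
robust at that size, not tuned to it.

## Known limitations

- Pore-block pharmacology only; rate-dependent (state-dependent) block is
  out of scope, so drugs like flecainide apply their fast-rate block level
  uniformly.
- Single-cell ERP at S1 CL 600 ms; tissue-level refractoriness during AF is
  shorter and more drug-sensitive (see the acute-amiodarone caveat above).
- The 2-D sheet has no pulmonary veins, no ectopic triggering, no regional
  electrophysiology beyond the LA/RA zone table, and no registered anatomy.
- Pseudo-ECG amplitudes are in arbitrary gain; only spectral/entropy
  content is meaningful.
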