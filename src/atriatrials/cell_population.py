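"""Populations of atrial cardiomyocyte models with ionic-current variability.

A virtual patient's electrophysiology is a :class:`ConductanceScaling`: twelve
dimensionless multipliers applied to the baseline maximal conductances/fluxes
of the CRN human atrial model (I_Kur, I_Kr, I_Ks, I_to, I_K1, I_CaL, I_Na,
Na+/K+ pump, Na+/Ca2+ exchanger, and SR release/leak/uptake).  Populations are
drawn by Latin hypercube sampling with each factor varied up to +/-50% around
baseline, then calibrated by accepting only profiles whose action-potential
biomarkers fall inside physiological ranges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy.stats import qmc

from . import _crn
from ._crn import FACTOR_NAMES, N_FACTORS, REST_STATE, STATE_NAMES
from .errors import IntegrationError, ValidationError

DEFAULT_BOUNDS = (0.5, 1.5)

# S1-S2 effective-refractory-period protocol (module standard)
ERP_S1_CL = 600.0       # ms
ERP_S1_BEATS = 8
ERP_RESOLUTION = 5.0    # ms
ERP_SCAN_MAX = 1000.0   # ms, longest coupling interval tried
STIM_AMP = -20.0        # pA/pF (negative = depolarizing)
STIM_DUR = 2.0          # ms


@dataclass
class ConductanceScaling:
    """Multiplicative ionic profile of one virtual patient (baseline = 1.0)."""

    g_Kur: float = 1.0
    g_Kr: float = 1.0
    g_Ks: float = 1.0
    g_to: float = 1.0
    g_K1: float = 1.0
    g_CaL: float = 1.0
    g_Na: float = 1.0
    g_NaK: float = 1.0
    g_NCX: float = 1.0
    g_rel: float = 1.0
    g_leak: float = 1.0
    g_up: float = 1.0
    profile_id: str = "baseline"

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FACTOR_NAMES], dtype=np.float64)

    @classmethod
    def from_array(cls, factors, profile_id: str = "") -> "ConductanceScaling":
        factors = np.asarray(factors, dtype=float)
        if factors.shape != (N_FACTORS,):
            raise ValidationError(f"expected {N_FACTORS} factors, got {factors.shape}")
        return cls(**dict(zip(FACTOR_NAMES, factors.tolist())), profile_id=profile_id)

    def scaled(self, **factors) -> "ConductanceScaling":
        """Copy with some factors replaced (keyword per factor name)."""
        return replace(self, **factors)


@dataclass
class CellState:
    """Complete CRN state vector plus simulation time."""

    y: np.ndarray = field(default_factory=lambda: REST_STATE.copy())
    t: float = 0.0

    @property
    def voltage(self) -> float:
        return float(self.y[0])

    def copy(self) -> "CellState":
        return CellState(self.y.copy(), self.t)


@dataclass
class APBiomarkers:
    """Action-potential biomarkers of the last paced beat."""

    rmp: float          # resting membrane potential, mV
    peak: float         # peak voltage, mV
    amplitude: float    # mV
    apd50: float        # ms
    apd90: float        # ms
    erp: float          # ms (nan if not measured, inf if inexcitable under S2)
    dvdt_max: float     # max upstroke velocity, mV/ms (== V/s)
    excitable: bool = True

    def as_dict(self) -> dict:
        return {
            "rmp": self.rmp, "peak": self.peak, "amplitude": self.amplitude,
            "apd50": self.apd50, "apd90": self.apd90, "erp": self.erp,
            "dvdt_max": self.dvdt_max, "excitable": self.excitable,
        }


def step_cell(state: CellState, scaling: ConductanceScaling, dt: float,
              i_stim: float = 0.0) -> CellState:
    """Advance a single cell by one time step of ``dt`` ms.

    ``i_stim`` is in pA/pF (negative = depolarizing).  Deterministic; raises
    :class:`IntegrationError` naming the offending variable if the state
    becomes non-finite.
    """
    if not (0.0 < dt <= 0.05):
        raise ValidationError(f"dt must be in (0, 0.05] ms, got {dt}")
    bad_in = np.flatnonzero(~np.isfinite(state.y))
    if bad_in.size:
        raise IntegrationError(
            f"non-finite state variable '{STATE_NAMES[int(bad_in[0])]}' "
            f"at t={state.t:.3f} ms")
    new = state.copy()
    try:
        _crn.step_cell(new.y, scaling.as_array(), dt, i_stim)
    except (ZeroDivisionError, ValueError, OverflowError) as exc:
        raise IntegrationError(
            f"integration failure at t={state.t:.3f} ms: {exc}") from exc
    if not np.all(np.isfinite(new.y)):
        bad = STATE_NAMES[int(np.flatnonzero(~np.isfinite(new.y))[0])]
        raise IntegrationError(
            f"non-finite state variable '{bad}' at t={state.t + dt:.3f} ms")
    new.t = state.t + dt
    return new


def sample_population(n: int, bounds=None, seed: int = 0) -> list[ConductanceScaling]:
    """Latin-hypercube sample of ``n`` ionic profiles.

    Each of the 12 factors is stratified into ``n`` equal-width bins occupied
    exactly once.  ``bounds`` maps factor names to (lo, hi) intervals and
    defaults to (0.5, 1.5) for every factor, i.e. current densities varied up
    to +/-50%.  Reproducible for a fixed ``seed``.
    """
    if n < 1:
        raise ValidationError(f"population size must be >= 1, got {n}")
    lo = np.full(N_FACTORS, DEFAULT_BOUNDS[0])
    hi = np.full(N_FACTORS, DEFAULT_BOUNDS[1])
    if bounds:
        for name, (a, b) in bounds.items():
            if name not in FACTOR_NAMES:
                raise ValidationError(f"unknown factor '{name}'")
            i = FACTOR_NAMES.index(name)
            lo[i], hi[i] = a, b
    if np.any(lo >= hi):
        raise ValidationError("inverted bounds (lo >= hi)")
    sampler = qmc.LatinHypercube(d=N_FACTORS, seed=seed)
    unit = sampler.random(n)
    samples = qmc.scale(unit, lo, hi)
    return [ConductanceScaling.from_array(row, profile_id=f"p{i:04d}")
            for i, row in enumerate(samples)]


def _beat_metrics(ts, vs, stim_time):
    """RMP / peak / APDs from one recorded beat (stimulus at ``stim_time``)."""
    pre = vs[ts <= stim_time]
    rmp = float(pre[-1]) if pre.size else float(vs[0])
    post = ts >= stim_time
    t, v = ts[post], vs[post]
    peak = float(v.max())
    amp = peak - rmp
    dv = np.gradient(v, t)
    act = float(t[np.argmax(dv)])
    apd = {}
    for frac in (0.5, 0.9):
        thr = peak - frac * amp
        idx = np.flatnonzero((v < thr) & (t > act))
        apd[frac] = float(t[idx[0]] - act) if idx.size else math.nan
    return rmp, peak, amp, apd[0.5], apd[0.9], act


def _s2_captures(snapshot, g, dt, ci):
    """True if an S2 delivered ``ci`` ms after the last S1 captures.

    Capture requires the membrane to have recovered below -40 mV at S2 onset
    and the premature response to overshoot 0 mV (the module's capture
    criterion, which includes post-repolarization refractoriness).
    """
    y = snapshot.copy()
    # deliver the final S1 at t=0, then run freely up to the coupling interval
    _crn.run_paced(y, g, dt, ci, 1e9, STIM_AMP, STIM_DUR, 0.0, max(ci, 1.0))
    if y[0] > -40.0:        # still depolarized: refractory by definition
        return False
    _, vs2, _ = _crn.run_paced(y, g, dt, 300.0, 1e9, STIM_AMP, STIM_DUR,
                               0.0, 1.0)
    return float(vs2.max()) > 0.0


def measure_erp(scaling: ConductanceScaling, dt: float = 0.02,
                s1_cl: float = ERP_S1_CL, n_s1: int = ERP_S1_BEATS) -> float:
    """Effective refractory period from an S1-S2 protocol.

    S1 train of ``n_s1`` beats at cycle length ``s1_cl``; S2 coupling
    interval scanned at 5 ms resolution (bisection; capture assumed monotone
    in the interval).  ERP is the shortest captured interval.  Returns
    ``inf`` when no S2 up to 1000 ms captures (complete block) and ``nan``
    when the S1 train itself fails to capture (inexcitable profile).
    """
    g = scaling.as_array()
    y = REST_STATE.copy()
    # S1 train minus the final beat; snapshot right before the last S1
    ts, vs, _ = _crn.run_paced(y, g, dt, s1_cl * (n_s1 - 1),
                               s1_cl, STIM_AMP, STIM_DUR, 0.0, 1.0)
    if float(vs.max()) < 0.0:
        return math.nan
    snapshot = y.copy()
    lo, hi = 20.0, ERP_SCAN_MAX
    if not _s2_captures(snapshot, g, dt, hi):
        return math.inf
    if _s2_captures(snapshot, g, dt, lo):
        return lo
    while hi - lo > ERP_RESOLUTION:
        mid = 0.5 * (lo + hi)
        if _s2_captures(snapshot, g, dt, mid):
            hi = mid
        else:
            lo = mid
    return float(ERP_RESOLUTION * math.ceil(hi / ERP_RESOLUTION))


def compute_biomarkers(scaling: ConductanceScaling, pacing_cl: float = 1000.0,
                       n_beats: int = 4, dt: float = 0.02,
                       include_erp: bool = True) -> APBiomarkers:
    """AP biomarkers measured on the last of ``n_beats`` paced beats.

    A profile whose S1 stimuli fail to elicit an overshooting action
    potential is returned with ``excitable=False`` rather than raising.
    """
    if pacing_cl < 300.0:
        raise ValidationError(f"pacing_cl must be >= 300 ms, got {pacing_cl}")
    if n_beats < 2:
        raise ValidationError(f"n_beats must be >= 2, got {n_beats}")
    g = scaling.as_array()
    y = REST_STATE.copy()
    _crn.run_paced(y, g, dt, pacing_cl * (n_beats - 1), pacing_cl,
                   STIM_AMP, STIM_DUR, 0.0, pacing_cl)
    ts, vs, dvdt = _crn.run_paced(y, g, dt, pacing_cl, pacing_cl,
                                  STIM_AMP, STIM_DUR, 0.0, 0.5)
    rmp, peak, amp, apd50, apd90, _ = _beat_metrics(ts, vs, 0.0)
    if peak < 0.0:
        return APBiomarkers(rmp=rmp, peak=peak, amplitude=amp, apd50=math.nan,
                            apd90=math.nan, erp=math.nan, dvdt_max=dvdt,
                            excitable=False)
    erp = measure_erp(scaling, dt=dt) if include_erp else math.nan
    return APBiomarkers(rmp=rmp, peak=peak, amplitude=amp, apd50=apd50,
                        apd90=apd90, erp=erp, dvdt_max=dvdt)


def default_calibration_ranges() -> dict:
    """Shipped biomarker acceptance windows (see data/calibration_ranges.yaml)."""
    text = resources.files("atriatrials.data").joinpath(
        "calibration_ranges.yaml").read_text()
    return yaml.safe_load(text)["ranges"]


def calibrate_population(profiles, biomarker_ranges=None, pacing_cl: float = 1000.0,
                         n_beats: int = 4, dt: float = 0.02):
    """Filter profiles by AP biomarkers.

    ``biomarker_ranges`` maps biomarker name -> (min, max); defaults to the
    shipped ranges.  Returns ``(accepted, report)`` where ``report`` is a
    DataFrame with one row per profile, its biomarkers, acceptance flag and
    failure reasons.  Inexcitable profiles are always rejected.
    """
    if biomarker_ranges is None:
        biomarker_ranges = default_calibration_ranges()
    if not biomarker_ranges:
        raise ValidationError("empty calibration range set")
    need_erp = "erp" in biomarker_ranges
    rows = []
    accepted = []
    for p in profiles:
        bm = compute_biomarkers(p, pacing_cl=pacing_cl, n_beats=n_beats, dt=dt,
                                include_erp=need_erp)
        reasons = []
        if not bm.excitable:
            reasons.append("inexcitable")
        else:
            for name, (lo, hi) in biomarker_ranges.items():
                val = getattr(bm, name)
                if not (lo <= val <= hi):
                    reasons.append(f"{name}={val:.1f} outside [{lo}, {hi}]")
        row = {"profile_id": p.profile_id, **bm.as_dict(),
               "accepted": not reasons, "reasons": "; ".join(reasons)}
        rows.append(row)
        if not reasons:
            accepted.append(p)
    return accepted, pd.DataFrame(rows)


def select_subset(profiles, n: int, seed: int = 0) -> list:
    """Random representative subset of ``n`` profiles (without replacement)."""
    if n > len(profiles):
        raise ValidationError(f"cannot select {n} from {len(profiles)} profiles")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(profiles), size=n, replace=False)
    return [profiles[i] for i in sorted(idx)]


def population_to_csv(profiles, path) -> None:
    pd.DataFrame([{"profile_id": p.profile_id,
                   **dict(zip(FACTOR_NAMES, p.as_array()))}
                  for p in profiles]).to_csv(path, index=False)


def population_from_csv(path) -> list[ConductanceScaling]:
    df = pd.read_csv(path)
    return [ConductanceScaling.from_array(row[list(FACTOR_NAMES)].to_numpy(float),
                                          profile_id=str(row["profile_id"]))
            for _, row in df.iterrows()]
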