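"""Pseudo-ECG forward computation and fibrillatory-wave biomarkers.

The extracellular potential at an electrode in an infinite homogeneous
volume conductor is the current-dipole integral over the sheet

    phi_e  ∝  - ∫ grad(Vm) . grad(1/r) dA,

evaluated on eight leads (I, II, V1-V6) formed from unipolar potentials at
fixed virtual electrode positions above the tissue plane.  Five biomarkers
quantify each lead during AF: dominant frequency (DF), organization index
(OI), normalized Shannon spectral entropy (SE), sample entropy (SaE) and
relative harmonic energy (RHE).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import UndefinedBiomarker, ValidationError

LEAD_NAMES = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")
DEFAULT_BAND = (3.0, 15.0)      # Hz, physiological AF band
WELCH_WINDOW_S = 4.0            # Welch segment length (s), Hann, 50% overlap
OI_HALF_WIDTH = 0.5             # Hz around DF and harmonics


@dataclass
class LeadSet:
    """Eight-lead pseudo-ECG sharing one time base."""

    data: np.ndarray            # (n_samples, 8)
    fs: float                   # Hz

    def __post_init__(self):
        if self.fs < 250.0:
            raise ValidationError(f"sampling rate must be >= 250 Hz, got {self.fs}")
        if self.data.ndim != 2 or self.data.shape[1] != len(LEAD_NAMES):
            raise ValidationError("lead data must be (n_samples, 8)")

    def lead(self, name: str) -> np.ndarray:
        return self.data[:, LEAD_NAMES.index(name)]

    def to_frame(self) -> pd.DataFrame:
        t = np.arange(self.data.shape[0]) / self.fs
        return pd.DataFrame(self.data, columns=list(LEAD_NAMES)).assign(time_s=t)


@dataclass
class ECGBiomarkers:
    df: float       # Hz
    oi: float       # [0, 1]
    se: float       # [0, 1]
    sae: float      # >= 0
    rhe: float      # [0, 1]


def default_electrodes(sheet) -> np.ndarray:
    """Nine unipolar electrode positions (mm): RA, LA, LL limb proxies and
    V1-V6 on a plane 50-80 mm above the sheet, loosely mimicking torso lead
    directions around the atria."""
    cx = 0.5 * sheet.nx * sheet.dx
    cy = 0.5 * sheet.ny * sheet.dx
    limb = [(cx - 90.0, cy - 70.0, 80.0),    # RA
            (cx + 90.0, cy - 70.0, 80.0),    # LA
            (cx + 30.0, cy + 110.0, 80.0)]   # LL
    chest = [(cx + (k - 2.5) * 16.0, cy + 12.0 * np.sin(0.6 * (k - 2.5)), 50.0)
             for k in range(6)]              # V1..V6
    return np.array(limb + chest)


def leads_from_unipolar(potentials: np.ndarray, fs: float) -> LeadSet:
    """Standard lead formation: I = LA-RA, II = LL-RA, Vi referenced to the
    Wilson central terminal (mean of the three limb potentials)."""
    if potentials.shape[1] != 9:
        raise ValidationError("expected 9 unipolar channels (RA, LA, LL, V1-V6)")
    ra, la, ll = potentials[:, 0], potentials[:, 1], potentials[:, 2]
    wct = (ra + la + ll) / 3.0
    cols = [la - ra, ll - ra] + [potentials[:, 3 + k] - wct for k in range(6)]
    return LeadSet(data=np.stack(cols, axis=1), fs=fs)


def unipolar_potentials(vframes: np.ndarray, dx: float, electrodes) -> np.ndarray:
    """Unipolar pseudo-potentials (n_frames, n_electrodes).

    Direct evaluation of the dipole-layer integral with central-difference
    voltage gradients; electrode z must be off the tissue plane.  Linear in
    the voltage field.
    """
    el = np.asarray(electrodes, float)
    if np.any(np.abs(el[:, 2]) < 1e-9):
        raise ValidationError("electrode lies in the tissue plane")
    nt, ny, nx = vframes.shape
    yy, xx = np.meshgrid(np.arange(ny) * dx, np.arange(nx) * dx, indexing="ij")
    gx = np.empty((len(el), ny, nx))
    gy = np.empty((len(el), ny, nx))
    for e, (ex, ey, ez) in enumerate(el):
        r = np.sqrt((ex - xx) ** 2 + (ey - yy) ** 2 + ez ** 2)
        gx[e] = (ex - xx) / r ** 3
        gy[e] = (ey - yy) / r ** 3
    pot = np.zeros((nt, len(el)))
    for k in range(nt):
        vy, vx = np.gradient(vframes[k].astype(float), dx)
        pot[k] = (-np.tensordot(gx, vx, axes=([1, 2], [0, 1]))
                  - np.tensordot(gy, vy, axes=([1, 2], [0, 1]))) * dx * dx
    return pot


def pseudo_ecg(vframes: np.ndarray, dx: float, electrodes, fs: float) -> LeadSet:
    """Eight-lead pseudo-ECG from a stored voltage history (n_frames, ny, nx)
    and the 9-electrode map of :func:`default_electrodes`."""
    el = np.asarray(electrodes, float)
    if len(el) != 9:
        raise ValidationError("lead formation expects 9 electrodes (RA, LA, LL, V1-V6)")
    return leads_from_unipolar(unipolar_potentials(vframes, dx, el), fs)


def _psd(x: np.ndarray, fs: float, band):
    x = np.asarray(x, float)
    if x.size < 4 or np.ptp(x) == 0.0:
        raise UndefinedBiomarker("signal too short or constant for spectral analysis")
    nperseg = min(len(x), int(round(WELCH_WINDOW_S * fs)))
    f, p = sps.welch(x - x.mean(), fs=fs, window="hann", nperseg=nperseg,
                     noverlap=nperseg // 2)
    sel = (f >= band[0]) & (f <= band[1])
    if not sel.any() or p[sel].sum() <= 0:
        raise UndefinedBiomarker("no in-band spectral power")
    return f, p, sel


def dominant_frequency(x, fs: float, band=DEFAULT_BAND) -> float:
    """Frequency (Hz) of maximum Welch PSD within ``band``."""
    f, p, sel = _psd(x, fs, band)
    return float(f[sel][np.argmax(p[sel])])


def organization_index(x, fs: float, band=DEFAULT_BAND) -> float:
    """In-band power within +/-0.5 Hz of the DF and its first two harmonics,
    over total in-band power."""
    f, p, sel = _psd(x, fs, band)
    df = f[sel][np.argmax(p[sel])]
    num = np.zeros_like(p)
    keep = np.zeros_like(f, bool)
    for h in (1, 2, 3):
        keep |= np.abs(f - h * df) <= OI_HALF_WIDTH
    return float(p[keep & sel].sum() / p[sel].sum())


def spectral_entropy(x, fs: float, band=DEFAULT_BAND) -> float:
    """Normalized Shannon entropy of the in-band PSD (0 = pure tone-like,
    1 = flat spectrum).  Constant input raises ``UndefinedBiomarker``."""
    f, p, sel = _psd(x, fs, band)
    q = p[sel] / p[sel].sum()
    q = q[q > 0]
    if q.size < 2:
        return 0.0
    return float(-(q * np.log(q)).sum() / np.log(len(p[sel])))


def relative_harmonic_energy(x, fs: float, band=DEFAULT_BAND) -> float:
    """Energy at the DF harmonics (excluding the DF peak itself) over total
    in-band energy."""
    f, p, sel = _psd(x, fs, band)
    df = f[sel][np.argmax(p[sel])]
    harm = np.zeros_like(f, bool)
    for h in (2, 3):
        harm |= np.abs(f - h * df) <= OI_HALF_WIDTH
    return float(p[harm & sel].sum() / p[sel].sum())


def sample_entropy(x, m: int = 2, r: float = 0.2) -> float:
    """SaE = -ln(A/B): conditional probability that templates of length m
    matching within ``r``*SD (Chebyshev distance, self-matches excluded)
    still match at length m+1."""
    x = np.asarray(x, float)
    n = len(x)
    if n < 100:
        raise ValidationError(f"sample entropy needs >= 100 samples, got {n}")
    tol = r * x.std()
    if tol == 0.0:
        return 0.0

    def count(mm):
        templ = np.lib.stride_tricks.sliding_window_view(x, mm)
        nt = templ.shape[0]
        c = 0
        for i in range(nt - 1):
            d = np.max(np.abs(templ[i + 1:] - templ[i]), axis=1)
            c += int((d <= tol).sum())
        return c

    b = count(m)
    a = count(m + 1)
    if b == 0:
        raise UndefinedBiomarker("no template matches at length m")
    if a == 0:
        return float(np.inf)
    return float(-np.log(a / b))


def lead_biomarkers(leads: LeadSet, band=DEFAULT_BAND, sae_m: int = 2,
                    sae_r: float = 0.2, sae_fs: float = 250.0) -> pd.DataFrame:
    """The five AF biomarkers for every lead; SaE computed on the signal
    decimated to ~250 Hz (clinical comparator rate)."""
    rows = []
    dec = max(1, int(round(leads.fs / sae_fs)))
    for k, name in enumerate(LEAD_NAMES):
        x = leads.data[:, k]
        try:
            bm = ECGBiomarkers(
                df=dominant_frequency(x, leads.fs, band),
                oi=organization_index(x, leads.fs, band),
                se=spectral_entropy(x, leads.fs, band),
                sae=sample_entropy(x[::dec], m=sae_m, r=sae_r),
                rhe=relative_harmonic_energy(x, leads.fs, band))
            rows.append({"lead": name, "df_hz": bm.df, "oi": bm.oi, "se": bm.se,
                         "sae": bm.sae, "rhe": bm.rhe})
        except UndefinedBiomarker:
            rows.append({"lead": name, "df_hz": np.nan, "oi": np.nan,
                         "se": np.nan, "sae": np.nan, "rhe": np.nan})
    return pd.DataFrame(rows)


def episode_leads(result) -> LeadSet:
    """LeadSet from an episode simulated with the default 9-electrode set."""
    if result.electrode_potentials is None or result.electrode_potentials.size == 0:
        raise ValidationError("episode was run without electrodes")
    return leads_from_unipolar(result.electrode_potentials, result.sample_rate_hz)
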