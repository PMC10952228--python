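"""Monodomain reaction-diffusion AF simulation on a substrate sheet.

The transmembrane voltage obeys the 2-D monodomain equation

    dVm/dt = div( D grad Vm ) - I_ion(Vm, y) - I_stim

with an anisotropic diffusivity tensor D aligned with the local fiber angle,
no-flux boundaries, CRN membrane kinetics per node, and D = sigma / (chi Cm).
LVA nodes carry 30% reduced conductivity, 8:1 anisotropy and additional
down-regulation of I_CaL / I_Na / I_K1 on top of the profile's own factors.
AF episodes are started from imposed spiral-wave re-entries (phase
distribution method) and classified as sustained when fibrillatory activity
persists to the episode horizon.

Numerics: forward Euler for voltage/concentrations and Rush-Larsen for the
gates, with voltage-dependent gate coefficients pre-tabulated at 0.02 mV
resolution; explicit 9-point anisotropic diffusion stencil with an a-priori
stability check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from numba import njit

from . import _crn
from .cell_population import ConductanceScaling, STIM_AMP, STIM_DUR
from .drug_library import DrugModel
from .errors import CalibrationFailure, IntegrationError, ValidationError
from .synthetic_substrate import SubstrateSheet

# LVA structural/ionic remodelling
LVA_CONDUCTIVITY_FACTOR = 0.70
LVA_ANISOTROPY_RATIO = 8.0
#: multiplicative ionic reductions in LVA nodes, by remodelling scheme:
#: (g_CaL, g_Na, g_K1) survive fractions
LVA_ION_SCHEMES = {
    "50-40-50": {"g_CaL": 0.5, "g_Na": 0.6, "g_K1": 0.5},
    "50-60-50": {"g_CaL": 0.5, "g_Na": 0.4, "g_K1": 0.5},
}

SUSTAIN_WINDOW_MS = 250.0       # no activation for this long => terminated
ACT_THRESHOLD_MV = -40.0
ACT_REFRACTORY_MS = 40.0        # dead time between recorded upstrokes
MAX_ACTIVATIONS = 128

_GATE_COLS = np.array([0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 14], dtype=np.int64)


@dataclass
class MonodomainParams:
    """Bulk tissue and solver parameters.

    ``sigma_l``/``sigma_t`` are the longitudinal/transverse conductivities of
    healthy bulk tissue in mS/cm (divided by chi*Cm to give diffusivity);
    defaults correspond to a ~4:1 conductivity anisotropy.  ``dt`` in ms,
    ``dx`` in mm.
    """

    sigma_l: float = 3.4        # mS/cm, calibrate with calibrate_conductivity
    sigma_t: float = None       # default sigma_l / anisotropy_ratio
    anisotropy_ratio: float = 4.0
    cm: float = 1.0             # uF/cm^2
    chi: float = 1400.0         # 1/cm
    dt: float = 0.01            # ms
    dx: float = 0.15            # mm
    lva_scheme: str = "50-40-50"

    def __post_init__(self):
        if self.sigma_t is None:
            self.sigma_t = self.sigma_l / self.anisotropy_ratio
        if self.sigma_l <= 0 or self.sigma_t <= 0:
            raise ValidationError("conductivities must be > 0")
        if self.sigma_t > self.sigma_l:
            raise ValidationError("transverse conductivity exceeds longitudinal")
        if self.lva_scheme not in LVA_ION_SCHEMES:
            raise ValidationError(f"unknown LVA scheme {self.lva_scheme!r}")

    def diffusivity(self, sigma: float) -> float:
        """sigma (mS/cm) -> D (mm^2/ms)."""
        return sigma / (self.chi * self.cm) * 100.0


@dataclass
class SpiralInitSpec:
    """Imposed spiral-wave re-entries: (x, y) node coords and chirality +/-1."""

    centers: Sequence[tuple]            # [(ix, iy, chirality), ...]
    zone_of: Sequence[str] = ()         # parallel zone labels ("LA"/"RA"), optional

    @classmethod
    def default(cls, sheet: SubstrateSheet) -> "SpiralInitSpec":
        """Six re-entries, three per chamber, adjacent ones counter-rotating."""
        la_cols = int(round(0.6 * sheet.nx))
        xs_la = la_cols // 2
        xs_ra = la_cols + (sheet.nx - la_cols) // 2
        ys = [sheet.ny // 6, sheet.ny // 2, 5 * sheet.ny // 6]
        centers = []
        zones = []
        for k, y in enumerate(ys):
            centers.append((xs_la, y, 1 if k % 2 == 0 else -1))
            zones.append("LA")
        for k, y in enumerate(ys):
            centers.append((xs_ra, y, -1 if k % 2 == 0 else 1))
            zones.append("RA")
        return cls(centers=centers, zone_of=zones)


@dataclass
class EpisodeResult:
    """Outcome of one simulated AF episode."""

    sustained: bool
    termination_time: Optional[float]   # ms, None when sustained
    horizon: float                      # ms
    act_times: np.ndarray               # (n_nodes, k) float32, ms
    act_counts: np.ndarray              # (n_nodes,)
    shape: tuple                        # (ny, nx)
    dx: float
    electrode_names: tuple = ()
    electrode_potentials: Optional[np.ndarray] = None   # (n_samples, n_el)
    sample_rate_hz: float = 1000.0
    vframes: Optional[np.ndarray] = None                # (n_frames, ny, nx) f32
    frame_times: Optional[np.ndarray] = None
    drug_label: Optional[str] = None
    profile_id: str = ""

    def last_activation(self) -> float:
        if self.act_counts.max() == 0:
            return 0.0
        idx = self.act_counts > 0
        return float(self.act_times[np.arange(len(self.act_counts))[idx],
                                    self.act_counts[idx] - 1].max())


def apply_lva_remodelling(sheet: SubstrateSheet, params: MonodomainParams,
                          scaling: ConductanceScaling, regional_factors=None):
    """Per-node conductance factors and conductivities.

    Returns ``(G, sigma_l, sigma_t)``: G is (n_nodes, 12) with the profile's
    factors everywhere, multiplied inside LVA by the ionic remodelling
    survival fractions; conductivities are the bulk values with the 30%
    reduction and 8:1 anisotropy inside LVA.  ``regional_factors`` optionally
    maps zone ("LA"/"RA") to {factor_name: multiplier} for the two-zone
    regional electrophysiology table.
    """
    n = sheet.n_nodes
    G = np.tile(scaling.as_array(), (n, 1))
    if regional_factors:
        zmasks = {"LA": sheet.la_mask().ravel(), "RA": sheet.ra_mask().ravel()}
        for zone, factors in regional_factors.items():
            if zone not in zmasks:
                raise ValidationError(f"unknown zone {zone!r}")
            for name, mult in factors.items():
                G[zmasks[zone], _crn.FACTOR_NAMES.index(name)] *= mult
    sig_l = np.full(n, params.sigma_l)
    sig_t = np.full(n, params.sigma_t)
    lva = (sheet.lva_mask() if sheet.lva is not None
           else np.zeros(sheet.shape, bool)).ravel()
    if lva.any():
        scheme = LVA_ION_SCHEMES[params.lva_scheme]
        for name, keep in scheme.items():
            G[lva, _crn.FACTOR_NAMES.index(name)] *= keep
        sig_l[lva] = params.sigma_l * LVA_CONDUCTIVITY_FACTOR
        sig_t[lva] = sig_l[lva] / LVA_ANISOTROPY_RATIO
    return G, sig_l, sig_t


def _diffusion_tensors(sheet, params, sig_l, sig_t):
    """Per-node Dxx/Dxy/Dyy (mm^2/ms) from fiber angles; Dxy zeroed on the
    boundary ring so the mixed-derivative stencil respects no-flux edges."""
    th = sheet.fiber_angle
    dl = params.diffusivity(sig_l).reshape(sheet.shape)
    dtr = params.diffusivity(sig_t).reshape(sheet.shape)
    c, s = np.cos(th), np.sin(th)
    dxx = dl * c * c + dtr * s * s
    dyy = dl * s * s + dtr * c * c
    dxy = (dl - dtr) * c * s
    dxy[0, :] = dxy[-1, :] = 0.0
    dxy[:, 0] = dxy[:, -1] = 0.0
    return dxx, dxy, dyy


def check_stability(params: MonodomainParams, dmax: float) -> None:
    """Explicit-diffusion stability bound dt <= dx^2 / (4 Dmax)."""
    limit = params.dx ** 2 / (4.0 * dmax)
    if params.dt > limit:
        raise ValidationError(
            f"dt={params.dt} ms unstable for dx={params.dx} mm and "
            f"D={dmax:.3g} mm^2/ms (limit {limit:.3g} ms)")


@njit(cache=False, fastmath=True)
def _laplacian(V, Dxx, Dxy, Dyy, inv_dx2, inv_4dx2, out):
    ny, nx = V.shape
    for j in range(ny):
        jm = j - 1 if j > 0 else 0
        jp = j + 1 if j < ny - 1 else ny - 1
        for i in range(nx):
            im = i - 1 if i > 0 else 0
            ip = i + 1 if i < nx - 1 else nx - 1
            v = V[j, i]
            fxp = (Dxx[j, ip] + Dxx[j, i]) * (V[j, ip] - v)
            fxm = (Dxx[j, i] + Dxx[j, im]) * (v - V[j, im])
            fyp = (Dyy[jp, i] + Dyy[j, i]) * (V[jp, i] - v)
            fym = (Dyy[j, i] + Dyy[jm, i]) * (v - V[jm, i])
            mixed = (Dxy[j, ip] * (V[jp, ip] - V[jm, ip])
                     - Dxy[j, im] * (V[jp, im] - V[jm, im])
                     + Dxy[jp, i] * (V[jp, ip] - V[jp, im])
                     - Dxy[jm, i] * (V[jm, ip] - V[jm, im]))
            out[j, i] = (0.5 * (fxp - fxm + fyp - fym) * inv_dx2
                         + mixed * inv_4dx2)


@njit(cache=False, fastmath=True)
def _run_block(V, Y, G, Dxx, Dxy, Dyy, lap, dt, inv_dx2, inv_4dx2,
               table, vmin_t, inv_dv, t0, n_steps,
               stim_mask, stim_amp, stim_start, stim_dur, stim_cl,
               ena_c, ek_c, eca_c, nernst_every,
               act_times, act_counts, act_last, last_act_in,
               el_gx, el_gy, el_pot, sample_every, sample_idx0):
    """Advance ``n_steps`` of the monodomain system.  Returns (last activation
    time, next electrode sample index, index of first non-finite node or -1).
    """
    ny, nx = V.shape
    n = ny * nx
    nrow = table.shape[0]
    Vf = V.ravel()
    e_fca = math.exp(-dt / 2.0)
    e_u = math.exp(-dt / 8.0)
    rtf = _crn.R_GAS * _crn.TEMP / _crn.FARADAY
    cf = _crn.CM_PF / (_crn.FARADAY * _crn.V_I)
    n_el = el_gx.shape[0]
    last_act = last_act_in
    samp = sample_idx0
    for step in range(n_steps):
        t = t0 + step * dt
        _laplacian(V, Dxx, Dxy, Dyy, inv_dx2, inv_4dx2, lap)
        lapf = lap.ravel()
        stim_on = False
        if stim_amp != 0.0 and t >= stim_start:
            if stim_cl > 0.0:
                stim_on = ((t - stim_start) % stim_cl) < stim_dur
            else:
                stim_on = (t - stim_start) < stim_dur
        update_nernst = (step % nernst_every) == 0
        for k in range(n):
            v = Vf[k]
            nai = Y[k, 15]
            ki = Y[k, 16]
            cai = Y[k, 17]
            caup = Y[k, 18]
            carel = Y[k, 19]
            if update_nernst:
                ena_c[k] = rtf * math.log(_crn.NA_O / nai)
                ek_c[k] = rtf * math.log(_crn.K_O / ki)
                eca_c[k] = 0.5 * rtf * math.log(_crn.CA_O / cai)
            pos = (v - vmin_t) * inv_dv
            i0 = int(pos)
            if i0 < 0:
                i0 = 0
            elif i0 > nrow - 2:
                i0 = nrow - 2
            fr = pos - i0
            if fr < 0.0:
                fr = 0.0
            elif fr > 1.0:
                fr = 1.0
            r0 = table[i0]
            r1 = table[i0 + 1]

            m = Y[k, 0]
            h = Y[k, 1]
            jj = Y[k, 2]
            oa = Y[k, 3]
            oi = Y[k, 4]
            ua = Y[k, 5]
            ui = Y[k, 6]
            xr = Y[k, 7]
            xs = Y[k, 8]
            d = Y[k, 9]
            f = Y[k, 10]
            fca = Y[k, 11]
            uu = Y[k, 12]
            vv = Y[k, 13]
            w = Y[k, 14]

            gkur_v = r0[24] + fr * (r1[24] - r0[24])
            ik1_g = r0[25] + fr * (r1[25] - r0[25])
            ikr_in = r0[26] + fr * (r1[26] - r0[26])
            fnak = r0[27] + fr * (r1[27] - r0[27])
            encx_p = r0[28] + fr * (r1[28] - r0[28])
            encx_m = r0[29] + fr * (r1[29] - r0[29])

            ena = ena_c[k]
            ek = ek_c[k]
            eca = eca_c[k]

            ina = G[k, 6] * _crn.G_NA_BASE * m * m * m * h * jj * (v - ena)
            ik1 = G[k, 4] * _crn.G_K1_BASE * (v - ek) * ik1_g
            ito = G[k, 3] * _crn.G_TO_BASE * oa * oa * oa * oi * (v - ek)
            ikur = G[k, 0] * gkur_v * ua * ua * ua * ui * (v - ek)
            ikr = G[k, 1] * _crn.G_KR_BASE * xr * (v - ek) * ikr_in
            iks = G[k, 2] * _crn.G_KS_BASE * xs * xs * (v - ek)
            ical = G[k, 5] * _crn.G_CAL_BASE * d * f * fca * (v - 65.0)
            inak = (G[k, 7] * _crn.I_NAK_MAX * fnak
                    * (_crn.K_O / (_crn.K_O + _crn.KM_K_O))
                    / (1.0 + (_crn.KM_NA_I / nai) ** 1.5))
            incx = (G[k, 8] * _crn.I_NCX_MAX
                    * (encx_p * nai ** 3 * _crn.CA_O - encx_m * _crn.NA_O ** 3 * cai)
                    / ((_crn.KM_NA ** 3 + _crn.NA_O ** 3) * (_crn.KM_CA + _crn.CA_O)
                       * (1.0 + _crn.K_SAT * encx_m)))
            ipca = _crn.I_PCA_MAX * cai / (0.0005 + cai)
            ibna = _crn.G_B_NA * (v - ena)
            ibca = _crn.G_B_CA * (v - eca)

            irel = G[k, 9] * _crn.K_REL * uu * uu * vv * w * (carel - cai)
            itr = (caup - carel) / 180.0
            iup = G[k, 11] * _crn.I_UP_MAX / (1.0 + _crn.K_UP / cai)
            iupleak = G[k, 10] * _crn.I_UP_MAX * caup / _crn.CA_UP_MAX

            fn = (1e-12 * _crn.V_REL * irel
                  - (1e-12 / _crn.FARADAY) * (0.5 * ical - 0.2 * incx) * _crn.CM_PF)
            u_inf = 1.0 / (1.0 + math.exp(-(fn - 3.4175e-13) / 1.367e-15))
            v_inf = 1.0 - 1.0 / (1.0 + math.exp(-(fn - 6.835e-14) / 1.367e-15))
            tau_v = 1.91 + 2.09 * u_inf
            fca_inf = 1.0 / (1.0 + cai / 0.00035)

            iion = (ina + ik1 + ito + ikur + ikr + iks + ical + ipca + inak
                    + incx + ibna + ibca)
            istim = 0.0
            if stim_on and stim_mask[k]:
                istim = stim_amp

            vnew = v + dt * (lapf[k] - iion - istim)

            # Rush-Larsen gate updates from the table
            for gidx in range(12):
                col = gidx
                inf = r0[col] + fr * (r1[col] - r0[col])
                rl = r0[col + 12] + fr * (r1[col + 12] - r0[col + 12])
                yc = _GATE_COLS[gidx]
                Y[k, yc] = inf + (Y[k, yc] - inf) * rl
            Y[k, 11] = fca_inf + (fca - fca_inf) * e_fca
            Y[k, 12] = u_inf + (uu - u_inf) * e_u
            Y[k, 13] = v_inf + (vv - v_inf) * math.exp(-dt / tau_v)

            dnai = cf * (-3.0 * inak - (3.0 * incx + ibna + ina))
            dki = cf * (2.0 * inak - (ik1 + ito + ikur + ikr + iks))
            b1 = (cf * 0.5 * (2.0 * incx - (ipca + ical + ibca))
                  + (_crn.V_UP * (iupleak - iup) + irel * _crn.V_REL) / _crn.V_I)
            b2 = (1.0 + _crn.TRPN_MAX * _crn.KM_TRPN / (cai + _crn.KM_TRPN) ** 2
                  + _crn.CMDN_MAX * _crn.KM_CMDN / (cai + _crn.KM_CMDN) ** 2)
            Y[k, 15] = nai + dt * dnai
            Y[k, 16] = ki + dt * dki
            Y[k, 17] = cai + dt * b1 / b2
            Y[k, 18] = caup + dt * (iup - iupleak - itr * _crn.V_REL / _crn.V_UP)
            Y[k, 19] = carel + dt * (itr - irel) / (
                1.0 + _crn.CSQN_MAX * _crn.KM_CSQN / (carel + _crn.KM_CSQN) ** 2)

            # upstroke detection
            if vnew >= ACT_THRESHOLD_MV and v < ACT_THRESHOLD_MV:
                if t - act_last[k] > ACT_REFRACTORY_MS:
                    c = act_counts[k]
                    if c < act_times.shape[1]:
                        act_times[k, c] = t
                        act_counts[k] = c + 1
                    act_last[k] = t
                    if t > last_act:
                        last_act = t
            Vf[k] = vnew

        if sample_every > 0 and ((step + 1) % sample_every) == 0:
            if samp < el_pot.shape[0]:
                for e in range(n_el):
                    acc = 0.0
                    for j in range(1, ny - 1):
                        base = j * nx
                        for i in range(1, nx - 1):
                            kk = base + i
                            vx = 0.5 * (Vf[kk + 1] - Vf[kk - 1])
                            vy = 0.5 * (Vf[kk + nx] - Vf[kk - nx])
                            acc += el_gx[e, kk] * vx + el_gy[e, kk] * vy
                    el_pot[samp, e] = -acc
                samp += 1

    # NaN check (cheap, once per block)
    bad = -1
    for k in range(n):
        if not math.isfinite(Vf[k]):
            bad = k
            break
    return last_act, samp, bad


def limit_cycle_library(scaling: ConductanceScaling, cl: float = 300.0,
                        n_beats: int = 6, dt: float = 0.02,
                        n_phase: int = 256) -> np.ndarray:
    """States sampled along one paced action-potential cycle.

    Paces a single cell for ``n_beats`` at cycle length ``cl`` and records the
    full state over the final cycle, resampled to ``n_phase`` entries.  Used
    to map a phase field onto tissue initial conditions.
    """
    g = scaling.as_array()
    y = _crn.REST_STATE.copy()
    _crn.run_paced(y, g, dt, cl * (n_beats - 1), cl, STIM_AMP, STIM_DUR, 0.0, cl)
    rec_dt = cl / n_phase
    lib = np.empty((n_phase, _crn.N_STATES))
    n_steps = int(round(cl / dt))
    per = max(1, int(round(rec_dt / dt)))
    idx = 0
    infs = np.empty(_crn.N_VGATES)
    taus = np.empty(_crn.N_VGATES)
    aux = np.empty(_crn.N_AUX)
    for s in range(n_steps):
        t = s * dt
        istim = STIM_AMP if t < STIM_DUR else 0.0
        if s % per == 0 and idx < n_phase:
            lib[idx] = y
            idx += 1
        _crn._step_core(y, g, dt, istim, infs, taus, aux)
    while idx < n_phase:
        lib[idx] = y
        idx += 1
    return lib


def choose_library_cl(scaling: ConductanceScaling,
                      candidates=(200.0, 250.0, 300.0, 400.0, 500.0),
                      dt: float = 0.02) -> float:
    """Shortest pacing cycle length with 1:1 capture for the profile.

    The limit-cycle library should be paced as fast as the cell supports so
    the imposed re-entries start with AF-like short wavelengths; profiles
    with long action potentials fall back to slower cycles.
    """
    for cl in candidates:
        g = scaling.as_array()
        y = _crn.REST_STATE.copy()
        _crn.run_paced(y, g, dt, cl * 6, cl, STIM_AMP, STIM_DUR, 0.0, cl)
        _, vs, _ = _crn.run_paced(y, g, dt, cl * 2, cl, STIM_AMP, STIM_DUR,
                                  0.0, 1.0)
        # 1:1 capture: exactly one upstroke per cycle over the last two
        # beats, with a clear diastolic interval; a captured fast-rate beat
        # need not overshoot 0 mV
        crossings = int(np.sum((vs[1:] >= -40.0) & (vs[:-1] < -40.0)))
        if crossings == 2 and vs.max() > -30.0 and vs.min() < -60.0:
            return cl
    return float(candidates[-1])


def init_spirals(sheet: SubstrateSheet, spec: SpiralInitSpec,
                 scaling: ConductanceScaling, lib_cl: Optional[float] = None,
                 dt: float = 0.02):
    """Initial (V, Y, phase, territory) fields from imposed spiral re-entries.

    Phase-distribution method: the sheet is partitioned into territories by
    nearest spiral centre (within the centre's zone when zones are given),
    and each node takes its state from a single-cell limit cycle at phase
    chirality * atan2 about its territory's core.  ``lib_cl`` defaults to
    the fastest 1:1-captured cycle length of the profile.  Deterministic.
    """
    for (ix, iy, ch) in spec.centers:
        if not (0 <= ix < sheet.nx and 0 <= iy < sheet.ny):
            raise ValidationError(f"spiral centre ({ix},{iy}) outside the sheet")
        if ch not in (-1, 1):
            raise ValidationError("chirality must be +/-1")
    if lib_cl is None:
        lib_cl = choose_library_cl(scaling, dt=dt)
    lib = limit_cycle_library(scaling, cl=lib_cl, dt=dt)
    n_phase = lib.shape[0]
    yy, xx = np.meshgrid(np.arange(sheet.ny), np.arange(sheet.nx), indexing="ij")
    la = sheet.la_mask()
    zones = spec.zone_of if spec.zone_of else None
    best_d = np.full(sheet.shape, np.inf)
    phase = np.zeros(sheet.shape)
    territory = np.full(sheet.shape, -1, dtype=np.int32)
    for idx, (ix, iy, ch) in enumerate(spec.centers):
        if zones is not None and len(zones) == len(spec.centers):
            zmask = la if zones[idx] == "LA" else ~la
        else:
            zmask = np.ones(sheet.shape, bool)
        d2 = (xx - ix) ** 2.0 + (yy - iy) ** 2.0
        closer = zmask & (d2 < best_d)
        # half-node offset keeps the defect inside a plaquette
        ang = np.arctan2(yy - iy - 0.5, xx - ix - 0.5)
        phase[closer] = (ch * ang[closer]) % (2 * np.pi)
        best_d[closer] = d2[closer]
        territory[closer] = idx
    pidx = np.minimum((phase / (2 * np.pi) * n_phase).astype(np.int64),
                      n_phase - 1)
    states = lib[pidx.ravel()]
    V = states[:, 0].reshape(sheet.shape).copy()
    Y = states[:, 1:].copy()
    return V, Y, phase, territory


def phase_singularities(phase: np.ndarray, territory=None) -> list:
    """Topological defects of a phase field: (ix, iy, charge) per 2x2 plaquette
    with winding number +/-1.

    ``territory`` (from :func:`init_spirals`) restricts detection to
    plaquettes interior to one territory, excluding the seams where the
    imposed field is discontinuous by construction.
    """
    def wrap(a):
        return (a + np.pi) % (2 * np.pi) - np.pi
    d1 = wrap(phase[:-1, 1:] - phase[:-1, :-1])
    d2 = wrap(phase[1:, 1:] - phase[:-1, 1:])
    d3 = wrap(phase[1:, :-1] - phase[1:, 1:])
    d4 = wrap(phase[:-1, :-1] - phase[1:, :-1])
    winding = (d1 + d2 + d3 + d4) / (2 * np.pi)
    if territory is not None:
        t = territory
        interior = ((t[:-1, :-1] == t[:-1, 1:]) & (t[:-1, :-1] == t[1:, :-1])
                    & (t[:-1, :-1] == t[1:, 1:]))
        winding = np.where(interior, winding, 0.0)
    out = []
    jj, ii = np.nonzero(np.abs(winding) > 0.5)
    for j, i in zip(jj, ii):
        out.append((int(i), int(j), int(np.sign(winding[j, i]))))
    return out


@dataclass
class DrugEvent:
    drug: DrugModel
    time_ms: float = 2000.0


def _electrode_fields(sheet, electrodes):
    """Per-node gradients of 1/r for each electrode (infinite homogeneous
    conductor pseudo-ECG kernel); electrode coords in mm, sheet in z=0."""
    el = np.asarray(electrodes, dtype=float)
    yy, xx = np.meshgrid(np.arange(sheet.ny) * sheet.dx,
                         np.arange(sheet.nx) * sheet.dx, indexing="ij")
    n = sheet.n_nodes
    gx = np.zeros((len(el), n))
    gy = np.zeros((len(el), n))
    for e, (ex, ey, ez) in enumerate(el):
        if abs(ez) < 1e-9:
            raise ValidationError("electrode lies in the tissue plane")
        rx = ex - xx
        ry = ey - yy
        r = np.sqrt(rx ** 2 + ry ** 2 + ez ** 2)
        # grad_source(1/r) = (r_vec)/r^3 with r_vec from source to electrode
        gx[e] = (rx / r ** 3).ravel()
        gy[e] = (ry / r ** 3).ravel()
    return gx, gy


def run_episode(sheet: SubstrateSheet, params: MonodomainParams,
                scaling: ConductanceScaling, init, horizon: float,
                drug_event: Optional[DrugEvent] = None,
                electrodes=None, sample_rate_hz: float = 1000.0,
                store_voltage_ms: Optional[float] = None,
                regional_factors=None,
                stim=None,
                early_stop: bool = True) -> EpisodeResult:
    """Integrate one AF episode.

    ``init`` is (V0, Y0) from :func:`init_spirals` (or ``None`` for a resting
    sheet).  ``drug_event`` multiplies the per-node conductance factors by
    (1 - block) at the administration time.  ``electrodes`` is an (n, 3)
    array of positions in mm (z != 0) whose unipolar pseudo-potentials are
    sampled at ``sample_rate_hz``.  ``stim`` optionally paces the sheet:
    dict(mask=bool array, amp, start, dur, cl).  Activations are upstroke
    crossings of -40 mV.  With ``early_stop`` the episode ends as terminated
    once no node has activated for the sustenance window.
    """
    if horizon <= 0:
        raise ValidationError("horizon must be positive")
    G, sig_l, sig_t = apply_lva_remodelling(sheet, params, scaling,
                                            regional_factors)
    dxx, dxy, dyy = _diffusion_tensors(sheet, params, sig_l, sig_t)
    check_stability(params, float(dxx.max()))
    n = sheet.n_nodes
    if init is None:
        V = np.full(sheet.shape, _crn.REST_STATE[0])
        Y = np.tile(_crn.REST_STATE[1:], (n, 1))
    else:
        V0, Y0 = init[0], init[1]
        V = np.array(V0, dtype=np.float64).reshape(sheet.shape)
        Y = np.array(Y0, dtype=np.float64).reshape(n, _crn.N_STATES - 1)

    table, vmin_t, inv_dv = _crn.build_gate_tables(params.dt)
    dt = params.dt
    inv_dx2 = 1.0 / (sheet.dx ** 2)
    inv_4dx2 = 0.25 * inv_dx2

    if stim is None:
        stim_mask = np.zeros(n, bool)
        stim_amp, stim_start, stim_dur, stim_cl = 0.0, 0.0, 0.0, 0.0
    else:
        stim_mask = np.asarray(stim["mask"], bool).ravel()
        stim_amp = float(stim.get("amp", STIM_AMP))
        stim_start = float(stim.get("start", 0.0))
        stim_dur = float(stim.get("dur", STIM_DUR))
        stim_cl = float(stim.get("cl", 0.0))

    if electrodes is None:
        el_gx = np.zeros((0, n))
        el_gy = np.zeros((0, n))
        sample_every = 0
        n_samples = 0
    else:
        el_gx, el_gy = _electrode_fields(sheet, electrodes)
        sample_every = max(1, int(round(1000.0 / sample_rate_hz / dt)))
        n_samples = int(round(horizon / dt)) // sample_every + 1
    el_pot = np.zeros((n_samples, el_gx.shape[0]))

    act_times = np.zeros((n, MAX_ACTIVATIONS), dtype=np.float32)
    act_counts = np.zeros(n, dtype=np.int32)
    act_last = np.full(n, -1e9)
    ena_c = np.zeros(n)
    ek_c = np.zeros(n)
    eca_c = np.zeros(n)
    lap = np.zeros(sheet.shape)

    block_ms = 5.0
    steps_per_block = int(round(block_ms / dt))
    n_blocks = int(math.ceil(horizon / block_ms))
    frames = []
    frame_times = []
    drug_applied = drug_event is None
    last_act = 0.0
    samp = 0
    terminated_at = None
    for b in range(n_blocks):
        t0 = b * block_ms
        if not drug_applied and t0 >= drug_event.time_ms - 1e-9:
            for cur, frac in drug_event.drug.block.items():
                from .drug_library import CURRENT_TO_FACTOR
                G[:, _crn.FACTOR_NAMES.index(CURRENT_TO_FACTOR[cur])] *= (1 - frac)
            drug_applied = True
        if store_voltage_ms is not None and (
                t0 % store_voltage_ms < block_ms - 1e-9):
            frames.append(V.astype(np.float32).copy())
            frame_times.append(t0)
        last_act, samp, bad = _run_block(
            V, Y, G, dxx, dxy, dyy, lap, dt, inv_dx2, inv_4dx2,
            table, vmin_t, inv_dv, t0, steps_per_block,
            stim_mask, stim_amp, stim_start, stim_dur, stim_cl,
            ena_c, ek_c, eca_c, 25,
            act_times, act_counts, act_last, last_act,
            el_gx, el_gy, el_pot, sample_every, samp)
        if bad >= 0:
            raise IntegrationError(
                f"non-finite voltage at node {bad} near t={t0 + block_ms:.1f} ms "
                f"(dt={dt}, dx={sheet.dx})")
        t_now = t0 + block_ms
        quiescent = (t_now - max(last_act, stim_start)) > SUSTAIN_WINDOW_MS
        if early_stop and quiescent and act_counts.max() >= 0 and stim_cl == 0.0:
            terminated_at = last_act if act_counts.max() > 0 else 0.0
            break

    sustained = terminated_at is None and (
        horizon - last_act) <= SUSTAIN_WINDOW_MS and act_counts.max() > 0
    if terminated_at is None and not sustained:
        terminated_at = last_act if act_counts.max() > 0 else 0.0
    return EpisodeResult(
        sustained=bool(sustained),
        termination_time=None if sustained else float(terminated_at),
        horizon=horizon,
        act_times=act_times, act_counts=act_counts,
        shape=sheet.shape, dx=sheet.dx,
        electrode_potentials=el_pot[:samp] if n_samples else None,
        sample_rate_hz=sample_rate_hz,
        vframes=np.array(frames) if frames else None,
        frame_times=np.array(frame_times) if frame_times else None,
        drug_label=drug_event.drug.label if drug_event else None,
        profile_id=scaling.profile_id)


def classify_sustained(result: EpisodeResult, horizon: Optional[float] = None):
    """(sustained, termination_time): sustained iff some node activates within
    the final sustenance window of the horizon."""
    horizon = horizon if horizon is not None else result.horizon
    last = result.last_activation()
    if result.act_counts.max() == 0:
        return False, 0.0
    if horizon - last <= SUSTAIN_WINDOW_MS:
        return True, None
    return False, last


def save_episode(result: EpisodeResult, path) -> None:
    """Persist an episode (activations, leads, optional voltage frames) to HDF5."""
    import h5py
    with h5py.File(path, "w") as f:
        kmax = max(int(result.act_counts.max()), 1)
        f.create_dataset("act_times", data=result.act_times[:, :kmax])
        f.create_dataset("act_counts", data=result.act_counts)
        if result.electrode_potentials is not None:
            f.create_dataset("electrode_potentials",
                             data=result.electrode_potentials)
        if result.vframes is not None:
            f.create_dataset("vframes", data=result.vframes)
            f.create_dataset("frame_times", data=result.frame_times)
        f.attrs.update({
            "sustained": result.sustained,
            "termination_time": (-1.0 if result.termination_time is None
                                 else result.termination_time),
            "horizon": result.horizon, "ny": result.shape[0],
            "nx": result.shape[1], "dx": result.dx,
            "sample_rate_hz": result.sample_rate_hz,
            "drug_label": result.drug_label or "",
            "profile_id": result.profile_id})


def load_episode(path) -> EpisodeResult:
    import h5py
    with h5py.File(path, "r") as f:
        a = dict(f.attrs)
        term = float(a["termination_time"])
        return EpisodeResult(
            sustained=bool(a["sustained"]),
            termination_time=None if term < 0 else term,
            horizon=float(a["horizon"]),
            act_times=f["act_times"][()],
            act_counts=f["act_counts"][()],
            shape=(int(a["ny"]), int(a["nx"])), dx=float(a["dx"]),
            electrode_potentials=(f["electrode_potentials"][()]
                                  if "electrode_potentials" in f else None),
            sample_rate_hz=float(a["sample_rate_hz"]),
            vframes=f["vframes"][()] if "vframes" in f else None,
            frame_times=f["frame_times"][()] if "frame_times" in f else None,
            drug_label=str(a["drug_label"]) or None,
            profile_id=str(a["profile_id"]))


def measure_strand_cv(params: MonodomainParams, scaling: ConductanceScaling,
                      length_mm: float = 60.0, width: int = 5) -> float:
    """Planar-wave conduction velocity (cm/s) along a fiber-aligned strand."""
    from .synthetic_substrate import SubstrateSheet as _S
    nx = int(round(length_mm / params.dx))
    ny = width
    labels = np.full((ny, nx), 5, dtype=np.int8)
    sheet = _S(nx=nx, ny=ny, dx=params.dx, labels=labels,
               fiber_angle=np.zeros((ny, nx)))
    mask = np.zeros((ny, nx), bool)
    mask[:, :max(3, int(round(1.5 / params.dx)))] = True
    res = run_episode(sheet, params, scaling, init=None,
                      horizon=length_mm / 0.2 + 50.0,
                      stim=dict(mask=mask, amp=STIM_AMP * 2, start=5.0,
                                dur=2.0, cl=0.0),
                      early_stop=False)
    acts = np.where(res.act_counts.reshape(ny, nx)[ny // 2] > 0,
                    res.act_times.reshape(ny, nx, -1)[ny // 2, :, 0], np.nan)
    i1, i2 = int(0.25 * nx), int(0.75 * nx)
    if not (np.isfinite(acts[i1]) and np.isfinite(acts[i2])) or acts[i2] <= acts[i1]:
        return math.nan
    dist_mm = (i2 - i1) * params.dx
    return float(dist_mm / (acts[i2] - acts[i1]) * 100.0)  # mm/ms -> cm/s


def calibrate_conductivity(target_cv: float, scaling: ConductanceScaling,
                           params: Optional[MonodomainParams] = None,
                           tol: float = 0.02, bracket=(0.1, 8.0),
                           max_iter: int = 40):
    """Bisect the longitudinal conductivity until the strand CV matches.

    Returns ``(sigma_l, achieved_cv)`` with |cv - target| <= tol * target.
    CV grows monotonically (~ sqrt sigma), so bisection is safe.
    """
    if target_cv <= 0:
        raise ValidationError("target CV must be positive")
    base = params or MonodomainParams()
    lo, hi = bracket

    def cv_of(sig):
        p = replace(base, sigma_l=sig, sigma_t=sig / base.anisotropy_ratio)
        return measure_strand_cv(p, scaling)

    cv_hi = cv_of(hi)
    if math.isnan(cv_hi) or cv_hi < target_cv:
        raise CalibrationFailure(
            f"target {target_cv} cm/s above bracket maximum CV {cv_hi}")
    cv_lo = cv_of(lo)
    if not math.isnan(cv_lo) and cv_lo > target_cv:
        raise CalibrationFailure(
            f"target {target_cv} cm/s below bracket minimum CV {cv_lo}")
    for _ in range(max_iter):
        mid = math.sqrt(lo * hi)
        cv = cv_of(mid)
        if not math.isnan(cv) and abs(cv - target_cv) <= tol * target_cv:
            return mid, cv
        if math.isnan(cv) or cv < target_cv:
            lo = mid
        else:
            hi = mid
    raise CalibrationFailure(
        f"CV calibration did not converge to {target_cv} cm/s")
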