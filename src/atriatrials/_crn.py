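"""Courtemanche–Ramirez–Nattel (CRN) human atrial action-potential model.

Numba-compiled core shared by the single-cell routines (:mod:`.cell_population`)
and the monodomain tissue solver (:mod:`.tissue_sim`).  The model is the
standard 21-variable formulation: membrane voltage, 15 gating variables,
intracellular Na+/K+/Ca2+ and the two sarcoplasmic-reticulum Ca2+ compartments.

Units: time ms, voltage mV, concentrations mM, membrane currents pA/pF.

Twelve maximal conductances / fluxes are scalable by dimensionless factors
(the "ionic profile" of a virtual patient), in the order given by
``FACTOR_NAMES``:

    g_Kur, g_Kr, g_Ks, g_to, g_K1, g_CaL, g_Na, g_NaK, g_NCX, g_rel, g_leak, g_up

A profile of all ones reproduces the published baseline model.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

FACTOR_NAMES = (
    "g_Kur", "g_Kr", "g_Ks", "g_to", "g_K1", "g_CaL",
    "g_Na", "g_NaK", "g_NCX", "g_rel", "g_leak", "g_up",
)
N_FACTORS = len(FACTOR_NAMES)

# index of each scaling factor in the factor vector
IKUR, IKR, IKS, ITO, IK1, ICAL, INA, INAK, INCX, IREL, ILEAK, IUP = range(12)

STATE_NAMES = (
    "V", "m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs",
    "d", "f", "fca", "u", "v", "w", "Nai", "Ki", "Cai", "Caup", "Carel",
)
N_STATES = len(STATE_NAMES)

# Baseline maximal conductances (nS/pF) and fluxes; the factor->absolute
# conversion for a current X is simply  g_X(profile) = factor * G_X_BASE.
G_NA_BASE = 7.8          # nS/pF
G_K1_BASE = 0.09
G_TO_BASE = 0.1652
G_KR_BASE = 0.029411765
G_KS_BASE = 0.12941176
G_CAL_BASE = 0.12375
I_NAK_MAX = 0.59933874   # pA/pF
I_NCX_MAX = 1600.0       # pA/pF
I_PCA_MAX = 0.275        # pA/pF
G_B_NA = 0.0006744375    # nS/pF
G_B_CA = 0.001131        # nS/pF
K_REL = 30.0             # 1/ms
I_UP_MAX = 0.005         # mM/ms
CA_UP_MAX = 15.0         # mM
K_UP = 0.00092           # mM

# physical constants and fixed concentrations
R_GAS = 8.3143
TEMP = 310.0
FARADAY = 96.4867
CM_PF = 100.0            # membrane capacitance, pF
V_I = 13668.0            # intracellular volume, um^3
V_UP = 1109.52
V_REL = 96.48
NA_O = 140.0
K_O = 5.4
CA_O = 1.8
CMDN_MAX = 0.05
TRPN_MAX = 0.07
CSQN_MAX = 10.0
KM_CMDN = 0.00238
KM_TRPN = 0.0005
KM_CSQN = 0.8
KM_NA_I = 10.0
KM_K_O = 1.5
KM_NA = 87.5
KM_CA = 1.38
K_SAT = 0.1
GAMMA_NCX = 0.35
KQ10 = 3.0

_SIGMA_NAK = (math.exp(NA_O / 67.3) - 1.0) / 7.0

#: published resting steady state (quiescent cell)
REST_STATE = np.array([
    -81.18,        # V
    2.908e-3,      # m
    9.649e-1,      # h
    9.775e-1,      # j
    3.043e-2,      # oa
    9.992e-1,      # oi
    4.966e-3,      # ua
    9.986e-1,      # ui
    3.296e-5,      # xr
    1.869e-2,      # xs
    1.367e-4,      # d
    9.996e-1,      # f
    7.755e-1,      # fca
    0.0,           # u
    1.0,           # v
    9.992e-1,      # w
    11.17,         # Nai
    139.0,         # Ki
    1.013e-4,      # Cai
    1.488,         # Caup
    1.488,         # Carel
], dtype=np.float64)

# number of voltage-dependent Rush-Larsen gates handled through the rate
# function below (fca, u, v depend on Cai / SR flux and are treated inline)
N_VGATES = 12
N_AUX = 6


@njit(cache=False, fastmath=True)
def gate_rates(V, infs, taus, aux):
    """Steady states / time constants of the 12 voltage-dependent gates.

    Fills ``infs``/``taus`` in state order m, h, j, oa, oi, ua, ui, xr, xs,
    d, f, w, and ``aux`` with voltage-only current terms:
    [g_Kur(V), IK1 gating, IKr inactivation, f_NaK, exp(+g FV/RT), exp(-(1-g) FV/RT)].
    """
    # INa gates (Luo-Rudy style)
    if abs(V + 47.13) < 1e-10:
        a_m = 3.2
    else:
        a_m = 0.32 * (V + 47.13) / (1.0 - math.exp(-0.1 * (V + 47.13)))
    b_m = 0.08 * math.exp(-V / 11.0)
    if V >= -40.0:
        a_h = 0.0
        b_h = 1.0 / (0.13 * (1.0 + math.exp(-(V + 10.66) / 11.1)))
        a_j = 0.0
        b_j = 0.3 * math.exp(-2.535e-7 * V) / (1.0 + math.exp(-0.1 * (V + 32.0)))
    else:
        a_h = 0.135 * math.exp(-(V + 80.0) / 6.8)
        b_h = 3.56 * math.exp(0.079 * V) + 3.1e5 * math.exp(0.35 * V)
        a_j = ((-1.2714e5 * math.exp(0.2444 * V) - 3.474e-5 * math.exp(-0.04391 * V))
               * (V + 37.78) / (1.0 + math.exp(0.311 * (V + 79.23))))
        b_j = 0.1212 * math.exp(-0.01052 * V) / (1.0 + math.exp(-0.1378 * (V + 40.14)))
    infs[0] = a_m / (a_m + b_m)
    taus[0] = 1.0 / (a_m + b_m)
    infs[1] = a_h / (a_h + b_h)
    taus[1] = 1.0 / (a_h + b_h)
    infs[2] = a_j / (a_j + b_j)
    taus[2] = 1.0 / (a_j + b_j)

    # Ito gates
    a_oa = 0.65 / (math.exp(-(V + 10.0) / 8.5) + math.exp(-(V - 30.0) / 59.0))
    b_oa = 0.65 / (2.5 + math.exp((V + 82.0) / 17.0))
    infs[3] = 1.0 / (1.0 + math.exp(-(V + 20.47) / 17.54))
    taus[3] = 1.0 / ((a_oa + b_oa) * KQ10)
    a_oi = 1.0 / (18.53 + math.exp((V + 113.7) / 10.95))
    b_oi = 1.0 / (35.56 + math.exp(-(V + 1.26) / 7.44))
    infs[4] = 1.0 / (1.0 + math.exp((V + 43.1) / 5.3))
    taus[4] = 1.0 / ((a_oi + b_oi) * KQ10)

    # IKur gates (same alpha/beta shape as oa for activation)
    a_ua = 0.65 / (math.exp(-(V + 10.0) / 8.5) + math.exp(-(V - 30.0) / 59.0))
    b_ua = 0.65 / (2.5 + math.exp((V + 82.0) / 17.0))
    infs[5] = 1.0 / (1.0 + math.exp(-(V + 30.3) / 9.6))
    taus[5] = 1.0 / ((a_ua + b_ua) * KQ10)
    a_ui = 1.0 / (21.0 + math.exp(-(V - 185.0) / 28.0))
    b_ui = math.exp((V - 158.0) / 16.0)
    infs[6] = 1.0 / (1.0 + math.exp((V - 99.45) / 27.48))
    taus[6] = 1.0 / ((a_ui + b_ui) * KQ10)

    # IKr activation
    if abs(V + 14.1) < 1e-10:
        a_xr = 0.0015
    else:
        a_xr = 3e-4 * (V + 14.1) / (1.0 - math.exp(-(V + 14.1) / 5.0))
    if abs(V - 3.3328) < 1e-10:
        b_xr = 3.7836118e-4
    else:
        b_xr = 7.3898e-5 * (V - 3.3328) / (math.exp((V - 3.3328) / 5.1237) - 1.0)
    infs[7] = 1.0 / (1.0 + math.exp(-(V + 14.1) / 6.5))
    taus[7] = 1.0 / (a_xr + b_xr)

    # IKs activation
    if abs(V - 19.9) < 1e-10:
        a_xs = 6.8e-4
        b_xs = 3.15e-4
    else:
        a_xs = 4e-5 * (V - 19.9) / (1.0 - math.exp(-(V - 19.9) / 17.0))
        b_xs = 3.5e-5 * (V - 19.9) / (math.exp((V - 19.9) / 9.0) - 1.0)
    infs[8] = (1.0 + math.exp(-(V - 19.9) / 12.7)) ** -0.5
    taus[8] = 0.5 / (a_xs + b_xs)

    # ICaL gates
    if abs(V + 10.0) < 1e-10:
        taus[9] = 1.0 / (6.24 * 0.035 * 2.0)
    else:
        e = math.exp(-(V + 10.0) / 6.24)
        taus[9] = (1.0 - e) / (0.035 * (V + 10.0) * (1.0 + e))
    infs[9] = 1.0 / (1.0 + math.exp(-(V + 10.0) / 8.0))
    infs[10] = 1.0 / (1.0 + math.exp((V + 28.0) / 6.9))
    taus[10] = 9.0 / (0.0197 * math.exp(-(0.0337 ** 2) * (V + 10.0) ** 2) + 0.02)

    # SR release voltage gate w
    if abs(V - 7.9) < 1e-10:
        taus[11] = 6.0 * 0.2 / 1.3
    else:
        e = math.exp(-(V - 7.9) / 5.0)
        taus[11] = 6.0 * (1.0 - e) / ((1.0 + 0.3 * e) * (V - 7.9))
    infs[11] = 1.0 - 1.0 / (1.0 + math.exp(-(V - 40.0) / 17.0))

    fvrt = FARADAY * V / (R_GAS * TEMP)
    aux[0] = 0.005 + 0.05 / (1.0 + math.exp(-(V - 15.0) / 13.0))      # g_Kur(V)
    aux[1] = 1.0 / (1.0 + math.exp(0.07 * (V + 80.0)))                # IK1 rectification
    aux[2] = 1.0 / (1.0 + math.exp((V + 15.0) / 22.4))                # IKr inactivation
    aux[3] = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * fvrt)
                    + 0.0365 * _SIGMA_NAK * math.exp(-fvrt))          # f_NaK
    aux[4] = math.exp(GAMMA_NCX * fvrt)                               # NCX forward
    aux[5] = math.exp((GAMMA_NCX - 1.0) * fvrt)                       # NCX reverse


@njit(cache=False, fastmath=True)
def _step_core(y, g, dt, istim, infs, taus, aux):
    V = y[0]
    Nai, Ki, Cai, Caup, Carel = y[16], y[17], y[18], y[19], y[20]

    gate_rates(V, infs, taus, aux)

    rtf = R_GAS * TEMP / FARADAY
    ena = rtf * math.log(NA_O / Nai)
    ek = rtf * math.log(K_O / Ki)
    eca = 0.5 * rtf * math.log(CA_O / Cai)

    ina = g[INA] * G_NA_BASE * y[1] ** 3 * y[2] * y[3] * (V - ena)
    ik1 = g[IK1] * G_K1_BASE * (V - ek) * aux[1]
    ito = g[ITO] * G_TO_BASE * y[4] ** 3 * y[5] * (V - ek)
    ikur = g[IKUR] * aux[0] * y[6] ** 3 * y[7] * (V - ek)
    ikr = g[IKR] * G_KR_BASE * y[8] * (V - ek) * aux[2]
    iks = g[IKS] * G_KS_BASE * y[9] ** 2 * (V - ek)
    ical = g[ICAL] * G_CAL_BASE * y[10] * y[11] * y[12] * (V - 65.0)
    inak = (g[INAK] * I_NAK_MAX * aux[3] * (K_O / (K_O + KM_K_O))
            / (1.0 + (KM_NA_I / Nai) ** 1.5))
    incx = (g[INCX] * I_NCX_MAX
            * (aux[4] * Nai ** 3 * CA_O - aux[5] * NA_O ** 3 * Cai)
            / ((KM_NA ** 3 + NA_O ** 3) * (KM_CA + CA_O) * (1.0 + K_SAT * aux[5])))
    ipca = I_PCA_MAX * Cai / (0.0005 + Cai)
    ibna = G_B_NA * (V - ena)
    ibca = G_B_CA * (V - eca)

    # SR fluxes
    irel = g[IREL] * K_REL * y[13] ** 2 * y[14] * y[15] * (Carel - Cai)
    itr = (Caup - Carel) / 180.0
    iup = g[IUP] * I_UP_MAX / (1.0 + K_UP / Cai)
    iupleak = g[ILEAK] * I_UP_MAX * Caup / CA_UP_MAX

    # Ca-release control gates (flux-dependent)
    fn = 1e-12 * V_REL * irel - (1e-12 / FARADAY) * (0.5 * ical - 0.2 * incx) * CM_PF
    u_inf = 1.0 / (1.0 + math.exp(-(fn - 3.4175e-13) / 1.367e-15))
    v_inf = 1.0 - 1.0 / (1.0 + math.exp(-(fn - 6.835e-14) / 1.367e-15))
    tau_v = 1.91 + 2.09 * u_inf
    fca_inf = 1.0 / (1.0 + Cai / 0.00035)

    iion = (ina + ik1 + ito + ikur + ikr + iks + ical + ipca + inak + incx
            + ibna + ibca)
    dv = -(iion + istim)

    # concentrations (forward Euler)
    cf = CM_PF / (FARADAY * V_I)
    dnai = cf * (-3.0 * inak - (3.0 * incx + ibna + ina))
    dki = cf * (2.0 * inak - (ik1 + ito + ikur + ikr + iks))
    b1 = (cf * 0.5 * (2.0 * incx - (ipca + ical + ibca))
          + (V_UP * (iupleak - iup) + irel * V_REL) / V_I)
    b2 = (1.0 + TRPN_MAX * KM_TRPN / (Cai + KM_TRPN) ** 2
          + CMDN_MAX * KM_CMDN / (Cai + KM_CMDN) ** 2)
    dcaup = iup - iupleak - itr * V_REL / V_UP
    dcarel = (itr - irel) / (1.0 + CSQN_MAX * KM_CSQN / (Carel + KM_CSQN) ** 2)

    y[0] = V + dt * dv
    for k in range(N_VGATES):
        # state indices of the tabulated gates: m..f are states 1..11, w is 15
        idx = 1 + k if k < 11 else 15
        y[idx] = infs[k] + (y[idx] - infs[k]) * math.exp(-dt / taus[k])
    y[12] = fca_inf + (y[12] - fca_inf) * math.exp(-dt / 2.0)
    y[13] = u_inf + (y[13] - u_inf) * math.exp(-dt / 8.0)
    y[14] = v_inf + (y[14] - v_inf) * math.exp(-dt / tau_v)
    y[16] = Nai + dt * dnai
    y[17] = Ki + dt * dki
    y[18] = Cai + dt * b1 / b2
    y[19] = Caup + dt * dcaup
    y[20] = Carel + dt * dcarel
    return dv


@njit(cache=False, fastmath=True)
def step_cell(y, g, dt, istim):
    """Advance one CRN state vector by ``dt`` (ms), in place.

    ``g`` is the 12-element factor vector (order ``FACTOR_NAMES``); ``istim``
    is the stimulus current in pA/pF (negative = depolarizing).  Rush-Larsen
    update for all gates, forward Euler for voltage and concentrations.
    Returns dV/dt (mV/ms) of the step for upstroke-velocity bookkeeping.
    """
    infs = np.empty(N_VGATES)
    taus = np.empty(N_VGATES)
    aux = np.empty(N_AUX)
    return _step_core(y, g, dt, istim, infs, taus, aux)


@njit(cache=False)
def run_paced(y, g, dt, duration, cl, stim_amp, stim_dur, first_stim, record_dt):
    """Integrate a single cell under periodic stimulation.

    Stimuli of ``stim_amp`` pA/pF (negative = depolarizing) and ``stim_dur``
    ms are delivered at ``first_stim + k*cl``.  Returns (times, voltages,
    max dV/dt) sampled every ``record_dt`` ms; the state ``y`` is advanced
    in place.
    """
    n_steps = int(round(duration / dt))
    rec_every = max(1, int(round(record_dt / dt)))
    n_rec = n_steps // rec_every + 1
    ts = np.empty(n_rec)
    vs = np.empty(n_rec)
    ts[0] = 0.0
    vs[0] = y[0]
    dvdt_max = -1e30
    irec = 1
    infs = np.empty(N_VGATES)
    taus = np.empty(N_VGATES)
    aux = np.empty(N_AUX)
    for step in range(n_steps):
        t = step * dt
        istim = 0.0
        if cl > 0.0 and t >= first_stim:
            phase = (t - first_stim) % cl
            if phase < stim_dur:
                istim = stim_amp
        dv = _step_core(y, g, dt, istim, infs, taus, aux)
        if dv > dvdt_max:
            dvdt_max = dv
        if (step + 1) % rec_every == 0 and irec < n_rec:
            ts[irec] = t + dt
            vs[irec] = y[0]
            irec += 1
    return ts[:irec], vs[:irec], dvdt_max


@njit(cache=False)
def run_free(y, g, dt, duration):
    """Integrate without stimulation; returns final V (state advanced in place)."""
    n_steps = int(round(duration / dt))
    infs = np.empty(N_VGATES)
    taus = np.empty(N_VGATES)
    aux = np.empty(N_AUX)
    for _ in range(n_steps):
        _step_core(y, g, dt, 0.0, infs, taus, aux)
    return y[0]


def build_gate_tables(dt, vmin=-110.0, vmax=70.0, dv=0.02):
    """Pre-tabulated gate updates / auxiliary terms for the tissue solver.

    Returns (table, vmin, inv_dv) where ``table`` has one row per voltage
    sample and 30 columns: 12 gate steady states, 12 Rush-Larsen factors
    exp(-dt/tau) for the same gates, then the 6 auxiliary voltage terms of
    :func:`gate_rates`.  Linear interpolation in V; the 0.02 mV resolution
    keeps the tabulation error far below the solver's discretization error.
    """
    n = int(round((vmax - vmin) / dv)) + 1
    table = np.empty((n, 2 * N_VGATES + N_AUX), dtype=np.float64)
    infs = np.empty(N_VGATES)
    taus = np.empty(N_VGATES)
    aux = np.empty(N_AUX)
    for i in range(n):
        V = vmin + i * dv
        gate_rates(V, infs, taus, aux)
        table[i, :N_VGATES] = infs
        table[i, N_VGATES:2 * N_VGATES] = np.exp(-dt / taus)
        table[i, 2 * N_VGATES:] = aux
    return table, vmin, 1.0 / dv
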