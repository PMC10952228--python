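"""Independent reference implementation of the CRN atrial model.

Deliberately coded separately from the package: a plain-Python right-hand
side integrated with scipy's stiff LSODA solver, written from the published
model equations in gate-by-gate functional form.  Serves as the oracle for
the action-potential traces and biomarkers produced by the package's
Rush-Larsen/forward-Euler stepper.
"""

import math

import numpy as np
from scipy.integrate import solve_ivp

R, T, F = 8.3143, 310.0, 96.4867
CM = 100.0
VI, VUP, VREL = 13668.0, 1109.52, 96.48
NAO, KO, CAO = 140.0, 5.4, 1.8


def _safe_exp_ratio(num, den_expr):
    return num / den_expr


def gates_inf_tau(v):
    """dict gate -> (inf, tau)."""
    out = {}

    am = 3.2 if abs(v + 47.13) < 1e-10 else \
        0.32 * (v + 47.13) / (1 - math.exp(-0.1 * (v + 47.13)))
    bm = 0.08 * math.exp(-v / 11.0)
    out["m"] = (am / (am + bm), 1.0 / (am + bm))

    if v >= -40.0:
        ah, bh = 0.0, 1.0 / (0.13 * (1 + math.exp(-(v + 10.66) / 11.1)))
        aj = 0.0
        bj = 0.3 * math.exp(-2.535e-7 * v) / (1 + math.exp(-0.1 * (v + 32)))
    else:
        ah = 0.135 * math.exp(-(v + 80) / 6.8)
        bh = 3.56 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.35 * v)
        aj = (-1.2714e5 * math.exp(0.2444 * v) - 3.474e-5 * math.exp(-0.04391 * v)) \
            * (v + 37.78) / (1 + math.exp(0.311 * (v + 79.23)))
        bj = 0.1212 * math.exp(-0.01052 * v) / (1 + math.exp(-0.1378 * (v + 40.14)))
    out["h"] = (ah / (ah + bh), 1.0 / (ah + bh))
    out["j"] = (aj / (aj + bj), 1.0 / (aj + bj))

    a = 0.65 / (math.exp(-(v + 10) / 8.5) + math.exp(-(v - 30) / 59.0))
    b = 0.65 / (2.5 + math.exp((v + 82) / 17.0))
    out["oa"] = (1 / (1 + math.exp(-(v + 20.47) / 17.54)), 1 / (3.0 * (a + b)))
    a = 1 / (18.53 + math.exp((v + 113.7) / 10.95))
    b = 1 / (35.56 + math.exp(-(v + 1.26) / 7.44))
    out["oi"] = (1 / (1 + math.exp((v + 43.1) / 5.3)), 1 / (3.0 * (a + b)))

    a = 0.65 / (math.exp(-(v + 10) / 8.5) + math.exp(-(v - 30) / 59.0))
    b = 0.65 / (2.5 + math.exp((v + 82) / 17.0))
    out["ua"] = (1 / (1 + math.exp(-(v + 30.3) / 9.6)), 1 / (3.0 * (a + b)))
    a = 1 / (21.0 + math.exp(-(v - 185) / 28.0))
    b = math.exp((v - 158) / 16.0)
    out["ui"] = (1 / (1 + math.exp((v - 99.45) / 27.48)), 1 / (3.0 * (a + b)))

    a = 0.0015 if abs(v + 14.1) < 1e-10 else \
        3e-4 * (v + 14.1) / (1 - math.exp(-(v + 14.1) / 5.0))
    b = 3.7836118e-4 if abs(v - 3.3328) < 1e-10 else \
        7.3898e-5 * (v - 3.3328) / (math.exp((v - 3.3328) / 5.1237) - 1)
    out["xr"] = (1 / (1 + math.exp(-(v + 14.1) / 6.5)), 1 / (a + b))

    if abs(v - 19.9) < 1e-10:
        a, b = 6.8e-4, 3.15e-4
    else:
        a = 4e-5 * (v - 19.9) / (1 - math.exp(-(v - 19.9) / 17.0))
        b = 3.5e-5 * (v - 19.9) / (math.exp((v - 19.9) / 9.0) - 1)
    out["xs"] = ((1 + math.exp(-(v - 19.9) / 12.7)) ** -0.5, 0.5 / (a + b))

    if abs(v + 10) < 1e-10:
        td = 1 / (6.24 * 0.07)
    else:
        e = math.exp(-(v + 10) / 6.24)
        td = (1 - e) / (0.035 * (v + 10) * (1 + e))
    out["d"] = (1 / (1 + math.exp(-(v + 10) / 8.0)), td)
    out["f"] = (1 / (1 + math.exp((v + 28) / 6.9)),
                9.0 / (0.0197 * math.exp(-0.0337 ** 2 * (v + 10) ** 2) + 0.02))

    if abs(v - 7.9) < 1e-10:
        tw = 6.0 * 0.2 / 1.3
    else:
        e = math.exp(-(v - 7.9) / 5.0)
        tw = 6.0 * (1 - e) / ((1 + 0.3 * e) * (v - 7.9))
    out["w"] = (1 - 1 / (1 + math.exp(-(v - 40) / 17.0)), tw)
    return out


ORDER = ["V", "m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs", "d", "f",
         "fca", "u", "v", "w", "Nai", "Ki", "Cai", "Caup", "Carel"]


def rhs(t, y, factors, istim_fn):
    (v, m, h, j, oa, oi, ua, ui, xr, xs, d, f, fca, u, vv, w,
     nai, ki, cai, caup, carel) = y
    fac = factors
    rtf = R * T / F
    ena, ek = rtf * math.log(NAO / nai), rtf * math.log(KO / ki)
    eca = rtf / 2 * math.log(CAO / cai)

    ina = fac["g_Na"] * 7.8 * m ** 3 * h * j * (v - ena)
    ik1 = fac["g_K1"] * 0.09 * (v - ek) / (1 + math.exp(0.07 * (v + 80)))
    ito = fac["g_to"] * 0.1652 * oa ** 3 * oi * (v - ek)
    gkur = 0.005 + 0.05 / (1 + math.exp(-(v - 15) / 13.0))
    ikur = fac["g_Kur"] * gkur * ua ** 3 * ui * (v - ek)
    ikr = fac["g_Kr"] * 0.029411765 * xr * (v - ek) / (1 + math.exp((v + 15) / 22.4))
    iks = fac["g_Ks"] * 0.12941176 * xs ** 2 * (v - ek)
    ical = fac["g_CaL"] * 0.12375 * d * f * fca * (v - 65.0)
    sig = (math.exp(NAO / 67.3) - 1) / 7.0
    fnak = 1 / (1 + 0.1245 * math.exp(-0.1 * F * v / (R * T))
                + 0.0365 * sig * math.exp(-F * v / (R * T)))
    inak = fac["g_NaK"] * 0.59933874 * fnak / (1 + (10.0 / nai) ** 1.5) \
        * KO / (KO + 1.5)
    g = F * v / (R * T)
    incx = fac["g_NCX"] * 1600.0 * (
        math.exp(0.35 * g) * nai ** 3 * CAO
        - math.exp(-0.65 * g) * NAO ** 3 * cai) / (
        (87.5 ** 3 + NAO ** 3) * (1.38 + CAO) * (1 + 0.1 * math.exp(-0.65 * g)))
    ipca = 0.275 * cai / (0.0005 + cai)
    ibna = 0.0006744375 * (v - ena)
    ibca = 0.001131 * (v - eca)

    irel = fac["g_rel"] * 30.0 * u ** 2 * vv * w * (carel - cai)
    itr = (caup - carel) / 180.0
    iup = fac["g_up"] * 0.005 / (1 + 0.00092 / cai)
    ileak = fac["g_leak"] * 0.005 * caup / 15.0

    fn = 1e-12 * VREL * irel - 1e-12 / F * (0.5 * ical - 0.2 * incx) * CM
    uinf = 1 / (1 + math.exp(-(fn - 3.4175e-13) / 1.367e-15))
    vinf = 1 - 1 / (1 + math.exp(-(fn - 6.835e-14) / 1.367e-15))
    tauv = 1.91 + 2.09 * uinf
    fcainf = 1 / (1 + cai / 0.00035)

    gt = gates_inf_tau(v)
    dy = np.empty_like(y)
    iion = (ina + ik1 + ito + ikur + ikr + iks + ical + ipca + inak + incx
            + ibna + ibca)
    dy[0] = -(iion + istim_fn(t))
    for idx, gname in [(1, "m"), (2, "h"), (3, "j"), (4, "oa"), (5, "oi"),
                       (6, "ua"), (7, "ui"), (8, "xr"), (9, "xs"), (10, "d"),
                       (11, "f"), (15, "w")]:
        inf, tau = gt[gname]
        dy[idx] = (inf - y[idx]) / tau
    dy[12] = (fcainf - fca) / 2.0
    dy[13] = (uinf - u) / 8.0
    dy[14] = (vinf - vv) / tauv

    cf = CM / (F * VI)
    dy[16] = cf * (-3 * inak - (3 * incx + ibna + ina))
    dy[17] = cf * (2 * inak - (ik1 + ito + ikur + ikr + iks))
    b1 = cf / 2 * (2 * incx - (ipca + ical + ibca)) \
        + (VUP * (ileak - iup) + irel * VREL) / VI
    b2 = 1 + 0.07 * 0.0005 / (cai + 0.0005) ** 2 \
        + 0.05 * 0.00238 / (cai + 0.00238) ** 2
    dy[18] = b1 / b2
    dy[19] = iup - ileak - itr * VREL / VUP
    dy[20] = (itr - irel) / (1 + 10.0 * 0.8 / (carel + 0.8) ** 2)
    return dy


def paced_trace(y0, factors, cl, n_beats, stim_amp=-20.0, stim_dur=2.0,
                sample_dt=1.0, rtol=1e-8, atol=1e-8):
    """Voltage sampled every ``sample_dt`` ms over the full paced run."""
    y = np.array(y0, float)
    ts_all, vs_all = [], []
    t_base = 0.0
    for _ in range(n_beats):
        for (t0, t1, amp) in [(0.0, stim_dur, stim_amp), (stim_dur, cl, 0.0)]:
            tt = np.arange(t0, t1, sample_dt)
            if tt.size == 0 or tt[-1] < t1:
                tt = np.append(tt, t1)
            sol = solve_ivp(rhs, (t0, t1), y, t_eval=tt, method="LSODA",
                            rtol=rtol, atol=atol, max_step=1.0,
                            args=(factors, lambda t: amp))
            y = sol.y[:, -1]
            ts_all.append(t_base + sol.t[:-1])
            vs_all.append(sol.y[0, :-1])
        t_base += cl
    return np.concatenate(ts_all), np.concatenate(vs_all), y


def apd90(ts, vs, stim_time):
    sel = ts >= stim_time
    t, v = ts[sel], vs[sel]
    peak = v.max()
    rmp = v[0]
    thr = peak - 0.9 * (peak - rmp)
    act = t[np.argmax(np.gradient(v, t))]
    below = np.flatnonzero((v < thr) & (t > act))
    return float(t[below[0]] - act)
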