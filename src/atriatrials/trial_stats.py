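"""Cohort assembly, sustenance/response grouping and trial statistics.

A cohort is the cross product (ionic profile x LVA substrate x treatment).
Control episodes determine which virtual atria sustain AF; treatments are
applied only to control-sustained pairs, and efficacy, sustenance groups,
drug-response groups and the treatment-stratification rule operate on the
resulting cohort table.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cell_population import ConductanceScaling
from .drug_library import DrugModel
from .errors import ValidationError
from .tissue_sim import (DrugEvent, EpisodeResult, MonodomainParams,
                         SpiralInitSpec, init_spirals, run_episode)

#: desk-scale cohort discretization: 8 x 6 cm sheet, coarse grid with the
#: conductivity calibrated at this same grid so the bulk CV target holds
DESK_DIMS = (160, 120)
DESK_DX = 0.5       # mm
DESK_DT = 0.05      # ms


def desk_params(sigma_l: float, **kw) -> MonodomainParams:
    """Monodomain parameters for the desk-scale cohort grid."""
    return MonodomainParams(sigma_l=sigma_l, dx=DESK_DX, dt=DESK_DT, **kw)


def run_control_episodes(profiles: Sequence[ConductanceScaling], sheets,
                         params: MonodomainParams, horizon: float,
                         electrodes=None, lib_cl=None,
                         **episode_kw):
    """Control (no-drug) episode per (profile x substrate).

    Returns ``(episodes, table)``: a dict keyed by (profile_id, substrate_id)
    and the control rows of the cohort table.  Substrates are enumerated by
    position (``s0``, ``s1``, ...) unless they carry a ``substrate_id``.
    """
    episodes = {}
    rows = []
    for p, (sid, sheet) in itertools.product(profiles, _named(sheets)):
        init = init_spirals(sheet, SpiralInitSpec.default(sheet), p, lib_cl=lib_cl)
        res = run_episode(sheet, params, p, init[:2], horizon=horizon,
                          electrodes=electrodes, **episode_kw)
        episodes[(p.profile_id, sid)] = res
        rows.append(_row(p, sid, "control", res, sheet))
    return episodes, pd.DataFrame(rows)


def run_drug_episodes(profiles, sheets, params, horizon, control_table,
                      drugs: Sequence[DrugModel], drug_time: float,
                      electrodes=None, lib_cl=None, **episode_kw):
    """Treated episodes for every control-sustained (profile x substrate) pair.

    The drug is administered ``drug_time`` ms into a re-run of the same
    episode (identical initial conditions), and the episode continues to the
    original horizon.
    """
    ctrl = control_table.set_index(["profile_id", "substrate_id"])
    rows = []
    prof_by_id = {p.profile_id: p for p in profiles}
    for sid, sheet in _named(sheets):
        inits = {}
        for (pid, s), r in ctrl.iterrows():
            if s != sid or not r["sustained"]:
                continue
            p = prof_by_id[pid]
            if pid not in inits:
                inits[pid] = init_spirals(sheet, SpiralInitSpec.default(sheet),
                                          p, lib_cl=lib_cl)
            for drug in drugs:
                res = run_episode(sheet, params, p, inits[pid][:2],
                                  horizon=horizon,
                                  drug_event=DrugEvent(drug, drug_time),
                                  electrodes=electrodes, **episode_kw)
                rows.append(_row(p, sid, drug.label, res, sheet))
    return pd.DataFrame(rows)


def _named(sheets):
    for i, s in enumerate(sheets):
        sid = getattr(s, "substrate_id", None) or f"s{i}"
        yield sid, s


def _row(profile, sid, treatment, res: EpisodeResult, sheet):
    from .synthetic_substrate import POSTERIOR_LABELS, lva_fraction
    row = {"profile_id": profile.profile_id, "substrate_id": sid,
           "treatment": treatment, "sustained": res.sustained,
           "termination_time": res.termination_time}
    try:
        row["lva_la"] = lva_fraction(sheet, "la")
        row["lva_pw"] = lva_fraction(sheet, POSTERIOR_LABELS)
    except ValidationError:
        row["lva_la"] = row["lva_pw"] = 0.0
    for name in ("g_CaL", "g_Na", "g_K1", "g_NaK", "g_to"):
        row[name] = getattr(profile, name)
    return row


def check_cohort(table: pd.DataFrame) -> None:
    """Bookkeeping invariant: every treated row has its control row, and
    treated rows exist exactly for control-sustained pairs x treatments."""
    ctrl = table[table.treatment == "control"]
    treated = table[table.treatment != "control"]
    ctrl_idx = set(zip(ctrl.profile_id, ctrl.substrate_id))
    for pid, sid in zip(treated.profile_id, treated.substrate_id):
        if (pid, sid) not in ctrl_idx:
            raise ValidationError(f"treated pair ({pid}, {sid}) lacks a control row")
    n_sust = int(ctrl.sustained.sum())
    n_treatments = treated.treatment.nunique()
    if n_treatments and len(treated) != n_sust * n_treatments:
        raise ValidationError(
            f"expected {n_sust * n_treatments} treated rows, found {len(treated)}")


def group_by_sustenance(table: pd.DataFrame) -> pd.DataFrame:
    """Per-profile fraction of substrates with sustained AF under control.

    Categories: low (< 25% of substrates), mid (25-75%), high (> 75%).
    Every profile must cover every substrate.
    """
    ctrl = table[table.treatment == "control"]
    if ctrl.empty:
        raise ValidationError("no control rows in cohort")
    cov = ctrl.groupby("profile_id")["substrate_id"].nunique()
    if cov.nunique() != 1:
        raise ValidationError("profiles do not cover the same substrates")
    frac = ctrl.groupby("profile_id")["sustained"].mean()

    def cat(f):
        if f < 0.25:
            return "low"
        if f > 0.75:
            return "high"
        return "mid"

    return pd.DataFrame({"sustained_fraction": frac,
                         "category": frac.map(cat)}).reset_index()


def group_by_drug_response(table: pd.DataFrame, drug_label: str) -> pd.DataFrame:
    """Per-profile fraction of control-sustained substrates responding to a
    drug (AF terminated), in categories 100%, 50-90% and 0-50%."""
    ctrl = table[(table.treatment == "control") & table.sustained]
    drg = table[table.treatment == drug_label].set_index(
        ["profile_id", "substrate_id"])
    rows = []
    for pid, grp in ctrl.groupby("profile_id"):
        n, resp = 0, 0
        for sid in grp.substrate_id:
            if (pid, sid) not in drg.index:
                raise ValidationError(
                    f"missing {drug_label} row for sustained pair ({pid}, {sid})")
            n += 1
            resp += int(not drg.loc[(pid, sid), "sustained"])
        f = resp / n
        cat = "100%" if f == 1.0 else ("50-90%" if f > 0.5 else "0-50%")
        rows.append({"profile_id": pid, "response_fraction": f, "category": cat,
                     "n_substrates": n})
    return pd.DataFrame(rows)


def compare_groups(values_a, values_b) -> dict:
    """Nonparametric two-group comparison report.

    Kolmogorov-Smirnov normality per group, two-sided Wilcoxon rank-sum
    p-value (exact when both n <= 10 and tie-free, asymptotic otherwise),
    medians, interquartile ranges (linear-interpolation quartiles) and the
    rank-biserial effect size.  Two identical groups return p = 1.0 (tie
    convention).
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) < 3 or len(b) < 3:
        raise ValidationError("each group needs n >= 3")

    def ks_norm(x):
        if x.std(ddof=1) == 0:
            return 0.0
        return float(stats.kstest((x - x.mean()) / x.std(ddof=1), "norm").pvalue)

    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0.0:
        p, method, u = 1.0, "degenerate-ties", len(a) * len(b) / 2.0
    else:
        exact = (len(a) <= 10 and len(b) <= 10
                 and len(np.unique(pooled)) == len(pooled))
        r = stats.mannwhitneyu(a, b, alternative="two-sided",
                               method="exact" if exact else "asymptotic")
        p, u = float(r.pvalue), float(r.statistic)
        method = "exact" if exact else "asymptotic"

    def iqr(x):
        q1, q3 = np.percentile(x, [25, 75])
        return (float(q1), float(q3))

    return {"n_a": len(a), "n_b": len(b),
            "median_a": float(np.median(a)), "median_b": float(np.median(b)),
            "iqr_a": iqr(a), "iqr_b": iqr(b),
            "ks_normality_p_a": ks_norm(a), "ks_normality_p_b": ks_norm(b),
            "p_value": p, "method": method,
            "rank_biserial": float(1.0 - 2.0 * u / (len(a) * len(b))),
            "significant": p < 0.05}


def benjamini_hochberg(p_values) -> np.ndarray:
    """Optional FDR adjustment (the default reporting uses raw p-values)."""
    p = np.asarray(p_values, float)
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.clip(ranked, 0, 1)
    return out


def stratify_treatment(scaling: ConductanceScaling, deadband: float = 0.0) -> str:
    """Recommended drug from the inward-current profile.

    I_Na not up-regulated -> flecainide; I_Na up-regulated -> vernakalant
    when I_CaL is high, amiodarone when I_CaL is low.  "Up-regulated" means
    factor > 1 + deadband; at I_CaL the boundary resolves high (>= 1 counts
    as high).
    """
    if scaling.g_Na <= 1.0 + deadband:
        return "flecainide"
    if scaling.g_CaL >= 1.0 - deadband:
        return "vernakalant"
    return "amiodarone"
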