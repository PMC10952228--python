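"""Shared fixtures: profiles, substrates and cached desk-scale AF episodes.

The tissue-level acceptance checks share one calibrated conductivity and a
small set of simulated episodes; everything heavy is session-scoped and
computed lazily so each episode is simulated exactly once per run.
"""

import numpy as np
import pytest

import atriatrials as at

DESK_SIGMA_GUESS = 5.0
HORIZON_MS = 2500.0        # desk-scale episode horizon (7 s-equivalent)
ROTOR_HORIZON_MS = 2000.0  # single-rotor episodes (DF estimation)
DENSITY_HORIZON_MS = 1600.0


@pytest.fixture(scope="session")
def baseline():
    return at.ConductanceScaling()


@pytest.fixture(scope="session")
def af_prone():
    return at.ConductanceScaling(g_K1=1.5, g_to=1.5, g_NaK=1.5, g_CaL=0.5,
                                 profile_id="af-prone")


@pytest.fixture(scope="session")
def af_resistant():
    return at.ConductanceScaling(g_CaL=1.5, g_NaK=0.5, profile_id="af-resistant")


@pytest.fixture(scope="session")
def desk_params(baseline):
    """Monodomain parameters with conductivity calibrated for 80 cm/s on the
    desk cohort grid."""
    sigma, _ = at.calibrate_conductivity(80.0, baseline,
                                         at.desk_params(DESK_SIGMA_GUESS))
    return at.desk_params(sigma)


@pytest.fixture(scope="session")
def sheet_small_lva():
    sheet = at.build_sheet(at.trial_stats.DESK_DIMS, dx=0.5)
    at.generate_voltage_map(sheet, at.LVAPattern(0.222, patch_scale_mm=4.0,
                                                 seed=7))
    return sheet


@pytest.fixture(scope="session")
def sheet_large_lva():
    sheet = at.build_sheet(at.trial_stats.DESK_DIMS, dx=0.5)
    at.generate_voltage_map(sheet, at.LVAPattern(0.442, patch_scale_mm=6.0,
                                                 seed=11))
    return sheet


@pytest.fixture(scope="session")
def homogeneous_sheet():
    sheet = at.build_sheet((100, 100), dx=0.5)
    sheet.bi = np.full(sheet.shape, 1.0)
    sheet.lva = at.binarize(sheet)
    return sheet


@pytest.fixture(scope="session")
def homogeneous_large_sheet():
    sheet = at.build_sheet(at.trial_stats.DESK_DIMS, dx=0.5)
    sheet.bi = np.full(sheet.shape, 1.0)
    sheet.lva = at.binarize(sheet)
    return sheet


def k1_variant_profiles(g_k1, n, seed=42):
    """Profiles sharing the AF-prone backbone (high g_to/g_NaK, low g_CaL)
    with the given g_K1 and mild variation in the repolarizing currents."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        out.append(at.ConductanceScaling(
            g_K1=g_k1, g_to=1.5, g_NaK=1.5, g_CaL=0.5,
            g_Kr=float(rng.uniform(0.8, 1.2)),
            g_Kur=float(rng.uniform(0.8, 1.2)),
            g_Ks=float(rng.uniform(0.8, 1.2)),
            profile_id=f"k1[{g_k1}]-{i}"))
    return out


class EpisodeCache:
    """Lazily simulated, memoized AF episodes keyed by configuration."""

    def __init__(self, params):
        self.params = params
        self._store = {}

    def episode(self, key, sheet, profile, horizon, *, centers=None,
                electrodes=False, drug=None, drug_time=None):
        if key in self._store:
            return self._store[key]
        spec = (at.SpiralInitSpec(centers=centers) if centers is not None
                else at.SpiralInitSpec.default(sheet))
        init = at.init_spirals(sheet, spec, profile)
        el = at.default_electrodes(sheet) if electrodes else None
        event = at.DrugEvent(drug, drug_time) if drug is not None else None
        res = at.run_episode(sheet, self.params, profile, init[:2],
                             horizon=horizon, electrodes=el,
                             sample_rate_hz=500.0, drug_event=event)
        self._store[key] = res
        return res


@pytest.fixture(scope="session")
def episodes(desk_params):
    return EpisodeCache(desk_params)


def lead_df(result, lead="V1", skip_ms=500.0):
    """Lead dominant frequency after discarding the initiation transient."""
    leads = at.episode_leads(result)
    skip = int(skip_ms / 1000.0 * leads.fs)
    return at.dominant_frequency(leads.lead(lead)[skip:], leads.fs)
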