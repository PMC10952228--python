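"""CRN cell model, ionic-profile sampling, AP biomarkers and calibration."""

import math

import numpy as np
import pytest

import atriatrials as at
from atriatrials import _crn
from atriatrials.cell_population import CellState, measure_erp
from atriatrials.errors import IntegrationError, ValidationError


@pytest.fixture(scope="module")
def baseline():
    return at.ConductanceScaling()


class TestStepCell:
    def test_rest_is_a_fixed_point(self, baseline):
        s = CellState()
        s2 = at.step_cell(s, baseline, dt=0.02)
        assert abs(s2.voltage - s.voltage) < 1e-3
        assert s2.t == pytest.approx(0.02)

    def test_unstimulated_cell_drifts_below_half_mv_over_10s(self, baseline):
        y = _crn.REST_STATE.copy()
        v = _crn.run_free(y, baseline.as_array(), 0.02, 10000.0)
        assert abs(v - _crn.REST_STATE[0]) < 0.5
        assert (y[16:] > 0).all()      # concentrations stay positive

    def test_determinism(self, baseline):
        a = at.step_cell(CellState(), baseline, 0.02, -20.0)
        b = at.step_cell(CellState(), baseline, 0.02, -20.0)
        assert np.array_equal(a.y, b.y)

    def test_dt_validation(self, baseline):
        with pytest.raises(ValidationError):
            at.step_cell(CellState(), baseline, 0.1)

    def test_non_finite_state_names_the_variable(self, baseline):
        s = CellState()
        s.y[18] = np.nan        # Cai
        with pytest.raises(IntegrationError, match="Cai|Carel|V"):
            at.step_cell(s, baseline, 0.02)


class TestSampling:
    def test_lhs_stratification_one_sample_per_bin(self):
        n = 50
        pop = at.sample_population(n, seed=5)
        arr = np.array([p.as_array() for p in pop])
        for col in range(arr.shape[1]):
            bins = np.floor((arr[:, col] - 0.5) / (1.0 / n)).astype(int)
            assert sorted(bins.tolist()) == list(range(n))

    def test_three_hundred_profiles_within_bounds(self):
        pop = at.sample_population(300, seed=0)
        assert len(pop) == 300
        arr = np.array([p.as_array() for p in pop])
        assert arr.min() >= 0.5 and arr.max() <= 1.5

    def test_single_profile_and_custom_bounds(self):
        (p,) = at.sample_population(1, bounds={"g_Na": (0.9, 1.1)}, seed=2)
        assert 0.9 <= p.g_Na <= 1.1

    def test_same_seed_reproduces_population(self):
        a = at.sample_population(20, seed=11)
        b = at.sample_population(20, seed=11)
        assert all(np.array_equal(x.as_array(), y.as_array())
                   for x, y in zip(a, b))

    @pytest.mark.parametrize("kw", [dict(n=0), dict(n=5, bounds={"g_Na": (1.2, 0.8)}),
                                    dict(n=5, bounds={"bogus": (0.5, 1.5)})])
    def test_validation_errors(self, kw):
        with pytest.raises(ValidationError):
            at.sample_population(kw.pop("n"), **kw)


class TestBiomarkers:
    def test_baseline_biomarker_consistency(self, baseline):
        bm = at.compute_biomarkers(baseline, pacing_cl=1000.0, n_beats=3)
        assert bm.excitable
        assert bm.amplitude > 0
        assert bm.apd50 <= bm.apd90 < 1000.0
        assert bm.erp >= bm.apd50
        assert -90 < bm.rmp < -70
        assert bm.dvdt_max > 100.0

    def test_low_gcal_shortens_apd90(self, baseline):
        ref = at.compute_biomarkers(baseline, n_beats=3, include_erp=False)
        low = at.compute_biomarkers(baseline.scaled(g_CaL=0.5), n_beats=3,
                                    include_erp=False)
        assert low.apd90 < ref.apd90

    def test_high_gk1_hyperpolarizes_rmp(self, baseline):
        ref = at.compute_biomarkers(baseline, n_beats=3, include_erp=False)
        up = at.compute_biomarkers(baseline.scaled(g_K1=1.5), n_beats=3,
                                   include_erp=False)
        assert up.rmp < ref.rmp

    def test_rmp_monotone_in_gk1(self, baseline):
        rmps = [at.compute_biomarkers(baseline.scaled(g_K1=g), n_beats=2,
                                      include_erp=False).rmp
                for g in (0.5, 0.75, 1.0, 1.25, 1.5)]
        assert all(b <= a + 1e-6 for a, b in zip(rmps, rmps[1:]))

    def test_zero_gna_flags_inexcitable(self, baseline):
        bm = at.compute_biomarkers(baseline.scaled(g_Na=0.0), n_beats=2,
                                   include_erp=False)
        assert not bm.excitable
        assert math.isnan(bm.apd90)

    def test_protocol_validation(self, baseline):
        with pytest.raises(ValidationError):
            at.compute_biomarkers(baseline, pacing_cl=200.0)
        with pytest.raises(ValidationError):
            at.compute_biomarkers(baseline, n_beats=1)


class TestERP:
    def test_erp_monotonicity_in_gk1_and_gcal(self, baseline):
        """AF-prone remodelling direction: higher g_K1 shortens the ERP,
        higher g_CaL lengthens it (within one 5 ms protocol step)."""
        res = 5.0
        erp_k1 = [measure_erp(baseline.scaled(g_K1=g))
                  for g in np.linspace(0.5, 1.5, 10)]
        assert all(b <= a + res for a, b in zip(erp_k1, erp_k1[1:]))
        erp_cal = [measure_erp(baseline.scaled(g_CaL=g))
                   for g in np.linspace(0.5, 1.5, 10)]
        assert all(b >= a - res for a, b in zip(erp_cal, erp_cal[1:]))

    def test_zero_block_drug_gives_zero_shift(self, baseline):
        zero = at.DrugModel("placebo", "0", "none", {})
        assert at.refractoriness_shift(baseline, zero) == 0.0

    def test_full_sodium_block_is_complete_block(self, baseline):
        blocker = at.DrugModel("tetrodotoxin", "sat", "full", {"I_Na": 1.0})
        assert at.refractoriness_shift(baseline, blocker) == math.inf


@pytest.fixture(scope="module")
def small_pop():
    return at.sample_population(30, seed=7)


class TestCalibration:

    def test_unbounded_ranges_accept_everything_excitable(self, small_pop):
        ranges = {"apd90": (-np.inf, np.inf), "rmp": (-np.inf, np.inf)}
        acc, rep = at.calibrate_population(small_pop, ranges, n_beats=2)
        assert len(acc) == int(rep.excitable.sum())

    def test_range_excluding_baseline_rejects_with_reason(self):
        base = at.ConductanceScaling()
        bm = at.compute_biomarkers(base, n_beats=3, include_erp=False)
        ranges = {"apd90": (bm.apd90 + 50.0, bm.apd90 + 100.0)}
        acc, rep = at.calibrate_population([base], ranges, n_beats=3)
        assert not acc
        assert "apd90" in rep.iloc[0].reasons

    def test_default_ranges_accept_a_majority(self, small_pop):
        acc, rep = at.calibrate_population(small_pop, n_beats=3)
        assert len(acc) > 0
        sub = at.select_subset(acc, min(10, len(acc)), seed=1)
        sub2 = at.select_subset(acc, min(10, len(acc)), seed=1)
        assert [p.profile_id for p in sub] == [p.profile_id for p in sub2]

    def test_empty_range_set_rejected(self, small_pop):
        with pytest.raises(ValidationError):
            at.calibrate_population(small_pop, {})


def test_population_csv_roundtrip(tmp_path):
    pop = at.sample_population(5, seed=9)
    path = tmp_path / "pop.csv"
    at.cell_population.population_to_csv(pop, path)
    back = at.cell_population.population_from_csv(path)
    assert all(np.allclose(a.as_array(), b.as_array())
               for a, b in zip(pop, back))
    assert [p.profile_id for p in back] == [p.profile_id for p in pop]
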