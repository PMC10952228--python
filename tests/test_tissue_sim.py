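"""Monodomain solver: LVA remodelling, CV behaviour, spiral initiation and
sustenance classification."""

import numpy as np
import pytest

import atriatrials as at
from atriatrials.cell_population import ConductanceScaling
from atriatrials.errors import CalibrationFailure, ValidationError
from atriatrials.tissue_sim import (LVA_ANISOTROPY_RATIO,
                                    LVA_CONDUCTIVITY_FACTOR, EpisodeResult,
                                    MonodomainParams, check_stability,
                                    _diffusion_tensors)


@pytest.fixture(scope="module")
def lva_sheet():
    sheet = at.build_sheet((60, 60), dx=0.5)
    at.generate_voltage_map(sheet, at.LVAPattern(0.3, seed=1))
    return sheet


class TestLVARemodelling:
    def test_ionic_and_conductivity_remodelling_exact(self, lva_sheet):
        params = at.desk_params(2.0)
        prof = ConductanceScaling(g_CaL=1.2, g_Na=1.0, g_K1=1.0, g_to=0.9)
        G, sig_l, sig_t = at.apply_lva_remodelling(lva_sheet, params, prof)
        lva = lva_sheet.lva_mask().ravel()
        i_cal = at.FACTOR_NAMES.index("g_CaL")
        i_na = at.FACTOR_NAMES.index("g_Na")
        i_k1 = at.FACTOR_NAMES.index("g_K1")
        i_to = at.FACTOR_NAMES.index("g_to")
        # non-LVA nodes keep the profile's factors
        assert np.allclose(G[~lva, i_cal], 1.2)
        assert np.allclose(sig_l[~lva], 2.0)
        # LVA nodes: 50/40/50% decreases applied multiplicatively
        assert np.allclose(G[lva, i_cal], 0.6)
        assert np.allclose(G[lva, i_na], 0.6)
        assert np.allclose(G[lva, i_k1], 0.5)
        assert np.allclose(G[lva, i_to], 0.9)     # untargeted current untouched
        # conductivity x0.70 and 8:1 anisotropy
        assert np.allclose(sig_l[lva], 2.0 * LVA_CONDUCTIVITY_FACTOR)
        assert np.allclose(sig_l[lva] / sig_t[lva], LVA_ANISOTROPY_RATIO)

    def test_alternative_scheme_switch(self, lva_sheet):
        params = at.desk_params(2.0, lva_scheme="50-60-50")
        G, _, _ = at.apply_lva_remodelling(lva_sheet, params,
                                           ConductanceScaling())
        lva = lva_sheet.lva_mask().ravel()
        assert np.allclose(G[lva, at.FACTOR_NAMES.index("g_Na")], 0.4)

    def test_composes_with_drug_block_commutatively(self, lva_sheet):
        params = at.desk_params(2.0)
        drug = at.get_drug("vernakalant", "30uM")
        prof = ConductanceScaling(g_CaL=1.2, g_Na=0.9)
        g_then_drug, _, _ = at.apply_lva_remodelling(
            lva_sheet, params, at.apply_drug(prof, drug))
        G0, _, _ = at.apply_lva_remodelling(lva_sheet, params, prof)
        for cur, frac in drug.block.items():
            from atriatrials.drug_library import CURRENT_TO_FACTOR
            G0[:, at.FACTOR_NAMES.index(CURRENT_TO_FACTOR[cur])] *= (1 - frac)
        assert np.allclose(g_then_drug, G0)

    def test_regional_zone_table(self, lva_sheet):
        params = at.desk_params(2.0)
        G, _, _ = at.apply_lva_remodelling(
            lva_sheet, params, ConductanceScaling(),
            regional_factors={"RA": {"g_to": 0.8}})
        ra = lva_sheet.ra_mask().ravel()
        i_to = at.FACTOR_NAMES.index("g_to")
        assert np.allclose(G[ra, i_to], 0.8)
        assert np.allclose(G[~ra, i_to], 1.0)


class TestParams:
    def test_validation(self):
        with pytest.raises(ValidationError):
            MonodomainParams(sigma_l=-1.0)
        with pytest.raises(ValidationError):
            MonodomainParams(sigma_l=1.0, sigma_t=2.0)
        with pytest.raises(ValidationError):
            MonodomainParams(lva_scheme="10-10-10")

    def test_stability_guard(self):
        p = MonodomainParams(sigma_l=3.4, dx=0.5, dt=0.9)
        with pytest.raises(ValidationError, match="unstable"):
            check_stability(p, p.diffusivity(p.sigma_l))

    def test_diffusivity_units(self):
        p = MonodomainParams(sigma_l=1.4)
        # 1.4 mS/cm over chi=1400/cm, Cm=1 uF/cm^2 -> 0.1 mm^2/ms
        assert p.diffusivity(1.4) == pytest.approx(0.1)

    def test_zero_cv_target_rejected(self):
        with pytest.raises(ValidationError):
            at.calibrate_conductivity(0.0, ConductanceScaling())

    def test_unreachable_cv_target_fails_loudly(self):
        with pytest.raises(CalibrationFailure):
            at.calibrate_conductivity(400.0, ConductanceScaling(),
                                      at.desk_params(3.0), bracket=(0.5, 4.0))


class TestSpiralInitiation:
    def test_default_spec_six_alternating_singularities(self):
        sheet = at.build_sheet((120, 100), dx=0.5)
        sheet.bi = np.full(sheet.shape, 1.0)
        sheet.lva = at.binarize(sheet)
        spec = at.SpiralInitSpec.default(sheet)
        prone = ConductanceScaling(g_K1=1.5, g_CaL=0.5)
        V, Y, phase, territory = at.init_spirals(sheet, spec, prone)
        ps = at.phase_singularities(phase, territory)
        assert len(ps) == 6
        found = {(x, y): ch for x, y, ch in ps}
        for (cx, cy, chir) in spec.centers:
            match = [c for (x, y), c in found.items()
                     if abs(x - cx) <= 1 and abs(y - cy) <= 1]
            assert match == [chir]
        # adjacent re-entries within each chamber counter-rotate
        la = sorted(spec.centers[:3], key=lambda c: c[1])
        ra = sorted(spec.centers[3:], key=lambda c: c[1])
        for group in (la, ra):
            assert group[0][2] == -group[1][2] == group[2][2]

    def test_mirrored_chirality_mirrors_the_phase_field(self):
        sheet = at.build_sheet((80, 80), dx=0.5)
        sheet.bi = np.full(sheet.shape, 1.0)
        sheet.lva = at.binarize(sheet)
        prone = ConductanceScaling(g_K1=1.5, g_CaL=0.5)
        _, _, ph_p, terr = at.init_spirals(
            sheet, at.SpiralInitSpec(centers=[(40, 40, 1)]), prone, lib_cl=250.0)
        _, _, ph_m, _ = at.init_spirals(
            sheet, at.SpiralInitSpec(centers=[(40, 40, -1)]), prone, lib_cl=250.0)
        ps_p = at.phase_singularities(ph_p, terr)
        ps_m = at.phase_singularities(ph_m, terr)
        assert [c for _, _, c in ps_p] == [1]
        assert [c for _, _, c in ps_m] == [-1]
        # mirror image: reflecting y flips the sense of rotation
        mirrored = np.flipud(ph_m)
        ps_mirror = at.phase_singularities(mirrored)
        assert [c for _, _, c in ps_mirror] == [1]

    def test_centre_outside_sheet_rejected(self):
        sheet = at.build_sheet((60, 60), dx=0.5)
        with pytest.raises(ValidationError):
            at.init_spirals(sheet, at.SpiralInitSpec(centers=[(999, 5, 1)]),
                            ConductanceScaling())


class TestEpisodes:
    def test_resting_sheet_stays_quiescent(self):
        sheet = at.build_sheet((60, 60), dx=0.5)
        sheet.bi = np.full(sheet.shape, 1.0)
        sheet.lva = at.binarize(sheet)
        res = at.run_episode(sheet, at.desk_params(4.95), ConductanceScaling(),
                             init=None, horizon=2000.0, early_stop=False)
        assert res.act_counts.max() == 0
        assert not res.sustained
        assert res.termination_time == 0.0

    def test_classify_sustained_rules(self):
        def episode(times):
            n = 4
            act = np.zeros((n, 64), np.float32)
            counts = np.zeros(n, np.int32)
            for t in times:
                act[0, counts[0]] = t
                counts[0] += 1
            return EpisodeResult(sustained=True, termination_time=None,
                                 horizon=7000.0, act_times=act,
                                 act_counts=counts, shape=(2, 2), dx=0.5)

        assert at.classify_sustained(episode([100, 2900, 3000])) == (False, 3000.0)
        sustained, term = at.classify_sustained(
            episode(np.arange(100, 7000, 150)))
        assert sustained and term is None
        assert at.classify_sustained(episode([100.0])) == (False, 100.0)
        assert at.classify_sustained(episode([])) == (False, 0.0)

    def test_paced_sheet_activates_every_node_at_the_drive_rate(self):
        sheet = at.build_sheet((60, 60), dx=0.5)
        sheet.bi = np.full(sheet.shape, 1.0)
        sheet.lva = at.binarize(sheet)
        mask = np.zeros(sheet.shape, bool)
        mask[:, :3] = True
        res = at.run_episode(sheet, at.desk_params(4.95),
                             ConductanceScaling(g_CaL=0.5), init=None,
                             horizon=900.0,
                             stim=dict(mask=mask, amp=-40.0, start=10.0,
                                       dur=2.0, cl=400.0),
                             early_stop=False)
        counts = res.act_counts.reshape(sheet.shape)
        assert (counts >= 2).all()          # both paced beats propagate
        # cycle length between activations matches the drive
        times = res.act_times.reshape(*sheet.shape, -1)
        cl = times[30, 40, 1] - times[30, 40, 0]
        assert cl == pytest.approx(400.0, abs=10.0)

    def test_episode_hdf5_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        act = np.zeros((12, 6), np.float32)
        counts = rng.integers(0, 6, 12).astype(np.int32)
        for k in range(12):
            act[k, :counts[k]] = np.sort(rng.uniform(0, 5000, counts[k]))
        res = EpisodeResult(sustained=True, termination_time=None,
                            horizon=7000.0, act_times=act, act_counts=counts,
                            shape=(3, 4), dx=0.5,
                            electrode_potentials=rng.normal(size=(50, 9)),
                            profile_id="p1", drug_label="digoxin:5nM:standard")
        path = tmp_path / "episode.h5"
        at.tissue_sim.save_episode(res, path)
        back = at.tissue_sim.load_episode(path)
        assert back.sustained and back.termination_time is None
        assert back.shape == (3, 4)
        assert np.array_equal(back.act_counts, counts)
        assert np.allclose(back.electrode_potentials,
                           res.electrode_potentials)
        assert back.drug_label == "digoxin:5nM:standard"
        assert back.profile_id == "p1"

    def test_horizon_validation(self):
        sheet = at.build_sheet((60, 60), dx=0.5)
        with pytest.raises(ValidationError):
            at.run_episode(sheet, at.desk_params(4.95), ConductanceScaling(),
                           None, horizon=-5.0)


class TestConductionVelocity:
    def test_anisotropy_ratio_matches_conductivity(self):
        """CV along vs across fibers follows sqrt(sigma_l/sigma_t)."""
        params = MonodomainParams(sigma_l=3.4, anisotropy_ratio=4.0)
        prone = ConductanceScaling()
        cv_l = at.measure_strand_cv(params, prone, length_mm=30.0)
        iso_t = MonodomainParams(sigma_l=params.sigma_t, sigma_t=params.sigma_t)
        cv_t = at.measure_strand_cv(iso_t, prone, length_mm=30.0)
        expected = np.sqrt(params.sigma_l / params.sigma_t)
        assert cv_l / cv_t == pytest.approx(expected, rel=0.10)

    def test_rotated_fibers_use_the_transverse_tensor(self):
        # a fiber field at 90 deg makes x-propagation transverse
        params = MonodomainParams(sigma_l=3.4)
        sheet = at.synthetic_substrate.SubstrateSheet(
            nx=200, ny=5, dx=params.dx,
            labels=np.full((5, 200), 5, dtype=np.int8),
            fiber_angle=np.full((5, 200), np.pi / 2))
        dxx, dxy, dyy = _diffusion_tensors(
            sheet, params, np.full(1000, params.sigma_l),
            np.full(1000, params.sigma_t))
        assert np.allclose(dxx, params.diffusivity(params.sigma_t))
        assert np.allclose(dyy[2, 2], params.diffusivity(params.sigma_l))

    def test_cv_converges_under_dt_halving(self):
        base = MonodomainParams(sigma_l=3.4)
        cv1 = at.measure_strand_cv(base, ConductanceScaling(), length_mm=30.0)
        fine = MonodomainParams(sigma_l=3.4, dt=base.dt / 2)
        cv2 = at.measure_strand_cv(fine, ConductanceScaling(), length_mm=30.0)
        assert abs(cv2 - cv1) / cv1 < 0.03

    def test_cv_converges_under_dx_halving(self):
        base = MonodomainParams(sigma_l=3.4)
        cv1 = at.measure_strand_cv(base, ConductanceScaling(), length_mm=30.0)
        fine = MonodomainParams(sigma_l=3.4, dx=base.dx / 2, dt=0.004)
        cv2 = at.measure_strand_cv(fine, ConductanceScaling(), length_mm=30.0)
        assert abs(cv2 - cv1) / cv1 < 0.05

    def test_cv_scales_with_sqrt_conductivity(self):
        p1 = MonodomainParams(sigma_l=1.2, dx=0.1, dt=0.01)
        p4 = MonodomainParams(sigma_l=4.8, dx=0.1, dt=0.005)
        cv1 = at.measure_strand_cv(p1, ConductanceScaling(), length_mm=30.0)
        cv4 = at.measure_strand_cv(p4, ConductanceScaling(), length_mm=30.0)
        assert cv4 / cv1 == pytest.approx(2.0, rel=0.10)
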