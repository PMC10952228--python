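"""Pseudo-ECG forward model and spectral/entropy biomarkers."""

import numpy as np
import pytest

import atriatrials as at
from atriatrials.ecg_analysis import LeadSet, leads_from_unipolar, unipolar_potentials
from atriatrials.errors import UndefinedBiomarker, ValidationError

FS = 500.0


def _tone(f, seconds=8.0, fs=FS):
    t = np.arange(int(seconds * fs)) / fs
    return np.sin(2 * np.pi * f * t)


class TestDominantFrequency:
    def test_pure_tone_recovered(self):
        assert at.dominant_frequency(_tone(6.0), FS) == pytest.approx(6.0, abs=0.25)

    def test_strongest_component_wins(self):
        x = _tone(5.0) + 0.3 * _tone(9.0)
        assert at.dominant_frequency(x, FS) == pytest.approx(5.0, abs=0.25)

    def test_synthetic_f_wave_rate_recovered_within_bin(self):
        # sawtooth-like fibrillatory train at a known rate
        rate = 7.25
        t = np.arange(int(8 * FS)) / FS
        x = np.sin(2 * np.pi * rate * t) + 0.4 * np.sin(4 * np.pi * rate * t + 1.1)
        assert at.dominant_frequency(x, FS) == pytest.approx(rate, abs=0.25)

    def test_tracks_a_frequency_sweep(self):
        for f in (4.0, 6.0, 8.0, 11.0):
            assert at.dominant_frequency(_tone(f), FS) == pytest.approx(f, abs=0.25)

    def test_silent_signal_is_undefined(self):
        with pytest.raises(UndefinedBiomarker):
            at.dominant_frequency(np.zeros(4000), FS)


class TestOrganizationIndex:
    def test_pure_tone_nearly_one(self):
        assert at.organization_index(_tone(6.0), FS) >= 0.95

    def test_white_noise_below_one_half(self):
        # Monte-Carlo bound: the in-band harmonic windows cover a minority of
        # the 3-15 Hz band, so broadband noise scores low over 100 draws
        rng = np.random.default_rng(11)
        ois = [at.organization_index(rng.standard_normal(int(8 * FS)), FS)
               for _ in range(100)]
        assert np.mean(ois) <= 0.3

    def test_tone_plus_noise_in_between(self):
        rng = np.random.default_rng(1)
        x = _tone(6.0)
        noisy = x + rng.standard_normal(x.size) * x.std()
        oi = at.organization_index(noisy, FS)
        assert 0.3 < oi < at.organization_index(x, FS)


class TestEntropies:
    def test_spectral_entropy_high_for_white_noise(self):
        rng = np.random.default_rng(5)
        ses = [at.spectral_entropy(rng.standard_normal(int(8 * FS)), FS)
               for _ in range(100)]
        assert min(ses) >= 0.9

    def test_spectral_entropy_low_for_tone(self):
        assert at.spectral_entropy(_tone(6.0), FS) <= 0.4

    def test_constant_signal_conventions(self):
        assert at.sample_entropy(np.ones(200)) == 0.0
        with pytest.raises(UndefinedBiomarker):
            at.spectral_entropy(np.ones(4000), FS)

    def test_sample_entropy_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(160)
        m, r = 2, 0.2
        tol = r * x.std()

        def brute(mm):
            c = 0
            for i in range(len(x) - mm + 1):
                for j in range(len(x) - mm + 1):
                    if i == j:
                        continue
                    if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= tol:
                        c += 1
            return c // 2

        expected = -np.log(brute(m + 1) / brute(m))
        assert at.sample_entropy(x, m=m, r=r) == pytest.approx(expected, abs=1e-12)

    def test_sample_entropy_orders_regular_vs_noise(self):
        rng = np.random.default_rng(9)
        periodic = _tone(6.0, seconds=2.0, fs=250.0)
        noise = rng.standard_normal(500)
        assert at.sample_entropy(periodic) < at.sample_entropy(noise)

    def test_relative_harmonic_energy_bounds(self):
        x = _tone(4.0) + 0.5 * _tone(8.0)
        rhe = at.relative_harmonic_energy(x, FS)
        assert 0.0 < rhe < 1.0
        assert at.relative_harmonic_energy(_tone(6.0), FS) <= 0.05


class TestPseudoECG:
    def _sheet(self):
        return at.build_sheet((60, 50), dx=0.5)

    def test_uniform_voltage_gives_zero_potential(self):
        frames = np.full((3, 40, 50), -20.0, dtype=np.float32)
        el = np.array([[10.0, 10.0, 50.0], [0.0, 0.0, -30.0]])
        pot = unipolar_potentials(frames, 0.5, el)
        assert np.allclose(pot, 0.0, atol=1e-9)

    def test_wavefront_mirror_symmetries(self):
        # the in-plane dipole layer of a planar front: potential flips sign
        # when the electrode is mirrored across the wavefront and is even
        # under reflection across the sheet plane
        ny, nx = 40, 40
        v = np.full((ny, nx), -80.0)
        v[:, :20] = 20.0   # front at x = 10 mm of a 20 mm sheet
        frames = v[None].astype(np.float32)
        front_x, mid_y = 9.75, 9.75   # node-centred front/midline positions
        left = unipolar_potentials(frames, 0.5, [[front_x - 6.0, mid_y, 40.0]])
        right = unipolar_potentials(frames, 0.5, [[front_x + 6.0, mid_y, 40.0]])
        below = unipolar_potentials(frames, 0.5, [[front_x - 6.0, mid_y, -40.0]])
        assert left[0, 0] == pytest.approx(-right[0, 0], rel=1e-6)
        assert left[0, 0] == pytest.approx(below[0, 0], rel=1e-9)
        assert abs(left[0, 0]) > 0

    def test_linearity_in_the_voltage_field(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(-80, 20, (1, 30, 30)).astype(np.float32)
        b = rng.uniform(-80, 20, (1, 30, 30)).astype(np.float32)
        el = [[7.0, 7.0, 30.0]]
        pa = unipolar_potentials(a, 0.5, el)
        pb = unipolar_potentials(b, 0.5, el)
        pab = unipolar_potentials(a + b, 0.5, el)
        assert pab == pytest.approx(pa + pb, rel=1e-6)

    def test_far_field_decay_of_a_pointlike_disc(self):
        # the dipole layer bounding a compact depolarized disc is a closed
        # loop with zero net dipole moment, so the 1/r kernel's far field
        # falls off one power faster than a single dipole: |phi| ~ r^-3
        ny = nx = 60
        v = np.full((ny, nx), -80.0)
        yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
        v[(yy - 30) ** 2 + (xx - 30) ** 2 <= 9] = 20.0
        frames = v[None].astype(np.float32)
        zs = np.array([40.0, 80.0, 160.0, 320.0])
        pots = [abs(unipolar_potentials(frames, 0.5, [[15.0, 15.0, z]])[0, 0])
                for z in zs]
        slope = np.polyfit(np.log(zs), np.log(pots), 1)[0]
        assert slope == pytest.approx(-3.0, abs=0.3)

    def test_electrode_in_plane_rejected(self):
        with pytest.raises(ValidationError):
            unipolar_potentials(np.zeros((1, 10, 10), np.float32), 0.5,
                                [[1.0, 1.0, 0.0]])

    def test_lead_formation_and_leadset_invariants(self):
        pot = np.random.default_rng(0).normal(size=(1000, 9))
        leads = leads_from_unipolar(pot, 500.0)
        assert leads.data.shape == (1000, 8)
        assert np.allclose(leads.lead("I"), pot[:, 1] - pot[:, 0])
        with pytest.raises(ValidationError):
            LeadSet(data=np.zeros((10, 8)), fs=100.0)   # below 250 Hz

    def test_default_electrode_geometry(self):
        sheet = self._sheet()
        el = at.default_electrodes(sheet)
        assert el.shape == (9, 3)
        assert (np.abs(el[:, 2]) > 0).all()
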