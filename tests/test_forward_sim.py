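"""Forward simulator: GPD cylinder vs Monte-Carlo, mixing, MT, noise."""

import math

import numpy as np
import pytest

from axonflow import forward_sim as fs
from axonflow import protocols as prot
from axonflow import substrates as sub
from axonflow.exceptions import EmptySubstrateError, ParameterError

from conftest import bloch_mcconnell_mt, mc_cylinder_attenuation


class TestCylinderGPD:
    def test_zero_gradient_gives_unity(self):
        assert fs.cylinder_perp_attenuation(2.0, 0.0, 5.0, 18.0) == 1.0

    def test_motional_narrowing_limit(self):
        assert fs.cylinder_perp_attenuation(0.01, 625.5, 5.0, 18.0) == \
            pytest.approx(1.0, abs=1e-6)

    def test_monotone_in_gradient_and_diameter(self):
        ds = np.array([0.5, 1.0, 2.0, 4.0])
        att_d = fs.cylinder_perp_attenuation(ds, 625.5, 5.0, 18.0)
        assert np.all(np.diff(att_d) < 0)
        Gs = np.array([100.0, 300.0, 625.5])
        att_g = fs.cylinder_perp_attenuation(2.0, Gs, 5.0, 18.0)
        assert np.all(np.diff(att_g) < 0)

    def test_matches_monte_carlo_oracle_in_validity_regime(self, mc_oracle):
        # The Gaussian-phase series is quantitative at qR <~ 1 (q = gamma G
        # delta): every such cell of the preset grid agrees within 1%.
        from conftest import GAMMA, MC_CONFIGS, MC_DIAMETERS
        checked = 0
        for (preset, tier), (G, dl, DL) in MC_CONFIGS.items():
            for d in MC_DIAMETERS:
                qR = GAMMA * G * 1e-3 * dl * 1e-3 * d / 2 * 1e-6
                if qR > 1.1:
                    continue
                gpd = fs.cylinder_perp_attenuation(d, G, dl, DL, 0.35)
                mc = mc_oracle[(preset, tier, d)]
                assert gpd == pytest.approx(mc, rel=0.01), \
                    f"{preset}/{tier}, d={d} um"
                checked += 1
        assert checked >= 12

    def test_gaussian_phase_overestimates_signal_at_strong_restriction(
            self, mc_oracle):
        # Beyond validity (qR ~ 1.6-2.1: d = 5 um at strong gradients) the
        # phase distribution is platykurtic and the Gaussian-phase series
        # overestimates the true (random-walk) signal: documented behavior.
        from conftest import MC_CONFIGS
        for preset in ("mouse", "cord"):
            G, dl, DL = MC_CONFIGS[(preset, "hi")]
            gpd = fs.cylinder_perp_attenuation(5.0, G, dl, DL, 0.35)
            mc = mc_oracle[(preset, "hi", 5.0)]
            assert gpd > mc
            assert gpd - mc < 0.06  # bounded absolute signal excess


class TestIntraAxonalSignal:
    def test_parallel_gradient_is_free_gaussian(self, mouse_protocols):
        p = prot.DiffusionProtocol(np.array([[0.0, 0.0, 1.0]]), [625.5],
                                   delta=5.0, Delta=18.0)
        s = fs.intra_axonal_signal(2.0, p)
        b_si = (prot.GAMMA_H * 0.6255 * 5e-3) ** 2 * (18e-3 - 5e-3 / 3)
        assert s[0] == pytest.approx(np.exp(-b_si * 0.35e-9), rel=1e-10)

    def test_perpendicular_gradient_is_cylinder_attenuation(self):
        p = prot.DiffusionProtocol(np.array([[1.0, 0.0, 0.0]]), [625.5],
                                   delta=5.0, Delta=18.0)
        s = fs.intra_axonal_signal(2.0, p)
        assert s[0] == pytest.approx(
            fs.cylinder_perp_attenuation(2.0, 625.5, 5.0, 18.0), rel=1e-10)

    def test_oblique_gradient_factorizes(self, mc_oracle):
        # 45 degrees: product of the free parallel factor (exact Gaussian)
        # and the perpendicular restricted factor (vs the MC oracle)
        n = np.array([[np.sqrt(0.5), 0.0, np.sqrt(0.5)]])
        p = prot.DiffusionProtocol(n, [625.5], delta=5.0, Delta=18.0)
        s = fs.intra_axonal_signal(2.0, p)[0]
        Gp = 625.5 * np.sqrt(0.5)
        b_par = (prot.GAMMA_H * (0.6255 * np.sqrt(0.5)) * 5e-3) ** 2 \
            * (18e-3 - 5e-3 / 3)
        par = np.exp(-b_par * 0.35e-9)
        perp_mc = mc_cylinder_attenuation(2.0, Gp, 5.0, 18.0)
        assert s == pytest.approx(par * perp_mc, rel=0.01)


class TestExtracellular:
    def _proto(self, direction):
        return prot.DiffusionProtocol(np.array([direction]), [625.5],
                                      delta=5.0, Delta=18.0)

    def test_isotropic_at_zero_avf(self):
        sx = fs.extracellular_signal(self._proto([1.0, 0, 0]), 0.0)
        sz = fs.extracellular_signal(self._proto([0, 0, 1.0]), 0.0)
        assert sx[0] == pytest.approx(sz[0], rel=1e-12)

    def test_stick_at_full_avf(self):
        s = fs.extracellular_signal(self._proto([1.0, 0, 0]), 1.0)
        assert s[0] == pytest.approx(1.0)

    def test_b0_unity(self):
        p = prot.DiffusionProtocol(np.array([[0.0, 0, 1.0]]), [0.0],
                                   delta=5.0, Delta=18.0)
        assert fs.extracellular_signal(p, 0.5)[0] == 1.0


class TestMixing:
    def test_hand_evaluated_mixing_formula(self, monkeypatch):
        # two axons d = (1, 2), forced s = (0.5, 0.25), AVF=0.4, ECF=0.5,
        # s_e = 0.8 -> S = 0.4*(0.2*0.5 + 0.8*0.25) + 0.5*0.8 = 0.52
        v = sub.VoxelSubstrate([1.0, 2.0], [0.7, 0.7])
        monkeypatch.setattr(fs, "volume_fractions",
                            lambda s: (0.4, 0.1, 0.5))
        monkeypatch.setattr(fs, "intra_axonal_signal",
                            lambda d, p, c: np.array([[0.5], [0.25]]))
        monkeypatch.setattr(fs, "extracellular_signal",
                            lambda p, avf, c: np.array([0.8]))
        S = fs.mix_voxel_signal(v, None, fs.TissueConstants())
        assert S[0] == pytest.approx(0.52, rel=1e-12)

    def test_b0_signal_equals_one_minus_mvf(self, mouse_protocols):
        dprot, _ = mouse_protocols
        rng = np.random.default_rng(4)
        for _ in range(3):
            n = rng.integers(5, 40)
            v = sub.VoxelSubstrate(rng.uniform(0.5, 3.0, n),
                                   rng.uniform(0.5, 0.95, n))
            S = fs.mix_voxel_signal(v, dprot)
            mvf = sub.volume_fractions(v)[1]
            b0 = S[dprot.gradient_amplitude == 0]
            np.testing.assert_allclose(b0, 1.0 - mvf, rtol=1e-12)

    def test_single_axon_weight_is_one(self, mouse_protocols):
        dprot, _ = mouse_protocols
        v = sub.VoxelSubstrate([2.0], [0.7])
        avf, mvf, ecf = sub.volume_fractions(v)
        s1 = fs.intra_axonal_signal(np.array([2.0]), dprot)[0]
        se = fs.extracellular_signal(dprot, avf)
        np.testing.assert_allclose(fs.mix_voxel_signal(v, dprot),
                                   avf * s1 + ecf * se, rtol=1e-12)

    def test_empty_substrate_raises(self, mouse_protocols):
        v = sub.VoxelSubstrate([1.0], [0.5])
        v.d_in = np.empty(0)
        v.g = np.empty(0)
        with pytest.raises(EmptySubstrateError):
            fs.mix_voxel_signal(v, mouse_protocols[0])


class TestBoundPool:
    def test_stated_constants(self):
        assert fs.mvf_to_bound_pool(0.0) == pytest.approx(0.086)
        assert fs.mvf_to_bound_pool(1.0) == pytest.approx(0.525)
        assert fs.mvf_to_bound_pool(0.2) == pytest.approx(0.1738)

    def test_strictly_increasing_and_invertible(self):
        mvf = np.linspace(0, 1, 11)
        F = fs.mvf_to_bound_pool(mvf)
        assert np.all(np.diff(F) > 0)
        np.testing.assert_allclose(fs.bound_pool_to_mvf(F), mvf, atol=1e-12)

    def test_out_of_range_raises(self):
        with pytest.raises(ParameterError):
            fs.mvf_to_bound_pool(1.5)


class TestMTSPGR:
    def test_vanishing_saturation_at_large_offset(self):
        p = prot.MTProtocol([1000.0], [5e6])
        assert fs.mt_spgr_signal(0.15, p)[0] == pytest.approx(1.0, abs=1e-3)

    def test_monotonicities_on_table_grid(self, mouse_protocols):
        _, mtprot = mouse_protocols
        S = fs.mt_spgr_signal(0.2, mtprot)
        for ang in np.unique(mtprot.flip_angles_equiv):
            m = mtprot.flip_angles_equiv == ang
            off = mtprot.offsets[m]
            assert np.all(np.diff(S[m][np.argsort(off)]) > 0)
        for off in np.unique(mtprot.offsets):
            m = mtprot.offsets == off
            ang = mtprot.flip_angles_equiv[m]
            assert np.all(np.diff(S[m][np.argsort(ang)]) < 0)

    def test_matches_bloch_mcconnell_ode_oracle(self):
        p = prot.MTProtocol.from_grid([1000.0], [2000.0, 6000.0, 22000.0])
        w1 = p.omega1_cwpe[0]
        for F in (0.08, 0.15, 0.3):
            closed = fs.mt_spgr_signal(F, p)
            for j, off in enumerate(p.offsets):
                ode = bloch_mcconnell_mt(F, w1, off)
                assert closed[j] == pytest.approx(ode, rel=0.02), \
                    f"F={F}, offset={off}"


class TestRicianNoise:
    def test_infinite_snr_is_identity(self):
        s = fs.SignalVector(np.array([0.5, 1.0]), np.array([0.9]))
        out = fs.add_rician_noise(s, math.inf, 0)
        np.testing.assert_array_equal(out.diffusion, s.diffusion)

    def test_zero_signal_mean_is_rayleigh(self):
        s = fs.SignalVector(np.zeros(40000), np.zeros(1))
        snr = 10.0
        out = fs.add_rician_noise(s, snr, seed_or_rng=3)
        sigma = 1.0 / snr
        expected = sigma * np.sqrt(np.pi / 2.0)
        se = sigma * np.sqrt(2 - np.pi / 2) / np.sqrt(40000)
        assert out.diffusion.mean() == pytest.approx(expected, abs=4 * se)

    def test_seeded_noise_reproducible(self):
        s = fs.SignalVector(np.full(10, 0.7), np.full(4, 0.9))
        a = fs.add_rician_noise(s, 32.0, 11)
        b = fs.add_rician_noise(s, 32.0, 11)
        np.testing.assert_array_equal(a.diffusion, b.diffusion)
        np.testing.assert_array_equal(a.mt, b.mt)

    def test_invalid_snr_raises(self):
        s = fs.SignalVector(np.zeros(2), np.zeros(2))
        with pytest.raises(ParameterError):
            fs.add_rician_noise(s, 0.0)


def test_dataset_simulation_bit_reproducible(mouse_protocols):
    dprot, mtprot = mouse_protocols
    voxels = sub.sample_population(sub.SubstrateParams(seed=2), 3, seed=2)
    a, ia = fs.simulate_dataset(voxels, dprot, mtprot, snrs=(100.0,), seed=5)
    b, ib = fs.simulate_dataset(voxels, dprot, mtprot, snrs=(100.0,), seed=5)
    np.testing.assert_array_equal(ia, ib)
    for sa, sb in zip(a, b):
        np.testing.assert_array_equal(sa.diffusion, sb.diffusion)
        np.testing.assert_array_equal(sa.mt, sb.mt)


def test_scaled_substrate_uses_frozen_mvf_for_mt(mouse_protocols):
    dprot, mtprot = mouse_protocols
    v = sub.VoxelSubstrate(np.full(50, 2.0), np.full(50, 0.7))
    sv_orig = fs.simulate_voxel(v, dprot, mtprot)
    scaled = sub.scale_diameters(v, 0.15)
    sv_scaled = fs.simulate_voxel(scaled, dprot, mtprot)
    np.testing.assert_allclose(sv_scaled.mt, sv_orig.mt, rtol=1e-12)
    assert not np.allclose(sv_scaled.diffusion, sv_orig.diffusion)
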