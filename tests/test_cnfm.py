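"""Flow model: context assembly, density contracts, sampling, heads."""

import numpy as np
import pytest

from axonflow._autodiff import Tensor
from axonflow.cnfm import (CNFM, EncoderSpec, FlowSpec, JointDensity,
                           protocol_fingerprint)
from axonflow.exceptions import (ParameterError, ProtocolFormatError)


def _fresh_model(seed=0, ablation=()):
    m = CNFM(10, 4, ablation=ablation, seed=seed)
    rng = np.random.default_rng(seed)
    m.stats.x_mean = np.zeros(m._sig_idx.size)
    m.stats.x_std = np.ones(m._sig_idx.size)
    m.stats.maps_mean = np.zeros(m._map_idx.size)
    m.stats.maps_std = np.ones(m._map_idx.size)
    m.stats.u_mean = np.array([np.log(2.0), 0.85])
    m.stats.u_std = np.array([0.5, 0.4])
    m.stats.d_max = 12.0
    return m, rng


class TestContext:
    def test_evaluation_mode_is_deterministic(self):
        m, rng = _fresh_model()
        x = rng.normal(size=(3, 14))
        maps = rng.normal(size=(3, 7))
        c1 = m.encode_context_np(x, maps)
        c2 = m.encode_context_np(x, maps)
        np.testing.assert_array_equal(c1, c2)
        assert c1.shape == (3, 23)

    @pytest.mark.parametrize("ablation, n_ctx", [
        ((), 23),
        (("no_maps",), 16),
        (("diffusion_only",), 21),   # 16 + 5 diffusion-derived maps
        (("mt_only",), 18),          # 16 + 2 MT-derived maps
    ])
    def test_ablation_context_widths(self, ablation, n_ctx):
        m, rng = _fresh_model(ablation=ablation)
        ctx = m.encode_context_np(rng.normal(size=(2, 14)),
                                  rng.normal(size=(2, 7)))
        assert ctx.shape == (2, n_ctx)

    def test_wrong_signal_length_names_channels(self):
        m, rng = _fresh_model()
        with pytest.raises(ProtocolFormatError, match="10 diffusion"):
            m.encode_context_np(rng.normal(size=(2, 9)),
                                rng.normal(size=(2, 7)))

    def test_exclusive_ablations_rejected(self):
        with pytest.raises(ParameterError):
            CNFM(10, 4, ablation=("diffusion_only", "mt_only"))


class TestDensity:
    def test_identity_initialized_flow_is_standard_normal(self):
        m, rng = _fresh_model()
        for blk in m.flow.blocks:     # exact identity transform
            blk.l3.W.data[:] = 0.0
        ctx = m.encode_context_np(rng.normal(size=(1, 14)),
                                  rng.normal(size=(1, 7)))
        d, g = 2.5, 0.72
        u = m._to_u(d, g)[0]
        expected = (-np.log(2 * np.pi) - 0.5 * (u ** 2).sum()
                    + m._log_jacobian(d, g)[0])
        assert m.log_density_np(d, g, ctx)[0] == pytest.approx(expected,
                                                               rel=1e-12)

    def test_quadrature_normalization(self, pretrained_small, small_dataset):
        # untrained and trained models, several contexts: integral ~ 1
        m, rng = _fresh_model(seed=3)
        ctxs = m.encode_context_np(rng.normal(size=(5, 14)),
                                   rng.normal(size=(5, 7)))
        for i in range(5):
            assert JointDensity(m, ctxs[i]).normalization() == \
                pytest.approx(1.0, abs=0.01)
        tm = pretrained_small.model
        tctx = tm.encode_context_np(small_dataset.signals[:5],
                                    small_dataset.maps[:5])
        for i in range(5):
            assert JointDensity(tm, tctx[i]).normalization() == \
                pytest.approx(1.0, abs=0.01)

    def test_flow_round_trip_invertibility(self):
        m, rng = _fresh_model(seed=1)
        u = rng.normal(size=(500, 2))
        ctx = np.tile(m.encode_context_np(rng.normal(size=(1, 14)),
                                          rng.normal(size=(1, 7))), (500, 1))
        z = m.flow.forward_np(u, ctx)
        back = m.flow.invert_np(z, ctx)
        assert np.abs(u - back).max() < 1e-5

    def test_non_finite_input_rejected(self):
        m, rng = _fresh_model()
        ctx = m.encode_context_np(rng.normal(size=(1, 14)),
                                  rng.normal(size=(1, 7)))
        with pytest.raises(ParameterError):
            m.log_density_np(-1.0, 0.5, ctx)


class TestSampling:
    def test_zero_draws_empty(self):
        m, rng = _fresh_model()
        ctx = m.encode_context_np(rng.normal(size=(1, 14)),
                                  rng.normal(size=(1, 7)))
        d, g = m.sample_joint(0, ctx)
        assert d.size == 0 and g.size == 0

    def test_seeded_draws_identical(self):
        m, rng = _fresh_model()
        ctx = m.encode_context_np(rng.normal(size=(1, 14)),
                                  rng.normal(size=(1, 7)))
        d1, g1 = m.sample_joint(500, ctx, seed=9)
        d2, g2 = m.sample_joint(500, ctx, seed=9)
        np.testing.assert_array_equal(d1, d2)
        np.testing.assert_array_equal(g1, g2)

    def test_samples_in_working_rectangle(self):
        m, rng = _fresh_model()
        ctx = m.encode_context_np(rng.normal(size=(1, 14)),
                                  rng.normal(size=(1, 7)))
        d, g = m.sample_joint(2000, ctx, seed=2)
        assert d.min() > 0 and d.max() <= m.stats.d_max
        assert 0 < g.min() and g.max() < 1

    def test_sample_mean_matches_density_mean(self, pretrained_small,
                                              small_dataset):
        m = pretrained_small.model
        ctx = m.encode_context_np(small_dataset.signals[:1],
                                  small_dataset.maps[:1])
        dens = JointDensity(m, ctx[0])
        d, g = dens.sample(100_000, seed=5)
        ed, eg = dens.mean(n_d=400, n_g=400)
        se_d = d.std() / np.sqrt(d.size)
        se_g = g.std() / np.sqrt(g.size)
        assert d.mean() == pytest.approx(ed, abs=max(3 * se_d, 3e-3 * ed))
        assert g.mean() == pytest.approx(eg, abs=max(3 * se_g, 3e-3 * eg))


class TestNLL:
    def test_duplicated_batch_same_loss(self):
        m, rng = _fresh_model()
        ctx = m.encode_context(rng.normal(size=(2, 14)),
                               rng.normal(size=(2, 7)), training=False)
        d = np.array([1.0, 2.0])
        g = np.array([0.6, 0.8])
        u = m._to_u(d, g)
        lj = m._log_jacobian(d, g)
        l1 = m.nll_loss(u, ctx[np.array([0, 1])], lj)
        l2 = m.nll_loss(u, ctx[np.array([0, 1])], lj)
        assert l1.data == l2.data

    def test_mode_beats_far_tail(self):
        m, rng = _fresh_model()
        ctx = m.encode_context_np(rng.normal(size=(1, 14)),
                                  rng.normal(size=(1, 7)))
        lp_mode = m.log_density_np(2.0, 0.7, ctx)[0]   # near transform center
        lp_tail = m.log_density_np(11.0, 0.01, ctx)[0]
        assert lp_mode > lp_tail

    def test_empty_batch_raises(self):
        m, _ = _fresh_model()
        with pytest.raises(ParameterError):
            m.nll_loss(np.empty((0, 2)), Tensor(np.empty((0, 23))),
                       np.empty(0))

    def test_loss_decreases_on_smoke_fixture(self, small_dataset):
        from axonflow import train
        ds = small_dataset.subset(np.arange(10))
        cfg = train.TrainConfig(epochs=50, monitor_every=50,
                                batch_voxels=10, pairs_per_voxel=16,
                                patience=1000)
        res = train.pretrain(ds, cfg, seed=3, val_frac=0.2)
        nll = [h["train_nll"] for h in res.history
               if np.isfinite(h["train_nll"])]
        assert nll[-1] < nll[0]


class TestHeads:
    def test_probabilities_sum_to_one(self):
        m, rng = _fresh_model()
        ctx = m.encode_context_np(rng.normal(size=(4, 14)),
                                  rng.normal(size=(4, 7)))
        pr, pg = m.classification_heads_np(ctx)
        np.testing.assert_allclose(pr.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_allclose(pg.sum(axis=1), 1.0, atol=1e-6)
        assert pr.shape == (4, 3) and pg.shape == (4, 2)

    def test_absent_under_no_multitask(self):
        m, rng = _fresh_model(ablation=("no_multitask",))
        ctx = m.encode_context_np(rng.normal(size=(1, 14)),
                                  rng.normal(size=(1, 7)))
        with pytest.raises(ParameterError):
            m.classification_heads_np(ctx)

    def test_separable_fixture_beats_chance(self, mouse_transfer_dataset):
        from axonflow import train
        ds = mouse_transfer_dataset
        m2 = CNFM(ds.n_diffusion, ds.n_mt, seed=4)
        train._set_standardization(m2, ds, np.arange(ds.n_voxels))
        cfg = train.TrainConfig(epochs=60, batch_voxels=16,
                                pairs_per_voxel=16, patience=1000)
        m2, _ = train.finetune(m2, ds, cfg, seed=4)
        ctx = m2.encode_context_np(ds.signals, ds.maps)
        pr, pg = m2.classification_heads_np(ctx)
        acc_r = (pr.argmax(axis=1) == ds.regions).mean()
        acc_g = (pg.argmax(axis=1) == ds.groups).mean()
        assert acc_g > 0.5 + 0.1   # chance 1/2
        assert acc_r > 1 / 3       # chance 1/3


class TestCheckpoint:
    def test_round_trip_preserves_density(self, tmp_path):
        m, rng = _fresh_model(seed=6)
        x = rng.normal(size=(1, 14))
        maps = rng.normal(size=(1, 7))
        ctx = m.encode_context_np(x, maps)
        m.fingerprint = "abc123"
        m.save(tmp_path / "model.npz")
        m2 = CNFM.load(tmp_path / "model.npz")
        ctx2 = m2.encode_context_np(x, maps)
        np.testing.assert_array_equal(ctx, ctx2)
        np.testing.assert_allclose(m.log_density_np(1.5, 0.6, ctx),
                                   m2.log_density_np(1.5, 0.6, ctx2))

    def test_fingerprint_mismatch_refused_unless_forced(self, tmp_path):
        m, _ = _fresh_model()
        m.fingerprint = "abc123"
        m.save(tmp_path / "model.npz")
        with pytest.raises(ProtocolFormatError):
            CNFM.load(tmp_path / "model.npz", expected_fingerprint="zzz")
        m2 = CNFM.load(tmp_path / "model.npz", expected_fingerprint="zzz",
                       force=True)
        assert m2.fingerprint == "abc123"


def test_protocol_fingerprint_sensitivity(mouse_protocols):
    dprot, mtprot = mouse_protocols
    f1 = protocol_fingerprint(dprot, mtprot)
    import dataclasses
    mt2 = dataclasses.replace(mtprot,
                              offsets=mtprot.offsets + 1.0,
                              flip_angles_equiv=mtprot.flip_angles_equiv)
    assert protocol_fingerprint(dprot, mt2) != f1
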