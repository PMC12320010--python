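"""Training workflows: splits, fold enumeration, freezing, selection."""

import itertools

import numpy as np
import pytest

from axonflow import train
from axonflow.cnfm import CNFM
from axonflow.exceptions import (FreezePlanError, ParameterError, RosterError,
                                 SelectionError)


class TestPretrain:
    def test_80_20_split_sizes(self, pretrained_small, small_dataset):
        n = small_dataset.n_voxels
        assert pretrained_small.train_idx.size == int(round(0.8 * n))
        assert pretrained_small.val_idx.size == n - int(round(0.8 * n))
        # 2000-voxel arithmetic of the reference configuration
        assert int(round(0.8 * 2000)) == 1600

    def test_split_disjoint_exhaustive(self, pretrained_small, small_dataset):
        union = np.union1d(pretrained_small.train_idx,
                           pretrained_small.val_idx)
        np.testing.assert_array_equal(union,
                                      np.arange(small_dataset.n_voxels))

    def test_seeded_training_reproducible(self, small_dataset):
        ds = small_dataset.subset(np.arange(30))
        cfg = train.TrainConfig(epochs=4, monitor_every=2, batch_voxels=16,
                                pairs_per_voxel=8, monitor_voxels=10)
        r1 = train.pretrain(ds, cfg, seed=13)
        r2 = train.pretrain(ds, cfg, seed=13)
        assert r1.history[-1]["val_jsd_d"] == r2.history[-1]["val_jsd_d"]
        assert r1.history[-1]["train_nll"] == r2.history[-1]["train_nll"]

    def test_validation_jsd_improves_over_initialization(self,
                                                         pretrained_small):
        hist = pretrained_small.history
        first = hist[0]
        last_valid = [h for h in hist if np.isfinite(h["val_jsd_d"])][-1]
        assert 0.5 * (last_valid["val_jsd_d"] + last_valid["val_jsd_g"]) < \
            0.5 * (first["val_jsd_d"] + first["val_jsd_g"])

    def test_hyperparameter_draws_respect_ranges(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            cfg = train.sample_train_config(rng)
            assert 1e-4 <= cfg.lr <= 1e-3
            assert 1e-6 <= cfg.weight_decay <= 1e-5
        with pytest.raises(ParameterError):
            train.TrainConfig(lr=5e-3)


class TestFolds:
    def _brute_force_count(self, flagged_group):
        # independent enumeration over explicit subject tuples
        wt = [f"w{i}" for i in range(4)]
        mut = [f"m{i}" for i in range(5)]
        flagged = "w0" if flagged_group == "wildtype" else "m0"
        count = 0
        for wtr in itertools.combinations(wt, 2):
            for wv in set(wt) - set(wtr):
                for wte in set(wt) - set(wtr) - {wv}:
                    for mtr in itertools.combinations(mut, 3):
                        for mv in set(mut) - set(mtr):
                            for mte in set(mut) - set(mtr) - {mv}:
                                if flagged in wtr + mtr:
                                    count += 1
        return count

    def test_enumeration_matches_brute_force_and_prints_120(self):
        perms = train.enumerate_valid_permutations(
            train.default_mouse_roster())
        assert len(perms) == 120
        assert len(perms) == self._brute_force_count("wildtype")

    def test_relaxing_flag_constraint_grows_pool(self):
        roster = train.default_mouse_roster()
        with_flag = train.enumerate_valid_permutations(roster, True)
        without = train.enumerate_valid_permutations(roster, False)
        assert len(without) > len(with_flag)
        assert len(without) == 240

    def test_folds_disjoint_exhaustive_and_flag_in_train(self):
        plan = train.make_cv_folds(n_folds=5, seed=3)
        assert plan.n_valid == 120
        ids = {s.id for s in plan.subjects}
        flagged = {s.id for s in plan.subjects if s.missing_splenium}
        for fold in plan.folds:
            parts = [set(fold[k]) for k in ("train", "val", "test")]
            assert parts[0] | parts[1] | parts[2] == ids
            assert sum(len(p) for p in parts) == 9
            assert flagged <= parts[0]

    def test_seeded_fold_choice_reproducible(self):
        a = train.make_cv_folds(n_folds=5, seed=8)
        b = train.make_cv_folds(n_folds=5, seed=8)
        assert a.folds == b.folds

    def test_infeasible_roster_raises(self):
        roster = [train.Subject("a", "wildtype"),
                  train.Subject("b", "mutant")]
        with pytest.raises(RosterError):
            train.make_cv_folds(roster)


class TestFinetune:
    def test_frozen_components_keep_parameter_hash(self,
                                                   mouse_transfer_dataset):
        ds = mouse_transfer_dataset
        model = CNFM(ds.n_diffusion, ds.n_mt, seed=5)
        train._set_standardization(model, ds, np.arange(ds.n_voxels))
        plan = ("encoder_layer_1", "encoder_layer_2", "encoder_layer_3")
        before = {c: model.parameter_hash(c) for c in plan}
        before_flow = model.parameter_hash("flow_block_1")
        cfg = train.TrainConfig(epochs=2, batch_voxels=8, pairs_per_voxel=8,
                                freeze_plan=plan)
        model, _ = train.finetune(model, ds, cfg, seed=5)
        after = {c: model.parameter_hash(c) for c in plan}
        assert before == after
        assert model.parameter_hash("flow_block_1") != before_flow

    def test_unknown_freeze_component_raises(self, mouse_transfer_dataset):
        ds = mouse_transfer_dataset
        model = CNFM(ds.n_diffusion, ds.n_mt, seed=5)
        train._set_standardization(model, ds, np.arange(ds.n_voxels))
        cfg = train.TrainConfig(epochs=1, freeze_plan=("encoder_layer_9",))
        with pytest.raises(FreezePlanError):
            train.finetune(model, ds, cfg)

    def test_transfer_reduces_validation_error(self, pretrained_small,
                                               mouse_transfer_dataset):
        # fine-tuning a large-axon pretrained model on a small-axon
        # (mouse-like) dataset must beat its epoch-0 percent error
        import copy
        ds = mouse_transfer_dataset
        model = copy.deepcopy(pretrained_small.model)
        val = np.arange(0, ds.n_voxels, 4)
        trn = np.setdiff1d(np.arange(ds.n_voxels), val)

        def pct(m):
            eg = train._predicted_mean_g(m, ds, val)
            mu = np.array([ds.pairs[i][:, 1].mean() for i in val])
            return float(np.mean(np.abs(mu - eg) / mu * 100))

        before = pct(model)
        cfg = train.TrainConfig(epochs=30, batch_voxels=16,
                                pairs_per_voxel=24)
        model, _ = train.finetune(model, ds, cfg, seed=6, train_idx=trn)
        assert pct(model) < before

    def test_pretrain_subsample_consumes_half(self, small_dataset):
        half = train.subsample_dataset(small_dataset, 0.5, seed=1)
        assert half.n_voxels == round(0.5 * small_dataset.n_voxels)
        again = train.subsample_dataset(small_dataset, 0.5, seed=1)
        np.testing.assert_array_equal(half.signals, again.signals)


class TestSelectModel:
    def _stub_candidates(self, monkeypatch, table):
        # table: candidate -> (val mean-g offsets, trainval mean-g offsets)
        class Stub:
            def __init__(self, tag):
                self.tag = tag

        def fake_mean_g(model, dataset, idx):
            truth = np.array([dataset.pairs[i][:, 1].mean() for i in idx])
            return truth * (1.0 + table[model.tag])

        monkeypatch.setattr(train, "_predicted_mean_g", fake_mean_g)
        return [Stub(t) for t in table]

    def test_single_candidate_returned(self, monkeypatch,
                                       mouse_transfer_dataset):
        cands = self._stub_candidates(monkeypatch, {"only": 0.05})
        best, report = train.select_model(cands, mouse_transfer_dataset,
                                          np.arange(4))
        assert best is cands[0]
        assert report["selected"] == 0

    def test_dominant_candidate_selected(self, monkeypatch,
                                         mouse_transfer_dataset):
        cands = self._stub_candidates(
            monkeypatch, {"bad": 0.10, "good": 0.01, "mid": 0.05})
        ds = mouse_transfer_dataset
        best, _ = train.select_model(cands, ds, np.arange(6),
                                     np.arange(ds.n_voxels))
        assert best.tag == "good"

    def test_rank_composite_matches_brute_force(self, monkeypatch,
                                                mouse_transfer_dataset):
        offsets = {"a": 0.02, "b": 0.07, "c": 0.01, "d": 0.10, "e": 0.04}
        cands = self._stub_candidates(monkeypatch, offsets)
        ds = mouse_transfer_dataset
        best, report = train.select_model(cands, ds, np.arange(6),
                                          np.arange(ds.n_voxels))
        # independent ranking: with uniform relative offsets both criteria
        # order candidates identically by |offset|
        expect = min(offsets, key=lambda k: abs(offsets[k]))
        assert best.tag == expect
        pct = [c["pct_error_mean_g"] for c in report["candidates"]]
        order = np.argsort(pct)
        np.testing.assert_array_equal(
            np.argsort(report["mean_rank"])[:1], order[:1])

    def test_empty_candidates_raise(self, mouse_transfer_dataset):
        with pytest.raises(SelectionError):
            train.select_model([], mouse_transfer_dataset, np.arange(2))


class TestSklearnFacade:
    def test_estimator_fit_predict_score(self, small_dataset):
        from sklearn.base import clone
        ds = small_dataset.subset(np.arange(40))
        X = np.hstack([ds.signals, ds.maps])
        est = train.ConditionalFlowDensity(
            n_diffusion=ds.n_diffusion, n_mt=ds.n_mt, epochs=4,
            random_state=1)
        est2 = clone(est)  # sklearn param contract
        est2.fit(X, ds.pairs)
        dens = est2.predict(X[:3])
        assert len(dens) == 3
        assert dens[0].normalization() == pytest.approx(1.0, abs=0.02)
        assert np.isfinite(est2.score(X[:10], ds.pairs[:10]))
        assert est2.best_epoch_ >= 0
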