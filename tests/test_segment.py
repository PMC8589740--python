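"""Segmenter training, ensemble prediction, fusion rule, cross-validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctnq.phantom import LABELS, brain_mask_from_labels
from ctnq.register import zscore_brain
from ctnq.segment import (
    SegmenterConfig,
    crossvalidate,
    dice,
    fuse_ensemble,
    predict_ensemble,
    train_ensemble,
    train_segmenter,
)
from ctnq.volume import Volume


def _seg_labels(lab):
    out = np.zeros(lab.shape, np.int16)
    out[lab == LABELS["csf"]] = 1
    out[lab == LABELS["wml"]] = 2
    return out


@pytest.fixture(scope="module")
def training_data(aligned_cohort):
    pairs, _ = aligned_cohort
    tp, masks = [], []
    for p in pairs:
        bm = brain_mask_from_labels(p.labels.data)
        z = zscore_brain(p.ct, Volume(bm, p.ct.affine))
        tp.append((z, p.labels.like(_seg_labels(p.labels.data))))
        masks.append(bm)
    return tp, masks


@pytest.fixture(scope="module")
def overfit_model(training_data):
    tp, masks = training_data
    cfg = SegmenterConfig(epochs=60, samples_per_volume=5000, seed=1)
    return train_segmenter(tp, cfg, masks)


class TestTraining:
    def test_loss_decreases(self, overfit_model):
        h = overfit_model.loss_history
        assert h[-1] < h[0]

    def test_training_dice_csf(self, overfit_model, training_data):
        tp, masks = training_data
        scores = []
        for (z, lab), m in zip(tp, masks):
            probs = overfit_model.predict(z, mask=m)
            scores.append(dice(probs["csf"].data >= 0.5, lab.data == 1))
        assert np.mean(scores) >= 0.8

    def test_probabilities_sum_to_one(self, overfit_model, training_data):
        tp, masks = training_data
        probs = overfit_model.predict(tp[0][0], mask=masks[0])
        total = sum(probs[c].data for c in ("background", "csf", "wml"))
        np.testing.assert_allclose(total, 1.0, atol=1e-9)

    def test_same_seed_reproduces_loss(self, training_data):
        tp, masks = training_data
        cfg = SegmenterConfig(epochs=3, samples_per_volume=500, seed=11)
        a = train_segmenter(tp, cfg, masks)
        b = train_segmenter(tp, cfg, masks)
        assert a.loss_history == b.loss_history

    def test_absent_class_warns(self):
        rng = np.random.default_rng(0)
        vols = [Volume(rng.normal(size=(16, 16, 16))) for _ in range(2)]
        labs = [Volume((v.data > 0).astype(np.int16)) for v in vols]  # no WML
        with pytest.warns(UserWarning, match="absent"):
            train_segmenter(
                list(zip(vols, labs)),
                SegmenterConfig(epochs=1, samples_per_volume=200),
            )


class TestEnsemblePrediction:
    def test_single_model_replicated_members_identical(self, overfit_model, training_data):
        tp, masks = training_data
        members = predict_ensemble(overfit_model, tp[0][0], K=3, mask=masks[0])
        assert len(members["csf"]) == 3
        np.testing.assert_array_equal(members["csf"][0].data, members["csf"][2].data)

    def test_distinct_seeds_differ(self, training_data):
        tp, masks = training_data
        cfg = SegmenterConfig(epochs=4, samples_per_volume=800, seed=0)
        models = train_ensemble(tp, cfg, K=2, masks=masks)
        members = predict_ensemble(models, tp[0][0], mask=masks[0])
        assert not np.array_equal(members["csf"][0].data, members["csf"][1].data)

    def test_k_below_two_rejected(self, overfit_model, training_data):
        tp, masks = training_data
        with pytest.raises(ValueError):
            predict_ensemble(overfit_model, tp[0][0], K=1)


from oracles import oracle_fusion  # noqa: E402 - shared loop-level oracle


class TestFusion:
    def _random_members(self, rng, K=10, shape=(8, 8, 8)):
        base = rng.random(shape)
        return [Volume(np.clip(base + rng.normal(0, rng.uniform(0.01, 0.5), shape), 0, 1))
                for _ in range(K)]

    def test_identical_members_uniform_weights(self):
        v = Volume(np.random.default_rng(0).random((8, 8, 8)))
        out = fuse_ensemble([v.copy() for _ in range(4)])
        np.testing.assert_allclose(out.weights, 0.25)
        np.testing.assert_array_equal(out.fused.data, v.data >= 0.5)

    def test_weights_sum_to_one_and_fused_binary(self):
        rng = np.random.default_rng(5)
        out = fuse_ensemble(self._random_members(rng))
        assert out.weights.sum() == pytest.approx(1.0)
        assert set(np.unique(out.fused.data)) <= {False, True}

    def test_outlier_member_downweighted(self):
        rng = np.random.default_rng(6)
        base = rng.random((8, 8, 8))
        members = [Volume(np.clip(base + rng.normal(0, 0.02, base.shape), 0, 1)) for _ in range(9)]
        members.append(Volume(1.0 - base))  # anti-correlated outlier
        out = fuse_ensemble(members)
        assert out.weights[-1] < 1.0 / 10.0
        w_o, n_o, fused_o = oracle_fusion([m.data for m in members])
        np.testing.assert_allclose(out.weights, w_o)
        np.testing.assert_array_equal(out.fused.data, fused_o)

    def test_high_correlation_reduces_to_unweighted_mean(self):
        rng = np.random.default_rng(7)
        base = rng.random((8, 8, 8))
        members = [Volume(np.clip(base + rng.normal(0, 0.01, base.shape), 0, 1)) for _ in range(6)]
        out = fuse_ensemble(members)
        assert (out.corr[~np.eye(6, dtype=bool)] > 0.8).all()
        np.testing.assert_allclose(out.weights, 1 / 6)
        mean = np.mean([m.data for m in members], axis=0)
        np.testing.assert_array_equal(out.fused.data, mean >= 0.5)

    def test_zero_variance_member_excluded_with_warning(self):
        rng = np.random.default_rng(8)
        base = rng.random((8, 8, 8))
        members = [Volume(np.clip(base + rng.normal(0, 0.02, base.shape), 0, 1)) for _ in range(3)]
        members.append(Volume(np.full((8, 8, 8), 0.3)))
        with pytest.warns(UserWarning, match="zero variance"):
            out = fuse_ensemble(members)
        assert out.weights[-1] == 0.0

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_order_invariance(self, seed):
        rng = np.random.default_rng(seed)
        members = self._random_members(rng, K=5, shape=(6, 6, 6))
        perm = np.random.default_rng(seed + 1).permutation(5)
        a = fuse_ensemble(members)
        b = fuse_ensemble([members[i] for i in perm])
        np.testing.assert_allclose(a.weights[perm], b.weights, atol=1e-12)
        np.testing.assert_array_equal(a.fused.data, b.fused.data)

    def test_needs_two_members(self):
        with pytest.raises(ValueError):
            fuse_ensemble([Volume(np.zeros((4, 4, 4)))])


class TestCrossValidation:
    def _tiny_pairs(self, n):
        rng = np.random.default_rng(3)
        pairs = []
        for _ in range(n):
            lab = rng.integers(0, 3, (12, 12, 12)).astype(np.int16)
            ct = Volume(lab + rng.normal(0, 0.3, lab.shape))
            pairs.append((ct, Volume(lab)))
        return pairs

    def test_each_sample_predicted_once_in_tenfold(self):
        pairs = self._tiny_pairs(10)
        cfg = SegmenterConfig(epochs=1, samples_per_volume=100, seed=2)
        res = crossvalidate(pairs, folds=10, config=cfg)
        counts = np.bincount(res.fold_assignment, minlength=10)
        assert (counts == 1).all()
        assert all(p is not None for p in res.predictions)

    def test_fold_sizes_balanced(self):
        pairs = self._tiny_pairs(20)
        cfg = SegmenterConfig(epochs=1, samples_per_volume=100, seed=2)
        res = crossvalidate(pairs, folds=10, config=cfg)
        counts = np.bincount(res.fold_assignment, minlength=10)
        assert (counts == 2).all()

    def test_more_folds_than_samples_rejected(self):
        pairs = self._tiny_pairs(3)
        with pytest.raises(ValueError):
            crossvalidate(pairs, folds=10)
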