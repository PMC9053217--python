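"""Hybrid loss terms, their identities, and the training loop contract."""

import numpy as np
import pytest

from ischeseg import netzoo
from ischeseg.nn import Tensor
from ischeseg.trainloop import (LossWeights, Sample, TrainConfig,
                                balanced_bce, downsample_truth,
                                generalized_dice_loss, hybrid_loss,
                                l1_predict_reg, standardize_channels, train)


class TestGeneralizedDice:
    def test_perfect_binary_prediction_is_zero(self, rng):
        g = (rng.random((4, 4, 4)) > 0.7).astype(float)
        assert generalized_dice_loss(g, g) == pytest.approx(0.0, abs=1e-9)

    def test_complement_prediction_is_maximal(self, rng):
        g = (rng.random((4, 4, 4)) > 0.7).astype(float)
        assert generalized_dice_loss(1.0 - g, g) == pytest.approx(1.0,
                                                                  abs=1e-6)

    def test_hand_computed_weighted_case(self):
        # 2x2x1 grid, truth = [1,0,0,0], pred = [0.5,0,0,0.5]
        truth = np.array([1.0, 0, 0, 0]).reshape(2, 2, 1)
        pred = np.array([0.5, 0, 0, 0.5]).reshape(2, 2, 1)
        w_les, w_bg = 1.0, 1.0 / 9.0
        # per-class soft overlaps: lesion p*g = 0.5;
        # background (1-p)(1-g) = 0 + 1 + 1 + 0.5 = 2.5
        num = w_les * 0.5 + w_bg * 2.5
        # per-class (p+g) sums: lesion Sp + Sg = 1.0 + 1.0;
        # background S(1-p) + S(1-g) = 3.0 + 3.0
        den = w_les * 2.0 + w_bg * 6.0
        expect = 1.0 - 2.0 * num / den
        assert generalized_dice_loss(pred, truth) == pytest.approx(
            expect, abs=1e-6)

    def test_range_zero_one(self, rng):
        p = rng.random((5, 5, 5))
        g = (rng.random((5, 5, 5)) > 0.8).astype(float)
        assert 0.0 <= generalized_dice_loss(p, g) <= 1.0


class TestBalancedBCE:
    def test_confident_perfect_prediction_near_zero(self, rng):
        g = (rng.random((4, 4, 4)) > 0.7).astype(float)
        assert balanced_bce(g, g) == pytest.approx(0.0, abs=1e-5)

    def test_all_lesion_truth_uses_positive_term_only(self):
        g = np.ones((3, 3, 3))
        p = np.full_like(g, 0.5)
        # beta = 0 -> only the (1-beta)(1-g) term could contribute, and g=1
        # kills it; the positive term has weight beta = 0 as well
        assert balanced_bce(p, g) == pytest.approx(0.0, abs=1e-12)

    def test_four_voxel_hand_case(self):
        g = np.array([1.0, 0, 0, 0]).reshape(4, 1, 1)
        p = np.array([0.8, 0.1, 0.1, 0.1]).reshape(4, 1, 1)
        beta = 0.75
        expect = -(beta * np.log(0.8)
                   + (1 - beta) * 3 * np.log(0.9)) / 4.0
        assert balanced_bce(p, g) == pytest.approx(expect, abs=1e-12)


class TestL1:
    def test_zero_prediction(self):
        assert l1_predict_reg(np.zeros((4, 4, 4))) == 0.0

    def test_constant_half(self):
        assert l1_predict_reg(np.full((4, 4, 2), 0.5)) == pytest.approx(16.0)

    def test_matches_brute_force_sum(self, rng):
        p = rng.normal(size=(5, 5, 5))
        assert l1_predict_reg(p) == pytest.approx(
            sum(abs(v) for v in p.ravel()), rel=1e-9)


class TestHybridLoss:
    def _outputs(self, rng, n_side=4, shape=(8, 8, 8)):
        outs = {"fuse": rng.random((1, 1, *shape)), "side": []}
        for level in range(n_side):
            s = tuple(d // 2 ** level for d in shape)
            outs["side"].append(rng.random((1, 1, *s)))
        return outs

    def test_additivity_identity(self, rng):
        outs = self._outputs(rng)
        truth = (rng.random((1, 1, 8, 8, 8)) > 0.8).astype(np.float32)
        levels = downsample_truth(truth)
        w = LossWeights()
        terms = hybrid_loss(outs, [levels[0]] + levels, w)
        assert terms.L_final == pytest.approx(
            terms.L_fuse + sum(terms.L_side), abs=1e-10)
        # and each piece recomputes from its own components
        assert terms.L_fuse == pytest.approx(
            w.w_gds * terms.gds[0] + w.w_bbc * terms.bbc[0]
            + w.w_r * terms.L_1, abs=1e-10)

    def test_perfect_outputs_near_zero_without_l1(self, rng):
        truth = (rng.random((1, 1, 8, 8, 8)) > 0.8).astype(np.float32)
        levels = downsample_truth(truth)
        outs = {"fuse": levels[0], "side": list(levels)}
        terms = hybrid_loss(outs, [levels[0]] + levels, LossWeights(w_r=0.0))
        assert terms.L_final == pytest.approx(0.0, abs=1e-4)

    def test_bbc_weight_scales_linearly(self, rng):
        outs = self._outputs(rng)
        truth = (rng.random((1, 1, 8, 8, 8)) > 0.8).astype(np.float32)
        levels = downsample_truth(truth)
        truths = [levels[0]] + levels
        t1 = hybrid_loss(outs, truths, LossWeights(w_bbc=1.0))
        t2 = hybrid_loss(outs, truths, LossWeights(w_bbc=2.0))
        assert t2.L_final - t1.L_final == pytest.approx(sum(t1.bbc),
                                                        rel=1e-9)

    def test_default_weights(self):
        w = LossWeights()
        assert (w.w_gds, w.w_bbc, w.w_r) == (1.0, 1.0, 1e-5)

    def test_mismatched_truths_rejected(self, rng):
        outs = self._outputs(rng)
        with pytest.raises(ValueError):
            hybrid_loss(outs, [np.zeros((1, 1, 8, 8, 8))])


class TestDownsampleTruth:
    def test_lesion_voxel_survives_max_pooling(self):
        truth = np.zeros((1, 1, 8, 8, 8), dtype=np.float32)
        truth[0, 0, 3, 5, 7] = 1.0
        levels = downsample_truth(truth)
        assert [l.shape[-1] for l in levels] == [8, 4, 2, 1]
        for l in levels:
            assert l.max() == 1.0


class TestStandardize:
    def test_zero_mean_unit_variance_in_brain(self, rng):
        sub = rng.normal(5.0, 3.0, (8, 8, 8, 3)).astype(np.float32)
        brain = np.ones((8, 8, 8), dtype=np.float32)
        out = standardize_channels(sub, brain)
        for c in range(2):
            assert abs(out[..., c].mean()) < 1e-4
            assert out[..., c].std() == pytest.approx(1.0, abs=1e-4)
        # third (probability) channel passes through untouched
        np.testing.assert_array_equal(out[..., 2], sub[..., 2])


@pytest.fixture(scope="module")
def tiny_samples():
    rng = np.random.default_rng(0)
    samples = []
    for i in range(6):
        image = rng.normal(size=(32, 32, 32, 2)).astype(np.float32)
        truth = np.zeros((32, 32, 32), dtype=np.float32)
        truth[8:16, 8:16, 8:16] = 1.0
        image[..., 0] += 3.0 * truth
        samples.append(Sample(image=image, truth=truth,
                              brain=np.ones_like(truth)))
    return samples


class TestTrainLoop:
    def test_fixed_seed_gives_identical_trajectory(self, tiny_samples):
        def run():
            net = netzoo.build_network("unet_ch2", nf=2, seed=5)
            cfg = TrainConfig(max_epochs=2, early_stop_epoch=2,
                              snapshot_every=2, seed=9)
            return train(net, tiny_samples, cfg).history

        h1, h2 = run(), run()
        assert h1 == h2

    def test_loss_decreases_on_learnable_toy(self, tiny_samples):
        net = netzoo.build_network("unet_ch2", nf=2, seed=5)
        cfg = TrainConfig(lr=3e-3, max_epochs=6, early_stop_epoch=6,
                          snapshot_every=6, seed=9)
        result = train(net, tiny_samples, cfg)
        assert result.history[-1]["train_loss"] < result.history[0][
            "train_loss"]

    def test_best_snapshot_selected(self, tiny_samples):
        net = netzoo.build_network("unet_ch2", nf=2, seed=5)
        cfg = TrainConfig(max_epochs=4, early_stop_epoch=4,
                          snapshot_every=2, seed=9)
        result = train(net, tiny_samples, cfg)
        assert result.best_val_dice == max(s["val_dice"]
                                           for s in result.snapshots)

    def test_empty_cohort_rejected(self):
        net = netzoo.build_network("unet_ch2", nf=2)
        with pytest.raises(ValueError):
            train(net, [], TrainConfig())
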