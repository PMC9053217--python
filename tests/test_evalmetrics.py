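"""Segmentation evaluation statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ischeseg import evalmetrics as em
from ischeseg.volspace import VolumeImage


def _img(data):
    return VolumeImage(np.asarray(data, dtype=np.float32), np.eye(4))


class TestConfusion:
    def test_perfect_agreement(self, rng):
        m = rng.random((5, 5, 5)) > 0.5
        c = em.confusion(m, m)
        assert (c.FP, c.FN) == (0, 0) and c.TP == m.sum()

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4)); a[0, 0, 0] = 1
        b = np.zeros((4, 4, 4)); b[1, 1, 1] = 1
        c = em.confusion(a, b)
        assert c.TP == 0 and c.FP == 1 and c.FN == 1

    def test_matches_brute_force_loop(self, rng):
        p = rng.random((6, 6, 6)) > 0.6
        t = rng.random((6, 6, 6)) > 0.6
        c = em.confusion(p, t)
        tp = fp = fn = 0
        for idx in np.ndindex(*p.shape):
            tp += p[idx] and t[idx]
            fp += p[idx] and not t[idx]
            fn += t[idx] and not p[idx]
        assert (c.TP, c.FP, c.FN) == (tp, fp, fn)


class TestMetrics:
    def test_worked_example(self):
        d, p, s = em.dice_precision_sensitivity(em.ConfusionCounts(5, 3, 2))
        assert d == pytest.approx(10 / 15)
        assert p == pytest.approx(0.625)
        assert s == pytest.approx(5 / 7)

    def test_perfect_prediction_all_ones(self):
        assert em.dice_precision_sensitivity(
            em.ConfusionCounts(10, 0, 0)) == (1.0, 1.0, 1.0)

    def test_empty_vs_empty_defined_as_one(self):
        assert em.dice_precision_sensitivity(
            em.ConfusionCounts(0, 0, 0)) == (1.0, 1.0, 1.0)

    @given(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_formula_oracle_random_counts(self, tp, fp, fn):
        if tp + fp + fn == 0:
            return
        d, p, s = em.dice_precision_sensitivity(
            em.ConfusionCounts(tp, fp, fn))
        assert d == pytest.approx(2 * tp / (2 * tp + fn + fp))
        if tp + fp:
            assert p == pytest.approx(tp / (tp + fp))
        if tp + fn:
            assert s == pytest.approx(tp / (tp + fn))

    def test_dice_symmetry_and_precision_sensitivity_duality(self, rng):
        p = rng.random((6, 6, 6)) > 0.6
        t = rng.random((6, 6, 6)) > 0.6
        d1 = em.dice_precision_sensitivity(em.confusion(p, t))
        d2 = em.dice_precision_sensitivity(em.confusion(t, p))
        assert d1[0] == pytest.approx(d2[0])      # Dice symmetric
        assert d1[1] == pytest.approx(d2[2])      # precision <-> sensitivity

    def test_sensitivity_monotone_for_nested_predictions(self, rng):
        truth = rng.random((6, 6, 6)) > 0.4
        p2 = truth & (rng.random(truth.shape) > 0.3)
        p1 = p2 & (rng.random(truth.shape) > 0.3)
        s1 = em.dice_precision_sensitivity(em.confusion(p1, truth))[2]
        s2 = em.dice_precision_sensitivity(em.confusion(p2, truth))[2]
        assert s2 >= s1


class TestSDR:
    def _mask(self, on):
        m = np.zeros((3, 3, 3))
        if on:
            m[1, 1, 1] = 1
        return m

    def test_three_of_four_detected(self):
        truths = [self._mask(True)] * 4
        preds = [self._mask(True)] * 3 + [self._mask(False)]
        assert em.subject_detection_rate(preds, truths)["sdr"] == 0.75

    def test_empty_predictions_on_not_visible_cohort(self):
        truths = [self._mask(False)] * 5
        preds = [self._mask(False)] * 5
        out = em.subject_detection_rate(preds, truths)
        assert out["fp_sdr"] == 0.0 and out["n_fp_gt10_voxels"] == 0

    def test_mixed_cohort_matches_hand_tally(self, rng):
        truths, preds = [], []
        # 2 detected, 1 missed (no overlap), 1 control clean, 1 control FP
        t = np.zeros((4, 4, 4)); t[:2, :2, :2] = 1
        truths += [t, t, t]
        preds += [t.copy(), np.roll(t, 1, 0), np.roll(t, 2, axis=2)]
        truths += [np.zeros((4, 4, 4))] * 2
        preds += [np.zeros((4, 4, 4)), t.copy()]
        out = em.subject_detection_rate(preds, truths)
        assert out["sdr"] == pytest.approx(2 / 3)
        assert out["fp_sdr"] == pytest.approx(1 / 2)
        assert out["n_lesioned"] == 3 and out["n_not_visible"] == 2

    def test_fp_gt10_counting(self):
        truths = [np.zeros((4, 4, 4))]
        pred = np.zeros((4, 4, 4)); pred.flat[:11] = 1
        assert em.subject_detection_rate([pred], truths)[
            "n_fp_gt10_voxels"] == 1


class TestContrast:
    def test_ratio_of_means(self):
        img = np.full((4, 4, 4), 100.0)
        lesion = np.zeros((4, 4, 4)); lesion[:2] = 1
        img[lesion > 0] = 300.0
        brain = np.ones((4, 4, 4))
        assert em.lesion_contrast(_img(img), lesion, brain) == pytest.approx(3.0)

    def test_uniform_image_gives_unity(self, rng):
        img = np.full((4, 4, 4), 7.0)
        lesion = rng.random((4, 4, 4)) > 0.7
        if not lesion.any() or lesion.all():
            lesion[:] = 0; lesion[0, 0, 0] = 1
        assert em.lesion_contrast(_img(img), lesion,
                                  np.ones((4, 4, 4))) == pytest.approx(1.0)

    def test_lesion_outside_brain_rejected(self):
        lesion = np.ones((3, 3, 3))
        brain = np.zeros((3, 3, 3))
        with pytest.raises(ValueError):
            em.lesion_contrast(_img(np.ones((3, 3, 3))), lesion, brain)


class TestSpearman:
    def test_monotone_pairs_give_one(self):
        x = np.arange(10.0)
        rho, lo, hi = em.spearman_with_ci(x, np.exp(x))
        assert rho == pytest.approx(1.0)

    def test_fisher_ci_direct_evaluation(self):
        # the reference point: rho = 0.5, n = 30 gives CI ~ [0.170, 0.729]
        z, se = np.arctanh(0.5), 1.96 / np.sqrt(27)
        assert np.tanh(z - se) == pytest.approx(0.170, abs=2e-3)
        assert np.tanh(z + se) == pytest.approx(0.729, abs=2e-3)

    def test_ci_path_matches_independent_fisher_formula(self, rng):
        x = rng.normal(size=30)
        y = 0.6 * x + rng.normal(size=30)
        rho, lo, hi = em.spearman_with_ci(x, y)
        se = 1.96 / np.sqrt(27)
        assert lo == pytest.approx(np.tanh(np.arctanh(rho) - se))
        assert hi == pytest.approx(np.tanh(np.arctanh(rho) + se))

    def test_ci_contains_point_estimate(self, rng):
        x = rng.normal(size=25)
        y = 0.5 * x + rng.normal(size=25)
        rho, lo, hi = em.spearman_with_ci(x, y)
        assert lo <= rho <= hi


class TestStrata:
    @pytest.mark.parametrize("volume,expected", [
        (1.69, "S"), (1.7, "M"), (13.99, "M"), (14.0, "L"),
        (0.1, "S"), (100.0, "L"),
    ])
    def test_boundaries(self, volume, expected):
        assert em.stratify_volume(volume) == expected


def test_cohort_table_reproduces_reports(rng):
    reports = [em.evaluate_subject(rng.random((4, 4, 4)) > 0.5,
                                   rng.random((4, 4, 4)) > 0.5, 8.0)
               for _ in range(5)]
    table = em.cohort_table(reports)
    assert len(table) == 5
    for col in ("dice", "precision", "sensitivity", "volume_ml", "stratum"):
        assert col in table.columns
    np.testing.assert_allclose(table["dice"], [r.dice for r in reports])
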