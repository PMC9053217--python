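"""Classical lesion mapping: templates, t-scores, c-fuzzy probability maps.

Oracle strategy: every vectorized formula is checked exactly against a
brute-force per-voxel Python loop on small random grids, and the pipeline
behaviour is checked on easy phantoms.
"""

import numpy as np
import pytest

from ischeseg import classical_seg as cs
from ischeseg.evalmetrics import confusion, dice_precision_sensitivity
from ischeseg.intensity_norm import fit_bimodal, normalize_dwi
from ischeseg.volspace import VolumeImage


def _img(data):
    return VolumeImage(np.asarray(data, dtype=np.float32), np.eye(4))


@pytest.fixture(scope="module")
def toy_templates(rng_mod):
    shape = (8, 8, 8)
    mean = rng_mod.normal(0.0, 1.0, shape)
    sd = rng_mod.uniform(0.5, 2.0, shape)
    return (cs.PopulationTemplate(mean, sd, "dwi", 5),
            cs.PopulationTemplate(mean * 0.5 + 1, sd * 0.8, "adc", 5))


@pytest.fixture(scope="module")
def rng_mod():
    return np.random.default_rng(42)


class TestTemplates:
    def test_closed_form_two_controls(self):
        a = (_img(np.zeros((4, 4, 4))), _img(np.zeros((4, 4, 4))))
        b = (_img(np.full((4, 4, 4), 2.0)), _img(np.full((4, 4, 4), 2.0)))
        tdwi, tadc = cs.build_templates([a, b])
        assert tdwi.mean[0, 0, 0] == pytest.approx(1.0)
        assert tdwi.sd[0, 0, 0] == pytest.approx(np.sqrt(2.0))  # sample SD

    def test_identical_controls_floor_sd(self):
        pair = (_img(np.ones((4, 4, 4))), _img(np.ones((4, 4, 4))))
        tdwi, _ = cs.build_templates([pair, pair, pair])
        assert np.all(tdwi.sd > 0)

    def test_matches_brute_force_loop(self, rng_mod):
        stacks = [rng_mod.normal(size=(4, 4, 4)) for _ in range(20)]
        pairs = [(_img(s), _img(s * 2)) for s in stacks]
        tdwi, tadc = cs.build_templates(pairs)
        for idx in [(0, 0, 0), (1, 2, 3), (3, 3, 3)]:
            vox = [s[idx] for s in stacks]
            assert tdwi.mean[idx] == pytest.approx(np.mean(vox))
            assert tdwi.sd[idx] == pytest.approx(np.std(vox, ddof=1))
            assert tadc.mean[idx] == pytest.approx(2 * np.mean(vox))

    def test_fewer_than_two_controls_rejected(self):
        with pytest.raises(ValueError):
            cs.build_templates([(_img(np.ones((2, 2, 2))),
                                _img(np.ones((2, 2, 2))))])


class TestSmoothing:
    def test_zero_fwhm_is_identity(self, rng_mod):
        data = rng_mod.normal(size=(6, 6, 6)).astype(np.float32)
        np.testing.assert_array_equal(cs.smooth_fwhm(data, 0.0), data)

    def test_total_intensity_conserved(self, rng_mod):
        data = np.zeros((24, 24, 24), dtype=np.float32)
        data[8:16, 8:16, 8:16] = rng_mod.random((8, 8, 8))
        sm = cs.smooth_fwhm(data, 3.0)
        assert sm.sum() == pytest.approx(data.sum(), rel=0.01)

    def test_delta_peak_matches_analytic_kernel(self):
        data = np.zeros((31, 31, 31), dtype=np.float32)
        data[15, 15, 15] = 1.0
        fwhm = 4.0
        sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        sm = cs.smooth_fwhm(data, fwhm)
        expected = (2.0 * np.pi * sigma ** 2) ** -1.5
        assert sm[15, 15, 15] == pytest.approx(expected, rel=0.01)


class TestDissimilarity:
    def test_zero_at_template_mean(self, toy_templates):
        tdwi, _ = toy_templates
        delta = cs.cfuzzy_dissimilarity(tdwi.mean, tdwi, alpha=1.5)
        np.testing.assert_allclose(delta, 0.0, atol=1e-12)

    def test_range_is_open_unit_interval(self, toy_templates, rng_mod):
        tdwi, _ = toy_templates
        # keep |z| moderate so float64 tanh does not saturate to exactly 1
        tdwi_unit = cs.PopulationTemplate(tdwi.mean, np.ones_like(tdwi.sd),
                                          "dwi", 5)
        delta = cs.cfuzzy_dissimilarity(
            tdwi.mean + rng_mod.uniform(-6, 6, tdwi.mean.shape),
            tdwi_unit, alpha=1.0)
        assert np.all(np.abs(delta) < 1.0)

    def test_one_sigma_gives_tanh_one(self, toy_templates):
        tdwi, _ = toy_templates
        delta = cs.cfuzzy_dissimilarity(tdwi.mean + tdwi.sd, tdwi, alpha=1.0)
        np.testing.assert_allclose(delta, np.tanh(1.0), atol=1e-9)
        assert delta.flat[0] == pytest.approx(0.76159, abs=1e-5)

    def test_matches_brute_force(self, toy_templates, rng_mod):
        tdwi, _ = toy_templates
        img = rng_mod.normal(0, 2, tdwi.mean.shape)
        delta = cs.cfuzzy_dissimilarity(img, tdwi, alpha=1.5)
        for idx in [(0, 0, 0), (2, 5, 7), (7, 7, 7)]:
            expect = np.tanh((img[idx] - tdwi.mean[idx])
                             / (1.5 * tdwi.sd[idx]))
            assert delta[idx] == pytest.approx(expect, abs=1e-12)


class TestAbnormalityMaps:
    def test_zero_delta_gives_zero_maps(self):
        h1, h2 = cs.abnormality_maps(np.zeros((3, 3, 3)), lam=2.0)
        assert not h1.any() and not h2.any()

    def test_disjoint_support(self, rng_mod):
        delta = rng_mod.uniform(-1, 1, (5, 5, 5))
        h1, h2 = cs.abnormality_maps(delta, lam=3.0)
        assert np.all(h1 * h2 == 0.0)

    def test_direct_evaluation(self):
        h1, h2 = cs.abnormality_maps(np.array([[[0.5, -0.5]]]), lam=2.0)
        np.testing.assert_allclose(h2[0, 0], [0.25, 0.0])
        np.testing.assert_allclose(h1[0, 0], [0.0, 0.25])


class TestTscore:
    def test_subject_at_template_mean_gives_empty_mask(self, toy_templates):
        tdwi, tadc = toy_templates
        mask = cs.tscore_segment(_img(tdwi.mean), _img(tadc.mean),
                                 toy_templates, cs.TscoreParams(W_fwhm=0))
        assert mask.sum() == 0

    def test_matches_brute_force_triple_threshold(self, toy_templates,
                                                  rng_mod):
        tdwi, tadc = toy_templates
        p = cs.TscoreParams(W_fwhm=0, sigma_dwi=1.0, sigma_adc=0.5,
                            sigma_id=0.5)
        dwi = rng_mod.normal(0, 3, tdwi.mean.shape)
        adc = rng_mod.normal(1, 2, tadc.mean.shape)
        mask = cs.tscore_segment(_img(dwi), _img(adc), toy_templates, p)
        mu, sd = dwi.mean(), dwi.std()
        for idx in np.ndindex(*dwi.shape):
            t_dwi = (dwi[idx] - tdwi.mean[idx]) / tdwi.sd[idx]
            t_adc = (tadc.mean[idx] - adc[idx]) / tadc.sd[idx]
            t_id = (dwi[idx] - mu) / sd
            expect = (t_dwi > p.sigma_dwi and t_adc > p.sigma_adc
                      and t_id > p.sigma_id)
            assert bool(mask[idx]) == expect

    def test_default_parameters_are_best_configuration(self):
        p = cs.TscoreParams()
        assert (p.W_fwhm, p.sigma_dwi, p.sigma_adc, p.sigma_id) == \
            (4.0, 2.0, 1.0, 3.5)


class TestISMap:
    def test_hand_case_product(self):
        # H2_dwi = 0.5, H1_adc = 0.8, Q(t_id) = 0.1 -> P_IS = 0.36
        assert 0.5 * 0.8 * (1.0 - 0.1) == pytest.approx(0.36)

    def test_gate_zeroes_below_sigma_id(self, toy_templates, rng_mod):
        tdwi, tadc = toy_templates
        p = cs.CfuzzyParams(W_fwhm=0)
        dwi = rng_mod.normal(0, 2, tdwi.mean.shape)
        adc = rng_mod.normal(1, 2, tadc.mean.shape)
        ism = cs.compute_is_map(_img(dwi), _img(adc), toy_templates, p)
        t_id = (dwi - dwi.mean()) / dwi.std()
        assert np.all(ism.data[t_id < p.sigma_id] == 0.0)

    def test_matches_brute_force_reference(self, toy_templates, rng_mod):
        tdwi, tadc = toy_templates
        p = cs.CfuzzyParams(W_fwhm=0, alpha_dwi=1.5, lambda_dwi=4,
                            alpha_adc=0.5, lambda_adc=2, sigma_id=0.3)
        dwi = rng_mod.normal(0, 2, tdwi.mean.shape)
        adc = rng_mod.normal(1, 2, tadc.mean.shape)
        ism = cs.compute_is_map(_img(dwi), _img(adc), toy_templates, p)
        mu, sd = dwi.mean(), dwi.std()
        for idx in np.ndindex(*dwi.shape):
            d_dwi = np.tanh((dwi[idx] - tdwi.mean[idx])
                            / (p.alpha_dwi * tdwi.sd[idx]))
            d_adc = np.tanh((adc[idx] - tadc.mean[idx])
                            / (p.alpha_adc * tadc.sd[idx]))
            h2 = d_dwi ** p.lambda_dwi if d_dwi > 0 else 0.0
            h1 = (-d_adc) ** p.lambda_adc if d_adc < 0 else 0.0
            t_id = (dwi[idx] - mu) / sd
            expect = (h2 * h1 * (1.0 - cs.qfunc(t_id))
                      if t_id >= p.sigma_id else 0.0)
            assert ism.data[idx] == pytest.approx(expect, abs=1e-6)

    def test_monotone_in_dwi_above_gate(self, toy_templates):
        tdwi, tadc = toy_templates
        p = cs.CfuzzyParams(W_fwhm=0, sigma_id=-10.0)
        adc = tadc.mean - 2 * tadc.sd  # fixed, abnormally low
        base = tdwi.mean + 1.0 * tdwi.sd
        hi = tdwi.mean + 2.0 * tdwi.sd
        # same within-subject stats: compare voxelwise maps from two images
        # whose t_id ordering matches the intensity ordering
        m1 = cs.compute_is_map(_img(base), _img(adc), toy_templates, p)
        m2 = cs.compute_is_map(_img(hi), _img(adc), toy_templates, p)
        assert (m2.data >= m1.data - 1e-9).mean() > 0.99

    def test_default_parameters_are_best_configuration(self):
        p = cs.CfuzzyParams()
        assert (p.W_fwhm, p.alpha_dwi, p.lambda_dwi, p.alpha_adc,
                p.lambda_adc, p.sigma_id) == (2.0, 1.5, 4.0, 0.5, 2.0, 2.0)


@pytest.fixture(scope="module")
def normalized(control_cohort, easy_subject):
    controls = []
    for sub in control_cohort:
        fit = fit_bimodal(sub.dwi.data[sub.brain_mask.data > 0.5])
        controls.append((normalize_dwi(sub.dwi, fit), sub.adc))
    templates = cs.build_templates(controls)
    fit = fit_bimodal(
        easy_subject.dwi.data[easy_subject.brain_mask.data > 0.5])
    dwi_n = normalize_dwi(easy_subject.dwi, fit)
    return templates, dwi_n


class TestOnPhantoms:
    def test_cfuzzy_dice_on_easy_phantom(self, normalized, easy_subject):
        templates, dwi_n = normalized
        brain = easy_subject.brain_mask.data > 0.5
        ism = cs.compute_is_map(dwi_n, easy_subject.adc, templates,
                                brain_mask=brain)
        c = confusion(ism.data > 0.5, easy_subject.lesion_mask.data)
        dice = dice_precision_sensitivity(c)[0]
        assert dice >= 0.5

    def test_tscore_dice_on_easy_phantom(self, normalized, easy_subject):
        templates, dwi_n = normalized
        brain = easy_subject.brain_mask.data > 0.5
        mask = cs.tscore_segment(dwi_n, easy_subject.adc, templates,
                                 brain_mask=brain)
        c = confusion(mask, easy_subject.lesion_mask.data)
        assert dice_precision_sensitivity(c)[0] >= 0.3
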