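"""Unsupervised ischemic-lesion mapping: t-score and modified c-fuzzy methods.

Both methods compare a subject's normalized DWI/ADC against voxelwise
population templates (mean and SD across lesion-free controls in the
standardized space).  The t-score method flags voxels by triple
thresholding; the modified c-fuzzy method produces a continuous ischemic
probability map

    P_IS = I_dwi,H2 * I_adc,H1 * (1 - Q(t_id))   where t_id >= sigma_id,
    P_IS = 0                                     otherwise,

built from tanh dissimilarities to the templates raised to sharpness
exponents, gated by the within-subject DWI z-score t_id.  P_IS doubles as
the optional third input channel of the segmentation networks.

Default parameters are the cross-validated best configurations:
t-score  W_fwhm=4, sigma_dwi=2, sigma_adc=1, sigma_id=3.5;
c-fuzzy  W_fwhm=2, alpha_dwi=1.5, lambda_dwi=4, alpha_adc=0.5,
         lambda_adc=2, sigma_id=2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import erfc

from .volspace import VolumeImage, Modality

__all__ = [
    "PopulationTemplate",
    "TscoreParams",
    "CfuzzyParams",
    "ISMap",
    "build_templates",
    "smooth_fwhm",
    "tscore_segment",
    "cfuzzy_dissimilarity",
    "abnormality_maps",
    "compute_is_map",
    "qfunc",
]

#: relative floor applied to template SD maps (fraction of the brain median)
SD_FLOOR_FRACTION = 0.05


@dataclass
class PopulationTemplate:
    """Voxelwise mean/SD of a modality across lesion-free controls."""

    mean: np.ndarray
    sd: np.ndarray
    modality: str
    n_controls: int

    def __post_init__(self):
        if self.mean.shape != self.sd.shape:
            raise ValueError("mean and sd grids must share a shape")
        if np.any(self.sd <= 0):
            raise ValueError("template SD must be strictly positive (floored)")


@dataclass(frozen=True)
class TscoreParams:
    W_fwhm: float = 4.0
    sigma_dwi: float = 2.0
    sigma_adc: float = 1.0
    sigma_id: float = 3.5


@dataclass(frozen=True)
class CfuzzyParams:
    W_fwhm: float = 2.0
    alpha_dwi: float = 1.5
    lambda_dwi: float = 4.0
    alpha_adc: float = 0.5
    lambda_adc: float = 2.0
    sigma_id: float = 2.0

    def __post_init__(self):
        if self.alpha_dwi <= 0 or self.alpha_adc <= 0:
            raise ValueError("sensitivity alpha must be positive")
        if self.lambda_dwi < 1 or self.lambda_adc < 1:
            raise ValueError("sharpness lambda must be >= 1")


@dataclass
class ISMap:
    """Voxelwise ischemic probability P_IS in [0, 1]."""

    data: np.ndarray
    params: CfuzzyParams

    def __post_init__(self):
        if self.data.min() < -1e-9 or self.data.max() > 1 + 1e-9:
            raise ValueError("P_IS must lie in [0, 1]")


def build_templates(controls) -> tuple[PopulationTemplate, PopulationTemplate]:
    """Voxelwise mean/SD templates from (dwi, adc) pairs of controls.

    ``controls`` is a sequence of (dwi, adc) :class:`VolumeImage` pairs, all
    normalized and in the standardized space.  Sample SD (ddof=1) is used
    and floored at 5% of its in-brain median to avoid division blow-ups.
    """
    controls = list(controls)
    if len(controls) < 2:
        raise ValueError("need at least 2 controls to build templates")
    out = []
    for idx, modality in ((0, "dwi"), (1, "adc")):
        stack = np.stack([np.asarray(pair[idx].data, dtype=np.float64)
                          for pair in controls])
        mean = stack.mean(axis=0)
        sd = stack.std(axis=0, ddof=1)
        pos = sd[sd > 0]
        floor = SD_FLOOR_FRACTION * (np.median(pos) if pos.size else 1.0)
        sd = np.maximum(sd, max(floor, 1e-12))
        out.append(PopulationTemplate(mean=mean, sd=sd, modality=modality,
                                      n_controls=len(controls)))
    return out[0], out[1]


def smooth_fwhm(img: VolumeImage | np.ndarray, W_fwhm: float):
    """Gaussian smoothing parameterized by full width at half maximum
    (in voxels); W_fwhm = 0 is the identity."""
    if W_fwhm < 0:
        raise ValueError("FWHM must be non-negative")
    data = img.data if isinstance(img, VolumeImage) else np.asarray(img)
    if W_fwhm == 0:
        sm = data.astype(np.float32, copy=True)
    else:
        sigma = W_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        sm = ndimage.gaussian_filter(data.astype(np.float32), sigma=sigma)
    if isinstance(img, VolumeImage):
        return img.with_data(sm)
    return sm


def qfunc(t: np.ndarray) -> np.ndarray:
    """Standard normal upper-tail probability Q(t) = P(Z > t)."""
    return 0.5 * erfc(np.asarray(t, dtype=np.float64) / np.sqrt(2.0))


def _subject_zstats(dwi_data, brain):
    vox = dwi_data[brain]
    if vox.size == 0:
        raise ValueError("empty brain mask")
    mu = float(vox.mean())
    sd = float(vox.std())
    if sd <= 0:
        raise ValueError("degenerate (constant) DWI inside the brain mask")
    return mu, sd


def tscore_segment(dwi: VolumeImage, adc: VolumeImage,
                   templates: tuple[PopulationTemplate, PopulationTemplate],
                   p: TscoreParams = TscoreParams(),
                   brain_mask: np.ndarray | None = None) -> np.ndarray:
    """Triple-threshold lesion mask from template t-scores.

    A voxel is flagged iff t_dwi > sigma_dwi AND t_adc > sigma_adc AND
    t_id > sigma_id, where t_s = (I_s - mean_s) / sd_s against the
    population templates (DWI hyper-, ADC hypo-intensity: the ADC score is
    taken as (mean - I)/sd so both thresholds are exceeded upward) and
    t_id is the within-subject DWI z-score.  Subject images and templates
    are both smoothed by W_fwhm.
    """
    tdwi, tadc = templates
    if dwi.data.shape != tdwi.mean.shape or adc.data.shape != tadc.mean.shape:
        raise ValueError("subject and template grids do not match")
    brain = (np.asarray(brain_mask, dtype=bool) if brain_mask is not None
             else np.ones(dwi.data.shape, dtype=bool))

    d = smooth_fwhm(dwi.data, p.W_fwhm)
    a = smooth_fwhm(adc.data, p.W_fwhm)
    t_dwi = (d - smooth_fwhm(tdwi.mean, p.W_fwhm)) / tdwi.sd
    t_adc = (smooth_fwhm(tadc.mean, p.W_fwhm) - a) / tadc.sd
    mu, sd = _subject_zstats(d, brain)
    t_id = (d - mu) / sd
    mask = (t_dwi > p.sigma_dwi) & (t_adc > p.sigma_adc) & (t_id > p.sigma_id)
    return (mask & brain).astype(np.uint8)


def cfuzzy_dissimilarity(img: np.ndarray, template: PopulationTemplate,
                         alpha: float) -> np.ndarray:
    """tanh dissimilarity to the template: values in (-1, 1)."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    img = np.asarray(img, dtype=np.float64)
    return np.tanh((img - template.mean) / (alpha * template.sd))


def abnormality_maps(delta: np.ndarray, lam: float) -> tuple[np.ndarray, np.ndarray]:
    """Abnormal low- (H1) and high-intensity (H2) probability maps.

    H1 = (-delta)^lambda on delta < 0, else 0; H2 = delta^lambda on
    delta > 0, else 0.  Supports are disjoint by construction.
    """
    if lam < 1:
        raise ValueError("lambda must be >= 1")
    delta = np.asarray(delta, dtype=np.float64)
    h1 = np.where(delta < 0, (-delta) ** lam, 0.0)
    h2 = np.where(delta > 0, delta ** lam, 0.0)
    return h1, h2


def compute_is_map(dwi: VolumeImage, adc: VolumeImage,
                   templates: tuple[PopulationTemplate, PopulationTemplate],
                   p: CfuzzyParams = CfuzzyParams(),
                   brain_mask: np.ndarray | None = None) -> ISMap:
    """The modified c-fuzzy ischemic probability map P_IS.

    DWI must be abnormally high against its template (H2), ADC abnormally
    low (H1), and the voxel relatively bright within its own DWI
    (t_id >= sigma_id); elsewhere P_IS = 0.
    """
    if templates is None:
        raise ValueError("population templates are required")
    tdwi, tadc = templates
    if dwi.data.shape != tdwi.mean.shape:
        raise ValueError("subject and template grids do not match")
    brain = (np.asarray(brain_mask, dtype=bool) if brain_mask is not None
             else np.ones(dwi.data.shape, dtype=bool))

    d = smooth_fwhm(dwi.data, p.W_fwhm)
    a = smooth_fwhm(adc.data, p.W_fwhm)
    tdwi_s = PopulationTemplate(smooth_fwhm(tdwi.mean, p.W_fwhm), tdwi.sd,
                                tdwi.modality, tdwi.n_controls)
    tadc_s = PopulationTemplate(smooth_fwhm(tadc.mean, p.W_fwhm), tadc.sd,
                                tadc.modality, tadc.n_controls)

    _, h2_dwi = abnormality_maps(cfuzzy_dissimilarity(d, tdwi_s, p.alpha_dwi),
                                 p.lambda_dwi)
    h1_adc, _ = abnormality_maps(cfuzzy_dissimilarity(a, tadc_s, p.alpha_adc),
                                 p.lambda_adc)
    mu, sd = _subject_zstats(d, brain)
    t_id = (d - mu) / sd
    pis = h2_dwi * h1_adc * (1.0 - qfunc(t_id))
    pis = np.where((t_id >= p.sigma_id) & brain, pis, 0.0)
    return ISMap(data=pis.astype(np.float32), params=p)
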