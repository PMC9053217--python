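"""DWI intensity normalization via a bimodal Gaussian histogram fit.

Clinical DWI intensities are in arbitrary scanner units, so images are made
comparable by fitting the in-brain intensity histogram with a two-peak model

    f(x) = a1 exp(-((x - b1)/c1)^2) + a2 exp(-((x - b2)/c2)^2),

where the low-mean peak (b1) captures "non-brain tissue" (mostly CSF) and the
high-mean dominant peak (b2) captures normal brain tissue.  The DWI is then
normalized so the brain-tissue mode has zero mean and unit standard
deviation.  Note the parameterization: c is sqrt(2) times the Gaussian SD,
so the normalizing scale is sigma2 = c2 / sqrt(2) — using c directly would
silently rescale every downstream threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .volspace import VolumeImage

__all__ = ["BimodalFit", "fit_bimodal", "normalize_dwi", "bimodal"]


@dataclass
class BimodalFit:
    """Least-squares coefficients of the two-peak histogram model.

    By convention b1 < b2 and the b2 peak is the dominant brain-tissue mode.
    """

    a1: float
    b1: float
    c1: float
    a2: float
    b2: float
    c2: float
    residual_norm: float = np.nan
    fallback: bool = False

    def __post_init__(self):
        # order peaks so b2 is the higher-mean (brain tissue) one
        if self.b1 > self.b2:
            self.a1, self.a2 = self.a2, self.a1
            self.b1, self.b2 = self.b2, self.b1
            self.c1, self.c2 = self.c2, self.c1
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("peak widths must be positive")

    @property
    def tissue_mean(self) -> float:
        return self.b2

    @property
    def tissue_sd(self) -> float:
        """Gaussian SD of the tissue peak: c2 / sqrt(2)."""
        return self.c2 / np.sqrt(2.0)

    def to_dict(self) -> dict:
        return {k: float(getattr(self, k))
                for k in ("a1", "b1", "c1", "a2", "b2", "c2", "residual_norm")}


def bimodal(x, a1, b1, c1, a2, b2, c2):
    """The two-peak model evaluated at x."""
    return (a1 * np.exp(-((x - b1) / c1) ** 2)
            + a2 * np.exp(-((x - b2) / c2) ** 2))


def _initial_guess(centers, counts):
    """Seed the fit from the two largest modes of the smoothed histogram."""
    sm = ndimage.gaussian_filter1d(counts.astype(float), sigma=3.0)
    # local maxima of the smoothed histogram
    peaks = [i for i in range(1, len(sm) - 1)
             if sm[i] >= sm[i - 1] and sm[i] >= sm[i + 1] and sm[i] > 0]
    peaks.sort(key=lambda i: sm[i], reverse=True)
    span = centers[-1] - centers[0]
    if len(peaks) >= 2:
        i1, i2 = sorted(peaks[:2], key=lambda i: centers[i])
    else:
        i2 = int(np.argmax(sm))
        i1 = max(0, i2 // 3)
    width = max(span / 20.0, 1e-6)
    return [sm[i1], centers[i1], width, sm[i2], centers[i2], width]


def fit_bimodal(intensities: np.ndarray, nbins: int = 256) -> BimodalFit:
    """Fit the bimodal model to the binned histogram of in-brain voxels.

    Uses 256 equal-width bins over the 0.5-99.5 percentile range.  If the
    nonlinear fit diverges, falls back (with a warning) to a robust
    mean/SD of the sample, reported as a single dominant peak.
    """
    x = np.asarray(intensities, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < 1000:
        raise ValueError("need at least 1000 voxels to fit the histogram")
    lo, hi = np.percentile(x, [0.5, 99.5])
    if not hi > lo:
        raise ValueError("intensity sample is constant")
    counts, edges = np.histogram(x, bins=nbins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    p0 = _initial_guess(centers, counts)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                bimodal, centers, counts, p0=p0,
                bounds=([0, lo, 1e-9, 0, lo, 1e-9],
                        [np.inf, hi, hi - lo, np.inf, hi, hi - lo]),
                maxfev=20000)
        resid = float(np.linalg.norm(bimodal(centers, *popt) - counts))
        fit = BimodalFit(*popt, residual_norm=resid)
        # the brain-tissue mode is the DOMINANT peak; if the high-mean peak
        # is marginal (near-unimodal sample, or a small hyperintense-lesion
        # peak above the tissue mode) the low-mean dominant peak is tissue
        if fit.a2 < 0.2 * fit.a1:
            fit = BimodalFit(a1=0.0, b1=fit.b1 - abs(fit.c1), c1=fit.c1,
                             a2=fit.a1, b2=fit.b1, c2=fit.c1,
                             residual_norm=resid)
        return fit
    except (RuntimeError, ValueError):
        warnings.warn("bimodal histogram fit diverged; falling back to "
                      "robust mean/SD of the masked voxels")
        med = float(np.median(x))
        mad_sd = float(1.4826 * np.median(np.abs(x - med)))
        mad_sd = max(mad_sd, 1e-9)
        return BimodalFit(a1=0.0, b1=med - 1.0, c1=mad_sd * np.sqrt(2),
                          a2=1.0, b2=med, c2=mad_sd * np.sqrt(2),
                          fallback=True)


def normalize_dwi(img: VolumeImage, fit: BimodalFit) -> VolumeImage:
    """Affine-rescale so the brain-tissue mode is zero mean, unit SD.

    The transform is (I - b2) / sigma2 with sigma2 = c2/sqrt(2); being
    affine and monotone it preserves voxel rank order and lesion contrast
    structure above the tissue peak.
    """
    sigma2 = fit.tissue_sd
    if not sigma2 > 0:
        raise ValueError("tissue-peak SD must be positive")
    out = (img.data.astype(np.float32) - fit.tissue_mean) / sigma2
    return img.with_data(out)
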