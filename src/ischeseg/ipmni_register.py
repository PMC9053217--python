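"""Constrained linear registration of B0 to a template ("in-plane MNI").

The B0 image (least affected by the acute lesion) is mapped to a template
with a deliberately restricted transform family: 3D translation, one
in-plane rotation about the slice-normal (z) axis, and in-plane scaling on
x and y.  No through-slice rotation is allowed, which preserves slice
contrast and the continuity of manual annotations in anisotropic clinical
acquisitions.  Similarity is normalized cross-correlation (NCC), optimized
sequentially (translation first, then rotation + scale) over a
three-level multi-resolution pyramid with Powell's method; the whole
procedure is deterministic given its inputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage, optimize

from .volspace import Modality, Space, VolumeImage

__all__ = ["IPTransform", "register_ipmni", "apply_transform", "ncc"]

#: NCC floor below which registration is declared failed (identity returned)
NCC_FLOOR = 0.2

#: search bounds: translations (mm), in-plane rotation (rad), log-scale
MAX_TRANSLATION_MM = 40.0
MAX_THETA = 0.35
MAX_LOG_SCALE = float(np.log(1.25))


@dataclass
class IPTransform:
    """In-plane transform: world-space translation (mm), rotation about the
    slice normal (radians), and in-plane scales.  There are deliberately no
    out-of-plane rotation parameters."""

    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    theta: float = 0.0
    sx: float = 1.0
    sy: float = 1.0

    def __post_init__(self):
        if self.sx <= 0 or self.sy <= 0:
            raise ValueError("in-plane scales must be positive")

    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 world-space map: template point -> subject point
        (the pull-back convention used when resampling into template space)."""
        c, s = np.cos(self.theta), np.sin(self.theta)
        m = np.eye(4)
        m[:3, :3] = np.array([[self.sx * c, -self.sy * s, 0.0],
                              [self.sx * s, self.sy * c, 0.0],
                              [0.0, 0.0, 1.0]])
        m[:3, 3] = (self.tx, self.ty, self.tz)
        return m

    @property
    def params(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz, self.theta, self.sx, self.sy])

    @classmethod
    def from_params(cls, p) -> "IPTransform":
        return cls(tx=float(p[0]), ty=float(p[1]), tz=float(p[2]),
                   theta=float(p[3]), sx=float(p[4]), sy=float(p[5]))

    def to_json(self) -> str:
        return json.dumps({**asdict(self), "matrix": self.matrix().tolist()},
                          indent=1)


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation of two equal-shape grids."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.dot(a, b) / denom)


def _resample_into_template(img: VolumeImage, template: VolumeImage,
                            t: IPTransform, order: int = 1) -> np.ndarray:
    """Sample ``img`` on the template grid through the world-space map."""
    # voxel chain: template ijk -> world -> transform -> world -> img ijk
    full = np.linalg.inv(img.affine) @ t.matrix() @ template.affine
    return ndimage.affine_transform(
        img.data.astype(np.float32), full[:3, :3], offset=full[:3, 3],
        output_shape=template.shape, order=order, mode="constant", cval=0.0,
        prefilter=order > 1)


def _downsample(img: VolumeImage, factor: int) -> VolumeImage:
    if factor == 1:
        return img
    sm = ndimage.gaussian_filter(img.data.astype(np.float32), sigma=factor / 2.0)
    data = sm[::factor, ::factor, ::factor]
    aff = img.affine.copy()
    aff[:3, :3] *= factor
    return img.with_data(data, affine=aff)


def register_ipmni(b0: VolumeImage, template: VolumeImage,
                   levels: tuple[int, ...] = (4, 2, 1)) -> IPTransform:
    """Estimate the in-plane transform maximizing NCC with the template.

    Optimization is sequential at every pyramid level: Powell over the
    three translations with rotation/scale held, then Powell over
    (theta, sx, sy) with translations held.  If the final similarity is
    below ``NCC_FLOOR`` a warning is issued and the identity returned.
    """
    params = np.array([0.0, 0.0, 0.0, 0.0, 1.0, 1.0])

    for factor in levels:
        b0_l = _downsample(b0, factor)
        tpl_l = _downsample(template, factor)

        # similarity is evaluated inside the (slightly dilated) template
        # support: the object boundary stays in view as a scale cue, while
        # the far background cannot inflate the score
        support = ndimage.binary_dilation(
            tpl_l.data > 0.05 * tpl_l.data.max(), iterations=3)

        def cost(p):
            # scales optimized on the log axis so line searches stay valid
            t = IPTransform(tx=p[0], ty=p[1], tz=p[2], theta=p[3],
                            sx=float(np.exp(p[4])), sy=float(np.exp(p[5])))
            moved = _resample_into_template(b0_l, tpl_l, t, order=1)
            return -ncc(moved[support], tpl_l.data[support])

        work = params.copy()
        work[4:] = np.log(work[4:])

        def cost_trans(tr):
            return cost(np.concatenate([tr, work[3:]]))

        tmax = MAX_TRANSLATION_MM
        res = optimize.minimize(cost_trans, work[:3], method="Powell",
                                bounds=[(-tmax, tmax)] * 3,
                                options={"xtol": 0.05 * factor, "ftol": 1e-6})
        work[:3] = res.x

        def cost_rot_scale(rs):
            return cost(np.concatenate([work[:3], rs]))

        res = optimize.minimize(
            cost_rot_scale, work[3:], method="Powell",
            bounds=[(-MAX_THETA, MAX_THETA),
                    (-MAX_LOG_SCALE, MAX_LOG_SCALE),
                    (-MAX_LOG_SCALE, MAX_LOG_SCALE)],
            options={"xtol": 1e-3, "ftol": 1e-6})
        work[3:] = res.x
        params = work.copy()
        params[4:] = np.exp(params[4:])

    t = IPTransform.from_params(params)
    final = -_final_cost(b0, template, t)
    if final < NCC_FLOOR:
        warnings.warn(f"registration similarity NCC={final:.3f} below floor; "
                      "returning identity transform")
        return IPTransform()
    return t


def _final_cost(b0, template, t):
    support = ndimage.binary_dilation(
        template.data > 0.05 * template.data.max(), iterations=3)
    moved = _resample_into_template(b0, template, t, order=1)
    return -ncc(moved[support], template.data[support])


def apply_transform(img: VolumeImage, t: IPTransform,
                    target: VolumeImage, inverse: bool = False,
                    order: int | None = None) -> VolumeImage:
    """Resample ``img`` onto the grid of ``target`` through the transform.

    Forward: ``img`` is native, ``target`` is the template — the result
    lives in template (IP-MNI) space.  Inverse: ``img`` is in template
    space and ``target`` supplies the native geometry to map back onto.
    Masks always use nearest-neighbour so outputs stay binary.
    """
    if order is None or img.modality == Modality.MASK:
        order = 0 if img.modality == Modality.MASK else 1
    if not inverse:
        # target ijk -> world -> T -> world -> img ijk
        full = np.linalg.inv(img.affine) @ t.matrix() @ target.affine
        space = Space.IPMNI
    else:
        # native ijk -> world -> T^{-1} -> template world -> img ijk
        full = np.linalg.inv(img.affine) @ np.linalg.inv(t.matrix()) @ target.affine
        space = Space.NATIVE
    out = ndimage.affine_transform(
        img.data.astype(np.float32), full[:3, :3], offset=full[:3, 3],
        output_shape=target.shape, order=order, mode="constant", cval=0.0,
        prefilter=order > 1)
    if img.modality == Modality.MASK:
        out = (out > 0.5).astype(np.uint8)
    return img.with_data(out, affine=target.affine.copy(), space=space)
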