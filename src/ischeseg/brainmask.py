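"""Brain extraction: a small 3D encoder-decoder at coarse resolution plus
the exact mask post-processing chain.

Skull stripping runs on (DWI, B0) pairs downsampled to a coarse 4 mm grid,
where a compact two-channel U-Net predicts a brain probability map.  The
raw output is thresholded, morphologically closed, hole-filled, upsampled
back to 1 mm (nearest-neighbour), dilated by one voxel and boundary-
smoothed (Gaussian, sigma = 1 voxel, re-thresholded at 0.5).  Masks from
DWI and B0 passes can be combined by voxelwise union.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import nn
from .nn import Tensor
from .trainloop import LossWeights, hybrid_loss
from .volspace import Modality, VolumeImage

__all__ = ["BrainMaskNet", "build_brainmask_net", "postprocess_mask",
           "union_masks", "train_brainmask", "standardize_volume",
           "MASK_DOWNSAMPLE"]

#: coarse-grid factor relative to the 1 mm working resolution
MASK_DOWNSAMPLE = 4


class BrainMaskNet(nn.Module):
    """3-level two-channel 3D U-Net with a sigmoid head.

    Blocks mirror the main segmentation networks: two 3^3 convolutions with
    batch normalization and SeLU each.
    """

    def __init__(self, nf: int = 8):
        if nf < 1:
            raise ValueError("nf must be >= 1")
        self.nf = nf
        self.enc1 = nn.ConvBlock(2, nf)
        self.enc2 = nn.ConvBlock(nf, 2 * nf)
        self.enc3 = nn.ConvBlock(2 * nf, 4 * nf)
        self.up2 = nn.ConvTranspose3d(4 * nf, 2 * nf, stride=2)
        self.bn2 = nn.BatchNorm3d(2 * nf)
        self.dec2 = nn.ConvBlock(4 * nf, 2 * nf)
        self.up1 = nn.ConvTranspose3d(2 * nf, nf, stride=2)
        self.bn1 = nn.BatchNorm3d(nf)
        self.dec1 = nn.ConvBlock(2 * nf, nf)
        self.head = nn.Conv3d(nf, 1, 3)

    def __call__(self, x: Tensor) -> dict:
        e1 = self.enc1(x)
        e2 = self.enc2(nn.maxpool3d(e1))
        e3 = self.enc3(nn.maxpool3d(e2))
        d2 = self.dec2(nn.concat([e2, nn.selu(self.bn2(self.up2(e3)))]))
        d1 = self.dec1(nn.concat([e1, nn.selu(self.bn1(self.up1(d2)))]))
        return {"fuse": nn.sigmoid(self.head(d1)), "side": []}


def build_brainmask_net(nf: int = 8, seed: int | None = 0) -> BrainMaskNet:
    """A coarse-grid brain extraction network ((D, H, W, 2) input)."""
    nn.rng_init(seed)
    return BrainMaskNet(nf)


def standardize_volume(data: np.ndarray) -> np.ndarray:
    """Zero-mean / unit-variance standardization of one channel volume."""
    data = np.asarray(data, dtype=np.float32)
    sd = data.std()
    return (data - data.mean()) / (sd if sd > 1e-6 else 1.0)


def predict_brain_prob(model: BrainMaskNet, dwi_coarse: np.ndarray,
                       b0_coarse: np.ndarray) -> np.ndarray:
    """Raw brain probability on the coarse grid from a (DWI, B0) pair."""
    x = np.stack([standardize_volume(dwi_coarse),
                  standardize_volume(b0_coarse)])[None]
    model.eval()
    return model(Tensor(x))["fuse"].data[0, 0]


def postprocess_mask(raw: VolumeImage, threshold: float = 0.5,
                     upsample: int = MASK_DOWNSAMPLE) -> VolumeImage:
    """Coarse probability map -> clean binary mask at the fine grid.

    Steps, in order: threshold; binary closing (3^3 cross, connectivity 1);
    internal hole filling; nearest-neighbour upsampling by ``upsample``;
    dilation by one voxel; Gaussian boundary smoothing (sigma = 1 voxel)
    re-thresholded at 0.5.  An empty thresholded mask is returned as-is
    with a warning.
    """
    prob = np.asarray(raw.data, dtype=np.float32)
    if prob.min() < -1e-6 or prob.max() > 1 + 1e-6:
        raise ValueError("raw mask probabilities must lie in [0, 1]")
    mask = prob > threshold
    structure = ndimage.generate_binary_structure(3, 1)
    fine_affine = raw.affine @ np.diag([1.0 / upsample] * 3 + [1.0])
    if not mask.any():
        warnings.warn("empty brain mask after thresholding")
        fine = np.zeros(tuple(np.asarray(mask.shape) * upsample), dtype=np.uint8)
        return VolumeImage(fine, fine_affine, modality=Modality.MASK,
                           space=raw.space)
    # closing is extensive; OR with the input guards scipy's border erosion
    mask = ndimage.binary_closing(mask, structure=structure) | mask
    mask = ndimage.binary_fill_holes(mask)
    fine = np.repeat(np.repeat(np.repeat(mask, upsample, axis=0),
                               upsample, axis=1), upsample, axis=2)
    fine = ndimage.binary_dilation(fine, structure=structure)
    sm = ndimage.gaussian_filter(fine.astype(np.float32), sigma=1.0)
    out = (sm > 0.5) | fine  # smoothing may round corners, never erode
    return VolumeImage(out.astype(np.uint8), fine_affine,
                       modality=Modality.MASK, space=raw.space)


def union_masks(a: VolumeImage, b: VolumeImage) -> VolumeImage:
    """Voxelwise logical OR of two masks on the same grid."""
    if a.data.shape != b.data.shape:
        raise ValueError("mask shapes do not match")
    out = ((a.data > 0.5) | (b.data > 0.5)).astype(np.uint8)
    return a.with_data(out)


def train_brainmask(model: BrainMaskNet, pairs, truths, epochs: int = 30,
                    lr: float = 3e-4, batch: int = 4, seed: int = 0) -> list:
    """Train on coarse-grid ((dwi, b0), truth) volumes; returns history.

    Loss is the hybrid generalized-Dice + balanced-BCE objective without
    the L1 term.
    """
    if not pairs:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    w = LossWeights(w_r=0.0)
    opt = nn.Adam(model.parameters(), lr=lr)
    xs = [np.stack([standardize_volume(d), standardize_volume(b)])
          for d, b in pairs]
    ts = [np.asarray(t, dtype=np.float32)[None] for t in truths]
    history = []
    for epoch in range(1, epochs + 1):
        model.train()
        order = rng.permutation(len(xs))
        losses, dices = [], []
        for start in range(0, len(order), batch):
            idx = order[start:start + batch]
            x = Tensor(np.stack([xs[i] for i in idx]), requires_grad=True)
            truth = np.stack([ts[i] for i in idx])
            out = model(x)
            terms = hybrid_loss(out, [truth], w, do_backward=True)
            opt.step()
            model.zero_grad()
            losses.append(terms.L_final)
            pred = out["fuse"].data > 0.5
            inter = (pred & (truth > 0.5)).sum()
            denom = pred.sum() + (truth > 0.5).sum()
            dices.append(2.0 * inter / denom if denom else 1.0)
        history.append({"epoch": epoch, "loss": float(np.mean(losses)),
                        "dice": float(np.mean(dices))})
    model.eval()
    return history
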