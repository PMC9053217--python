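"""Tiled network inference, stitching, morphological cleanup, back-mapping.

Inference runs the 16 stride-phase subvolumes through the network (with the
same per-subvolume channel standardization used in training), reassembles
them by exact interleaving — every standardized-grid voxel is predicted
exactly once — thresholds strictly above 0.5, applies binary closing with a
connectivity-1 structuring element, removes 2D clusters smaller than 5
pixels per axial slice (the smallest lesion size annotated by human
evaluators), and finally maps the mask back to the subject's native grid
with nearest-neighbour interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .nn import Tensor
from .trainloop import standardize_channels
from .volspace import (Modality, Space, SubvolumeStack, VolumeImage,
                       split_subvolumes, stitch_subvolumes)
from .ipmni_register import IPTransform, apply_transform

__all__ = ["LesionPrediction", "predict_volume", "predict_subject",
           "filter_small_clusters", "postprocess_prediction"]

#: decision threshold on the network probability (strictly greater-than)
PROB_THRESHOLD = 0.5
#: minimum surviving in-slice 2D cluster size, in pixels
MIN_CLUSTER_PIXELS = 5


@dataclass
class LesionPrediction:
    """Stitched probability map, standardized- and native-space masks."""

    prob_ipmni: np.ndarray
    mask_ipmni: np.ndarray
    mask_native: VolumeImage | None
    volume_ml: float

    def to_report(self) -> dict:
        return {"volume_ml": float(self.volume_ml),
                "ipmni_voxels": int(self.mask_ipmni.sum())}


def predict_volume(model, image: np.ndarray, brain: np.ndarray,
                   batch: int = 4) -> np.ndarray:
    """Stitched probability grid for one standardized-space subject.

    ``image`` is channel-last (X, Y, Z, C) on the standardized grid; the
    16 phase subvolumes are standardized and forwarded, and the outputs
    interleaved back so that the stitched probability at voxel
    (2x+i, 2y+j, 4z+k) is exactly the subvolume-(i, j, k) output at
    (x, y, z).
    """
    if image.ndim != 4:
        raise ValueError("expected a channel-last (X, Y, Z, C) volume")
    if model.cfg.in_channels != image.shape[-1]:
        raise ValueError(
            f"model expects {model.cfg.in_channels} channels, "
            f"got {image.shape[-1]}")
    stack = split_subvolumes(image)
    brain_stack = split_subvolumes(brain.astype(np.float32))
    model.eval()
    outputs = []
    subs = []
    for (phase, sub), (_, bsub) in zip(stack, brain_stack):
        x = standardize_channels(sub, bsub)
        subs.append(np.moveaxis(x, -1, 0))
    for start in range(0, len(subs), batch):
        x = Tensor(np.stack(subs[start:start + batch]))
        out = model(x)["fuse"].data[:, 0]      # (N, D, H, W)
        outputs.extend(out)
    prob_stack = SubvolumeStack(volumes=[np.asarray(o, dtype=np.float32)
                                         for o in outputs],
                                phase_index=list(stack.phase_index),
                                stride=stack.stride)
    return stitch_subvolumes(prob_stack)


def filter_small_clusters(mask: np.ndarray,
                          min_pixels: int = MIN_CLUSTER_PIXELS) -> np.ndarray:
    """Remove per-axial-slice 2D connected components with < min_pixels.

    Components are 8-connected within each slice (third axis = slice);
    clusters of exactly ``min_pixels`` survive (strict "<" rule).
    """
    mask = np.asarray(mask) > 0.5
    out = np.zeros_like(mask)
    structure = np.ones((3, 3), dtype=int)
    for z in range(mask.shape[2]):
        sl = mask[:, :, z]
        if not sl.any():
            continue
        labels, n = ndimage.label(sl, structure=structure)
        if n == 0:
            continue
        counts = np.bincount(labels.ravel())
        keep = np.flatnonzero(counts >= min_pixels)
        keep = keep[keep > 0]
        out[:, :, z] = np.isin(labels, keep)
    return out.astype(np.uint8)


def postprocess_prediction(prob: np.ndarray,
                           threshold: float = PROB_THRESHOLD,
                           min_pixels: int = MIN_CLUSTER_PIXELS) -> np.ndarray:
    """Threshold (strictly >), close with connectivity 1, filter clusters."""
    mask = prob > threshold
    if mask.any():
        structure = ndimage.generate_binary_structure(3, 1)
        mask = ndimage.binary_closing(mask, structure=structure)
        mask = filter_small_clusters(mask, min_pixels)
    return np.asarray(mask, dtype=np.uint8)


def predict_subject(model, dwi: VolumeImage, adc: VolumeImage,
                    ismap: np.ndarray | None, brain_mask: VolumeImage,
                    transform: IPTransform | None = None,
                    native_ref: VolumeImage | None = None,
                    ) -> LesionPrediction:
    """Full per-subject inference in the standardized space.

    Inputs must already be preprocessed (standardized grid, normalized
    DWI).  CH3 models require ``ismap``; CH2 models ignore it.  If a
    registration transform and native reference geometry are given the
    final mask is mapped back to the subject's native grid.
    """
    channels = [dwi.data, adc.data]
    if model.cfg.in_channels == 3:
        if ismap is None:
            raise ValueError("CH3 model requires the IS probability map")
        channels.append(np.asarray(ismap, dtype=np.float32))
    image = np.stack(channels, axis=-1).astype(np.float32)
    prob = predict_volume(model, image, brain_mask.data)
    mask = postprocess_prediction(prob)

    mask_native = None
    if transform is not None and native_ref is not None:
        mask_ipmni_vol = VolumeImage(mask, dwi.affine.copy(),
                                     modality=Modality.MASK,
                                     space=Space.IPMNI)
        mask_native = apply_transform(mask_ipmni_vol, transform,
                                      native_ref, inverse=True)
        vox_ml = float(np.prod(mask_native.spacing)) / 1000.0
        volume_ml = float(mask_native.data.sum()) * vox_ml
    else:
        vox_ml = float(np.prod(dwi.spacing)) / 1000.0
        volume_ml = float(mask.sum()) * vox_ml
    return LesionPrediction(prob_ipmni=prob, mask_ipmni=mask,
                            mask_native=mask_native, volume_ml=volume_ml)
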