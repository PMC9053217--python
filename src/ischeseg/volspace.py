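"""Volume containers, NIfTI I/O, resampling, padding and the 16-subvolume tiling.

All pipeline stages pass :class:`VolumeImage` objects around: a 3D scalar grid
plus a 4x4 voxel-to-world affine (mm) and a modality tag.  The standardized
working grid ("IP-MNI" space) is 192 x 224 x 192 voxels at 1 mm isotropic;
networks operate on its stride-(2, 2, 4) phase decomposition into sixteen
96 x 112 x 48 subvolumes ("IP-MNI DS" space).  Smaller grids with the same
8/7-ish aspect can be used for scaled-down experiments via :class:`GridSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Modality",
    "Space",
    "GridSpec",
    "STANDARD_GRID",
    "SUBVOLUME_STRIDE",
    "VolumeImage",
    "SubvolumeStack",
    "load_volume",
    "save_volume",
    "resample_to_iso",
    "pad_to_grid",
    "pad_to_ipmni",
    "split_subvolumes",
    "stitch_subvolumes",
]


class Modality:
    DWI = "DWI"
    B0 = "B0"
    ADC = "ADC"
    MASK = "MASK"
    PROB = "PROB"


class Space:
    NATIVE = "NATIVE"
    ISO1MM = "ISO1MM"
    IPMNI = "IPMNI"
    IPMNI_DS = "IPMNI_DS"


#: Phase-decomposition stride from the standardized grid to the network grid.
SUBVOLUME_STRIDE = (2, 2, 4)


@dataclass(frozen=True)
class GridSpec:
    """A standardized grid: padded shape, voxel spacing, and tiling stride."""

    shape: tuple[int, int, int] = (192, 224, 192)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    stride: tuple[int, int, int] = SUBVOLUME_STRIDE

    @property
    def subvolume_shape(self) -> tuple[int, int, int]:
        return tuple(s // d for s, d in zip(self.shape, self.stride))

    @property
    def n_subvolumes(self) -> int:
        return int(np.prod(self.stride))

    def affine(self) -> np.ndarray:
        a = np.diag(list(self.spacing) + [1.0]).astype(float)
        # centre the grid on the world origin, as templates conventionally are
        a[:3, 3] = -(np.asarray(self.shape) - 1) * np.asarray(self.spacing) / 2.0
        return a


STANDARD_GRID = GridSpec()


@dataclass
class VolumeImage:
    """A 3D scalar volume with voxel-to-world geometry.

    Invariants: ``affine`` is invertible with strictly positive voxel
    spacings; MASK data is binary; PROB data lies in [0, 1].
    """

    data: np.ndarray
    affine: np.ndarray
    modality: str = Modality.DWI
    space: str = Space.NATIVE

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D grid, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacings must be strictly positive")
        if self.modality == Modality.MASK:
            vals = np.unique(self.data)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("MASK data must be binary")
        if self.modality == Modality.PROB:
            if self.data.min() < -1e-6 or self.data.max() > 1 + 1e-6:
                raise ValueError("PROB data must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths in mm along the three axes."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def with_data(self, data: np.ndarray, **kw) -> "VolumeImage":
        return replace(self, data=data, **kw)

    def voxel_to_world(self, ijk) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return (self.affine[:3, :3] @ ijk.T + self.affine[:3, 3:4]).T.squeeze()

    def world_to_voxel(self, xyz) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return (inv[:3, :3] @ xyz.T + inv[:3, 3:4]).T.squeeze()


def load_volume(path, modality: str = Modality.DWI,
                space: str = Space.NATIVE) -> VolumeImage:
    """Read a NIfTI volume, reorienting to the canonical RAS+ axis order."""
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if modality == Modality.MASK:
        data = (data > 0.5).astype(np.uint8)
    return VolumeImage(data=data, affine=img.affine, modality=modality, space=space)


def save_volume(vol: VolumeImage, path) -> None:
    data = vol.data
    if vol.modality == Modality.MASK:
        data = data.astype(np.uint8)
    else:
        data = data.astype(np.float32)
    nib.save(nib.Nifti1Image(data, vol.affine), str(path))


def resample_to_iso(img: VolumeImage, spacing_mm: float = 1.0,
                    order: int | None = None) -> VolumeImage:
    """Resample onto an isotropic grid of ``spacing_mm`` per axis.

    World-space extent is preserved within one voxel.  Intensity images are
    interpolated trilinearly by default; MASK volumes always use
    nearest-neighbour so the output stays binary.
    """
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    if order is None:
        order = 0 if img.modality == Modality.MASK else 1
    if img.modality == Modality.MASK:
        order = 0
    old_spacing = img.spacing
    zoom = old_spacing / spacing_mm
    new_shape = np.maximum(1, np.round(np.asarray(img.shape) * zoom)).astype(int)
    # voxel map: new index n -> old index n / zoom (corner-aligned grids)
    matrix = np.diag(1.0 / zoom)
    dtype = np.float64 if img.data.dtype == np.float64 else np.float32
    out = ndimage.affine_transform(
        img.data.astype(dtype), matrix, order=order,
        output_shape=tuple(new_shape), mode="constant", cval=0.0,
        prefilter=order > 1)
    new_affine = img.affine @ np.diag([1.0 / z for z in zoom] + [1.0])
    if img.modality == Modality.MASK:
        out = (out > 0.5).astype(np.uint8)
    return img.with_data(out, affine=new_affine, space=Space.ISO1MM)


def pad_to_grid(img: VolumeImage, grid: GridSpec = STANDARD_GRID) -> VolumeImage:
    """Zero-pad to the standardized grid shape, content centred.

    With an odd shape difference the extra voxel goes on the high side.
    Cropping is refused: a dimension larger than the target raises.
    """
    target = np.asarray(grid.shape)
    cur = np.asarray(img.shape)
    if np.any(cur > target):
        raise ValueError(
            f"volume shape {img.shape} exceeds target {grid.shape}; refusing to crop")
    lo = (target - cur) // 2
    hi = target - cur - lo
    out = np.pad(img.data, [(int(a), int(b)) for a, b in zip(lo, hi)])
    new_affine = img.affine.copy()
    new_affine[:3, 3] -= new_affine[:3, :3] @ lo
    return img.with_data(out, affine=new_affine, space=Space.IPMNI)


def pad_to_ipmni(img: VolumeImage) -> VolumeImage:
    """Pad to the standard 192 x 224 x 192 IP-MNI grid."""
    return pad_to_grid(img, STANDARD_GRID)


@dataclass
class SubvolumeStack:
    """The stride-phase decomposition of a standardized volume.

    Entry ``(i, j, k)`` holds the voxels at original coordinates
    ``(sx*x + i, sy*y + j, sz*z + k)`` for stride ``(sx, sy, sz)``; phases are
    ordered lexicographically and form a bijection onto the stride lattice.
    """

    volumes: list[np.ndarray]
    phase_index: list[tuple[int, int, int]]
    stride: tuple[int, int, int] = SUBVOLUME_STRIDE

    def __post_init__(self) -> None:
        n = int(np.prod(self.stride))
        if len(self.volumes) != n or len(self.phase_index) != n:
            raise ValueError(f"expected exactly {n} subvolumes")
        expected = [(i, j, k)
                    for i in range(self.stride[0])
                    for j in range(self.stride[1])
                    for k in range(self.stride[2])]
        if sorted(self.phase_index) != expected:
            raise ValueError("phase triples must be a bijection onto the stride lattice")

    def __iter__(self):
        return iter(zip(self.phase_index, self.volumes))


def split_subvolumes(vol: np.ndarray,
                     stride: tuple[int, int, int] = SUBVOLUME_STRIDE) -> SubvolumeStack:
    """Decompose a (X, Y, Z[, C]) grid into its stride phases.

    For the standard grid this yields 16 subvolumes of 96 x 112 x 48 (x C).
    """
    vol = np.asarray(vol)
    sx, sy, sz = stride
    if vol.ndim not in (3, 4):
        raise ValueError("expected a 3D or channel-last 4D grid")
    if any(s % d for s, d in zip(vol.shape[:3], stride)):
        raise ValueError(f"shape {vol.shape[:3]} not divisible by stride {stride}")
    phases, subs = [], []
    for i in range(sx):
        for j in range(sy):
            for k in range(sz):
                phases.append((i, j, k))
                subs.append(np.ascontiguousarray(vol[i::sx, j::sy, k::sz]))
    return SubvolumeStack(volumes=subs, phase_index=phases, stride=stride)


def stitch_subvolumes(stack: SubvolumeStack) -> np.ndarray:
    """Exact inverse of :func:`split_subvolumes` (bit-exact reassembly)."""
    sx, sy, sz = stack.stride
    sub_shape = stack.volumes[0].shape
    out_shape = (sub_shape[0] * sx, sub_shape[1] * sy, sub_shape[2] * sz) + sub_shape[3:]
    out = np.empty(out_shape, dtype=stack.volumes[0].dtype)
    for (i, j, k), sub in stack:
        if sub.shape != sub_shape:
            raise ValueError("inconsistent subvolume shapes")
        out[i::sx, j::sy, k::sz] = sub
    return out
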