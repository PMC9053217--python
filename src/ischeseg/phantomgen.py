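"""Seeded synthetic brain-phantom cohorts for diffusion MRI.

The generator emulates the statistics every pipeline stage relies on, without
any anatomical realism: an ellipsoidal "brain" whose DWI histogram is bimodal
(a small low-intensity CSF peak from ventricles, a dominant tissue peak),
ADC maps with high CSF / moderate tissue values, and ischemic lesions as
smoothed random ellipsoidal blobs that are hyperintense in DWI (contrast
kappa_DWI > 1) and hypointense in ADC (kappa_ADC < 1), grown to a target
volume in ml.  Voxels can be anisotropic (clinical 1 x 1 x 5 mm defaults) or
match a standardized grid directly.  Optional "lesion-like" artifacts are
thin hyperintense shells at tissue interfaces.  Noise is Rician by default
(magnitude MRI) with configurable sigma.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volspace import GridSpec, Modality, Space, VolumeImage, load_volume, save_volume

__all__ = [
    "PhantomSpec",
    "PhantomSubject",
    "generate_subject",
    "generate_cohort",
    "save_cohort",
    "load_cohort",
    "make_template",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Construction parameters of one synthetic subject.

    Intensity defaults mimic clinical trace DWI (arbitrary units, tissue
    mode ~200) and ADC in 1e-4 mm^2/s (tissue ~8, CSF ~30).  Lesion volume
    and DWI contrast defaults sit inside the clinical interquartile ranges
    (volume ~1-22 ml, kappa_DWI ~2.3-4.5).
    """

    shape: tuple[int, int, int] = (160, 192, 32)
    spacing: tuple[float, float, float] = (1.0, 1.0, 5.0)
    space: str = Space.NATIVE

    tissue_dwi: float = 200.0
    csf_dwi: float = 60.0
    tissue_b0: float = 180.0
    csf_b0: float = 260.0
    tissue_adc: float = 8.0
    csf_adc: float = 30.0

    n_lesions: int = 1
    lesion_volume_ml: float = 10.0
    kappa_dwi: float = 3.0
    kappa_adc: float = 0.55
    blob_smoothness_mm: float = 1.5

    artifacts: bool = False
    noise_model: str = "rician"  # or "gaussian", "none"
    noise_sigma: float = 8.0

    #: relative jitter of brain/ventricle geometry and global intensity scale
    subject_jitter: float = 0.03

    seed: int = 0

    def __post_init__(self):
        if self.n_lesions > 0:
            if not self.kappa_dwi > 1:
                raise ValueError("target kappa_DWI must exceed 1")
            if not 0 < self.kappa_adc < 1:
                raise ValueError("target kappa_ADC must lie in (0, 1)")
            if self.lesion_volume_ml <= 0:
                raise ValueError("lesion volume must be positive")


@dataclass
class PhantomSubject:
    """One generated subject: five geometrically consistent volumes."""

    dwi: VolumeImage
    b0: VolumeImage
    adc: VolumeImage
    brain_mask: VolumeImage
    lesion_mask: VolumeImage
    spec: PhantomSpec
    meta: dict = field(default_factory=dict)


def _mm_grid(shape, spacing):
    """Coordinate grids in mm, centred on the volume centre."""
    axes = [(np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(xx, yy, zz, centre_mm, semi_mm, rot=None):
    d = np.stack([xx - centre_mm[0], yy - centre_mm[1], zz - centre_mm[2]])
    if rot is not None:
        d = np.einsum("ab,bxyz->axyz", rot, d)
    r = (d[0] / semi_mm[0]) ** 2 + (d[1] / semi_mm[1]) ** 2 + (d[2] / semi_mm[2]) ** 2
    return r <= 1.0


def _random_rotation(rng):
    # QR of a Gaussian matrix gives a uniform rotation (sign-fixed)
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    return q * np.sign(np.diag(r))


def generate_subject(spec: PhantomSpec) -> PhantomSubject:
    """Build one phantom subject; bit-reproducible given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    shape, spacing = spec.shape, spec.spacing
    xx, yy, zz = _mm_grid(shape, spacing)
    extent = np.asarray(shape) * np.asarray(spacing)

    j = spec.subject_jitter
    semi = 0.42 * extent * (1.0 + rng.uniform(-j, j, size=3))
    brain = _ellipsoid(xx, yy, zz, (0.0, 0.0, 0.0), semi)
    if not brain.any():
        raise ValueError("degenerate phantom: empty brain")

    # two lateral ventricles (CSF), offset from the midline
    vent_semi = semi * np.array([0.10, 0.30, 0.22]) * (1.0 + rng.uniform(-j, j, size=3))
    off = semi[0] * 0.16
    csf = np.zeros(shape, dtype=bool)
    for sx in (-1.0, 1.0):
        csf |= _ellipsoid(xx, yy, zz, (sx * off, 0.0, 0.0), vent_semi)
    csf &= brain
    tissue = brain & ~csf

    gain = 1.0 + rng.normal(0.0, j)  # scanner-like global intensity scale
    dwi = np.where(brain, np.where(csf, spec.csf_dwi, spec.tissue_dwi), 0.0) * gain
    b0 = np.where(brain, np.where(csf, spec.csf_b0, spec.tissue_b0), 0.0) * gain
    adc = np.where(brain, np.where(csf, spec.csf_adc, spec.tissue_adc), 0.0)

    voxel_ml = float(np.prod(spacing)) / 1000.0
    lesion = np.zeros(shape, dtype=bool)
    for _ in range(spec.n_lesions):
        lesion |= _grow_lesion(rng, spec, xx, yy, zz, tissue, semi, voxel_ml)

    meta = {}
    if lesion.any():
        normal = brain & ~lesion
        sm_vox = np.maximum(spec.blob_smoothness_mm / np.asarray(spacing), 1e-6)
        prof = ndimage.gaussian_filter(lesion.astype(np.float32), sigma=sm_vox)
        prof /= max(prof.max(), 1e-9)
        dwi = _apply_contrast(dwi, prof, lesion, normal, spec.kappa_dwi)
        adc = _apply_contrast(adc, prof, lesion, normal, spec.kappa_adc)
        meta["lesion_volume_ml"] = float(lesion.sum()) * voxel_ml

    if spec.artifacts:
        shell = brain & ~ndimage.binary_erosion(brain, iterations=2)
        patch = _ellipsoid(xx, yy, zz, (0.0, -semi[1] * 0.9, 0.0), semi * 0.35)
        art = shell & patch & ~lesion
        dwi[art] = spec.tissue_dwi * 2.5 * gain
        meta["artifact_voxels"] = int(art.sum())

    dwi = _add_noise(rng, dwi, spec)
    b0 = _add_noise(rng, b0, spec)
    adc = _add_noise(rng, adc, spec, sigma=spec.noise_sigma * spec.tissue_adc
                     / spec.tissue_dwi)

    grid = GridSpec(shape=tuple(shape), spacing=tuple(spacing))
    aff = grid.affine()

    def vol(data, modality):
        return VolumeImage(data=data.astype(np.float32) if modality not in
                           (Modality.MASK,) else data.astype(np.uint8),
                           affine=aff, modality=modality, space=spec.space)

    return PhantomSubject(
        dwi=vol(dwi, Modality.DWI),
        b0=vol(b0, Modality.B0),
        adc=vol(adc, Modality.ADC),
        brain_mask=vol(brain, Modality.MASK),
        lesion_mask=vol(lesion, Modality.MASK),
        spec=spec, meta=meta)


def _grow_lesion(rng, spec, xx, yy, zz, tissue, brain_semi, voxel_ml):
    """One random ellipsoidal blob of the target volume, inside tissue."""
    target_vox = spec.lesion_volume_ml / voxel_ml
    if target_vox > 0.5 * tissue.sum():
        raise ValueError("infeasible lesion target: larger than half the brain")
    # random semi-axis ratios with the right product: V = 4/3 pi a b c
    ratios = rng.uniform(0.6, 1.7, size=3)
    ratios /= ratios.prod() ** (1 / 3)
    r0 = (3.0 * spec.lesion_volume_ml * 1000.0 / (4.0 * np.pi)) ** (1 / 3)
    semi = r0 * ratios
    rot = _random_rotation(rng)
    for _ in range(50):
        centre = rng.uniform(-0.55, 0.55, size=3) * brain_semi
        les = _ellipsoid(xx, yy, zz, centre, semi, rot) & tissue
        if les.sum() >= 0.9 * target_vox:
            return les
    raise ValueError("could not place lesion inside brain tissue")


def _apply_contrast(img, profile, lesion, normal, kappa):
    """Blend a lesion profile so mean(img|lesion)/mean(img|normal) == kappa."""
    base_normal = img[normal].mean()
    delta = (base_normal - img) * profile  # profile==1 -> intensity == normal mean
    lifted = img + delta
    # scale an additive bump so the measured contrast is exact pre-noise
    bump = profile.copy()
    num = kappa * base_normal - lifted[lesion].mean()
    den = bump[lesion].mean()
    out = lifted + (num / den) * bump
    return np.where(profile > 1e-4, out, img)


def _add_noise(rng, img, spec, sigma=None):
    s = spec.noise_sigma if sigma is None else sigma
    if spec.noise_model == "none" or s <= 0:
        return img
    if spec.noise_model == "gaussian":
        return img + rng.normal(0.0, s, size=img.shape)
    if spec.noise_model == "rician":
        n1 = rng.normal(0.0, s, size=img.shape)
        n2 = rng.normal(0.0, s, size=img.shape)
        return np.sqrt((img + n1) ** 2 + n2 ** 2)
    raise ValueError(f"unknown noise model {spec.noise_model!r}")


def generate_cohort(n_controls: int, n_lesioned: int, seed: int,
                    base_spec: PhantomSpec | None = None,
                    volume_range_ml: tuple[float, float] = (0.8, 40.0),
                    kappa_dwi_range: tuple[float, float] = (2.3, 4.5),
                    kappa_adc_range: tuple[float, float] = (0.4, 0.7),
                    ) -> list[PhantomSubject]:
    """A seeded cohort: lesion-free controls (the "not visible" analogue)
    plus lesioned subjects with volumes log-uniform over ``volume_range_ml``
    (spanning the small/medium/large strata) and contrasts uniform over the
    clinical interquartile-like ranges."""
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n_controls):
        spec = replace(base, n_lesions=0, seed=int(rng.integers(2 ** 31)))
        subjects.append(generate_subject(spec))
    for i in range(n_lesioned):
        vol = float(np.exp(rng.uniform(np.log(volume_range_ml[0]),
                                       np.log(volume_range_ml[1]))))
        spec = replace(base, n_lesions=max(1, base.n_lesions),
                       lesion_volume_ml=vol,
                       kappa_dwi=float(rng.uniform(*kappa_dwi_range)),
                       kappa_adc=float(rng.uniform(*kappa_adc_range)),
                       seed=int(rng.integers(2 ** 31)))
        subjects.append(generate_subject(spec))
    return subjects


_VOLUMES = ("dwi", "b0", "adc", "brain_mask", "lesion_mask")


def save_cohort(subjects: list[PhantomSubject], out_dir) -> Path:
    """Write a cohort directory of NIfTI files plus a manifest JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for idx, sub in enumerate(subjects):
        name = f"sub-{idx:03d}"
        (out / name).mkdir(exist_ok=True)
        rec = {"name": name, "spec": asdict(sub.spec), "meta": sub.meta}
        for key in _VOLUMES:
            path = out / name / f"{key}.nii.gz"
            save_volume(getattr(sub, key), path)
            rec[key] = str(path.relative_to(out))
        manifest.append(rec)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out / "manifest.json"


def load_cohort(manifest_path) -> list[PhantomSubject]:
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    subjects = []
    for rec in json.loads(manifest_path.read_text()):
        spec_d = rec["spec"]
        for key in ("shape", "spacing"):
            spec_d[key] = tuple(spec_d[key])
        spec = PhantomSpec(**spec_d)
        vols = {}
        for key in _VOLUMES:
            modality = (Modality.MASK if key.endswith("mask")
                        else getattr(Modality, key.upper(), Modality.DWI))
            vols[key] = load_volume(root / rec[key], modality=modality,
                                    space=spec.space)
        subjects.append(PhantomSubject(spec=spec, meta=rec.get("meta", {}), **vols))
    return subjects


def make_template(grid: GridSpec | None = None, modality: str = Modality.B0,
                  ) -> VolumeImage:
    """A noise-free canonical phantom in standardized space, used as the
    registration target in place of a population-average template."""
    grid = grid or GridSpec()
    spec = PhantomSpec(shape=grid.shape, spacing=grid.spacing, n_lesions=0,
                       noise_model="none", subject_jitter=0.0, seed=0,
                       space=Space.IPMNI)
    sub = generate_subject(spec)
    vol = {Modality.B0: sub.b0, Modality.DWI: sub.dwi, Modality.ADC: sub.adc}[modality]
    return vol
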