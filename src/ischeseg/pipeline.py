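"""End-to-end segmentation pipeline: preprocess -> map -> segment -> report.

Stage order for one subject (native DWI/B0/ADC):

1. resample to the template's isotropic resolution;
2. brain extraction (trained coarse-grid network if provided, otherwise a
   deterministic intensity heuristic);
3. constrained in-plane registration of B0 to the template; DWI/ADC/mask
   are carried into the standardized space on the template grid;
4. DWI intensity normalization via the bimodal histogram fit;
5. optional classical ischemic-probability (IS) map against population
   templates;
6. lesion segmentation: a trained network (tiled inference + morphological
   post-processing) or a classical method directly;
7. back-mapping of the mask to the subject's original grid and a JSON
   report (lesion volume, contrasts, fit and transform parameters).

Every stage is deterministic given its inputs and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import brainmask as bm
from . import classical_seg as cs
from . import evalmetrics as em
from . import infer_post as ip
from . import intensity_norm as inorm
from . import netzoo
from .ipmni_register import IPTransform, apply_transform, register_ipmni
from .volspace import (GridSpec, Modality, Space, VolumeImage, load_volume,
                       resample_to_iso, save_volume)

__all__ = ["RunConfig", "SubjectBundle", "heuristic_brainmask",
           "preprocess_subject", "segment_subject", "run_segment",
           "build_population_templates", "save_templates", "load_templates"]

MODEL_CHOICES = ("dagmnet_ch3", "dagmnet_ch2", "unet_ch3", "unet_ch2",
                 "fcn_ch3", "fcn_ch2", "cfuzzy", "tscore")


@dataclass
class RunConfig:
    """Inputs and choices of one pipeline run."""

    dwi: str
    b0: str
    adc: str
    out_dir: str
    model: str = "cfuzzy"
    checkpoint: str | None = None
    nf: int | None = None
    template: str | None = None
    templates_npz: str | None = None
    truth: str | None = None
    brainmask_net: str | None = None
    brainmask_nf: int = 8
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self):
        if self.model not in MODEL_CHOICES:
            raise ValueError(
                f"unknown model {self.model!r}; choose from {MODEL_CHOICES}")
        if self.model.endswith(("ch2", "ch3")) and self.checkpoint is None:
            raise ValueError(f"model {self.model!r} requires --checkpoint")


@dataclass
class SubjectBundle:
    """All per-subject artifacts accumulated along the pipeline."""

    native_dwi: VolumeImage
    dwi: VolumeImage            # standardized space, normalized
    adc: VolumeImage
    brain: VolumeImage
    transform: IPTransform
    fit: inorm.BimodalFit
    ismap: cs.ISMap | None = None
    report: dict = field(default_factory=dict)


def heuristic_brainmask(dwi: VolumeImage, b0: VolumeImage) -> VolumeImage:
    """Deterministic intensity-based brain extraction fallback.

    Thresholds B0+DWI at a fraction of their bright percentile, closes,
    fills holes and keeps the largest connected component.
    """
    combo = (dwi.data.astype(np.float64) / max(np.percentile(dwi.data, 99), 1e-9)
             + b0.data.astype(np.float64) / max(np.percentile(b0.data, 99), 1e-9))
    mask = combo > 0.25
    structure = ndimage.generate_binary_structure(3, 1)
    mask = ndimage.binary_closing(mask, structure=structure, iterations=2)
    mask = ndimage.binary_fill_holes(mask)
    labels, n = ndimage.label(mask)
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        mask = labels == counts.argmax()
    return dwi.with_data(mask.astype(np.uint8), modality=Modality.MASK)


def network_brainmask(net: bm.BrainMaskNet, dwi: VolumeImage,
                      b0: VolumeImage) -> VolumeImage:
    """Brain extraction through the coarse-grid network + post-processing."""
    factor = bm.MASK_DOWNSAMPLE
    spacing = float(dwi.spacing[0]) * factor
    dwi_c = resample_to_iso(dwi, spacing)
    b0_c = resample_to_iso(b0, spacing)
    prob = bm.predict_brain_prob(net, dwi_c.data, b0_c.data)
    raw = VolumeImage(prob.astype(np.float32), dwi_c.affine,
                      modality=Modality.PROB, space=dwi_c.space)
    fine = bm.postprocess_mask(raw, upsample=factor)
    # crop/pad the upsampled grid back onto the working grid
    out = np.zeros(dwi.shape, dtype=np.uint8)
    sl = tuple(slice(0, min(a, b)) for a, b in zip(dwi.shape, fine.shape))
    out[sl] = fine.data[sl]
    return dwi.with_data(out, modality=Modality.MASK)


def preprocess_subject(dwi: VolumeImage, b0: VolumeImage, adc: VolumeImage,
                       template: VolumeImage,
                       brain_net: bm.BrainMaskNet | None = None,
                       ) -> SubjectBundle:
    """Native volumes -> standardized-space, intensity-normalized bundle."""
    spacing = float(template.spacing[0])
    native_dwi = dwi
    dwi_i = resample_to_iso(dwi, spacing)
    b0_i = resample_to_iso(b0, spacing)
    adc_i = resample_to_iso(adc, spacing)

    if brain_net is not None:
        brain_i = network_brainmask(brain_net, dwi_i, b0_i)
    else:
        brain_i = heuristic_brainmask(dwi_i, b0_i)

    transform = register_ipmni(b0_i, template)
    dwi_s = apply_transform(dwi_i, transform, template)
    adc_s = apply_transform(adc_i, transform, template)
    brain_s = apply_transform(brain_i, transform, template)

    fit = inorm.fit_bimodal(dwi_s.data[brain_s.data > 0.5])
    dwi_n = inorm.normalize_dwi(dwi_s, fit)

    return SubjectBundle(native_dwi=native_dwi, dwi=dwi_n, adc=adc_s,
                         brain=brain_s, transform=transform, fit=fit)


def build_population_templates(bundles) -> tuple:
    """Population mean/SD templates from preprocessed control bundles."""
    pairs = [(b.dwi, b.adc) for b in bundles]
    return cs.build_templates(pairs)


def save_templates(templates, path):
    tdwi, tadc = templates
    np.savez_compressed(path, dwi_mean=tdwi.mean, dwi_sd=tdwi.sd,
                        adc_mean=tadc.mean, adc_sd=tadc.sd,
                        n_controls=tdwi.n_controls)


def load_templates(path):
    with np.load(path) as zf:
        n = int(zf["n_controls"])
        return (cs.PopulationTemplate(zf["dwi_mean"], zf["dwi_sd"], "dwi", n),
                cs.PopulationTemplate(zf["adc_mean"], zf["adc_sd"], "adc", n))


def segment_subject(bundle: SubjectBundle, model_name: str,
                    templates=None, network=None) -> VolumeImage:
    """Segment a preprocessed subject; returns the standardized-space mask
    and fills ``bundle.report`` / ``bundle.ismap``."""
    brain = bundle.brain.data > 0.5
    if model_name == "tscore":
        mask = cs.tscore_segment(bundle.dwi, bundle.adc, templates,
                                 brain_mask=brain)
        prob = mask.astype(np.float32)
    elif model_name == "cfuzzy":
        bundle.ismap = cs.compute_is_map(bundle.dwi, bundle.adc, templates,
                                         brain_mask=brain)
        prob = bundle.ismap.data
        mask = ip.postprocess_prediction(prob)
    else:
        if network.cfg.in_channels == 3:
            bundle.ismap = cs.compute_is_map(bundle.dwi, bundle.adc,
                                             templates, brain_mask=brain)
            ismap = bundle.ismap.data
        else:
            ismap = None
        pred = ip.predict_subject(network, bundle.dwi, bundle.adc, ismap,
                                  bundle.brain)
        prob, mask = pred.prob_ipmni, pred.mask_ipmni
    bundle.report["prob_max"] = float(np.asarray(prob).max())
    return bundle.dwi.with_data(np.asarray(mask, dtype=np.uint8),
                                modality=Modality.MASK)


def normalize_standardized_subject(sub):
    """Per-subject DWI normalization for cohorts already on the
    standardized grid (no registration step needed)."""
    brain = sub.brain_mask.data > 0.5
    fit = inorm.fit_bimodal(sub.dwi.data[brain])
    return inorm.normalize_dwi(sub.dwi, fit), fit


def cohort_to_samples(subjects, in_channels: int = 3, templates=None):
    """Standardized-grid phantom subjects -> training Samples.

    Normalizes every subject's DWI, builds population templates from the
    lesion-free controls when none are given, and (for 3-channel models)
    computes the classical IS probability map as the third channel.
    Returns (samples, templates).
    """
    from .trainloop import Sample

    normed = []
    for sub in subjects:
        dwi_n, _ = normalize_standardized_subject(sub)
        normed.append((sub, dwi_n))
    if templates is None:
        controls = [(dwi_n, sub.adc) for sub, dwi_n in normed
                    if not (sub.lesion_mask.data > 0).any()]
        if len(controls) >= 2:
            templates = cs.build_templates(controls)
    samples = []
    for i, (sub, dwi_n) in enumerate(normed):
        brain = sub.brain_mask.data > 0.5
        channels = [dwi_n.data, sub.adc.data]
        if in_channels == 3:
            if templates is None:
                raise ValueError("3-channel samples need population templates")
            ismap = cs.compute_is_map(dwi_n, sub.adc, templates,
                                      brain_mask=brain)
            channels.append(ismap.data)
        samples.append(Sample(
            image=np.stack(channels, axis=-1).astype(np.float32),
            truth=(sub.lesion_mask.data > 0.5).astype(np.float32),
            brain=brain.astype(np.float32),
            name=f"sub-{i:03d}"))
    return samples, templates


def run_segment(cfg: RunConfig) -> dict:
    """The single-command pipeline; writes artifacts, returns the report."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = []

    def say(msg):
        log.append(msg)
        if cfg.verbosity:
            print(f"[ischeseg] {msg}")

    dwi = load_volume(cfg.dwi, Modality.DWI)
    b0 = load_volume(cfg.b0, Modality.B0)
    adc = load_volume(cfg.adc, Modality.ADC)
    say(f"loaded volumes, native shape {dwi.shape}, spacing "
        f"{np.round(dwi.spacing, 2).tolist()} mm")

    if cfg.template:
        template = load_volume(cfg.template, Modality.B0, Space.IPMNI)
    else:
        from .phantomgen import make_template
        template = make_template()
    say(f"template grid {template.shape} at "
        f"{float(template.spacing[0]):g} mm")

    brain_net = None
    if cfg.brainmask_net:
        brain_net = bm.build_brainmask_net(cfg.brainmask_nf, seed=cfg.seed)
        brain_net.load(cfg.brainmask_net)
        say("brain extraction: trained network")
    else:
        say("brain extraction: intensity heuristic")

    bundle = preprocess_subject(dwi, b0, adc, template, brain_net=brain_net)
    say(f"registered (t=({bundle.transform.tx:.1f},{bundle.transform.ty:.1f},"
        f"{bundle.transform.tz:.1f}) mm, theta={bundle.transform.theta:.3f}, "
        f"s=({bundle.transform.sx:.3f},{bundle.transform.sy:.3f}))")
    say(f"DWI tissue peak {bundle.fit.tissue_mean:.1f} "
        f"(SD {bundle.fit.tissue_sd:.1f})")

    templates = load_templates(cfg.templates_npz) if cfg.templates_npz else None
    needs_templates = cfg.model in ("cfuzzy", "tscore") or \
        cfg.model.endswith("ch3")
    if needs_templates and templates is None:
        raise ValueError(f"model {cfg.model!r} needs population templates "
                         "(--templates)")

    network = None
    if cfg.model.endswith(("ch2", "ch3")):
        network = netzoo.build_network(cfg.model, seed=cfg.seed, nf=cfg.nf)
        network.load(cfg.checkpoint)
        say(f"model {cfg.model} ({netzoo.count_parameters(network):,d} "
            "parameters)")
    else:
        say(f"model {cfg.model} (classical, no checkpoint)")

    mask_s = segment_subject(bundle, cfg.model, templates=templates,
                             network=network)
    mask_native = apply_transform(mask_s, bundle.transform, dwi, inverse=True)
    vox_ml = float(np.prod(mask_native.spacing)) / 1000.0
    volume_ml = float(mask_native.data.sum()) * vox_ml
    say(f"lesion volume {volume_ml:.2f} ml "
        f"({int(mask_native.data.sum())} native voxels)")

    report = {
        "model": cfg.model,
        "seed": cfg.seed,
        "volume_ml": volume_ml,
        "stratum": em.stratify_volume(volume_ml) if volume_ml > 0 else None,
        "transform": json.loads(bundle.transform.to_json()),
        "bimodal_fit": bundle.fit.to_dict(),
        **bundle.report,
    }

    if cfg.truth:
        truth = load_volume(cfg.truth, Modality.MASK)
        brain_native = apply_transform(bundle.brain, bundle.transform, dwi,
                                       inverse=True)
        rep = em.evaluate_subject(mask_native, truth,
                                  float(np.prod(truth.spacing)),
                                  dwi=dwi, adc=adc, brain=brain_native)
        report["evaluation"] = rep.to_dict()
        say(f"vs truth: Dice {rep.dice:.3f}, precision {rep.precision:.3f}, "
            f"sensitivity {rep.sensitivity:.3f}")

    save_volume(mask_native, out_dir / "lesion_mask_native.nii.gz")
    if bundle.ismap is not None:
        save_volume(bundle.dwi.with_data(bundle.ismap.data,
                                         modality=Modality.PROB),
                    out_dir / "ismap_ipmni.nii.gz")
    (out_dir / "report.json").write_text(json.dumps(report, indent=1))
    (out_dir / "run.log").write_text("\n".join(log) + "\n")
    say(f"artifacts written to {out_dir}")
    return report
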