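"""Unsupervised lesion mapping: the c-fuzzy ischemic probability map.

Population mean/SD templates are built from lesion-free controls; a
lesioned subject is compared against them with tanh dissimilarities and
the within-subject DWI z-score gate, yielding a voxelwise ischemic
probability P_IS.
"""

import dataclasses

from ischeseg import classical_seg as cs
from ischeseg import evalmetrics as em
from ischeseg.intensity_norm import fit_bimodal, normalize_dwi
from ischeseg.phantomgen import PhantomSpec, generate_cohort, generate_subject
from ischeseg.volspace import GridSpec, Space

grid = GridSpec(shape=(64, 80, 64), spacing=(3.0, 2.8, 3.0))
base = PhantomSpec(shape=grid.shape, spacing=grid.spacing, space=Space.IPMNI)


def normalized(sub):
    fit = fit_bimodal(sub.dwi.data[sub.brain_mask.data > 0.5])
    return normalize_dwi(sub.dwi, fit)


controls = generate_cohort(10, 0, seed=11, base_spec=base)
templates = cs.build_templates([(normalized(c), c.adc) for c in controls])

subject = generate_subject(dataclasses.replace(
    base, lesion_volume_ml=10.0, kappa_dwi=4.0, kappa_adc=0.5, seed=7))
brain = subject.brain_mask.data > 0.5
ism = cs.compute_is_map(normalized(subject), subject.adc, templates,
                        brain_mask=brain)

pred = ism.data > 0.5
counts = em.confusion(pred, subject.lesion_mask.data)
dice, precision, sensitivity = em.dice_precision_sensitivity(counts)
print(f"P_IS > 0.5 voxels: {pred.sum()}  (truth: "
      f"{subject.lesion_mask.data.sum()})")
print(f"Dice = {dice:.3f}  precision = {precision:.3f}  "
      f"sensitivity = {sensitivity:.3f}")
# P_IS doubles as the optional third input channel of the networks
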