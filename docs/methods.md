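# Methods

This note records the model and procedure choices behind `ischeseg`, the
parameters that matter, what the synthetic phantoms do and do not emulate,
and the numerical decisions a maintainer would want written down.

## Geometry and spaces

All volumes travel as a 3D scalar grid plus a 4×4 voxel-to-world affine
(mm). Four spaces are distinguished: native, 1 mm isotropic, the
standardized template grid ("in-plane MNI", 192 × 224 × 192 at 1 mm), and
its stride-(2, 2, 4) phase decomposition (sixteen 96 × 112 × 48
subvolumes). The decomposition assigns phase (i, j, k) the voxels at
original coordinates (2x+i, 2y+j, 4z+k); phases are ordered
lexicographically. It is a pure re-indexing — no interpolation — so
split/stitch round trips are bit-exact, and stitched network predictions
assign each standardized-grid voxel exactly one predicted value (the
overlapping-phase predictions are interleaved, not averaged).

Resampling uses trilinear interpolation for intensity images and
nearest-neighbour for masks. Padding to the standardized shape centres the
content with the odd voxel on the high side and refuses to crop. Volumes
are reoriented to the canonical right-handed (RAS) axis order on load.

Scaled grids with the same world extent (tests and demonstrations use
64 × 80 × 64 at 3 × 2.8 × 3 mm) keep every mechanism — stride phases,
four network levels, coarse-grid masking — while staying tractable on one
CPU; problem sizes below were chosen on that basis.

## Brain extraction

A compact three-level two-channel (DWI, B0) U-Net predicts a brain
probability map on a 4 mm grid (each block: two 3³ convolutions +
batch-norm + SeLU, mirroring the main networks so there is one block
idiom in the code base). Post-processing, in order: threshold at 0.5;
binary closing with the 3³ cross (connectivity 1), OR-ed with the input
because closing is extensive but array borders would otherwise erode;
internal hole filling; nearest-neighbour upsampling to the fine grid;
dilation by one voxel; Gaussian boundary smoothing (σ = 1 voxel)
re-thresholded at 0.5 and OR-ed again so the final mask is a strict
superset of the thresholded input. The dilate-then-smooth order is a fixed
convention. A deterministic intensity heuristic (percentile threshold +
closing + largest component) is available when no trained mask network is
at hand; the pipeline accepts either.

## DWI intensity normalization

The in-brain histogram (256 equal-width bins over the 0.5–99.5 percentile
range) is fit by least squares with
f(x) = a₁ exp(−((x−b₁)/c₁)²) + a₂ exp(−((x−b₂)/c₂)²), initialized from the
two largest modes of the smoothed histogram. Note the parameterization:
c = √2 · SD, so normalization divides by σ₂ = c₂/√2 — using c directly
would silently rescale every downstream threshold. Peaks are ordered so b₂
is the higher-mean peak; if the high-mean peak is marginal (amplitude
below 20% of the other), the dominant low-mean peak is taken as tissue —
this covers near-unimodal samples and the case where a bright lesion forms
a small third mode that the fit latches onto. If the fit diverges the code
falls back, with a warning, to median/MAD statistics. The fit uses
brain-masked voxels only (the low peak is CSF, not background). ADC is not
histogram-normalized; classical methods compare it against population
templates, and network inputs are re-standardized per subvolume anyway.

## Constrained registration

B0 is registered to the template with translations (tx, ty, tz), one
rotation θ about the slice normal, and in-plane scales (sx, sy) — no
through-slice rotation exists in the parameterization, so each output
slice is a function of a single input slice (tested as an invariant).
Similarity is normalized cross-correlation evaluated inside the template
support dilated by 3 voxels: the dilation keeps the object boundary in
view (the main scale cue) while excluding the far background, whose
matching zeros would otherwise inflate the score. Optimization is
sequential Powell (translations first, then θ and log-scales) over a
multi-resolution pyramid (factors 4, 2, 1 at full scale), with bounds
±40 mm, ±0.35 rad, scales in [0.8, 1.25]; scales are optimized on the log
axis so line searches cannot cross zero. If the final NCC is below 0.2 the
registration is declared failed: a warning is raised and the identity
returned. Everything is deterministic given the inputs.

## Classical lesion mapping

Population templates are the voxelwise mean and sample SD (ddof = 1) of
normalized DWI and raw ADC across lesion-free controls; the SD is floored
at 5% of its in-brain median to prevent division blow-ups. Gaussian
smoothing is parameterized by FWHM in voxels (σ = FWHM/(2√(2 ln 2))); both
the subject image and the template mean are smoothed identically.

The t-score method flags voxels where t_dwi > σ_dwi, t_adc > σ_adc and
t_id > σ_id, with t_dwi = (I − μ)/σ against the DWI template,
t_adc = (μ − I)/σ against the ADC template (sign-flipped so the upper
threshold captures the ADC *hypo*intensity of ischemia), and t_id the
within-subject z-score of smoothed DWI over brain-masked voxels. Defaults
are the cross-validated best configuration: FWHM 4, σ_dwi 2, σ_adc 1,
σ_id 3.5.

The modified c-fuzzy method computes ΔI_s = tanh((I_s − I_{s,μ})/(α_s
I_{s,σ})), takes H2 = Δ^λ on Δ > 0 (DWI) and H1 = (−Δ)^λ on Δ < 0 (ADC),
and sets P_IS = H2_dwi · H1_adc · (1 − Q(t_id)) where t_id ≥ σ_id, else 0;
Q is implemented with the complementary error function. Defaults: FWHM 2,
α_dwi 1.5, λ_dwi 4, α_adc 0.5, λ_adc 2, σ_id 2. Both methods are verified
against brute-force per-voxel reference loops.

## Network architectures

The engine (`ischeseg.nn`) is a small reverse-mode autograd over float32
NumPy arrays: im2col + BLAS matmul 3D convolution, non-overlapping
transposed convolution, 2× max/average pooling, global pooling, dense
layers, batch normalization, SeLU/sigmoid, trilinear 2× upsampling, and
Adam with a reduce-on-plateau schedule. Gradients are validated against
finite differences, and the trilinear upsampler against its exact adjoint.

The main network has four levels with feature widths (N_f, 2N_f, 4N_f,
8N_f); every conv block is two 3³ convolutions + batch-norm + SeLU, and
initialization is LeCun-normal (the self-normalizing pairing for SeLU).
Wiring, with the open details pinned by the parameter census (the 10.7 M
budget at N_f = 32 and the 27·N_f CH3−CH2 delta acted as arbitration
between otherwise-plausible readings):

* image path: the level-1 stem encodes the raw C-channel input; levels 2–4
  re-encode (2, 2, 2) average-pooled image-path features (N_f each). This
  feature-space pyramid is what makes the CH3−CH2 parameter difference
  exactly one first-kernel slice;
* accumulated path: levels 2–4 concatenate the image-path features with
  max-pooled deeper features and encode to 2/4/8 N_f;
* dual attention gate per level: the channel gate squeezes the accumulated
  features by global average+max pooling, maps the concatenated descriptor
  through one sigmoid dense layer, and excites the channels; the spatial
  gate squeezes each input (channel max, channel mean, 1³ projection),
  excites each squeeze with a 5³ SeLU convolution (32 intermediate
  channels), sums, and calibrates with a 1³ sigmoid convolution; the gate
  output concatenates both spatially gated streams;
* decoders: level 4 takes the gate output alone; levels 1–3 concatenate it
  with the upsampled deeper decoder output (stride-2 transposed conv +
  batch-norm + SeLU);
* fuse block: per-level intraskips (chained stride-2 transposed convs down
  to N_f channels; a 1³ conv at level 1) are concatenated and fused by one
  conv block; five 3³-conv sigmoid heads (fuse + four sides) provide deep
  supervision, each side head at its native scale.
* prediction-head biases start at −2 so the initial output is mostly
  background; lesions are a sparse class and this removes the burn-in in
  which the network must first learn to silence the background.

The generic UNet (interskip concatenation, single head, trilinear-resize +
1³-conv upsampling, N_f = 44 → 10.0 M) and FCN (no skip concatenations,
light upsampling head with one 3³ refinement per octave, N_f = 50 →
10.1 M) serve as benchmarks at matched budgets.

## Training

Per head the loss is w_gds·L_gds + w_bbc·L_bbc (+ w_r·L_1 on the fused
head only), summed over the fused and four side outputs; defaults
w_gds = w_bbc = 1, w_r = 1e-5. L_gds is the generalized Dice loss over
{lesion, background} with 1/(Σg)² class weights and an ε = 1e-7 guard;
L_bbc is class-balanced cross-entropy with β = the negative-voxel
fraction, probabilities clipped to [1e-7, 1−1e-7]; L_1 is the absolute sum
of predicted voxels (a false-positive regularizer). Side-output ground
truth at level i is the (2, 2, 2) max-pooled mask, so a lesion voxel
always survives pooling.

Optimization: Adam at 3e-4, halved when the validation loss fails to
improve by more than 1e-4 for 5 consecutive epochs (floor 1e-5); batch
size 4; per subject per step one of the 16 stride-phase subvolumes drawn
uniformly; DWI and ADC channels standardized to zero mean/unit variance
within the brain mask of the subvolume (the probability channel passes
through). A seeded 20% subject split provides validation; snapshots are
kept every 10 epochs and the best validation-Dice snapshot is returned.
Fixed seeds give bit-identical trajectories.

The deployed default of 3e-4 belongs to the full-scale regime
(hundreds of subjects, 100–200 epochs, tens of thousands of steps). The
scaled-down demonstration — N_f = 4, 20 phantoms, 30 epochs ≈ 150 steps —
is roughly two orders of magnitude shorter, and no setting of the
schedule lets 3e-4 travel far enough in 150 steps; diagnostics showed
healthy gradients (a single batch overfits to Dice 0.95 in 60 steps at
3e-3). The demonstration regime therefore raises the rate to 3e-3, a
choice made from that step-budget argument and kept fixed thereafter.
Under it the toy run reaches mean full-volume training Dice ≈ 0.8–0.9 by
epoch 30.

## Inference and post-processing

The 16 subvolumes are standardized exactly as in training, forwarded, and
interleaved back. The mask is the stitched probability strictly above 0.5,
then binary closing (3³ cross, connectivity 1), then removal of 2D
connected components (8-connected within each axial slice) smaller than 5
pixels — clusters of exactly 5 survive; 5 pixels is the smallest lesion
human annotators delineate. The mask is mapped to the subject's native
grid by the inverse registration transform with nearest-neighbour
sampling, and all evaluation statistics are computed there.

## Evaluation

Dice = 2TP/(2TP+FN+FP), precision = TP/(TP+FP), sensitivity = TP/(TP+FN)
from exact voxel counts; when both masks are empty all three are defined
as 1 and such subjects are reported separately. A lesion-positive subject
counts as detected if prediction and truth overlap by ≥ 1 voxel; a
lesion-free subject counts as a false-positive detection if its prediction
is nonempty, with the number of subjects exceeding 10 false-positive
voxels reported alongside. Lesion volume strata: small < 1.7 ml ≤ medium
< 14 ml ≤ large. Contrast κ is the mean intensity in the lesion over the
mean in brain-minus-lesion, on raw intensities. Spearman correlations come
with Fisher-transform 95% intervals, tanh(atanh ρ ± 1.96/√(n−3)).

## Synthetic phantoms

Each phantom is an ellipsoidal "brain" (semi-axes ≈ 0.42 of the field of
view, jittered ±3% per subject) containing two ellipsoidal ventricles
(CSF). Intensity defaults: DWI tissue 200 / CSF 60 (so the in-brain
histogram is bimodal with a dominant tissue peak), B0 tissue 180 / CSF 260,
ADC tissue 8 / CSF 30 (units of 1e-4 mm²/s); a per-subject global gain
(±3%) mimics scanner variation. Lesions are random-orientation ellipsoids
grown inside tissue to a target volume, with intensity blended through a
smoothed profile and rescaled so the measured DWI contrast κ_DWI and ADC
contrast κ_ADC are exact before noise. Noise is Rician by default
(magnitude MRI; σ = 8 on the DWI scale, scaled proportionally for ADC).
Optional "lesion-like" artifacts are thin hyperintense shells at the
brain/background interface for false-positive testing. Cohort defaults
span the clinically typical ranges: volumes log-uniform 0.8–40 ml
(covering all three strata), κ_DWI uniform 2.3–4.5, κ_ADC 0.4–0.7; the
toy training cohort restricts to 8–40 ml and κ_DWI 3–5 (visible lesions).

What the phantoms do not emulate: real anatomy and cortical folding,
partial-volume mixtures, susceptibility and motion artifacts, multifocal
scattered lesions, or between-scanner protocol diversity. Passing tests
therefore demonstrate that the mechanisms are implemented correctly and
behave sensibly under controlled statistics — not clinical-grade accuracy;
the classical methods in particular profit from the phantoms' clean
contrast.

## Numerical choices and degenerate inputs

Decision thresholds are strict (> 0.5). Template SDs are floored; fit
divergence falls back to robust statistics; empty thresholded brain masks
are returned (with a warning) rather than raised; registration below the
similarity floor returns the identity with a warning; masks stay binary
through every resampling (nearest-neighbour); probabilities are clipped
before logs; the sigmoid clamps its preactivation so float32 exp cannot
overflow. Max-pooling gradients split ties evenly so the backward pass
conserves the incoming gradient. All stochastic components take explicit
seeds; derived seeds stay below 2³¹.

## Known limitations

The NumPy engine is single-threaded and trains small networks at small
grids only; full-scale training (N_f = 32 on the 1 mm grid) is out of its
intended range. The registration family is linear and in-plane by design —
strong oblique acquisitions would need a preliminary reorientation. The
classical methods inherit the usual template-method weakness: they compare
against a control population, so systematic acquisition differences
masquerade as abnormality. No pretrained clinical weights ship with the
package; the training loop and phantom generator produce demonstration
checkpoints instead.
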