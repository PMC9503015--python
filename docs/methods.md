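# Methods

## Problem and design

The task is binary classification of whole DBT slices — does this slice
belong to a case with microcalcification clusters (MCs) or not — without
any prior localization. Because the public reconstructed volumes the
design is based on are large and expensive to obtain, the package ships a
synthetic generator whose *stated world* mirrors the reference data's
structure: four breast-density classes at population prevalence
10/40/40/10%, full-scale per-volume slice counts 62/57/47/38, positive
cases carrying 4 clusters of 5 calcifications, and residual signal
contamination outside the breast. Every downstream stage (masking,
preprocessing arms, slice selection, patient-level cross-validation,
CNN training, ROC analysis) is the real method, exercised on that world.

## Synthetic data model

A slice is built in three layers:

- **Breast outline.** A mildly perturbed semi-ellipse touching the
  chest-wall edge, star-shaped about a point on that edge — hence a
  single connected, hole-free region. Outline extent shrinks from fatty
  to dense, mirroring the smaller reconstructed grids of denser breasts.
- **Anatomical texture.** Power-law (1/f^β) Gaussian noise added to a
  glandular mean, with β (2.2→3.1), mean intensity (0.30→0.54) and
  texture amplitude (0.05→0.14) all increasing fatty→dense; a smooth
  intensity fade over the outer ~6 px models the thinning compressed
  edge. These choices make in-mask variance strictly ordered by density
  and give the mask pipeline a genuinely ambiguous rim to recover.
- **Contamination and lesions.** Outside the breast: strictly positive
  uniform noise (0.002–0.015) plus a low-amplitude structured component —
  visible, but below the region-growing admission threshold. Lesions are
  additive soft-edged disks (defaults: 5 per cluster, diameters cycling
  3/3/2 px, contrast 0.40 above local background, cluster radius 8 px),
  clipped to [0, 1]. Cluster slice indices are drawn with replacement, so
  two clusters can share a slice, as the reference data notes.

All randomness in a cohort flows from one `CohortSpec.seed` through
spawned `SeedSequence` children; regeneration is bit-identical. What the
generator does *not* emulate: the X-ray imaging chain (quantum noise,
reconstruction artifacts, out-of-plane blur), 3-D lesion morphology
across slices, spiculated masses. A green end-to-end test therefore
establishes that the pipeline is correct and learnable on structured
textured data with ground truth — not clinical performance.

## Background suppression

`binarize → fill_holes → largest_component → region_grow`, computed on
the original image and reused for every preprocessing arm (contrast
transforms amplify contamination and would corrupt a recomputed mask).
Numerical choices: Otsu threshold by default (a fixed fraction can be
passed for degenerate inputs); 8-connected components with scan-order
tie-break; region growing admits boundary neighbors above 10% of the
initial in-mask mean, ring by ring to fixation. A constant image cannot
be thresholded: it returns an all-zeros mask with a degenerate flag
rather than raising mid-pipeline.

## Preprocessing arms

- **TV denoising** solves the ROF model min_u (λ/2)‖u−f‖² + TV(u)
  (isotropic TV, forward differences) with Chambolle's dual projection,
  step 1/4, stopping at relative change 1e-4 or 200 iterations, λ = 14.
  The unit test compares the converged solution against
  `skimage.restoration.denoise_tv_chambolle` (weight = 1/λ) to 1e-3 —
  an independent solver for the same objective.
- **CLAHE** is `skimage.exposure.equalize_adapthist` (clip limit 0.01,
  8×8 tile grid, 256 bins). Only the uniform target histogram is
  supported; the distribution parameter 0.4 is stored in the spec for
  interface fidelity but is inert under a uniform target. Constant
  images are returned unchanged by contract.
- **Squared normalization** maps to ((x−min)/(max−min))², attenuating
  background and highlighting the brightest structures (the MCs).
- Arms p3/p4 and p6 compose these in the stated orders; every arm's
  output is clipped to [0, 1] and masked.

Resizing (antialiased, nearest-neighbor for masks) happens after
preprocessing, so lesion-scale operations see the native grid; nothing
is ever resampled in z. Storage is 8-bit TIFF; the per-image mean is
subtracted at model-input time (zero-centering).

## Architectures

CNN-a is the AlexNet topology with (a) both local-response-normalization
layers replaced by batch normalization, (b) one extra 3×3 max-pool,
stride 2, padding 0, between the two adjacent grouped convolutions
(conv4/conv5), (c) single-channel input, (d) a two-way classifier. At
the full-scale 512-px input the extra pool restores the stock 6×6
pre-classifier map — the apparent purpose of the modification. Fully
connected input sizes are derived from the actual feature-map shape, so
the net also builds at desk scale; with floor-mode pooling the smallest
valid input is 131 px (the desk preset uses 132). Channel widths the
architecture description leaves unstated keep stock values; dropout
stays at 0.5.

The four references (AlexNet with LRN, GoogLeNet with batchnorm
inception blocks, ResNet18, SqueezeNet 1.1) are always randomly
initialized — the study trains from scratch, transfer learning being
ruled out by the input-size requirement.

Because no deep-learning framework is assumed, the layers run on a small
numpy reverse-mode autodiff engine (`dbtmc.nn`): im2col convolutions on
BLAS, argmax-scatter max-pool backward, standard batchnorm backward.
Every op is verified against central-difference gradients in the tests.

**Initialization.** Weights are Glorot/Xavier uniform, the default of
the MATLAB training environment the protocol comes from. This matters:
with fan-in (He) scaling the pre-classifier activations are large
(std ≈ 2.6), the effective step on the logits scales with ‖features‖²
through the 4096-wide fc stack, and SGDM at small epoch budgets diverges
and then collapses to constant predictions. Glorot keeps the activation
scale bounded and the same budgets train cleanly.

## Training and evaluation

SGD with momentum 0.9, cross-entropy plus L2 penalty 5e-3 (implemented
as weight decay on the gradient), data reshuffled every epoch, training
images augmented by a 0.5-probability left-right flip then a uniform
±20° rotation (bilinear, zero fill). No early stopping: a fixed epoch
budget. Full-scale defaults: lr 1e-3, batch 32, 200 epochs, 512-px
input. Desk preset (one CPU core, ~60-case cohorts): lr 2e-3, batch 16,
10 epochs, 132-px input — the smaller batch and larger lr compensate for
the tiny step budget; these were fixed during development on the
generator's stated world.

Evaluation is slice-level. AUC is the trapezoid over the full ROC
(ties handled by the curve construction; the suite checks exact equality
with an exhaustive pairwise-concordance oracle). Threshold metrics
default to 0.5 on the positive-class probability. Fold curves are
averaged vertically on a 101-point FPR grid. Fitted pipelines are
compared by an unpaired pooled-variance t-test on per-fold AUCs
(two-tailed; with k=3 per side this has 4 df and little power — treat
p-values as indicative). Density-stratified evaluation splits one
model's test scores by density; a subset with one class reports None.
Folds are patient-level and stratified by (density, label) — the
stratification is an addition so that desk-scale cohorts keep both
classes in every fold.

## Design choices where the design was open

- Cluster in-plane spread is a free parameter (8 px default): no spacing
  is stated for the reference lesions.
- Cohort rounding uses largest-remainder in both density counts and the
  positive split, keeping label balance within one case.
- The background mask is computed once from the original image per slice
  and reused across arms (see above).
- The flip probability is 0.5 per draw; per-image zero-centering.
- Fold-summary SD is the sample SD (ddof 1) over the three folds.

## Known limitations

Slice independence stands in for the anisotropic z-dimension; no
case-level aggregation of slice scores; the t-test at k=3 is
low-powered; CLAHE follows the skimage redistribution rather than the
MATLAB `adapthisteq` internals (same model, slightly different clipped
histogram redistribution); reference-architecture training at full
scale is possible but far outside a desktop CPU budget.
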