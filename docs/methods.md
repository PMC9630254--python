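# Methods

This note records the modelling choices behind `emseg`, the defaults and
why they were chosen, what the synthetic phantoms do and do not emulate,
and the numerical conventions a user extending the package should know.

## Problem setting and model

The task is multi-class semantic segmentation of 2-D EM slices with very
small labelled datasets (tens to a few hundred images). Volumetric stacks
are treated as independent 2-D slices; the background is a segmentation
class in its own right, so every pixel carries a label.

A *base-learner* is a U-Net whose encoder is a classification backbone
and whose decoder is fixed: five nearest-neighbour ×2 upsampling stages
with filter widths 256/128/64/32/16, each concatenating the matching-
scale encoder activation (long skip) and applying two conv3×3–BN–ReLU
blocks, then a 3×3 convolution with bias and a per-pixel softmax. Long
skips are taken at 1/16, 1/8, 1/4 and 1/2 scale (VGG additionally
contributes a full-resolution skip); the deepest encoder activation at
1/32 scale is the *bottleneck*. ResNet-family encoders use the
pre-activation residual layout with an initial unscaled batch norm on the
raw input and 1×1 projection shortcuts on the first unit of every stage;
SeResNet34 adds squeeze-excite gates (reduction 16) before each residual
addition; EfficientNet uses MBConv blocks with depthwise convolutions and
squeeze-excite (ratio 0.25 of the block's input width); InceptionV3 uses
the standard mixed blocks with scale-free batch norms.

These details are not stylistic: they are pinned by exact parameter
accounting. The configuration above reproduces the published totals for
this family of segmentation networks to the digit (ResNet34 U-Net
24 456 444; ResNet18 14 340 860; SeResNet34 24 617 640; InceptionV3
29 933 395; EfficientNet-B0 10 115 791; EfficientNet-B4 25 735 307), which
is how shortcut placement, batch-norm scales and the final 3×3 (not 1×1)
head were fixed. A narrative description elsewhere of a separate
1024-channel bottleneck convolution is arithmetically incompatible with
those totals; `build_base_learner(..., bottleneck_channels=...)` makes
such a block available but it is off by default. VGG U-Net totals could
not be reconciled with any printed figure (the published VGG numbers are
also mutually inconsistent); only the sub-30 M bound is relied upon for
VGG.

`pretrained=True` loads encoder weights from a local checkpoint only;
nothing is ever downloaded, and all tests run with random (He-normal,
seeded) initialization.

## Losses

Focal loss uses the standard hard-example form
`−α_c (1−p_t)^γ log p_t` with defaults γ = 2, α = 0.25, probabilities
clipped to [1e-7, 1−1e-7]. (The degenerate variant `−α(1−p)^γ log(1−p)`,
which is zero at p = 0, is deliberately not implemented.) Class balancing
multiplies α by mean-one inverse-pixel-frequency weights computed over the
training split. Soft dice is computed per class with smoothing 1e-6 in
numerator and denominator and averaged over the classes present in the
ground truth; the combined objective is the unweighted sum focal + dice,
non-negative and zero only at a perfect prediction.

## Training regime

Adam, initial learning rate 1e-4, mini-batch of one image (gradients are
optionally accumulated for larger batches), learning rate multiplied by
0.25 whenever validation loss fails to improve for 10 consecutive epochs,
floored at 1e-7 to avoid underflow. `max_epochs` defaults to 100 with no
early stopping; the best-validation-loss weights are checkpointed and
restored at the end. One augmentation is drawn uniformly per sample per
epoch from {identity, vertical flip, horizontal flip, transpose, random
rotate, grid distortion}; rotation draws an angle uniformly in ±90° with
reflect padding, grid distortion uses a 5×5 grid with distortion limit
0.3, and masks are always resampled nearest-neighbour so no new labels
can appear. Transpose swaps the two axes and is intended for the square
inputs the networks require (sides divisible by 32).

Model selection: learners are ranked by mean validation Jaccard across
the repeated k-fold plan (5×5 by default; the statistic is a deliberate
choice — no particular ranking statistic is canonical) and the top three
become ensemble members.

## Ensemble weight search

The fusion is a per-pixel, per-class convex combination of probability
maps (fusing probabilities rather than hard masks is what makes
fractional weights meaningful). The grid takes raw weights in
{0, 0.1, …, 1} per member, drops the all-zero vector, normalizes to sum
one and deduplicates; every one-hot and the uniform vector survive, which
guarantees the selected ensemble's search-set score is at least every
member's solo score and the equal-weight score. Scoring uses the mean
Jaccard of the fused argmax on validation images — never the hold-out
test set.

Argmax scores tie easily: once one member is sufficiently accurate, every
blend that keeps it dominant decodes identically. Ties are therefore
resolved by a cascade: (1) higher mean fused probability of the true
class (confidence) — this makes a perfect member win the full weight
outright; (2) maximal weight entropy — identical members resolve to equal
weights; (3) lexicographic order, for exact reproducibility. Reported
weights are rounded to two decimals with largest-remainder correction so
they still sum to one (a uniform triple prints as 0.34/0.33/0.33).

## Grad-CAM conventions

The class score `Y^c` for dense prediction is the spatial sum of
pre-softmax class-c logits over all output pixels (no restriction to
pixels predicted as c); filter weights are the global average of
`∂Y^c/∂A^k` over the bottleneck's Z spatial positions, and the saliency
map is the ReLU of the weighted activation sum, bilinearly resampled to
the input size and min-max normalized per map (an all-zero map is
returned as all zeros rather than divided by zero). The bottleneck is the
default target because the deepest encoder features are the most
class-informative layer of a U-Net; any node can be selected by name.
Saliency maps localize coarse regions only — at 1/32 scale a 64×64 input
yields a 2×2 map — and are not pixel-level attributions.

## Synthetic phantoms

`emseg.synthetic` draws, per sample: a large jittered cytoplasm ellipse
roughly centred in the frame, a darker nucleus ellipse constrained inside
it (regenerated up to 100 times if the geometry degenerates), and, in the
4-class configuration, 1–6 small elongated mitochondria-like ellipses on
the cytoplasm. Intensity is a per-class base level (background brightest)
plus low-pass-filtered Gaussian texture (σ = size/16, amplitude 20 grey
levels), a global contrast factor drawn in ±15 %, and additive Gaussian
noise (σ = 8 on a 0–255 scale). Defaults (64×64, 3 classes) were chosen
once as a realistic CPU-scale miniature of whole-cell EM slices: class
prevalences are strongly imbalanced (≈72/22/6 % background/cytoplasm/
nucleus), structures are nested, and contrast varies between samples.
Chromosomes are not modelled separately — at phantom fidelity they are
indistinguishable from other small dark blobs.

What the phantoms do *not* emulate: beam and section artifacts,
anisotropic noise, membrane ultrastructure, touching cells, staining
variability, or any appearance diversity between imaging modalities.
Passing phantom tests therefore demonstrates that the pipeline's
mechanics (losses, training loop, ranking, weight search, metrics,
saliency) are correct and that the ensemble effect materializes under
controlled conditions — not that any particular Jaccard level transfers
to real EM data.

`simulate_predictor` interpolates between the one-hot ground truth and a
per-pixel Dirichlet(1) simplex (the flat, maximally uninformative
choice): η = 0 is an oracle, η = 1 carries no information, and argmax
Jaccard decays monotonically in expectation. It stands in for trained
members wherever ensemble logic is tested in isolation.

## Problem sizes and numerics

The packaged experiments use 64×64 phantoms, 60-image datasets
(40 train / 8 validation / 12 held-out), three `tiny` base-learners
(~122 k parameters) and 30 epochs — sizes chosen so the full suite and
the acceptance script each complete in about a minute on one CPU while
still exhibiting the ensemble-over-members effect. Batch norm uses
momentum 0.99 and ε = 1e-3 with statistics over H×W (batch of one);
argmax ties break toward the lower class index everywhere; per-class
metrics undefined on an image (class absent from both masks) are NaN and
excluded from means rather than scored 1. Checkpoints are `.npz` archives
in parameter-construction order with a JSON sidecar (encoder, classes,
input channels, normalization).

## Known limitations

- CPU-only numpy execution: full-size encoders build and differentiate
  correctly but are impractical to *train* at realistic image sizes; the
  intended use of the big backbones here is architecture accounting,
  inference and saliency, with `tiny` carrying the training-dependent
  experiments.
- No stratification in the hold-out split; no instance separation; no 3-D
  context; no boundary-aware metrics (Hausdorff etc.).
- ImageNet weights are not bundled; transfer-learning claims are outside
  what the phantom experiments can demonstrate.
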