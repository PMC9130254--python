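# Methods

`cartiseg` implements a slice-wise deep-learning pipeline for segmenting a
thin, low-contrast cartilage shell (the embryonic nasal capsule) in large
contrast-stained µCT volumes, together with the two analyses that bracket
it: synthetic phantom generation for desk-scale validation, and local
wall-thickness measurement of the resulting binary models. This note
records the model, the conventions, and the choices made where the design
was genuinely open.

## Problem setting and model

Reconstructed µCT scans of PTA-stained embryo heads exceed 1000 voxels per
axis; a fully 3-D convolutional network at that size is memory-infeasible
and patch-based training discards the global context needed to localise
cartilage, so segmentation is performed per axial slice with a fully
convolutional encoder-decoder and the volume is assembled from the slice
predictions.

The network is a U-shaped encoder-decoder with skip connections, built
from three residual block types:

- **downsampling** blocks halve H and W: a strided 3×3 convolution pair in
  the convolutional path, 2×2 max-pooling followed by a channel-matching
  1×1 convolution in the identity path;
- **flat** blocks preserve dimensions: two 3×3 convolutions against an
  identity (or 1×1-projected) shortcut;
- **upsampling** blocks double H and W: a 2×2 stride-2 transposed
  convolution plus a 3×3 convolution against nearest-neighbour upsampling
  with a 1×1 projection.

At the reference scale the input is fixed at 1792×1280 pixels and
downsampled six times, bottoming out at 28×20 feature maps; channel width
doubles per level from a configurable base (default 16). Activations are
SELU with LeCun-normal initialisation (He-normal with ReLU in the ablation
configuration); no batch or layer normalisation is used anywhere — SELU's
self-normalizing property substitutes for it.

**Deep supervision.** Each decoder level feeds a 1×1 convolution with
sigmoid activation, upsampled (nearest-neighbour) to ground-truth
resolution. With depth 6 this yields 7 supervised outputs whose Dice
losses are combined with fixed weights, deepest to shallowest:
0.03, 0.05, 0.08, 0.12, 0.15, 0.2, 0.37 (sum 1). The shallowest
(full-resolution, weight 0.37) head is the network's output at inference;
auxiliary heads only shape gradients during training.

**Training objective.** Soft Dice loss
`1 − (2 Σ p·t + s)/(Σ p + Σ t + s)` with smoothing `s = 1e−6`, computed
per sample and averaged over the batch so slices with large foreground do
not dominate. Evaluation uses the hard Dice coefficient
`2TP/(2TP+FP+FN)`; the degenerate both-empty case is defined as 1.
Optimiser: Adam with AMSGrad, default learning rate 1e−4, batch size 4,
50 epochs; weights are returned from the epoch with the lowest validation
loss. Accuracy is assessed by sevenfold cross-validation: 14 samples
split into 7 folds, each fold training on 12 samples and validating on 2.

## Block internals (open design)

Only the block *types* are externally constrained; their internals are a
package convention: two 3×3 convolutions per convolutional path (the
U-Net/ResNet convention), "same" padding everywhere so only explicit
stride/transpose layers change dimensions (required for the 28×20
arithmetic), and a variance-preserving residual merge
`(identity + convolutional)/√2` followed by the activation. The scaling
matters in the depth-6 configuration: with a plain sum, activation
standard deviation grows roughly with the square root of the block count
and reaches ≈4 at initialisation, leaving SELU's self-normalizing regime;
with the √2 merge, pre-activations at every level stay near zero mean and
unit variance at init (property-tested).

## Numerical engine

The network and its training loop run on a compact reverse-mode automatic
differentiation engine written on NumPy (`cartiseg.nn`): convolution
(im2col + matmul, with the transposed-convolution/zero-stuffing identities
for the backward passes), 2×2 max-pooling, nearest-neighbour upsampling,
SELU/ReLU/sigmoid, channel concatenation, the soft Dice loss, and
Adam/AMSGrad. Every operation's analytic gradient is verified against
central finite differences in the test suite. All arithmetic is float32;
bitwise reproducibility is promised per platform/BLAS build, not across
them.

## Data preparation

Volumes are brought onto the fixed network grid in three recorded,
invertible steps:

1. **In-plane rescale** to a unified voxel size (default 6 µm), bilinear
   for intensities and nearest-neighbour for masks so they stay binary.
   The slice axis is never resampled; slice spacing travels as metadata.
   Resampling uses pixel-centre alignment with edge clamping.
2. **Canvas fitting**: each slice is centred on the canvas (default
   1792×1280), zero-padded if smaller, centre-cropped if larger; odd
   remainders place the extra pixel on the high side. Original voxel
   values inside the placed region are untouched.
3. **Standardization** to zero mean, unit variance, computed over the
   whole volume (not per slice) to preserve inter-slice intensity
   relations that slice-wise inference relies on.

The recorded `GridTransform` maps predictions back to the native grid;
padded border pixels can never contribute foreground after inversion.

Sparse manual annotation is emulated by `interpolate_sparse_labels`:
given every k-th slice annotated (the protocol uses k = 3), intermediate
slices are filled by voxelwise linear blending of the bracketing
annotations, thresholded at 0.5. Voxelwise blending is the deterministic,
literal reading of linear interpolation between slices; shape-based
(distance-transform) morphing is a known alternative that this package
does not implement.

## Augmentation policy

Each training slice undergoes **two consecutive transforms** drawn jointly
from a 6×6 probability matrix over {rotation, vertical flip, gamma,
elastic, scaling, none} — ordered pairs, 36 entries summing to 1. The
reference matrix factorises as the outer product of the marginals
(0.1, 0.2, 0.1, 0.3, 0.2, 0.1), e.g. P(elastic, elastic) = 0.09.
Parameter ranges: rotation ±10°, gamma exponent 0.9–1.1, scale 0.9–1.1;
continuous parameters are sampled independently per transform.

Conventions where the operating point was unspecified: geometric
transforms use bilinear sampling for the image and nearest for the mask,
zero fill outside the canvas; gamma operates on a min–max normalised copy
mapped to [0, 1] and restored afterwards (gamma on z-scored, negative
intensities is otherwise undefined); elastic deformation uses a coarse
random displacement grid (control-point spacing 128 px, max displacement
10 px) upsampled bicubically — chosen to deform at the scale of cartilage
wall undulations without tearing thin structures; scaling and rotation are
about the slice centre with the canvas size retained.

## Inference

`segment_volume` applies the preparation steps, runs every axial slice
through the network (mini-batched for throughput; numerically identical to
slice-at-a-time), thresholds the main head at 0.5 (the sigmoid decision
boundary; `p >= t` is foreground, exposed as a flag), and inverts the grid
transform. No post-processing (morphology, largest-component filtering) is
applied by default: the mask is the raw network decision.

## Wall thickness

Local thickness at a foreground voxel is the diameter of the largest
sphere fully inscribed in the foreground that contains the voxel's centre.
The implementation is the distance-transform + descending-radius
sphere-stamping scheme (Hildebrand–Rüegsegger), with redundant spheres
(provably contained in a neighbour's sphere) eliminated by an exact
integer test. Discrete convention: a sphere centred at voxel `c` has
squared radius equal to the integer squared Euclidean distance to the
nearest background voxel centre (the array boundary is not background);
it covers voxels with strictly smaller squared distance; the reported
diameter is `2R − 1` voxel widths. Under this convention an `n`-voxel slab
measures exactly `n` voxels and a digitised ball of radius `r` measures
`2r` within one voxel, and the fast path is voxel-for-voxel identical to
exhaustive sphere enumeration (the central correctness property, tested on
random volumes up to 16³). Isotropic voxels are required; anisotropic
input is rejected with an explicit error. Histograms use half-open bins
(default width 6 µm = one reference voxel); distributions are compared by
Spearman rank correlation of the count vectors.

## Synthetic phantoms

The generator emulates the structural situation the method assumes, not
the physics of X-ray imaging: a large bright soft-tissue "head" (a
randomly perturbed ellipsoid with a smooth intensity texture), a thin
curved cartilage shell obtained by eroding a deformed inner ellipsoid to a
prescribed wall thickness (default 30 µm = 5 voxels at 6 µm), an optional
planar septum of the same thickness spanning the interior cavity, Gaussian
blur for partial-volume effects (σ = 0.7 voxels) and additive Gaussian
noise (sd 0.05 in base-intensity units).

Two controls mirror the difficult cases of a realistic cohort:
`staining_quality` scales the cartilage-to-tissue contrast (1 = proper;
0.1 emulates an improperly stained sample), and `mutant_severity` removes
a fraction of the septum (underdeveloped-septum morphology, moderate to
severe). The default cohort composition is 10 control / 3 mutant /
1 poorly stained out of 14. Cartilage is rendered *darker* than the
surrounding tissue by `contrast × staining_quality` background standard
deviations (default contrast 3), a separation large enough to learn from
context but spatially confounded by the smooth texture field, so plain
global thresholding does not solve the task.

What the phantoms do **not** emulate: real anatomy (the shell is a smooth
closed surface, not a folded capsule with foramina), reconstruction
artefacts (beam hardening, rings), anisotropic resolution, or
inter-scanner intensity variation. Passing the desk-scale tests therefore
demonstrates that the pipeline's mechanics are correct and that the
architecture can learn thin-shell segmentation from limited data — not
that any particular accuracy transfers to real scans.

## Problem sizes used in the shipped tests

The test suite validates at sizes a single CPU handles in minutes, chosen
as the package's own desk-scale operating point: the learnability check
trains the depth-4, 8-filter configuration on 10 phantoms of 32 slices at
64×64 px (all slices, on-the-fly augmentation, Adam/AMSGrad at lr 3e−4
for 12 epochs — the scaled-down problem converges in fewer, larger steps
than the full-scale default of 1e−4/50) and evaluates volume Dice on 4
held-out phantoms; the thickness oracle comparison uses 50 random volumes
up to 16³; the reference-scale network is built and inspected but not
trained. The full-scale phantom preset (1792×1280 slices) exists for
integration smoke tests only.

## Known limitations

- Training on CPU via the NumPy engine is orders of magnitude slower than
  a GPU framework; the package is sized for method validation and
  desk-scale studies, not full-resolution production training.
- Voxelwise sparse-label interpolation produces stair-step artefacts for
  k > 3 on rapidly changing geometry.
- The thickness map is exact under its discrete convention but, like all
  voxel-based inscribed-sphere estimators, differs from continuum
  thickness by up to about one voxel near curved surfaces.
- Depth-axis resampling is deliberately unsupported; strongly anisotropic
  scans should be resampled upstream if isotropy is required.
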