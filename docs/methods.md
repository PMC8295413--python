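# Methods

This note records the model implemented by `condyseg`, the numerical choices
behind it, and its limitations.

## Problem

Given a stack of axial CBCT slices, measure the thickness of the cortical
shell of the mandibular condyle head everywhere on its outer surface. The
chain is: find the condyle-bearing slices, segment each of them into
background / marrow / cortical bone, extract the outer-bone and marrow
surfaces, and report the outer-to-marrow surface distance as the local
cortical thickness.

Conventions used throughout: volumes are arrays in (slice, row, column) order;
voxels are isotropic (default 0.3 mm) and corner-anchored, i.e. voxel
(i, j, k) sits at (i, j, k) × spacing in millimetres; class codes are 0 =
background, 1 = marrow, 2 = cortical.

## Networks

**Presence classifier** (`condyseg.classifier`). Four convolutions with
kernels (5, 5, 3, 3), each followed by ReLU and a kernel-3 max pool of
stride 2 (padding 1), then a single linear layer producing two logits. The
kernel sequence is fixed by design; channel widths default to (8, 16, 32, 32).
The pool stride/padding are implementation choices — kernel-3 pooling needs a
stride convention, and stride 2 with padding 1 halves the map per stage,
giving a minimum input side of 16.

The raw per-slice decisions can flicker between neighboring slices, so the
binary vector is convolved with a uniform kernel (default width 5, zero
padded) and re-thresholded at 0.5 (using ≥). A single pass can itself create
a new isolated flip (e.g. `[1,1,0,1,0,1,1]` → `[1,1,1,0,1,1,1]`), so the
filter is iterated to its fixed point; this is idempotent, reproduces the
single-pass result wherever that result is already stable, and guarantees no
isolated single-slice flips remain. `max_iter=1` recovers the plain one-pass
filter.

**Segmentation U-Net** (`condyseg.unet`). Classic contracting/expansive
layout with three modifications: every convolution uses same padding, so skip
connections concatenate without cropping and the output resolution equals the
input; batch normalization is applied before every weighted layer (the very
first convolution sees the already z-scored input and skips it); the head is
a 1×1 convolution with a pixel-wise softmax over the three classes.
Downsampling is 2×2 max pooling, upsampling a kernel-2 stride-2 transposed
convolution. Defaults: depth 4, 64 base channels, doubling per stage. A
conventional conv→BN→ReLU variant is available via `bn_position="after"`.

**Autodiff engine** (`condyseg.nn`). Both networks run on a small NumPy
reverse-mode engine (float64) implementing exactly the ops needed:
convolution, transposed convolution, max pooling, batch norm, concat,
log-softmax, and the dice / cross-entropy losses. Every operation is checked
against central finite differences to ~1e-7 in the test suite. This keeps
the package dependency-light and fully deterministic, at the cost of speed —
hence the scaled default problem sizes below.

## Losses and training

The segmentation loss is the sum of a dice loss over the flattened
probability fields,

  L_dice(p, p̂) = 1 − 2⟨p, p̂⟩ / (⟨p, p⟩ + ⟨p̂, p̂⟩),

and the mean per-pixel cross-entropy −Σ p log p̂. The classifier uses
cross-entropy alone. Optimization is Adam with betas (0.9, 0.999), learning
rate 1e-4, L2 weight decay 1e-4 and batch size 1 for 30 epochs; per-epoch
validation IoU (and classifier accuracy) select the best-epoch weights. The
U-Net trains only on condyle-bearing slices; the classifier trains on all
slices.

Evaluation uses a Monte Carlo cross-validation: the cohort (25 subjects at
full scale) is repeatedly resplit into train/validation/test arms at 18:5:2,
with every repeat retraining from scratch; per-class IoU and symmetric
Hausdorff distance (in mm, via boundary voxel point sets) are reported per
test subject and repeat.

## Phantoms

Real image data cannot ship with the package, so validation uses synthetic
subjects with exact gold labels (`condyseg.phantom`). A subject is a slice
stack containing one "condyle": an ellipsoidal marrow core wrapped by a
cortical shell whose thickness is a function of the outward surface direction
— constant, or blending linearly between a top-pole and a bottom-pole value
across hemispheres. Voxel labels are assigned from the implicit geometry;
intensities are per-class means (background 0.15, marrow 0.5, cortical 0.9)
plus Gaussian noise (default sd 0.04) and a few bright ellipsoidal
distractor blobs painted into the *intensities only*, outside a safety margin
around the phantom, so the labels stay exact while the classifier has
something to reject. `condyle_slice_fraction` sizes the core's z semi-axis so
a target fraction of slices (9% at full scale) intersects bone, and the stack
placement is seeded per subject.

What the phantom emulates: the three-tissue contrast structure, the thin
(0.9–3 mm) direction-dependent shell, the sparse condyle-bearing run inside a
long stack, and per-subject geometric variability. What it does not emulate:
real CBCT noise texture and beam-hardening artifacts, the mandibular neck and
surrounding anatomy, open or perforated shells, and inter-observer labeling
noise. Results on phantoms are therefore a validation of the machinery, not
a clinical performance claim.

## Thickness measurement

Surfaces are extracted per axial slice by Canny edge detection (σ = 1.0,
thresholds 0.1/0.4) on two binary masks — cortical∪marrow (outer bone
envelope) and marrow alone — and pooled into 3D point clouds in mm. On
\{0,1\} masks the Canny localization coincides with the morphological
boundary to within one pixel (asserted over seeded phantoms in the tests); a
`method="morphology"` alternative is provided. Thickness at an outer point
is the distance to its nearest marrow-surface point (k-d tree query), with
the realizing "foot" point recorded.

Accuracy at 0.3 mm voxels, measured on shells of known thickness 0.9–3.0 mm:
mean absolute error ≈ 0.07–0.10 mm, maximum ≈ 0.35 mm. The error is
discretization-dominated: halving the voxel size to 0.15 mm scales the pooled
mean error by ≈ 0.59 (per-geometry ratios 0.56–0.66). Thickness histograms
use 0.1 mm bins, normalized to unit area; predicted-vs-gold curves are
compared by L1 distance between densities (range [0, 2]).

## Meshing and rendering

The bone envelope (or marrow) indicator is padded by one voxel, smoothed with
a Gaussian of σ = 0.8 voxels, and meshed at the 0.5 isosurface with marching
cubes. The σ was chosen empirically: meshing the raw binary field inflates
sphere areas by ~9%, while σ = 0.8 keeps area errors within ±3% for radii
6–16 voxels and preserves the Euler characteristic 2 of closed phantom
surfaces. Each vertex takes the thickness of its nearest thickness-map
point, clamped to a fixed display range (0–6 mm) and mapped through viridis;
rendering is deterministic off-screen rasterization with a colorbar legend
whose tick values are recorded in the run metadata.

## Scaled problem sizes

The defaults mirror the full-scale design (512×512 slices, depth-4/64-channel
U-Net, 30 epochs, 25 subjects, 50 CV repeats), but a pure-NumPy engine on one
CPU cannot train that in reasonable time. The package therefore defines a
scaled configuration used by the tests, the examples and the acceptance
script: 8 subjects of 48 slices at 64×64, ~35% condyle-bearing (so the shell
still spans enough slices to resolve), shells 0.9–1.5 mm, a depth-2/8-channel
U-Net, and a 10-epoch schedule at learning rate 1e-3
(`scaled_train_config`; the rate is raised because the scaled run takes ~50×
fewer optimization steps). Under these conditions the trained pipeline
reaches marrow/cortical IoU ≈ 0.99 and perfect presence accuracy on held-out
subjects in about a minute.

## Limitations

- Phantom-only validation: no claims transfer to clinical CBCT without
  retraining and re-evaluation on real annotated data.
- The nearest-point thickness is a discrete proxy for the perpendicular
  shell thickness; on strongly curved or very thin (< 2 voxels) shells it is
  biased low by surface discretization.
- The engine is single-threaded float64 NumPy; full-scale (512×512, depth-4)
  training is functional but slow, and is not exercised by the test suite.
- Hausdorff distances are reported as NaN (with a warning) when a predicted
  class region is empty.
- Slices are processed independently (2D), matching the axial acquisition;
  no 3D context is used by the networks.
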