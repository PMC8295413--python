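# condyseg

Automated cortical thickness measurement of the mandibular condyle head from
CBCT-style axial slice stacks, using a two-stage deep-learning segmentation
followed by geometric thickness mapping and 3D visualization.

Temporomandibular disorders thin or perforate the cortical shell of the
condyle head, so the thickness of that shell is a clinically meaningful
quantity. This package implements the full measurement chain:

1. **Slice classification** — a small CNN flags which axial slices contain the
   condyle head (typically ~9% of a 512-slice stack), and a uniform-kernel
   smoothing step turns the per-slice bits into contiguous runs with no
   isolated single-slice flips.
2. **Segmentation** — a modified U-Net (same-padding convolutions, batch
   normalization before every weighted layer, softmax head) labels each
   flagged slice into background / bone marrow / cortical bone.
3. **Thickness mapping** — Canny edges of the outer-bone and marrow masks are
   pooled into 3D surface point clouds; cortical thickness at each outer point
   is the distance to the nearest marrow-surface point.
4. **Visualization** — a marching-cubes mesh of the bone envelope is
   color-coded by thickness (viridis, 0–6 mm) and rendered off-screen.

Because no patient data can ship with a library, the package includes a
**phantom generator** that synthesizes subjects with exactly known geometry —
an ellipsoidal marrow core wrapped in a cortical shell of prescribed,
direction-dependent thickness — so every stage can be validated against
analytic ground truth. Networks are built on a small, fully tested NumPy
reverse-mode autodiff engine (`condyseg.nn`); no deep-learning framework is
required.

## Quick start

```python
import numpy as np
import condyseg as cs
from condyseg.classifier import ClassifierConfig, predict_presence, smooth_presence
from condyseg.training import draw_split, scaled_train_config, train_models
from condyseg.unet import UNetConfig, segment_slices, stack_to_labelvolume

cohort = cs.make_phantom_cohort(8, n_slices=48, in_plane=(64, 64), seed=0,
                                condyle_slice_fraction=0.35,
                                thickness_range_mm=(0.9, 1.5))
split = draw_split([s.subject_id for s in cohort], (5, 2, 1), np.random.default_rng(0))
models = train_models(cohort, split, scaled_train_config(seed=0),
                      UNetConfig(depth=2, base_channels=8, input_shape=(64, 64)),
                      ClassifierConfig(input_shape=(64, 64)))

subject = {s.subject_id: s for s in cohort}[split.test_ids[0]]
presence = smooth_presence(predict_presence(models.classifier, subject.volume))
labels = stack_to_labelvolume(segment_slices(models.unet, subject.volume, presence),
                              subject.volume)
print(cs.iou(labels, subject.labels, cs.MARROW))    # 0.996
print(cs.iou(labels, subject.labels, cs.CORTICAL))  # 0.988
```

This scaled run (8 subjects, 48 slices of 64×64, 10 epochs) takes about a
minute on one CPU core and reaches marrow/cortical IoU ≈ 0.99 with perfect
presence classification on the held-out subject. The full-scale recipe
(512×512 slices, depth-4 U-Net with 64 base channels, 30 epochs, Adam with
learning rate 1e-4 and batch size 1, 50 Monte Carlo repeats at an 18:5:2
subject split) is the package default — see `condyseg.TrainConfig` and
`condyseg.UNetConfig`.

From gold (or predicted) labels, the geometric half of the chain is:

```python
from condyseg.thickness import extract_surfaces, measure_thickness, thickness_distribution
from condyseg.viz import colorize_mesh, mesh_from_labels, render_views

tm = measure_thickness(*extract_surfaces(labels))        # per-point thickness (mm)
curve = thickness_distribution(tm, bin_width_mm=0.1)     # normalized density
cmesh = colorize_mesh(mesh_from_labels(labels, "outer"), tm)
render_views(cmesh, [(20, 30), (-20, 210)], "views/")
```

On shell phantoms of known thickness (0.9–3.0 mm at 0.3 mm voxels) the mapped
thickness has a mean absolute error of about 0.09 mm, and the error roughly
halves when the voxel size is halved.

## Command line

```bash
condyseg phantom   --out cohort/ --subjects 2 --slices 64 --in-plane 64 --slice-fraction 0.3 --seed 0
condyseg train     --out run/ --epochs 10 --seed 0
condyseg segment   --input volume.nii.gz --checkpoint run/checkpoint.npz --out seg/
condyseg thickness --labels labels.nii.gz --out thick/
condyseg render    --labels labels.nii.gz --out views/
condyseg cv        --out cv/ --repeats 5 --seed 0
condyseg run       --config pipeline.yaml
```

Exit codes: 0 success, 2 validation error, 3 stage failure. Every pipeline
run writes a `manifest.json` with per-stage content hashes and timings, so
reruns are verifiably bit-identical.

## Examples

`examples/` contains one short narrative script per capability: phantom
generation, training + segmentation, thickness mapping, mesh rendering, and
Monte Carlo cross-validation. Each runs standalone in roughly a minute or
less.

## Tests

```bash
python -m pytest -q tests/
```

The suite (189 tests, ~90 s) checks every autodiff operation against central
finite differences, the metrics against brute-force references, the phantom
geometry against analytic volumes and thicknesses, and the end-to-end scaled
training run against quantitative quality floors (`tests/test_acceptance.py`).

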