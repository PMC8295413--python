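"""Train the slice classifier and U-Net on phantoms, then segment a held-out subject.

The full-scale recipe (30 epochs, learning rate 1e-4, batch size 1) targets
512x512 slices; here we use the scaled recipe (10 epochs, learning rate 1e-3)
on 64x64 phantoms so the run finishes in about a minute on one CPU core.
"""

import numpy as np

import condyseg as cs
from condyseg.classifier import ClassifierConfig, predict_presence, smooth_presence
from condyseg.training import draw_split, scaled_train_config, train_models
from condyseg.unet import UNetConfig, segment_slices, stack_to_labelvolume

cohort = cs.make_phantom_cohort(
    8, n_slices=48, in_plane=(64, 64), seed=0,
    condyle_slice_fraction=0.35, thickness_range_mm=(0.9, 1.5),
)
split = draw_split([s.subject_id for s in cohort], (5, 2, 1), np.random.default_rng(0))
models = train_models(
    cohort, split, scaled_train_config(seed=0),
    UNetConfig(depth=2, base_channels=8, input_shape=(64, 64)),
    ClassifierConfig(input_shape=(64, 64)),
)
print(models.history[["epoch", "val_iou_marrow", "val_iou_cortical",
                      "val_clf_accuracy"]].to_string(index=False))

# full inference chain on the held-out test subject
subject = {s.subject_id: s for s in cohort}[split.test_ids[0]]
presence = smooth_presence(predict_presence(models.classifier, subject.volume))
predicted = stack_to_labelvolume(
    segment_slices(models.unet, subject.volume, presence), subject.volume)

for cls, name in ((cs.MARROW, "marrow"), (cs.CORTICAL, "cortical")):
    print(f"test {name} IoU: {cs.iou(predicted, subject.labels, cls):.3f}")
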