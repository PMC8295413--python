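"""Monte Carlo cross-validation: repeated random resplits of the cohort.

Each repeat redraws a train/validation/test partition at a fixed ratio,
trains both networks from scratch and evaluates the full inference chain on
the held-out test subjects.  The full-scale design uses 25 subjects at an
18:5:2 ratio for 50 repeats; this example runs 2 repeats on a small cohort.
"""

import condyseg as cs
from condyseg.classifier import ClassifierConfig
from condyseg.pipeline import run_experiment
from condyseg.training import scaled_train_config
from condyseg.unet import UNetConfig

cohort = cs.make_phantom_cohort(
    8, n_slices=48, in_plane=(64, 64), seed=1,
    condyle_slice_fraction=0.35, thickness_range_mm=(0.9, 1.5),
)

result = run_experiment(
    cohort,
    "example_output_cv",
    ratio=(5, 2, 1),
    n_repeats=2,
    cfg=scaled_train_config(seed=1, epochs=5),
    unet_config=UNetConfig(depth=2, base_channels=8, input_shape=(64, 64)),
    clf_config=ClassifierConfig(input_shape=(64, 64)),
)

print(result.summary().to_string())
print("tables and overlay figures in example_output_cv/")
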