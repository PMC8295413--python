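"""Shared fixtures: small phantoms and one session-scoped scaled training run."""

from __future__ import annotations

import numpy as np
import pytest

import condyseg as cs
from condyseg.classifier import ClassifierConfig
from condyseg.training import draw_split, evaluate_models, scaled_train_config, train_models
from condyseg.unet import UNetConfig

# scaled conditions used for the end-to-end learning checks:
# 8 subjects, 48 axial slices of 64x64, ~35% condyle-bearing (the condyle must
# span enough slices for its shell to resolve at this height), shells 0.9-1.5 mm
SCALED = dict(
    n_subjects=8,
    n_slices=48,
    in_plane=(64, 64),
    condyle_slice_fraction=0.35,
    thickness_range_mm=(0.9, 1.5),
)


def make_scaled_cohort(seed: int = 0, n_subjects: int | None = None):
    return cs.make_phantom_cohort(
        n_subjects or SCALED["n_subjects"],
        n_slices=SCALED["n_slices"],
        in_plane=SCALED["in_plane"],
        seed=seed,
        condyle_slice_fraction=SCALED["condyle_slice_fraction"],
        thickness_range_mm=SCALED["thickness_range_mm"],
    )


@pytest.fixture(scope="session")
def shell_labels():
    """Spherical shell phantom: core radius 10 vox, shell 0.9 mm (3 vox)."""
    spec = cs.PhantomSpec(
        grid_shape=(40, 40, 40),
        core_radii_vox=(10.0, 10.0, 10.0),
        shell_thickness_fn=cs.ConstantThickness(0.9),
        noise_sd=0.0,
        distractor_count=0,
    )
    _, labels = cs.generate_condyle_phantom(spec, seed=0)
    return spec, labels


@pytest.fixture(scope="session")
def scaled_training_run():
    """Train both networks once at the scaled conditions; reused by many tests."""
    cohort = make_scaled_cohort(seed=0)
    split = draw_split(
        [s.subject_id for s in cohort], (5, 2, 1), np.random.default_rng(0)
    )
    cfg = scaled_train_config(seed=0)
    models = train_models(
        cohort,
        split,
        cfg,
        UNetConfig(depth=2, base_channels=8, input_shape=SCALED["in_plane"]),
        ClassifierConfig(input_shape=SCALED["in_plane"]),
    )
    subjects = {s.subject_id: s for s in cohort}
    test_subjects = [subjects[i] for i in split.test_ids]
    reports = evaluate_models(models, test_subjects, experiment="scaled")
    return {
        "cohort": cohort,
        "split": split,
        "models": models,
        "test_subjects": test_subjects,
        "reports": reports,
    }
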