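"""Training loops, best-epoch selection and Monte Carlo cross-validation.

Both networks are optimized with Adam (betas 0.9/0.999, weight decay 1e-4,
batch size 1, learning rate 1e-4, 30 epochs at full scale).  The U-Net sees
only condyle-bearing slices and minimizes dice + cross-entropy; the classifier
sees all axial slices and minimizes cross-entropy.  After training, the epoch
with the best validation IoU is kept.  Monte Carlo cross-validation redraws a
random subject-level split at a fixed ratio (18:5:2 at full scale) for each
repeat and evaluates IoU and Hausdorff distance on the test arm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import nn
from .classifier import (
    ClassifierConfig,
    PresenceClassifier,
    build_classifier,
    normalize_volume,
    predict_presence,
    smooth_presence,
)
from .core import CORTICAL, MARROW, ValidationError
from .metrics import MetricsReport, hausdorff_labels_mm, iou
from .nn import autograd as ag
from .phantom import PhantomSubject
from .unet import UNet, UNetConfig, build_unet, segment_slices, stack_to_labelvolume

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimizer and schedule settings (defaults are the full-scale recipe)."""

    optimizer: str = "adam"
    betas: tuple[float, float] = (0.9, 0.999)
    weight_decay: float = 1e-4
    learning_rate: float = 1e-4
    batch_size: int = 1
    epochs: int = 30
    seed: int = 0
    best_metric: str = "mean"  # "mean" | "marrow" | "cortical"

    def validate(self) -> None:
        if self.optimizer != "adam":
            raise ValidationError("optimizer: only 'adam' is supported")
        if not all(0 < b < 1 for b in self.betas):
            raise ValidationError("betas: must lie in (0, 1)")
        if min(self.learning_rate, self.batch_size, self.epochs) <= 0:
            raise ValidationError("learning_rate/batch_size/epochs: must be positive")
        if self.weight_decay < 0:
            raise ValidationError("weight_decay: must be nonnegative")


def scaled_train_config(**overrides) -> TrainConfig:
    """A short-schedule recipe for small phantoms: 10 epochs at lr 1e-3.

    The learning rate is raised because the scaled runs take roughly 50x fewer
    optimization steps than the full schedule.
    """
    cfg = TrainConfig(epochs=10, learning_rate=1e-3)
    return replace(cfg, **overrides)


@dataclass
class SplitSpec:
    """Subject-level split; arms must be disjoint."""

    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    def validate(self) -> None:
        arms = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        for i in range(3):
            for j in range(i + 1, 3):
                leak = arms[i] & arms[j]
                if leak:
                    raise ValidationError(f"subject leakage across arms: {sorted(leak)}")

    def signature(self) -> tuple:
        return (tuple(sorted(self.train_ids)), tuple(sorted(self.val_ids)),
                tuple(sorted(self.test_ids)))


def draw_split(subject_ids, ratio: tuple[int, int, int] = (18, 5, 2),
               rng: np.random.Generator | None = None) -> SplitSpec:
    """Randomly partition subjects into train/val/test arms at a fixed ratio."""
    ids = list(subject_ids)
    if sum(ratio) > len(ids):
        raise ValidationError(
            f"ratio {ratio} needs {sum(ratio)} subjects but only {len(ids)} are available"
        )
    rng = rng or np.random.default_rng()
    perm = rng.permutation(len(ids))
    n_tr, n_va, n_te = ratio
    pick = [ids[i] for i in perm[: n_tr + n_va + n_te]]
    split = SplitSpec(tuple(pick[:n_tr]), tuple(pick[n_tr:n_tr + n_va]),
                      tuple(pick[n_tr + n_va:]))
    split.validate()
    return split


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _one_hot(labels2d: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((1, n_classes) + labels2d.shape)
    for c in range(n_classes):
        out[0, c] = labels2d == c
    return out


@dataclass
class TrainedModels:
    unet: UNet
    classifier: PresenceClassifier
    history: pd.DataFrame
    best_unet_epoch: int
    best_classifier_epoch: int
    n_unet_train_slices: int = 0
    n_classifier_train_slices: int = 0


def _subject_map(dataset: list[PhantomSubject]) -> dict[str, PhantomSubject]:
    return {s.subject_id: s for s in dataset}


def _unet_val_iou(model: UNet, subjects: list[PhantomSubject]) -> tuple[float, float]:
    """Mean marrow/cortical IoU over validation subjects, gold-presence gated."""
    ious_m, ious_c = [], []
    for s in subjects:
        result = segment_slices(model, s.volume, s.presence)
        pred = stack_to_labelvolume(result, s.volume)
        ious_m.append(iou(pred, s.labels, MARROW))
        ious_c.append(iou(pred, s.labels, CORTICAL))
    return float(np.mean(ious_m)), float(np.mean(ious_c))


def _classifier_val_acc(model: PresenceClassifier, subjects: list[PhantomSubject]) -> float:
    accs = []
    for s in subjects:
        pred = predict_presence(model, s.volume)
        accs.append(np.mean(pred.values == s.presence.values))
    return float(np.mean(accs))


def select_best_epoch(history, metric_column: str = "val_iou_mean") -> int:
    """1-based index of the epoch with the best validation metric.

    Ties break toward the earliest epoch (numpy argmax returns the first
    maximal entry).
    """
    values = np.asarray(
        history[metric_column] if isinstance(history, pd.DataFrame) else history,
        dtype=np.float64,
    )
    if values.size == 0:
        raise ValidationError("history: empty")
    return int(np.argmax(values)) + 1


def train_models(
    dataset: list[PhantomSubject],
    split: SplitSpec,
    cfg: TrainConfig,
    unet_config: UNetConfig | None = None,
    clf_config: ClassifierConfig | None = None,
) -> TrainedModels:
    """Train the U-Net (condyle slices only) and the classifier (all slices).

    Per-epoch validation IoU / accuracy is recorded; the returned models carry
    the weights of their best validation epoch.
    """
    cfg.validate()
    split.validate()
    subjects = _subject_map(dataset)
    train = [subjects[i] for i in split.train_ids]
    val = [subjects[i] for i in split.val_ids]
    in_plane = tuple(train[0].volume.shape[1:])

    unet_config = unet_config or UNetConfig(input_shape=in_plane)
    clf_config = clf_config or ClassifierConfig(input_shape=in_plane)
    rng = np.random.default_rng(cfg.seed)
    unet = build_unet(unet_config, seed=int(rng.integers(0, 2**31 - 1)))
    clf = build_classifier(clf_config, seed=int(rng.integers(0, 2**31 - 1)))

    # pre-normalized slice pools
    unet_pool: list[tuple[np.ndarray, np.ndarray]] = []  # (slice, onehot)
    clf_pool: list[tuple[np.ndarray, int]] = []
    for s in train:
        x = normalize_volume(s.volume)
        for z in range(s.volume.n_slices):
            bit = int(s.presence.values[z])
            clf_pool.append((x[z], bit))
            if bit:
                unet_pool.append((x[z], _one_hot(s.labels.labels[z], unet_config.n_classes)))
    logger.info(
        "training pools: %d condyle slices (U-Net), %d slices (classifier)",
        len(unet_pool), len(clf_pool),
    )

    opt_u = nn.Adam(unet.parameters(), lr=cfg.learning_rate, betas=cfg.betas,
                    weight_decay=cfg.weight_decay)
    opt_c = nn.Adam(clf.parameters(), lr=cfg.learning_rate, betas=cfg.betas,
                    weight_decay=cfg.weight_decay)

    rows = []
    best_u, best_c = -np.inf, -np.inf
    best_u_state, best_c_state = None, None
    best_u_epoch = best_c_epoch = 1
    metric_key = {"mean": "val_iou_mean", "marrow": "val_iou_marrow",
                  "cortical": "val_iou_cortical"}[cfg.best_metric]

    for epoch in range(1, cfg.epochs + 1):
        unet.train()
        order = rng.permutation(len(unet_pool))
        u_losses = []
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            xb = np.stack([unet_pool[i][0] for i in idx])[:, None]
            tb = np.concatenate([unet_pool[i][1] for i in idx], axis=0)
            logits = unet.forward_logits(nn.Tensor(xb))
            logp = ag.log_softmax(logits, axis=1)
            probs = ag.softmax(logits, axis=1)
            loss = ag.add(ag.dice_loss_op(probs, tb), ag.nll_loss(logp, tb))
            opt_u.zero_grad()
            loss.backward()
            opt_u.step()
            u_losses.append(float(loss.data))

        clf.train()
        order = rng.permutation(len(clf_pool))
        c_losses = []
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            xb = np.stack([clf_pool[i][0] for i in idx])[:, None]
            tb = np.zeros((len(idx), 2))
            for r, i in enumerate(idx):
                tb[r, clf_pool[i][1]] = 1.0
            logits = clf(nn.Tensor(xb))
            loss = ag.nll_loss(ag.log_softmax(logits, axis=1), tb)
            opt_c.zero_grad()
            loss.backward()
            opt_c.step()
            c_losses.append(float(loss.data))

        iou_m, iou_c = _unet_val_iou(unet.eval(), val)
        acc = _classifier_val_acc(clf.eval(), val)
        row = {
            "epoch": epoch,
            "unet_train_loss": float(np.mean(u_losses)) if u_losses else np.nan,
            "clf_train_loss": float(np.mean(c_losses)) if c_losses else np.nan,
            "val_iou_marrow": iou_m,
            "val_iou_cortical": iou_c,
            "val_iou_mean": (iou_m + iou_c) / 2.0,
            "val_clf_accuracy": acc,
        }
        rows.append(row)
        logger.info(
            "epoch %d: unet loss %.4f, val IoU m/c %.3f/%.3f, clf acc %.3f",
            epoch, row["unet_train_loss"], iou_m, iou_c, acc,
        )
        if row[metric_key] > best_u:
            best_u, best_u_state, best_u_epoch = row[metric_key], unet.state_arrays(), epoch
        if acc > best_c:
            best_c, best_c_state, best_c_epoch = acc, clf.state_arrays(), epoch

    unet.load_state_arrays(best_u_state)
    clf.load_state_arrays(best_c_state)
    history = pd.DataFrame(rows)
    return TrainedModels(unet.eval(), clf.eval(), history, best_u_epoch, best_c_epoch,
                         n_unet_train_slices=len(unet_pool),
                         n_classifier_train_slices=len(clf_pool))


# ---------------------------------------------------------------------------
# evaluation and Monte Carlo cross-validation
# ---------------------------------------------------------------------------

def evaluate_models(
    models: TrainedModels,
    subjects: list[PhantomSubject],
    experiment: str = "eval",
    presence_kernel_width: int = 5,
    presence_threshold: float = 0.5,
) -> list[MetricsReport]:
    """Full-pipeline evaluation (classifier -> smoothing -> U-Net) per subject."""
    reports = []
    for s in subjects:
        presence = smooth_presence(
            predict_presence(models.classifier, s.volume),
            kernel_width=presence_kernel_width, threshold=presence_threshold,
        )
        pred = stack_to_labelvolume(segment_slices(models.unet, s.volume, presence), s.volume)
        hd = {}
        for cls, name in ((MARROW, "marrow"), (CORTICAL, "cortical")):
            try:
                hd[name] = hausdorff_labels_mm(pred, s.labels, cls, s.labels.voxel_spacing_mm)
            except ValidationError:
                logger.warning("%s: empty %s region; Hausdorff recorded as NaN",
                               s.subject_id, name)
                hd[name] = np.nan
        reports.append(MetricsReport(
            experiment=experiment,
            subject=s.subject_id,
            iou_marrow=iou(pred, s.labels, MARROW),
            iou_cortical=iou(pred, s.labels, CORTICAL),
            hausdorff_marrow_mm=hd["marrow"],
            hausdorff_cortical_mm=hd["cortical"],
        ))
    return reports


@dataclass
class CVResult:
    """Outcome of a Monte Carlo cross-validation run."""

    reports: list[MetricsReport]
    splits: list[SplitSpec]
    selected_epochs: list[int]
    seeds: list[int]
    histories: list[pd.DataFrame] = field(default_factory=list)
    last_models: "TrainedModels | None" = None

    def frame(self) -> pd.DataFrame:
        rows = []
        for i, split in enumerate(self.splits):
            for r in self.reports:
                if r.experiment == f"repeat{i:03d}":
                    for cls in ("marrow", "cortical"):
                        rows.append({
                            "repeat": i,
                            "subject": r.subject,
                            "class": cls,
                            "iou": getattr(r, f"iou_{cls}"),
                            "hausdorff_mm": getattr(r, f"hausdorff_{cls}_mm"),
                        })
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        f = self.frame()
        return f.groupby("class")[["iou", "hausdorff_mm"]].agg(["mean", "std"])


def plan_cv_splits(
    subject_ids,
    ratio: tuple[int, int, int] = (18, 5, 2),
    n_repeats: int = 50,
    seed: int = 0,
) -> list[SplitSpec]:
    """Draw the per-repeat random splits (the resampling backbone of the CV).

    Each repeat uses an independent seeded generator (``seed + repeat``);
    duplicate split signatures are logged but kept, as redraws are part of the
    random design.
    """
    splits = []
    seen = set()
    for i in range(n_repeats):
        split = draw_split(subject_ids, ratio, np.random.default_rng(seed + i))
        sig = split.signature()
        if sig in seen:
            logger.warning("repeat %d drew a duplicate split signature", i)
        seen.add(sig)
        splits.append(split)
    return splits


def monte_carlo_cv(
    dataset: list[PhantomSubject],
    ratio: tuple[int, int, int] = (18, 5, 2),
    n_repeats: int = 50,
    cfg: TrainConfig | None = None,
    unet_config: UNetConfig | None = None,
    clf_config: ClassifierConfig | None = None,
) -> CVResult:
    """Repeatedly resplit, train and evaluate on the held-out test arm."""
    cfg = cfg or TrainConfig()
    ids = [s.subject_id for s in dataset]
    splits = plan_cv_splits(ids, ratio, n_repeats, seed=cfg.seed)
    subjects = _subject_map(dataset)
    reports: list[MetricsReport] = []
    epochs, seeds, histories = [], [], []
    models = None
    for i, split in enumerate(splits):
        repeat_seed = cfg.seed + i
        repeat_cfg = replace(cfg, seed=repeat_seed)
        models = train_models(dataset, split, repeat_cfg, unet_config, clf_config)
        test_subjects = [subjects[j] for j in split.test_ids]
        for r in evaluate_models(models, test_subjects, experiment=f"repeat{i:03d}"):
            reports.append(r)
        epochs.append(models.best_unet_epoch)
        seeds.append(repeat_seed)
        histories.append(models.history)
        logger.info("repeat %d done (best epoch %d)", i, models.best_unet_epoch)
    return CVResult(reports, splits, epochs, seeds, histories, last_models=models)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_models(models: TrainedModels, path) -> None:
    """Persist both networks (weights + configs) as a single .npz checkpoint."""
    import json
    from dataclasses import asdict

    state = {}
    for prefix, mod in (("unet.", models.unet), ("clf.", models.classifier)):
        for k, v in mod.state_arrays().items():
            state[prefix + k] = v
    meta = {
        "unet_config": asdict(models.unet.config),
        "clf_config": asdict(models.classifier.config),
        "best_unet_epoch": models.best_unet_epoch,
        "best_classifier_epoch": models.best_classifier_epoch,
    }
    np.savez_compressed(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_models(path) -> TrainedModels:
    """Restore a checkpoint written by :func:`save_models`."""
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        ucfg = UNetConfig(**{k: tuple(v) if isinstance(v, list) else v
                             for k, v in meta["unet_config"].items()})
        ccfg = ClassifierConfig(**{k: tuple(v) if isinstance(v, list) else v
                                   for k, v in meta["clf_config"].items()})
        unet = build_unet(ucfg, seed=0)
        clf = build_classifier(ccfg, seed=0)
        unet.load_state_arrays({k[len("unet."):]: data[k] for k in data.files
                                if k.startswith("unet.")})
        clf.load_state_arrays({k[len("clf."):]: data[k] for k in data.files
                               if k.startswith("clf.")})
    return TrainedModels(unet.eval(), clf.eval(), pd.DataFrame(),
                         meta["best_unet_epoch"], meta["best_classifier_epoch"])
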