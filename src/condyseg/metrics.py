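"""Training objectives and segmentation evaluation metrics.

The dice loss is the vector form ``1 - 2<p, q> / (<p, p> + <q, q>)`` over the
flattened one-hot gold field ``p`` and predicted probability field ``q``; the
combined training objective adds the cross-entropy.  Evaluation uses the
intersection-over-union per tissue class and the symmetric Hausdorff distance
between boundary point sets, reported in millimetres.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion
from scipy.spatial import cKDTree

from .core import LabelVolume, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def dice_loss(p, p_hat, smooth: bool = False, eps: float = 1e-6) -> float:
    """Dice loss ``1 - 2(p . p_hat) / (p . p + p_hat . p_hat)`` on flat vectors.

    Inputs of any shape are flattened; entries must be nonnegative.  With both
    vectors all-zero the loss is undefined and raises unless ``smooth`` is on,
    in which case ``eps`` is added to numerator and denominator.
    """
    p = np.asarray(p, dtype=np.float64).ravel()
    q = np.asarray(p_hat, dtype=np.float64).ravel()
    if p.shape != q.shape:
        raise ValidationError("dice_loss: inputs differ in length")
    if np.any(p < 0) or np.any(q < 0):
        raise ValidationError("dice_loss: negative entries")
    num = 2.0 * np.dot(p, q)
    den = np.dot(p, p) + np.dot(q, q)
    if den == 0.0:
        if not smooth:
            raise ValidationError("dice_loss: both inputs are all-zero (undefined)")
        return 1.0 - (num + eps) / (den + eps)
    if smooth:
        return 1.0 - (num + eps) / (den + eps)
    return 1.0 - num / den


def cross_entropy(p, p_hat, class_axis: int | None = None, clamp: float = 1e-12) -> float:
    """Cross-entropy ``-sum p log p_hat``, averaged over pixels.

    For 1D inputs the whole vector is one categorical distribution.  For
    multidimensional fields, ``class_axis`` (default 0) indexes the class
    dimension and the per-pixel cross-entropies are averaged.  Zeros in
    ``p_hat`` where ``p`` is positive are clamped to ``clamp`` and logged.
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(p_hat, dtype=np.float64)
    if p.shape != q.shape:
        raise ValidationError("cross_entropy: shape mismatch")
    if np.any((q <= 0) & (p > 0)):
        logger.warning("cross_entropy: clamping log of zero probabilities to log(%g)", clamp)
    q = np.clip(q, clamp, None)
    if p.ndim <= 1:
        return float(-np.sum(p * np.log(q)))
    axis = 0 if class_axis is None else class_axis
    per_pixel = -np.sum(p * np.log(q), axis=axis)
    return float(np.mean(per_pixel))


def combined_loss(p, p_hat, class_axis: int | None = None) -> float:
    """Sum of the dice loss and the cross-entropy (the training objective)."""
    return dice_loss(p, p_hat) + cross_entropy(p, p_hat, class_axis=class_axis)


# ---------------------------------------------------------------------------
# evaluation metrics
# ---------------------------------------------------------------------------

def _labels_array(x) -> np.ndarray:
    return x.labels if isinstance(x, LabelVolume) else np.asarray(x)


def iou(pred, gold, class_id: int) -> float:
    """Intersection over union of one class between two label volumes.

    If the class is empty in both volumes the IoU is 1 by convention (logged).
    """
    a = _labels_array(pred) == class_id
    b = _labels_array(gold) == class_id
    if a.shape != b.shape:
        raise ValidationError("iou: shape mismatch between prediction and gold")
    union = np.logical_or(a, b).sum()
    if union == 0:
        logger.info("iou: class %d empty in both volumes; returning 1.0", class_id)
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def hausdorff_mm(a_points, b_points, spacing_mm: float) -> float:
    """Symmetric Hausdorff distance between voxel point sets, in millimetres.

    ``max(sup_a inf_b d, sup_b inf_a d)`` with Euclidean distance on voxel
    coordinates scaled by the isotropic spacing; accelerated with KD-trees.
    """
    a = np.atleast_2d(np.asarray(a_points, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b_points, dtype=np.float64))
    if a.size == 0:
        raise ValidationError("hausdorff_mm: first point set is empty")
    if b.size == 0:
        raise ValidationError("hausdorff_mm: second point set is empty")
    d_ab = cKDTree(b).query(a)[0].max()
    d_ba = cKDTree(a).query(b)[0].max()
    return float(max(d_ab, d_ba) * spacing_mm)


def boundary_points(labels, class_id: int) -> np.ndarray:
    """Voxel coordinates of the morphological boundary of one class region."""
    mask = _labels_array(labels) == class_id
    if not mask.any():
        raise ValidationError(f"boundary_points: class {class_id} is empty")
    interior = binary_erosion(mask)
    return np.argwhere(mask & ~interior)


def hausdorff_labels_mm(pred, gold, class_id: int, spacing_mm: float) -> float:
    """Hausdorff distance between the class boundaries of two label volumes."""
    return hausdorff_mm(
        boundary_points(pred, class_id), boundary_points(gold, class_id), spacing_mm
    )


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Per-(experiment, subject) segmentation quality summary."""

    experiment: str
    subject: str
    iou_marrow: float
    iou_cortical: float
    hausdorff_marrow_mm: float
    hausdorff_cortical_mm: float

    def __post_init__(self) -> None:
        for name in ("iou_marrow", "iou_cortical"):
            v = getattr(self, name)
            if not (np.isnan(v) or 0.0 <= v <= 1.0):
                raise ValidationError(f"{name}: value {v} outside [0, 1]")
        for name in ("hausdorff_marrow_mm", "hausdorff_cortical_mm"):
            v = getattr(self, name)
            if not (np.isnan(v) or v >= 0.0):
                raise ValidationError(f"{name}: negative distance")


def reports_to_frame(reports: list[MetricsReport]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in reports])


def write_reports(reports: list[MetricsReport], csv_path=None, json_path=None) -> None:
    frame = reports_to_frame(reports)
    if csv_path is not None:
        frame.to_csv(csv_path, index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump([asdict(r) for r in reports], fh, indent=2)
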