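"""Core in-memory containers shared by every stage of the pipeline.

A CBCT acquisition is represented as a stack of axial slices: axis 0 is the
slice (acquisition) axis, axes 1 and 2 are image rows and columns.  Physical
coordinates are corner-anchored: voxel ``(i, j, k)`` sits at
``(i, j, k) * voxel_spacing_mm`` millimetres.  The label alphabet is fixed to
the three tissue classes used throughout: 0 = background, 1 = marrow bone,
2 = cortical bone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: label codes
BACKGROUND, MARROW, CORTICAL = 0, 1, 2
LABEL_NAMES = {BACKGROUND: "background", MARROW: "marrow", CORTICAL: "cortical"}


class ValidationError(ValueError):
    """Raised when a container or parameter set violates its invariants."""


@dataclass
class Volume:
    """A 3D scalar image: ``intensities[slice, row, col]`` with isotropic spacing."""

    intensities: np.ndarray
    voxel_spacing_mm: float = 0.3

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ValidationError("intensities: expected a 3D array")
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError("intensities: non-finite values present")
        if not (self.voxel_spacing_mm > 0):
            raise ValidationError("voxel_spacing_mm: must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def n_slices(self) -> int:
        return self.intensities.shape[0]


@dataclass
class LabelVolume:
    """Per-voxel class map over {background, marrow, cortical}."""

    labels: np.ndarray
    voxel_spacing_mm: float = 0.3

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError("labels: expected a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if np.any(self.labels != np.round(self.labels)):
                raise ValidationError("labels: non-integer values present")
            self.labels = self.labels.astype(np.uint8)
        bad = np.setdiff1d(np.unique(self.labels), [BACKGROUND, MARROW, CORTICAL])
        if bad.size:
            raise ValidationError(f"labels: values outside {{0,1,2}}: {bad.tolist()}")
        self.labels = self.labels.astype(np.uint8)
        if not (self.voxel_spacing_mm > 0):
            raise ValidationError("voxel_spacing_mm: must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def class_mask(self, class_id: int) -> np.ndarray:
        return self.labels == class_id

    def slice_has_object(self) -> np.ndarray:
        """Boolean per slice: does the slice contain any non-background label?"""
        return (self.labels != BACKGROUND).any(axis=(1, 2))


@dataclass
class PresenceVector:
    """Per-slice binary indicator of condyle presence, with optional soft scores."""

    values: np.ndarray
    scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        bad = np.setdiff1d(np.unique(self.values), [0, 1])
        if self.values.ndim != 1 or bad.size:
            raise ValidationError("values: expected a 1D binary vector")
        self.values = self.values.astype(np.uint8)
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=np.float64)
            if self.scores.shape != self.values.shape:
                raise ValidationError("scores: shape must match values")

    def __len__(self) -> int:
        return len(self.values)

    def runs(self) -> list[tuple[int, int]]:
        """Contiguous runs of ones as (start, stop) half-open index pairs."""
        v = np.concatenate([[0], self.values, [0]])
        d = np.diff(v.astype(np.int8))
        starts = np.flatnonzero(d == 1)
        stops = np.flatnonzero(d == -1)
        return list(zip(starts.tolist(), stops.tolist()))


@dataclass
class SurfacePointSet:
    """Surface sample points in millimetres with their anatomical role."""

    points_mm: np.ndarray
    role: str  # "outer-cortical" | "marrow"

    def __post_init__(self) -> None:
        self.points_mm = np.atleast_2d(np.asarray(self.points_mm, dtype=np.float64))
        if self.points_mm.ndim != 2 or self.points_mm.shape[1] != 3:
            raise ValidationError("points_mm: expected an (N, 3) array")
        if self.role not in ("outer-cortical", "marrow"):
            raise ValidationError(f"role: unknown role {self.role!r}")

    def __len__(self) -> int:
        return len(self.points_mm)


@dataclass
class ThicknessMap:
    """Cortical thickness sampled on the outer surface.

    For every outer-surface point, ``thickness_mm`` is the Euclidean distance to
    its nearest marrow-surface point and ``foot_mm`` is that marrow point.
    """

    points_mm: np.ndarray
    thickness_mm: np.ndarray
    foot_mm: np.ndarray

    def __post_init__(self) -> None:
        self.points_mm = np.asarray(self.points_mm, dtype=np.float64)
        self.thickness_mm = np.asarray(self.thickness_mm, dtype=np.float64)
        self.foot_mm = np.asarray(self.foot_mm, dtype=np.float64)
        n = len(self.points_mm)
        if self.thickness_mm.shape != (n,) or self.foot_mm.shape != (n, 3):
            raise ValidationError("thickness/foot arrays inconsistent with points")
        if np.any(self.thickness_mm < 0):
            raise ValidationError("thickness_mm: negative thickness")

    def __len__(self) -> int:
        return len(self.points_mm)


@dataclass
class DistributionCurve:
    """A binned probability density of thickness values (integrates to 1)."""

    bin_centers_mm: np.ndarray
    density: np.ndarray
    bin_width_mm: float = field(default=0.1)

    def __post_init__(self) -> None:
        self.bin_centers_mm = np.asarray(self.bin_centers_mm, dtype=np.float64)
        self.density = np.asarray(self.density, dtype=np.float64)
        if self.bin_centers_mm.shape != self.density.shape:
            raise ValidationError("bin centers and density differ in length")
        if not (self.bin_width_mm > 0):
            raise ValidationError("bin_width_mm: must be positive")
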