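"""Synthetic condyle-head phantoms with analytically known cortical thickness.

The phantom is a marrow ellipsoid wrapped in a cortical shell whose thickness
varies with the outward radial direction from the core centre, so every outer
surface point has a closed-form ground-truth thickness.  Around the condyle,
bone-like "distractor" blobs are painted into the intensities (but never into
the labels) to emulate the surrounding anatomy that confuses purely
intensity-based segmentation.  Intensities live in [0, 1]; the default voxel
spacing of 0.3 mm matches a typical dental CBCT protocol.

At full scale a subject is a stack of 512 axial slices of which roughly 9%
intersect the condyle head; both numbers are the generator defaults and can be
scaled down for fast experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .core import (
    BACKGROUND,
    CORTICAL,
    MARROW,
    LabelVolume,
    PresenceVector,
    ValidationError,
    Volume,
)

logger = logging.getLogger(__name__)

# class mean intensities (arbitrary calibration, [0, 1] scale)
BACKGROUND_MEAN = 0.15
MARROW_MEAN = 0.50
CORTICAL_MEAN = 0.90
DISTRACTOR_MEAN = 0.80


# ---------------------------------------------------------------------------
# shell thickness fields
# ---------------------------------------------------------------------------

class ConstantThickness:
    """Shell thickness independent of direction."""

    def __init__(self, thickness_mm: float):
        if thickness_mm <= 0:
            raise ValidationError("shell_thickness_fn: thickness must be positive")
        self.thickness_mm = float(thickness_mm)
        self.bounds_mm = (self.thickness_mm, self.thickness_mm)

    def __call__(self, directions: np.ndarray) -> np.ndarray:
        directions = np.asarray(directions, dtype=np.float64)
        return np.full(directions.shape[:-1], self.thickness_mm)


class HemisphericThickness:
    """Thickness blending linearly in the slice-axis direction component.

    ``t(u) = t_bottom + (t_top - t_bottom) * (1 + u_z) / 2`` where ``u_z`` is
    the component of the unit direction along axis 0 (the slice axis).  The
    value is ``t_top`` at the +z pole, ``t_bottom`` at the -z pole and the
    midpoint of the two on the equator.
    """

    def __init__(self, t_top_mm: float, t_bottom_mm: float):
        if t_top_mm <= 0 or t_bottom_mm <= 0:
            raise ValidationError("shell_thickness_fn: thicknesses must be positive")
        self.t_top_mm = float(t_top_mm)
        self.t_bottom_mm = float(t_bottom_mm)
        lo, hi = sorted((self.t_top_mm, self.t_bottom_mm))
        self.bounds_mm = (lo, hi)

    def __call__(self, directions: np.ndarray) -> np.ndarray:
        directions = np.asarray(directions, dtype=np.float64)
        uz = directions[..., 0]
        return self.t_bottom_mm + (self.t_top_mm - self.t_bottom_mm) * (1.0 + uz) / 2.0


# ---------------------------------------------------------------------------
# phantom specification
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Geometry, intensity and noise parameters of one synthetic condyle.

    ``condyle_slice_fraction``, when set, overrides the slice-axis semi-axis of
    the marrow core so that the phantom (core plus shell) spans that fraction
    of the grid's slices.  Set it to ``None`` to use ``core_radii_vox[0]``
    verbatim.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing_mm: float = 0.3
    core_center_vox: tuple[float, float, float] | None = None
    core_radii_vox: tuple[float, float, float] = (10.0, 14.0, 14.0)
    shell_thickness_fn: Callable[[np.ndarray], np.ndarray] = field(
        default_factory=lambda: ConstantThickness(1.5)
    )
    noise_sd: float = 0.04
    distractor_count: int = 3
    condyle_slice_fraction: float | None = None

    # -- derived helpers ----------------------------------------------------

    def thickness_bounds_mm(self) -> tuple[float, float]:
        fn = self.shell_thickness_fn
        if hasattr(fn, "bounds_mm"):
            return fn.bounds_mm
        # probe a direction sample for unknown callables
        rng = np.random.default_rng(0)
        u = rng.normal(size=(512, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        t = np.asarray(fn(u), dtype=np.float64)
        return float(t.min()), float(t.max())

    def center(self) -> np.ndarray:
        if self.core_center_vox is not None:
            return np.asarray(self.core_center_vox, dtype=np.float64)
        return (np.asarray(self.grid_shape, dtype=np.float64) - 1.0) / 2.0

    def resolved_radii(self) -> np.ndarray:
        """Core semi-axes with the slice axis adjusted to the target fraction."""
        radii = np.asarray(self.core_radii_vox, dtype=np.float64).copy()
        if self.condyle_slice_fraction is not None:
            extent = self.condyle_slice_fraction * self.grid_shape[0]
            fn = self.shell_thickness_fn
            t_up = float(np.asarray(fn(np.array([1.0, 0.0, 0.0]))))
            t_dn = float(np.asarray(fn(np.array([-1.0, 0.0, 0.0]))))
            rz = (extent - (t_up + t_dn) / self.voxel_spacing_mm) / 2.0
            if rz <= 0:
                raise ValidationError(
                    "condyle_slice_fraction: too small for the shell thickness "
                    f"(implied core z semi-axis {rz:.2f} vox)"
                )
            radii[0] = rz
        return radii

    def validate(self) -> None:
        shape = np.asarray(self.grid_shape)
        if shape.shape != (3,) or np.any(shape <= 0) or not np.issubdtype(shape.dtype, np.integer):
            raise ValidationError("grid_shape: expected 3 positive integers")
        if not (self.voxel_spacing_mm > 0):
            raise ValidationError("voxel_spacing_mm: must be positive")
        if np.any(np.asarray(self.core_radii_vox, dtype=np.float64) <= 0):
            raise ValidationError("core_radii_vox: semi-axes must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd: must be nonnegative")
        if self.distractor_count < 0:
            raise ValidationError("distractor_count: must be nonnegative")
        if self.condyle_slice_fraction is not None and not (0 < self.condyle_slice_fraction <= 1):
            raise ValidationError("condyle_slice_fraction: must lie in (0, 1]")
        t_lo, t_hi = self.thickness_bounds_mm()
        if t_lo < self.voxel_spacing_mm:
            raise ValidationError(
                "shell_thickness_fn: minimum thickness "
                f"{t_lo:.3f} mm is below one voxel spacing ({self.voxel_spacing_mm} mm)"
            )
        radii = self.resolved_radii()
        reach = radii + t_hi / self.voxel_spacing_mm
        c = self.center()
        if np.any(c - reach < -0.5) or np.any(c + reach > shape - 0.5):
            raise ValidationError(
                "grid_shape: core ellipsoid plus maximal shell does not fit inside the grid"
            )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _phantom_fields(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rasterize the marrow/cortical masks; returns (marrow, cortical, bbox)."""
    radii = spec.resolved_radii()
    c = spec.center()
    t_lo, t_hi = spec.thickness_bounds_mm()
    reach = radii + t_hi / spec.voxel_spacing_mm
    lo = np.maximum(np.floor(c - reach).astype(int) - 1, 0)
    hi = np.minimum(np.ceil(c + reach).astype(int) + 2, np.asarray(spec.grid_shape))

    zz, yy, xx = np.meshgrid(
        np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]), np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    v = np.stack([zz - c[0], yy - c[1], xx - c[2]], axis=-1).astype(np.float64)
    d2 = np.sum((v / radii) ** 2, axis=-1)
    rho = np.linalg.norm(v, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(rho[..., None] > 0, v / np.where(rho[..., None] > 0, rho[..., None], 1.0), 0.0)
        r_core = np.where(d2 > 0, rho / np.sqrt(np.where(d2 > 0, d2, 1.0)), np.inf)
    t_vox = np.asarray(spec.shell_thickness_fn(u), dtype=np.float64) / spec.voxel_spacing_mm

    marrow_box = d2 < 1.0
    cortical_box = (~marrow_box) & (rho <= r_core + t_vox)

    marrow = np.zeros(spec.grid_shape, dtype=bool)
    cortical = np.zeros(spec.grid_shape, dtype=bool)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    marrow[sl] = marrow_box
    cortical[sl] = cortical_box
    bbox = np.array([lo, hi])
    return marrow, cortical, bbox


def _place_distractors(
    intensities: np.ndarray,
    bbox: np.ndarray,
    count: int,
    rng: np.random.Generator,
) -> int:
    """Paint bone-like ellipsoidal blobs that avoid the dilated phantom box."""
    shape = np.asarray(intensities.shape)
    lo = np.maximum(bbox[0] - 2, 0)
    hi = np.minimum(bbox[1] + 2, shape)
    placed = 0
    for _ in range(count):
        ok = False
        for _attempt in range(200):
            radii = rng.uniform(2.0, 4.0, size=3)
            if np.any(shape - 2 * radii - 1.0 <= 0):
                continue
            center = rng.uniform(radii + 0.5, shape - radii - 0.5)
            # keep distractor z near the phantom so it stresses the classifier
            z_lo = max(bbox[0][0], radii[0] + 0.5)
            z_hi = min(bbox[1][0], shape[0] - radii[0] - 0.5)
            if z_lo < z_hi:
                center[0] = rng.uniform(z_lo, z_hi)
            blo = np.maximum(np.floor(center - radii).astype(int), 0)
            bhi = np.minimum(np.ceil(center + radii).astype(int) + 1, shape)
            # reject any overlap with the phantom bounding box dilated by 2
            if np.all(bhi > lo) and np.all(blo < hi):
                continue
            zz, yy, xx = np.meshgrid(
                np.arange(blo[0], bhi[0]), np.arange(blo[1], bhi[1]),
                np.arange(blo[2], bhi[2]), indexing="ij",
            )
            d2 = (
                ((zz - center[0]) / radii[0]) ** 2
                + ((yy - center[1]) / radii[1]) ** 2
                + ((xx - center[2]) / radii[2]) ** 2
            )
            region = tuple(slice(a, b) for a, b in zip(blo, bhi))
            patch = intensities[region]
            patch[d2 <= 1.0] = DISTRACTOR_MEAN
            placed += 1
            ok = True
            break
        if not ok:
            logger.warning("could not place a distractor without overlap; skipping")
    return placed


def generate_condyle_phantom(spec: PhantomSpec, seed: int) -> tuple[Volume, LabelVolume]:
    """Generate one phantom volume and its gold-standard label volume.

    Voxels strictly inside the core ellipsoid are marrow; voxels in the
    direction-dependent shell band are cortical; everything else background.
    Distractor blobs appear in the intensities only.  Identical (spec, seed)
    pairs give bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    marrow, cortical, bbox = _phantom_fields(spec)

    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    labels[marrow] = MARROW
    labels[cortical] = CORTICAL

    intensities = np.full(spec.grid_shape, BACKGROUND_MEAN, dtype=np.float64)
    intensities[marrow] = MARROW_MEAN
    intensities[cortical] = CORTICAL_MEAN
    if spec.distractor_count:
        _place_distractors(intensities, bbox, spec.distractor_count, rng)
    if spec.noise_sd > 0:
        intensities = intensities + rng.normal(0.0, spec.noise_sd, size=intensities.shape)
        np.clip(intensities, 0.0, 1.0, out=intensities)

    return (
        Volume(intensities, spec.voxel_spacing_mm),
        LabelVolume(labels, spec.voxel_spacing_mm),
    )


def generate_subject_stack(
    spec: PhantomSpec, n_slices: int, seed: int
) -> tuple[Volume, LabelVolume, PresenceVector]:
    """A full subject stack: the phantom placed at a seeded slice offset.

    The phantom occupies one contiguous run of slices; the returned gold
    presence vector is 1 exactly on slices whose label plane is non-background.
    """
    rng = np.random.default_rng(seed)
    base = replace(spec, grid_shape=(int(n_slices),) + tuple(spec.grid_shape[1:]))
    # resolve geometry against the full stack height
    radii = base.resolved_radii()
    t_lo, t_hi = base.thickness_bounds_mm()
    half = radii[0] + t_hi / base.voxel_spacing_mm
    if 2 * half > n_slices:
        raise ValidationError(
            f"n_slices: phantom spans {2 * half:.1f} slices but the stack has {n_slices}"
        )
    zc = rng.uniform(half + 0.5, n_slices - half - 0.5)
    c = base.center()
    placed = replace(
        base,
        core_center_vox=(float(zc), float(c[1]), float(c[2])),
        core_radii_vox=tuple(radii),
        condyle_slice_fraction=None,
    )
    vol, lab = generate_condyle_phantom(placed, seed=int(rng.integers(0, 2**31 - 1)))
    presence = PresenceVector(lab.slice_has_object().astype(np.uint8))
    return vol, lab, presence


def analytic_thickness(spec: PhantomSpec, direction: Sequence[float]) -> float:
    """Ground-truth shell thickness (mm) along an outward unit direction."""
    d = np.asarray(direction, dtype=np.float64)
    if d.shape != (3,) or abs(np.linalg.norm(d) - 1.0) > 1e-6:
        raise ValidationError("direction: expected a unit 3-vector")
    return float(np.asarray(spec.shell_thickness_fn(d)))


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class PhantomSubject:
    """One synthetic subject: volume, gold labels, gold presence, and its spec."""

    subject_id: str
    volume: Volume
    labels: LabelVolume
    presence: PresenceVector
    spec: PhantomSpec


def make_phantom_cohort(
    n_subjects: int,
    n_slices: int = 512,
    in_plane: tuple[int, int] = (512, 512),
    seed: int = 0,
    voxel_spacing_mm: float = 0.3,
    condyle_slice_fraction: float = 0.09,
    thickness_range_mm: tuple[float, float] = (0.9, 3.0),
    noise_sd: float = 0.04,
    distractor_count: int = 3,
) -> list[PhantomSubject]:
    """Generate a cohort of subjects with per-subject randomized geometry.

    Defaults emulate a full-scale acquisition: 512 axial slices per subject of
    which ~9% intersect the condyle head, 0.3 mm isotropic voxels.  Each
    subject draws its own in-plane core radii and a hemispherically varying
    shell thickness from ``thickness_range_mm`` (typical condylar cortices run
    roughly 1-3 mm).
    """
    subjects = []
    for i in range(n_subjects):
        rng = np.random.default_rng([seed, i])
        t_top = rng.uniform(*thickness_range_mm)
        t_bot = rng.uniform(*thickness_range_mm)
        fn = HemisphericThickness(t_top, t_bot)
        # in-plane core semi-axes ~3.5-5.5 mm (a condyle head is ~1 cm wide),
        # capped so core + shell + distractor clearance fits the grid
        max_r = min(in_plane) / 2.0 - max(t_top, t_bot) / voxel_spacing_mm - 3.0
        r_hi = min(5.5 / voxel_spacing_mm, max_r)
        r_lo = min(3.5 / voxel_spacing_mm, r_hi - 1e-6)
        ry, rx = rng.uniform(r_lo, r_hi, size=2)
        spec = PhantomSpec(
            grid_shape=(n_slices, *in_plane),
            voxel_spacing_mm=voxel_spacing_mm,
            core_radii_vox=(10.0, float(ry), float(rx)),
            shell_thickness_fn=fn,
            noise_sd=noise_sd,
            distractor_count=distractor_count,
            condyle_slice_fraction=condyle_slice_fraction,
        )
        vol, lab, presence = generate_subject_stack(
            spec, n_slices, seed=int(rng.integers(0, 2**31 - 1))
        )
        subjects.append(PhantomSubject(f"subj{i:03d}", vol, lab, presence, spec))
    return subjects
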