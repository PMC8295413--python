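"""Marching-cubes surface extraction and thickness color mapping.

The segmented condyle is rendered as a triangle mesh from the binary region
indicator (outer bone or marrow).  A light Gaussian pre-filter (sigma 0.8
voxels) anti-aliases the binary field so the 0.5-isosurface sits at the
sub-voxel boundary rather than on voxel staircases; phantoms wholly inside
the grid yield closed genus-0 surfaces.  Per-vertex cortical thickness is
looked up from the nearest thickness-map point, clamped to a display range
(default 0-6 mm) and mapped through a perceptually uniform colormap.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from skimage import measure

from .core import MARROW, LabelVolume, ThicknessMap, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_RANGE_MM = (0.0, 6.0)
DEFAULT_COLORMAP = "viridis"
DEFAULT_SMOOTH_SIGMA = 0.8


def mesh_from_labels(
    labels: LabelVolume,
    region: str = "outer",
    smoothing_sigma: float = DEFAULT_SMOOTH_SIGMA,
) -> trimesh.Trimesh:
    """Marching-cubes mesh of a label region, vertices in millimetres.

    ``region`` is ``"outer"`` (cortical union marrow, the bone envelope) or
    ``"marrow"``.  The indicator is padded by one background voxel so surfaces
    touching the grid edge still close.
    """
    if region == "outer":
        mask = labels.labels != 0
    elif region == "marrow":
        mask = labels.labels == MARROW
    else:
        raise ValidationError(f"region: expected 'outer' or 'marrow', got {region!r}")
    if not mask.any():
        raise ValidationError(f"region {region!r} is empty")
    sp = labels.voxel_spacing_mm
    f = np.pad(mask.astype(np.float64), 1)
    if smoothing_sigma > 0:
        f = gaussian_filter(f, smoothing_sigma)
    verts, faces, _, _ = measure.marching_cubes(f, level=0.5, spacing=(sp, sp, sp))
    verts = verts - sp  # undo the one-voxel pad
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    mesh.remove_unreferenced_vertices()
    return mesh


@dataclass
class ColoredMesh:
    """Triangle mesh with per-vertex thickness (mm) and RGB colors."""

    vertices: np.ndarray
    faces: np.ndarray
    thickness_mm: np.ndarray
    rgb: np.ndarray  # (N, 3) uint8
    colormap: str = DEFAULT_COLORMAP
    range_mm: tuple[float, float] = DEFAULT_RANGE_MM
    clamp_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        n = len(self.vertices)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= n):
            raise ValidationError("faces: vertex index out of range")
        if self.thickness_mm.shape != (n,) or self.rgb.shape != (n, 3):
            raise ValidationError("per-vertex arrays inconsistent with vertex count")

    def as_trimesh(self) -> trimesh.Trimesh:
        mesh = trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)
        mesh.visual.vertex_colors = np.column_stack(
            [self.rgb, np.full(len(self.rgb), 255, dtype=np.uint8)]
        )
        return mesh


def colorize_mesh(
    mesh: trimesh.Trimesh,
    tm: ThicknessMap,
    colormap: str = DEFAULT_COLORMAP,
    range_mm: tuple[float, float] = DEFAULT_RANGE_MM,
) -> ColoredMesh:
    """Assign each vertex the thickness of its nearest map point, then color it."""
    import matplotlib

    if len(tm) == 0:
        raise ValidationError("thickness map: empty")
    lo, hi = range_mm
    if not lo < hi:
        raise ValidationError("range_mm: expected (lo, hi) with lo < hi")
    _, idx = cKDTree(tm.points_mm).query(mesh.vertices)
    thickness = tm.thickness_mm[idx]
    clamped = np.clip(thickness, lo, hi)
    frac = float(np.mean((thickness < lo) | (thickness > hi)))
    if frac:
        logger.info("colorize_mesh: %.1f%% of vertices clamped to range", 100 * frac)
    cmap = matplotlib.colormaps[colormap]
    rgba = cmap((clamped - lo) / (hi - lo))
    rgb = (rgba[:, :3] * 255).round().astype(np.uint8)
    return ColoredMesh(
        vertices=np.asarray(mesh.vertices),
        faces=np.asarray(mesh.faces),
        thickness_mm=thickness,
        rgb=rgb,
        colormap=colormap,
        range_mm=(float(lo), float(hi)),
        clamp_fraction=frac,
    )


@dataclass
class RenderResult:
    """Paths and metadata of rendered snapshot images."""

    view_paths: list[str]
    legend_path: str
    metadata: dict = field(default_factory=dict)


def render_views(
    cmesh: ColoredMesh,
    view_angles: list[tuple[float, float]],
    out_dir,
    size: tuple[int, int] = (640, 640),
) -> RenderResult:
    """Off-screen snapshots of the colored mesh plus a colorbar legend (mm).

    Each view angle is an (elevation, azimuth) pair in degrees.  Rendering is
    rasterized through the Agg backend and deterministic for a fixed mesh,
    view list and size.  The legend tick values are returned in the metadata.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import cm, colors
    from mpl_toolkits.mplot3d.art3d import Poly3DCollection
    from pathlib import Path

    if not view_angles:
        raise ValidationError("view_angles: at least one view required")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    tri = cmesh.vertices[cmesh.faces]
    face_rgb = cmesh.rgb[cmesh.faces].mean(axis=1) / 255.0
    dpi = 100
    paths = []
    for i, (elev, azim) in enumerate(view_angles):
        fig = plt.figure(figsize=(size[0] / dpi, size[1] / dpi), dpi=dpi)
        ax = fig.add_subplot(projection="3d")
        coll = Poly3DCollection(tri, facecolors=face_rgb, edgecolors="none")
        ax.add_collection3d(coll)
        lo = cmesh.vertices.min(axis=0)
        hi = cmesh.vertices.max(axis=0)
        c = (lo + hi) / 2
        r = (hi - lo).max() / 2
        ax.set_xlim(c[0] - r, c[0] + r)
        ax.set_ylim(c[1] - r, c[1] + r)
        ax.set_zlim(c[2] - r, c[2] + r)
        ax.view_init(elev=elev, azim=azim)
        ax.set_axis_off()
        p = out_dir / f"view_{i:02d}.png"
        fig.savefig(p, dpi=dpi)
        plt.close(fig)
        paths.append(str(p))

    lo, hi = cmesh.range_mm
    norm = colors.Normalize(vmin=lo, vmax=hi)
    fig, ax = plt.subplots(figsize=(1.4, 4.0), dpi=dpi)
    cb = fig.colorbar(cm.ScalarMappable(norm=norm, cmap=cmesh.colormap), cax=ax)
    cb.set_label("cortical thickness (mm)")
    ticks = [float(t) for t in cb.get_ticks() if lo <= t <= hi]
    legend_path = out_dir / "legend.png"
    fig.savefig(legend_path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)

    metadata = {
        "colormap": cmesh.colormap,
        "range_mm": list(cmesh.range_mm),
        "clamp_fraction": cmesh.clamp_fraction,
        "legend_ticks_mm": ticks,
        "views": [list(v) for v in view_angles],
        "size": list(size),
    }
    with open(out_dir / "render_metadata.json", "w") as fh:
        json.dump(metadata, fh, indent=2)
    return RenderResult(paths, str(legend_path), metadata)
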