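"""Reading and writing volumes, label maps and meshes in standard formats.

Supported volume carriers: NIfTI (``.nii``/``.nii.gz`` via nibabel), DICOM
series directories (via pydicom, slices stacked by ascending Instance
Number), and PNG slice stacks with a JSON sidecar holding the voxel spacing
and intensity calibration.  Axis order is always (slice, row, column) and
voxel indices are corner-anchored: voxel (i, j, k) sits at (i, j, k) * spacing
millimetres.  Label round trips are lossless; volume round trips are lossless
up to the declared bit depth of the carrier.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .core import LabelVolume, ValidationError, Volume

logger = logging.getLogger(__name__)

PNG_SIDECAR = "stack_meta.json"


@dataclass
class VolumeHandle:
    """Where and how a volume is stored on disk."""

    path: str
    format: str  # "nifti" | "dicom" | "png"
    spacing_mm: float
    shape: tuple[int, int, int]


def _detect_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if path.is_dir():
        if any(path.glob("*.dcm")):
            return "dicom"
        if any(path.glob("*.png")):
            return "png"
    raise ValidationError(f"path: cannot infer volume format of {path}")


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def read_volume(path, format: str | None = None, spacing_mm: float | None = None) -> Volume:
    """Read a volume; spacing comes from metadata unless supplied."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"path: {path} does not exist")
    fmt = format or _detect_format(path)
    if fmt == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        zooms = img.header.get_zooms()[:3]
        sp = spacing_mm if spacing_mm is not None else float(zooms[0])
        if spacing_mm is None and not np.allclose(zooms, zooms[0], atol=1e-6):
            raise ValidationError(f"{path}: anisotropic spacing {zooms} unsupported")
        return Volume(data, sp)
    if fmt == "png":
        return _read_png_stack(path, spacing_mm)
    if fmt == "dicom":
        return _read_dicom_series(path, spacing_mm)
    raise ValidationError(f"format: unsupported format tag {fmt!r}")


def _read_png_stack(path: Path, spacing_mm: float | None) -> Volume:
    files = sorted(path.iterdir())
    bad = [f.name for f in files if f.is_file() and f.suffix not in (".png", ".json")]
    if bad:
        raise ValidationError(f"{path}: non-image files present: {bad}")
    pngs = sorted(path.glob("*.png"))
    if not pngs:
        raise ValidationError(f"{path}: no PNG slices found")
    meta = {}
    sidecar = path / PNG_SIDECAR
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    sp = spacing_mm if spacing_mm is not None else meta.get("voxel_spacing_mm")
    if sp is None:
        raise ValidationError(f"{path}: no spacing sidecar and none supplied")
    slices = [iio.imread(f) for f in pngs]
    data = np.stack(slices).astype(np.float64)
    if "intensity_min" in meta:
        vmin, vmax = meta["intensity_min"], meta["intensity_max"]
        maxcode = float(meta.get("max_code", 65535))
        data = data / maxcode * (vmax - vmin) + vmin
    return Volume(data, float(sp))


def _read_dicom_series(path: Path, spacing_mm: float | None) -> Volume:
    import pydicom

    files = sorted(path.glob("*.dcm"))
    if not files:
        raise ValidationError(f"{path}: no DICOM files found")
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
            slices.append((int(ds.InstanceNumber), f, ds))
        except Exception as exc:  # pragma: no cover - corrupt file path
            raise ValidationError(f"{f}: unreadable DICOM file ({exc})") from exc
    slices.sort(key=lambda t: t[0])
    spacings = set()
    arrays = []
    for _, f, ds in slices:
        px = getattr(ds, "PixelSpacing", None)
        if px is not None:
            spacings.add((round(float(px[0]), 6), round(float(px[1]), 6)))
            if len(spacings) > 1:
                raise ValidationError(f"{f}: mixed pixel spacing within series")
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arrays.append(arr * slope + intercept)
    if spacing_mm is not None:
        sp = spacing_mm
    elif spacings:
        sp = spacings.pop()[0]
    else:
        raise ValidationError(f"{path}: no PixelSpacing and none supplied")
    return Volume(np.stack(arrays), float(sp))


def write_volume(volume: Volume, path, format: str = "nifti") -> VolumeHandle:
    """Write a volume as NIfTI (float64, lossless) or a 16-bit PNG stack."""
    path = Path(path)
    if format == "nifti":
        import nibabel as nib

        affine = np.diag([volume.voxel_spacing_mm] * 3 + [1.0])
        nib.save(nib.Nifti1Image(volume.intensities, affine), str(path))
    elif format == "png":
        path.mkdir(parents=True, exist_ok=True)
        vmin, vmax = float(volume.intensities.min()), float(volume.intensities.max())
        scale = (vmax - vmin) or 1.0
        codes = np.round((volume.intensities - vmin) / scale * 65535).astype(np.uint16)
        for z in range(volume.n_slices):
            iio.imwrite(path / f"slice_{z:04d}.png", codes[z])
        meta = {
            "voxel_spacing_mm": volume.voxel_spacing_mm,
            "intensity_min": vmin,
            "intensity_max": vmax,
            "max_code": 65535,
            "n_slices": volume.n_slices,
        }
        (path / PNG_SIDECAR).write_text(json.dumps(meta, indent=2))
    else:
        raise ValidationError(f"format: unsupported format tag {format!r}")
    return VolumeHandle(str(path), format, volume.voxel_spacing_mm, volume.shape)


# ---------------------------------------------------------------------------
# label maps
# ---------------------------------------------------------------------------

def write_labelmap(labels: LabelVolume, path, format: str = "nifti") -> VolumeHandle:
    """Write the {0,1,2} label codes losslessly (integer datatype)."""
    path = Path(path)
    if format == "nifti":
        import nibabel as nib

        affine = np.diag([labels.voxel_spacing_mm] * 3 + [1.0])
        img = nib.Nifti1Image(labels.labels.astype(np.uint8), affine)
        img.header.set_data_dtype(np.uint8)
        nib.save(img, str(path))
    elif format == "png":
        path.mkdir(parents=True, exist_ok=True)
        for z in range(labels.shape[0]):
            iio.imwrite(path / f"label_{z:04d}.png", labels.labels[z])
        meta = {"voxel_spacing_mm": labels.voxel_spacing_mm, "labelmap": True}
        (path / PNG_SIDECAR).write_text(json.dumps(meta, indent=2))
    else:
        raise ValidationError(f"format: unsupported format tag {format!r}")
    return VolumeHandle(str(path), format, labels.voxel_spacing_mm, labels.shape)


def read_labelmap(path, format: str | None = None, spacing_mm: float | None = None) -> LabelVolume:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"path: {path} does not exist")
    fmt = format or _detect_format(path)
    if fmt == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        sp = spacing_mm if spacing_mm is not None else float(img.header.get_zooms()[0])
        return LabelVolume(np.asarray(img.dataobj).astype(np.uint8), sp)
    if fmt == "png":
        meta = json.loads((path / PNG_SIDECAR).read_text())
        pngs = sorted(path.glob("*.png"))
        data = np.stack([iio.imread(f) for f in pngs]).astype(np.uint8)
        sp = spacing_mm if spacing_mm is not None else meta["voxel_spacing_mm"]
        return LabelVolume(data, float(sp))
    raise ValidationError(f"format: unsupported format tag {fmt!r}")


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

def write_mesh(mesh, path, format: str | None = None) -> str:
    """Write a mesh as PLY (per-vertex RGB preserved) or OBJ (geometry only).

    OBJ export of a colored mesh drops the colors with a warning.
    """
    from .viz import ColoredMesh

    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("ply", "obj"):
        raise ValidationError(f"format: unsupported mesh format {fmt!r}")
    tm = mesh.as_trimesh() if isinstance(mesh, ColoredMesh) else mesh
    if len(tm.vertices) == 0 or len(tm.faces) == 0:
        raise ValidationError("mesh: empty mesh cannot be written")
    if fmt == "obj" and isinstance(mesh, ColoredMesh):
        msg = "OBJ export drops per-vertex colors; geometry only"
        logger.warning(msg)
        warnings.warn(msg, UserWarning, stacklevel=2)
    tm.export(str(path), file_type=fmt)
    return str(path)


def read_mesh(path):
    import trimesh

    return trimesh.load(str(path), process=False)
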