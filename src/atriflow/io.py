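"""Readers and writers for NIfTI volumes, 4D-flow layouts and transforms.

Canonical interchange format is NIfTI-1 (affine-carrying, mask-friendly);
a DICOM series can be read for the angiography input.  A 4D-flow dataset
on disk is a directory (or explicit file set) of four 4D NIfTI files —
magnitude plus the three velocity components — and a JSON sidecar:

    flow.json:
      {"magnitude": "mag.nii.gz",
       "velocity": ["vx.nii.gz", "vy.nii.gz", "vz.nii.gz"],
       "velocity_units": "m/s" | "cm/s",
       "venc": <number, in velocity_units>,
       "frame_duration_ms": <number, optional>}

Velocities are converted to m/s on load.  Affines are used verbatim
(NIfTI s-form convention); registration is meaningless without them.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .image_model import (
    BinaryMask,
    FourDFlowSeries,
    ImageGrid,
    RigidTransform,
    ScalarVolume,
)

__all__ = [
    "read_volume",
    "read_mask",
    "read_flow",
    "write_volume",
    "write_mask",
    "write_flow",
    "read_transform",
    "write_transform",
    "read_dicom_series",
]

_RAD_PER_DEG = np.pi / 180.0


def _grid_from_nifti(img) -> ImageGrid:
    affine = np.asarray(img.affine, dtype=float)
    shape = img.shape[:3]
    return ImageGrid(tuple(int(s) for s in shape), affine)


def read_volume(path: str | Path) -> ScalarVolume:
    """Load a 3D NIfTI scalar volume (or a DICOM series directory)."""
    path = Path(path)
    if path.is_dir():
        return read_dicom_series(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return ScalarVolume(_grid_from_nifti(img), data)


def read_mask(path: str | Path, label: str = "OTHER") -> BinaryMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D mask, got shape {data.shape}")
    return BinaryMask(_grid_from_nifti(img), data > 0, label)


def write_volume(vol: ScalarVolume, path: str | Path) -> None:
    """Write float32 NIfTI with the volume's affine."""
    img = nib.Nifti1Image(vol.values.astype(np.float32), vol.grid.affine)
    nib.save(img, str(path))


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write uint8 NIfTI with the mask's affine."""
    img = nib.Nifti1Image(mask.values.astype(np.uint8), mask.grid.affine)
    nib.save(img, str(path))


def _load_4d(path: Path) -> tuple[ImageGrid, np.ndarray]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 3:
        data = data[..., None]
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D volume, got shape {data.shape}")
    # NIfTI stores time last; this package keeps frames first
    return _grid_from_nifti(img), np.moveaxis(data, 3, 0)


def read_flow(path: str | Path) -> FourDFlowSeries:
    """Load a 4D-flow series from a sidecar JSON (or a directory holding one)."""
    path = Path(path)
    sidecar = path / "flow.json" if path.is_dir() else path
    if not sidecar.exists():
        raise FileNotFoundError(f"flow sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    base = sidecar.parent
    units = meta.get("velocity_units")
    if units not in ("m/s", "cm/s"):
        raise ValueError(
            f"{sidecar}: velocity_units must be 'm/s' or 'cm/s', got {units!r}"
        )
    scale = 1.0 if units == "m/s" else 0.01

    grid, magnitude = _load_4d(base / meta["magnitude"])
    comps = []
    for comp_path in meta["velocity"]:
        cgrid, comp = _load_4d(base / comp_path)
        if comp.shape != magnitude.shape or not cgrid.same_geometry(grid):
            raise ValueError(
                f"{comp_path}: velocity component shape/affine does not match magnitude"
            )
        comps.append(comp * scale)
    velocity = np.stack(comps, axis=-1)
    venc = meta.get("venc")
    return FourDFlowSeries(
        grid,
        magnitude,
        velocity,
        venc=None if venc is None else float(venc) * scale,
        frame_duration_ms=meta.get("frame_duration_ms"),
    )


def write_flow(series: FourDFlowSeries, out_dir: str | Path) -> Path:
    """Write the magnitude/velocity NIfTI set plus sidecar; returns the sidecar path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = series.grid.affine

    def save4d(field: np.ndarray, name: str) -> None:
        data = np.moveaxis(field, 0, 3).astype(np.float32)
        nib.save(nib.Nifti1Image(data, aff), str(out_dir / name))

    save4d(series.magnitude, "mag.nii.gz")
    names = ["vx.nii.gz", "vy.nii.gz", "vz.nii.gz"]
    for axis, name in enumerate(names):
        save4d(series.velocity[..., axis], name)
    meta = {
        "magnitude": "mag.nii.gz",
        "velocity": names,
        "velocity_units": "m/s",
        "venc": series.venc,
        "frame_duration_ms": series.frame_duration_ms,
    }
    sidecar = out_dir / "flow.json"
    sidecar.write_text(json.dumps(meta, indent=2))
    return sidecar


def write_transform(t: RigidTransform, path: str | Path) -> None:
    """Serialise a rigid transform as JSON (angles in degrees)."""
    payload = {
        "convention": "intrinsic-ZYX; pull-back fixed-world -> moving-world",
        "angles_deg": [a / _RAD_PER_DEG for a in t.angles],
        "translation_mm": list(t.translation),
        "center_mm": list(t.center),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_transform(path: str | Path) -> RigidTransform:
    payload = json.loads(Path(path).read_text())
    return RigidTransform(
        angles=tuple(a * _RAD_PER_DEG for a in payload["angles_deg"]),
        translation=tuple(payload["translation_mm"]),
        center=tuple(payload["center_mm"]),
    )


def read_dicom_series(directory: str | Path) -> ScalarVolume:
    """Assemble a 3D volume from a single-series DICOM directory.

    Slices are sorted by projection of ImagePositionPatient onto the slice
    normal; the affine is built from ImageOrientationPatient, PixelSpacing
    and the inter-slice vector (LPS coordinates as stored, no axis
    flipping).
    """
    import pydicom

    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "ImagePositionPatient") and hasattr(ds, "PixelData"):
            datasets.append(ds)
    if len(datasets) < 2:
        raise ValueError(f"{directory}: fewer than 2 readable DICOM slices")
    ref = datasets[0]
    orient = np.asarray(ref.ImageOrientationPatient, dtype=float)
    row, col = orient[:3], orient[3:]
    normal = np.cross(row, col)
    datasets.sort(key=lambda d: float(np.dot(d.ImagePositionPatient, normal)))

    slices = [d.pixel_array.astype(np.float64) for d in datasets]
    arr2d = np.stack(slices, axis=0)  # (n_slices, rows, cols)
    positions = np.asarray([d.ImagePositionPatient for d in datasets], dtype=float)
    step = positions[1] - positions[0]
    spacing_rc = np.asarray(ref.PixelSpacing, dtype=float)  # (row, col)

    # volume axes: (col/i, row/j, slice/k) so the affine columns are the
    # stored direction cosines scaled by spacing
    values = np.transpose(arr2d, (2, 1, 0))
    affine = np.eye(4)
    affine[:3, 0] = row * spacing_rc[1]
    affine[:3, 1] = col * spacing_rc[0]
    affine[:3, 2] = step
    affine[:3, 3] = positions[0]
    grid = ImageGrid(values.shape, affine)
    return ScalarVolume(grid, values)
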