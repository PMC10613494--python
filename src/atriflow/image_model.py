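"""Core volumetric data types and world/index coordinate arithmetic.

Conventions used throughout the package:

* World coordinates are right-handed patient coordinates in millimetres,
  taken verbatim from each file's affine (NIfTI s-form style); no axis
  flipping is applied on load.
* A grid's affine maps homogeneous voxel *indices* (i, j, k, 1) to world
  millimetres.  Fractional indices are allowed everywhere.
* Rigid rotations use intrinsic Z-Y-X Euler angles: ``R = Rz @ Ry @ Rx``.
  Because Euler angles are gimbal-ambiguous, transform comparisons should be
  done on the rotation matrix, not the angles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ImageGrid",
    "ScalarVolume",
    "FourDFlowSeries",
    "BinaryMask",
    "RigidTransform",
    "MASK_LABELS",
]

MASK_LABELS = ("LA", "LAA", "PV", "AORTA", "LV", "OTHER")


@dataclass(frozen=True)
class ImageGrid:
    """A 3D voxel lattice with an index-to-world affine (mm).

    Parameters
    ----------
    shape
        Number of voxels along each axis; all components >= 1.
    affine
        4x4 index-to-world map in millimetres, last row (0, 0, 0, 1).
    """

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be 3 positive integers, got {shape}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {aff.shape}")
        if not np.allclose(aff[3], [0.0, 0.0, 0.0, 1.0], atol=1e-9):
            raise ValueError("affine last row must be (0, 0, 0, 1)")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        aff = aff.copy()
        aff.setflags(write=False)
        object.__setattr__(self, "affine", aff)

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing (mm): Euclidean norms of the affine's direction columns."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @classmethod
    def from_spacing(
        cls,
        shape: tuple[int, int, int],
        spacing: tuple[float, float, float] | float,
        origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    ) -> "ImageGrid":
        """Axis-aligned grid from spacing and world origin of voxel (0,0,0)."""
        spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (3,))
        aff = np.eye(4)
        aff[:3, :3] = np.diag(spacing)
        aff[:3, 3] = origin
        return cls(tuple(shape), aff)

    def world_from_index(self, index: np.ndarray) -> np.ndarray:
        """Map (fractional) voxel indices to world mm.  Accepts (..., 3)."""
        idx = np.asarray(index, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def index_from_world(self, world: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`world_from_index`; returns fractional indices."""
        w = np.asarray(world, dtype=float)
        inv = np.linalg.inv(self.affine)
        return w @ inv[:3, :3].T + inv[:3, 3]

    def center_world(self) -> np.ndarray:
        """World coordinates of the grid centre (index (shape-1)/2)."""
        return self.world_from_index((np.asarray(self.shape, dtype=float) - 1.0) / 2.0)

    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def same_geometry(self, other: "ImageGrid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=atol)


def world_from_index(grid: ImageGrid, index) -> np.ndarray:
    """Functional alias for :meth:`ImageGrid.world_from_index`."""
    return grid.world_from_index(index)


def index_from_world(grid: ImageGrid, world) -> np.ndarray:
    """Functional alias for :meth:`ImageGrid.index_from_world`."""
    return grid.index_from_world(world)


def _check_field(grid: ImageGrid, values: np.ndarray, name: str) -> None:
    if tuple(values.shape) != grid.shape:
        raise ValueError(f"{name} shape {values.shape} does not match grid shape {grid.shape}")


@dataclass(frozen=True)
class ScalarVolume:
    """A scalar intensity field over an :class:`ImageGrid`."""

    grid: ImageGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        _check_field(self.grid, vals, "values")
        if not np.all(np.isfinite(vals)):
            raise ValueError("scalar volume contains non-finite values")
        object.__setattr__(self, "values", vals)

    def with_values(self, values: np.ndarray) -> "ScalarVolume":
        return ScalarVolume(self.grid, values)


@dataclass(frozen=True)
class BinaryMask:
    """A boolean segmentation field over a grid, tagged with a structure label."""

    grid: ImageGrid
    values: np.ndarray
    label: str = "OTHER"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.dtype != bool:
            uniq = np.unique(vals)
            if not np.isin(uniq, (0, 1)).all():
                raise ValueError("mask values must be boolean (0/1)")
            vals = vals.astype(bool)
        _check_field(self.grid, vals, "values")
        if self.label not in MASK_LABELS:
            raise ValueError(f"label must be one of {MASK_LABELS}, got {self.label!r}")
        object.__setattr__(self, "values", vals)

    @property
    def count(self) -> int:
        return int(self.values.sum())

    def with_values(self, values: np.ndarray, label: str | None = None) -> "BinaryMask":
        return BinaryMask(self.grid, values, label if label is not None else self.label)

    def foreground_world(self) -> np.ndarray:
        """World coordinates (n, 3) of foreground voxel centres."""
        idx = np.argwhere(self.values)
        return self.grid.world_from_index(idx)


@dataclass(frozen=True)
class FourDFlowSeries:
    """Time-resolved 4D-flow data: per-frame magnitude and 3-component velocity.

    ``magnitude`` has shape (N, *grid.shape); ``velocity`` has shape
    (N, *grid.shape, 3) in m/s.  ``venc`` is the velocity-encoding limit in
    m/s (speeds beyond it alias); when set, component magnitudes must stay
    within 1.05 * venc.
    """

    grid: ImageGrid
    magnitude: np.ndarray
    velocity: np.ndarray
    venc: float | None = None
    frame_duration_ms: float | None = None

    def __post_init__(self) -> None:
        mag = np.asarray(self.magnitude, dtype=np.float64)
        vel = np.asarray(self.velocity, dtype=np.float64)
        if mag.ndim != 4:
            raise ValueError("magnitude must be (n_frames, nx, ny, nz)")
        if vel.shape != mag.shape + (3,):
            raise ValueError(
                f"velocity shape {vel.shape} must be magnitude shape {mag.shape} + (3,)"
            )
        if mag.shape[0] < 1:
            raise ValueError("series needs at least one frame")
        if tuple(mag.shape[1:]) != self.grid.shape:
            raise ValueError("per-frame field shape does not match grid shape")
        if not np.all(np.isfinite(mag)) or not np.all(np.isfinite(vel)):
            raise ValueError("flow series contains non-finite values")
        if self.venc is not None and np.abs(vel).max() > self.venc * 1.05:
            raise ValueError(
                f"velocity components exceed venc * 1.05 ({self.venc * 1.05:.3f} m/s)"
            )
        object.__setattr__(self, "magnitude", mag)
        object.__setattr__(self, "velocity", vel)

    @property
    def n_frames(self) -> int:
        return int(self.magnitude.shape[0])


def _rotation_matrix(angles: np.ndarray) -> np.ndarray:
    """Intrinsic Z-Y-X rotation matrix: R = Rz(az) @ Ry(ay) @ Rx(ax)."""
    ax, ay, az = angles
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


@dataclass(frozen=True)
class RigidTransform:
    """A 6-parameter rigid (rotation + translation) map of world points.

    ``apply(p) = R @ (p - center) + center + translation`` with R the
    intrinsic Z-Y-X Euler rotation built from ``angles`` (radians).  The
    rotation centre is in world mm and is *not* an optimised parameter; it
    defaults to the fixed image's grid centre during registration.
    """

    angles: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("angles", "translation", "center"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be 3 finite reals")
            object.__setattr__(self, name, tuple(float(x) for x in v))

    @property
    def rotation(self) -> np.ndarray:
        return _rotation_matrix(np.asarray(self.angles))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to one world point (3,) or many (..., 3)."""
        p = np.asarray(points, dtype=float)
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        return (p - c) @ self.rotation.T + c + t

    def matrix(self) -> np.ndarray:
        """Equivalent homogeneous 4x4 world-to-world matrix."""
        m = np.eye(4)
        r = self.rotation
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        m[:3, :3] = r
        m[:3, 3] = c + t - r @ c
        return m

    def inverse(self) -> "RigidTransform":
        """Exact inverse, expressed about the same rotation centre."""
        r_inv = self.rotation.T
        angles = _euler_from_matrix(r_inv)
        c = np.asarray(self.center)
        m_inv = np.linalg.inv(self.matrix())
        t_new = m_inv[:3, 3] - c + m_inv[:3, :3] @ c
        return RigidTransform(tuple(angles), tuple(t_new), tuple(c))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return T such that T(p) = self(other(p)), centred at self.center."""
        m = self.matrix() @ other.matrix()
        angles = _euler_from_matrix(m[:3, :3])
        c = np.asarray(self.center)
        t = m[:3, 3] - c + m[:3, :3] @ c
        return RigidTransform(tuple(angles), tuple(t), tuple(c))

    def with_center(self, center) -> "RigidTransform":
        """Same world map re-expressed about a different rotation centre."""
        m = self.matrix()
        c = np.asarray(center, dtype=float)
        t = m[:3, 3] - c + m[:3, :3] @ c
        return RigidTransform(self.angles, tuple(t), tuple(c))

    @classmethod
    def from_matrix(cls, matrix: np.ndarray, center=(0.0, 0.0, 0.0)) -> "RigidTransform":
        m = np.asarray(matrix, dtype=float)
        r = m[:3, :3]
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-6) or np.linalg.det(r) < 0:
            raise ValueError("matrix rotation part is not a proper rotation")
        angles = _euler_from_matrix(r)
        c = np.asarray(center, dtype=float)
        t = m[:3, 3] - c + r @ c
        return cls(tuple(angles), tuple(t), tuple(c))


def _euler_from_matrix(r: np.ndarray) -> np.ndarray:
    """Recover intrinsic Z-Y-X Euler angles (ax, ay, az) from a rotation matrix."""
    # R = Rz @ Ry @ Rx; r[2,0] = -sin(ay)
    sy = -r[2, 0]
    sy = np.clip(sy, -1.0, 1.0)
    ay = np.arcsin(sy)
    if abs(sy) < 1.0 - 1e-12:
        ax = np.arctan2(r[2, 1], r[2, 2])
        az = np.arctan2(r[1, 0], r[0, 0])
    else:  # gimbal lock: ax and az degenerate; put everything in az
        ax = 0.0
        az = np.arctan2(-r[0, 1], r[1, 1])
    return np.array([ax, ay, az])


def apply_rigid(t: RigidTransform, p) -> np.ndarray:
    """Functional alias for :meth:`RigidTransform.apply`."""
    return t.apply(p)
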