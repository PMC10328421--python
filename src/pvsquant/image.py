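"""Core in-memory containers: image volumes, binary masks, rigid transforms.

Conventions
-----------
* Voxel indices are 0-based ``(i, j, k)`` in array order; the affine maps
  voxel indices to world coordinates in mm (RAS+, the NIfTI convention).
* ``spacing`` is the per-axis voxel size in mm, derived from the affine.
* A :class:`BinaryMask` is geometrically congruent with its parent volume:
  same grid shape, same affine.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np


class GeometryError(ValueError):
    """Raised when two grids that must be congruent are not."""


class NonFiniteIntensityError(ValueError):
    """Raised when an operation encounters NaN/Inf voxels it cannot accept."""


@dataclass
class ImageVolume:
    """A 3D intensity grid with physical voxel spacing and pose.

    Parameters
    ----------
    data:
        3D float array of intensities in arbitrary scanner units.
    affine:
        4x4 voxel-to-world (mm, RAS+) transform.
    modality:
        ``"T1"``, ``"T2"`` or ``"derived"``.
    """

    data: np.ndarray
    affine: np.ndarray
    modality: str = "derived"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("ImageVolume requires a non-empty 3D grid")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(np.isfinite(self.affine)):
            raise ValueError("affine must be finite")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel size in mm per array axis (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def assert_finite(self) -> None:
        if not np.all(np.isfinite(self.data)):
            n = int(np.sum(~np.isfinite(self.data)))
            raise NonFiniteIntensityError(f"{n} non-finite voxels in volume")

    def like(self, data: np.ndarray, modality: str | None = None) -> "ImageVolume":
        """New volume on the same grid with different voxel values."""
        return ImageVolume(data, self.affine.copy(), modality or self.modality)

    def slice_axis(self) -> int:
        """Array axis of the thick (slice-select) direction.

        The axial slice axis is identified as the axis with the dominant
        spacing (e.g. 4.4 mm slices against 0.4-0.8 mm in-plane).

        Raises
        ------
        GeometryError
            If no axis has a spacing at least 20% larger than the others.
        """
        return _slice_axis_from_spacing(self.spacing)


@dataclass
class BinaryMask:
    """Boolean grid congruent with a parent :class:`ImageVolume`."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("BinaryMask requires a non-empty 3D grid")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def count(self) -> int:
        return int(self.data.sum())

    def like(self, data: np.ndarray) -> "BinaryMask":
        return BinaryMask(np.asarray(data, dtype=bool), self.affine.copy())

    def slice_axis(self) -> int:
        return _slice_axis_from_spacing(self.spacing)


def _slice_axis_from_spacing(sp: np.ndarray) -> int:
    order = np.argsort(sp)
    if sp[order[2]] < 1.2 * sp[order[1]]:
        raise GeometryError(
            f"ambiguous slice axis: spacings {tuple(np.round(sp, 3))}"
        )
    return int(order[2])


def assert_congruent(a: ImageVolume | BinaryMask, b: ImageVolume | BinaryMask) -> None:
    """Check that two grids share shape and pose (affine within 1e-6)."""
    if a.shape != b.shape:
        raise GeometryError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not np.allclose(a.affine, b.affine, atol=1e-6):
        raise GeometryError("affine (pose) mismatch between grids")


@dataclass
class RigidTransform:
    """6-DOF rigid transform: intrinsic ZYX Euler rotation then translation.

    Maps fixed-space physical points (mm) to moving-space physical points,
    the resampling convention: ``resampled(x) = moving(R @ (x - c) + c + t)``
    with ``c`` the rotation centre.
    """

    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix (rotation about ``center``)."""
        R = rotation_matrix(*self.rotation)
        c = np.asarray(self.center, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        M = np.eye(4)
        M[:3, :3] = R
        M[:3, 3] = c + t - R @ c
        return M

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (N, 3) array of mm points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        M = self.matrix()
        return pts @ M[:3, :3].T + M[:3, 3]

    def inverse(self) -> "RigidTransform":
        M = np.linalg.inv(self.matrix())
        ang = euler_from_matrix(M[:3, :3])
        return RigidTransform(rotation=ang, translation=tuple(M[:3, 3]), center=(0, 0, 0))

    def is_identity(self, atol: float = 1e-12) -> bool:
        return np.allclose(self.matrix(), np.eye(4), atol=atol)

    def to_dict(self) -> dict:
        return {
            "rotation_rad": list(self.rotation),
            "translation_mm": list(self.translation),
            "center_mm": list(self.center),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            rotation=tuple(d.get("rotation_rad", (0, 0, 0))),
            translation=tuple(d.get("translation_mm", (0, 0, 0))),
            center=tuple(d.get("center_mm", (0, 0, 0))),
        )


def rotation_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    """Proper rotation matrix from Euler angles (radians), R = Rz @ Ry @ Rx."""
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx

def euler_from_matrix(R: np.ndarray) -> tuple[float, float, float]:
    """Inverse of :func:`rotation_matrix` (R = Rz @ Ry @ Rx)."""
    ry = np.arcsin(-np.clip(R[2, 0], -1.0, 1.0))
    if np.abs(np.cos(ry)) > 1e-8:
        rx = np.arctan2(R[2, 1], R[2, 2])
        rz = np.arctan2(R[1, 0], R[0, 0])
    else:  # gimbal lock
        rx = np.arctan2(-R[1, 2], R[1, 1])
        rz = 0.0
    return (float(rx), float(ry), float(rz))


def affine_from_spacing(spacing, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Axis-aligned RAS affine from spacing (mm) and origin (mm)."""
    A = np.eye(4)
    A[:3, :3] = np.diag(np.asarray(spacing, dtype=float))
    A[:3, 3] = np.asarray(origin, dtype=float)
    return A
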