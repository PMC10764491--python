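"""Rigid transforms and voxel grids.

Conventions used throughout the package (fixed once, here):

* World coordinates are right-handed and expressed in millimetres.
* Voxel indices are 0-based.  A voxel with centre ``c`` and isotropic
  spacing ``s`` owns the half-open cube ``[c - s/2, c + s/2)`` along every
  axis.
* A frame pose maps in-plane coordinates ``(u, v, 0)`` (mm) to world mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["RigidPose", "VoxelGridSpec"]

_ORTHO_TOL = 1e-8


def _vec3(x) -> np.ndarray:
    return np.array(x, dtype=float).reshape(3)


@dataclass(frozen=True)
class RigidPose:
    """Proper rigid transform (rotation + translation).

    Parameters
    ----------
    rotation:
        3x3 orthonormal matrix with determinant +1.
    translation:
        3-vector, mm.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.array(self.rotation, dtype=float).reshape(3, 3)
        t = _vec3(self.translation)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-7):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-6):
            raise ValueError("rotation must be proper (determinant +1)")
        R.setflags(write=False)
        t.setflags(write=False)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    # -- constructors -------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidPose":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_quaternion(cls, quat_wxyz, translation) -> "RigidPose":
        """Build from a scalar-first unit quaternion ``(w, x, y, z)``."""
        q = np.asarray(quat_wxyz, dtype=float).reshape(4)
        n = np.linalg.norm(q)
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ValueError("quaternion is not unit length")
        rot = Rotation.from_quat(np.r_[q[1:], q[0]] / n)  # scipy is xyzw
        return cls(rot.as_matrix(), translation)

    @classmethod
    def from_rotvec(cls, rotvec, translation) -> "RigidPose":
        """Build from an axis-angle rotation vector (radians)."""
        return cls(Rotation.from_rotvec(np.asarray(rotvec, float)).as_matrix(), translation)

    # -- accessors ----------------------------------------------------
    def as_quaternion(self) -> np.ndarray:
        """Scalar-first unit quaternion with canonical sign (w >= 0)."""
        q = Rotation.from_matrix(self.rotation).as_quat()  # xyzw
        q = np.r_[q[3], q[:3]]
        # canonicalise sign so round trips are byte-stable
        for c in q:
            if c > 0:
                break
            if c < 0:
                q = -q
                break
        return q

    # -- algebra ------------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (N, 3) array (or a single 3-vector) to world mm."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidPose") -> "RigidPose":
        """Return ``self @ other`` (apply *other* first, then *self*)."""
        return RigidPose(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidPose":
        return RigidPose(self.rotation.T, -(self.rotation.T @ self.translation))

    def allclose(self, other: "RigidPose", atol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.rotation, other.rotation, atol=atol)
            and np.allclose(self.translation, other.translation, atol=atol)
        )


@dataclass(frozen=True)
class VoxelGridSpec:
    """Axis-aligned isotropic voxel grid.

    ``origin`` is the world position (mm) of the centre of voxel
    ``(0, 0, 0)``; ``dims`` are the number of voxels along x, y, z.
    """

    origin: np.ndarray
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        o = _vec3(self.origin)
        o.setflags(write=False)
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "spacing", float(self.spacing))
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        if self.spacing <= 0:
            raise ValueError("voxel spacing must be positive")
        if len(self.dims) != 3 or any(d < 1 for d in self.dims):
            raise ValueError("grid dims must be three integers >= 1")

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def voxel_index(self, points: np.ndarray) -> np.ndarray:
        """Integer voxel index of each world point (half-open cube rule).

        Indices may fall outside the grid; see :meth:`contains`.
        """
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return np.floor((p - self.origin) / self.spacing + 0.5).astype(np.int64)

    def contains(self, indices: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(indices)
        return np.all((idx >= 0) & (idx < np.array(self.dims)), axis=1)

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        return self.origin + np.atleast_2d(indices) * self.spacing

    def all_centers(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of voxel-centre world coordinates."""
        ax = [self.origin[i] + self.spacing * np.arange(self.dims[i]) for i in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)

    def affine(self) -> np.ndarray:
        """NIfTI-style 4x4 affine mapping voxel index to world mm."""
        a = np.diag([self.spacing, self.spacing, self.spacing, 1.0])
        a[:3, 3] = self.origin
        return a

    @classmethod
    def from_affine(cls, affine: np.ndarray, dims, rtol: float = 1e-6) -> "VoxelGridSpec":
        a = np.asarray(affine, dtype=float)
        lin = a[:3, :3]
        sp = np.linalg.norm(lin, axis=0)
        if not np.allclose(sp, sp[0], rtol=rtol):
            raise ValueError(f"anisotropic voxel spacing {tuple(sp)}; isotropic grid required")
        if not np.allclose(lin, np.diag(sp), atol=rtol * sp[0]):
            raise ValueError("oblique affine; axis-aligned grid required")
        return cls(a[:3, 3], float(sp[0]), tuple(int(d) for d in dims))

    def matches(self, other: "VoxelGridSpec", atol: float = 1e-9) -> bool:
        return bool(
            self.dims == other.dims
            and np.isclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )
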