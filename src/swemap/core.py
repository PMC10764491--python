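"""In-memory containers for frames, volumes, masks and point sets.

An :class:`SWVFrame` is a single 2D shear-wave-velocity (or B-mode)
measurement together with its tracked probe pose.  Pixel ``(i, j)`` (row
``i``, column ``j``) sits at in-plane coordinates ``(u, v, 0) =
(j * du, i * dv, 0)`` mm; the pose maps these to world mm.  Rows therefore
index depth below the transducer face and columns the lateral/width axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import RigidPose, VoxelGridSpec

__all__ = ["SWVFrame", "SWVVolume", "SegmentationMask", "MaskedPointSet"]

CHANNELS = ("swv", "bmode")


@dataclass
class SWVFrame:
    """One pose-annotated 2D elastography frame.

    ``values`` are stored as float32 (the on-disk precision), in m/s for
    the ``swv`` channel.  ``valid`` marks pixels carrying a measurement;
    invalid pixels are zeroed.
    """

    values: np.ndarray
    valid: np.ndarray
    pixel_spacing: tuple[float, float]  # (du, dv) mm: column and row pitch
    pose: RigidPose
    timestamp: float = 0.0
    channel: str = "swv"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.ndim != 2 or self.values.shape != self.valid.shape:
            raise ValueError("values and valid must be 2D arrays of equal shape")
        du, dv = (float(s) for s in self.pixel_spacing)
        if du <= 0 or dv <= 0:
            raise ValueError("pixel spacing must be positive")
        self.pixel_spacing = (du, dv)
        if not np.all(np.isfinite(self.values[self.valid])):
            raise ValueError("values must be finite where valid")
        self.values = self.values.copy()
        self.values[~self.valid] = 0.0
        self.timestamp = float(self.timestamp)
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def pixel_plane_coords(self) -> np.ndarray:
        """(rows*cols, 3) in-plane coordinates (u, v, 0) of every pixel."""
        nr, nc = self.values.shape
        du, dv = self.pixel_spacing
        jj, ii = np.meshgrid(np.arange(nc), np.arange(nr))
        return np.column_stack(
            [jj.ravel() * du, ii.ravel() * dv, np.zeros(nr * nc)]
        )

    def pixel_world_coords(self, valid_only: bool = False) -> np.ndarray:
        coords = self.pose.apply(self.pixel_plane_coords())
        if valid_only:
            coords = coords[self.valid.ravel()]
        return coords

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]


@dataclass
class SWVVolume:
    """Gridded 3D scalar field with per-voxel sample counts.

    Voxels that received no sample carry the NaN sentinel and a count of
    zero.  ``fill_mask`` marks voxels whose value was produced by explicit
    hole filling rather than by measurement (these also have count 0).
    """

    grid: VoxelGridSpec
    values: np.ndarray
    counts: np.ndarray
    fill_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.values.shape != self.grid.dims or self.counts.shape != self.grid.dims:
            raise ValueError(
                f"values/counts shape {self.values.shape}/{self.counts.shape} "
                f"does not match grid dims {self.grid.dims}"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        filled = self.fill_mask if self.fill_mask is not None else np.zeros(self.grid.dims, bool)
        sentinel = np.isnan(self.values)
        expected_sentinel = (self.counts == 0) & ~filled
        if not np.array_equal(sentinel, expected_sentinel):
            raise ValueError("NaN sentinel must appear exactly where counts == 0 (and not filled)")

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)


@dataclass
class SegmentationMask:
    """Binary voxel mask on the same grid as its paired volume."""

    grid: VoxelGridSpec
    voxels: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.shape != self.grid.dims:
            raise ValueError("mask shape does not match grid dims")
        if not self.voxels.any():
            raise ValueError("segmentation mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


@dataclass
class MaskedPointSet:
    """World-space point samples of a masked volume (one per defined, masked voxel)."""

    points: np.ndarray  # (N, 3) world mm
    values: np.ndarray  # (N,) m/s
    coverage: float = field(default=float("nan"))  # defined-and-masked / masked
    spacing: float | None = None  # voxel pitch the points were sampled on (mm)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.values = np.asarray(self.values, dtype=float).reshape(-1)
        if len(self.points) != len(self.values):
            raise ValueError("points and values length mismatch")

    def __len__(self) -> int:
        return len(self.values)
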