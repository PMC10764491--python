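"""Freehand 3D compounding: project pose-annotated frames into a voxel grid.

Each valid pixel is transformed by its frame's recorded pose and
accumulated into the voxel containing it (nearest-voxel assignment); the
voxel value is the arithmetic mean of its accumulated samples.  This
compounding rule is order-independent, so any permutation of the input
frames yields an identical volume.  Voxels that receive no sample remain
undefined (NaN sentinel) rather than being interpolated; small-gap hole
filling is available behind an explicit flag.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import MaskedPointSet, SegmentationMask, SWVFrame, SWVVolume
from .geometry import VoxelGridSpec

__all__ = ["auto_grid", "reconstruct", "apply_mask", "fill_small_holes", "mask_from_phantom"]


def auto_grid(frames: list[SWVFrame], spacing_mm: float = 1.0) -> VoxelGridSpec:
    """Axis-aligned bounding grid of all valid pixel positions, padded by
    one voxel on every side."""
    if not frames:
        raise ValueError("empty frame set")
    mins = np.full(3, np.inf)
    maxs = np.full(3, -np.inf)
    any_valid = False
    for f in frames:
        pts = f.pixel_world_coords(valid_only=True)
        if len(pts):
            any_valid = True
            mins = np.minimum(mins, pts.min(axis=0))
            maxs = np.maximum(maxs, pts.max(axis=0))
    if not any_valid:
        raise ValueError("empty frame set (no valid pixels)")
    dims = np.floor((maxs - mins) / spacing_mm).astype(int) + 1 + 2
    origin = mins - spacing_mm
    return VoxelGridSpec(origin=origin, spacing=float(spacing_mm), dims=tuple(dims))


def reconstruct(
    frames: list[SWVFrame], grid: VoxelGridSpec, channel: str = "swv"
) -> SWVVolume:
    """Mean-compound frames of the requested channel into ``grid``."""
    use = [f for f in frames if f.channel == channel]
    if not use:
        raise ValueError(f"no frames with channel {channel!r}")
    sums = np.zeros(grid.n_voxels)
    counts = np.zeros(grid.n_voxels, dtype=np.int64)
    dims = np.array(grid.dims)
    any_inside = False
    for f in use:
        pts = f.pixel_world_coords(valid_only=True)
        if not len(pts):
            continue
        idx = grid.voxel_index(pts)
        inside = grid.contains(idx)
        if not inside.any():
            continue
        any_inside = True
        flat = np.ravel_multi_index(idx[inside].T, dims)
        vals = f.valid_values().astype(float)[inside]
        np.add.at(sums, flat, vals)
        np.add.at(counts, flat, 1)
    if not any_inside:
        raise ValueError("grid does not cover scan")
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return SWVVolume(
        grid=grid,
        values=values.reshape(grid.dims),
        counts=counts.reshape(grid.dims),
    )


def apply_mask(volume: SWVVolume, mask: SegmentationMask) -> MaskedPointSet:
    """Emit the voxels that are both masked and defined, as world points.

    ``coverage`` is the fraction of masked voxels that carry a value; zero
    coverage raises a warning but still returns an (empty) point set.
    """
    if not volume.grid.matches(mask.grid):
        raise ValueError("volume and mask grids do not match")
    sel = mask.voxels & volume.defined
    coverage = float(sel.sum() / mask.n_voxels)
    if sel.sum() == 0:
        warnings.warn("mask does not overlap the defined region (coverage 0)", stacklevel=2)
    idx = np.argwhere(sel)
    return MaskedPointSet(
        points=volume.grid.voxel_centers(idx),
        values=volume.values[sel],
        coverage=coverage,
        spacing=volume.grid.spacing,
    )


def fill_small_holes(volume: SWVVolume, min_neighbors: int = 4) -> SWVVolume:
    """Fill one-voxel holes with the mean of their defined 6-neighbours.

    Off by default everywhere in the pipeline: undefined voxels are never
    silently invented.  Filled voxels keep count 0 and are recorded in the
    returned volume's ``fill_mask``.
    """
    defined = volume.defined
    vals = np.nan_to_num(volume.values, nan=0.0)
    # pad so that np.roll cannot wrap values across opposite faces
    padded_v = np.pad(np.where(defined, vals, 0.0), 1)
    padded_d = np.pad(defined.astype(float), 1)
    nbr_sum = np.zeros_like(vals)
    nbr_cnt = np.zeros_like(vals)
    core = (slice(1, -1),) * 3
    for ax in range(3):
        for shift in (1, -1):
            nbr_sum += np.roll(padded_v, shift, axis=ax)[core]
            nbr_cnt += np.roll(padded_d, shift, axis=ax)[core]
    fill = (~defined) & (nbr_cnt >= min_neighbors)
    values = volume.values.copy()
    values[fill] = nbr_sum[fill] / nbr_cnt[fill]
    prev_fill = volume.fill_mask if volume.fill_mask is not None else np.zeros(defined.shape, bool)
    return SWVVolume(
        grid=volume.grid, values=values, counts=volume.counts.copy(),
        fill_mask=prev_fill | fill,
    )


def mask_from_phantom(phantom, grid: VoxelGridSpec) -> SegmentationMask:
    """Ground-truth segmentation of a phantom rasterized onto a grid
    (stands in for the manual B-mode segmentation of a real scan)."""
    centers = grid.all_centers().reshape(-1, 3)
    voxels = phantom.mask_fn(centers).reshape(grid.dims)
    return SegmentationMask(grid=grid, voxels=voxels)
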