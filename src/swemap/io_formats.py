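"""On-disk formats: frame sets, NIfTI volumes, parameterized-map CSV, YAML.

Frame sets are stored as one multi-page 32-bit-float TIFF (values), one
multi-page TIFF (validity), a CSV pose/timing sidecar (unit quaternion,
scalar first, plus translation) and a JSON manifest.  Volumes and masks
use NIfTI-1 with the grid encoded in the affine; undefined voxels are NaN
and per-voxel sample counts live in a companion NIfTI.  Parameterized
maps use a long-format CSV with one row per cell, including empty cells.

All round trips are lossless to the stated tolerances (values bit-exact,
poses to 1e-12) and file outputs carry no timestamps, so identical inputs
produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import SegmentationMask, SWVFrame, SWVVolume
from .geometry import RigidPose, VoxelGridSpec
from .parameterization import MuscleConfig, ParameterizedMap

__all__ = [
    "write_frameset",
    "read_frameset",
    "write_volume",
    "read_volume",
    "write_mask",
    "read_mask",
    "write_param_maps",
    "read_param_maps",
    "write_param_map",
    "read_param_map",
    "load_yaml",
    "dump_yaml",
]

_FLOAT_FMT = "%.17g"  # round-trips float64 exactly

PARAM_MAP_COLUMNS = [
    "subject",
    "session",
    "muscle",
    "slice_idx",
    "angular_idx",
    "radial_idx",
    "mean_swv_mps",
    "n_voxels",
]


# ---------------------------------------------------------------------------
# frame sets
# ---------------------------------------------------------------------------


def write_frameset(frames: list[SWVFrame], path: str | Path) -> dict:
    """Write a homogeneous frame set to a directory; returns the manifest."""
    if not frames:
        raise ValueError("empty frame set")
    shape = frames[0].shape
    spacing = frames[0].pixel_spacing
    channel = frames[0].channel
    for i, f in enumerate(frames):
        if f.shape != shape or f.pixel_spacing != spacing or f.channel != channel:
            raise ValueError(f"frame {i} has inhomogeneous geometry or channel")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path / "values.tiff",
        np.stack([f.values for f in frames]),
        photometric="minisblack",
    )
    tifffile.imwrite(
        path / "valid.tiff",
        np.stack([f.valid for f in frames]).astype(np.uint8),
        photometric="minisblack",
    )
    rows = []
    for i, f in enumerate(frames):
        q = f.pose.as_quaternion()
        t = f.pose.translation
        rows.append([i, f.timestamp, *q, *t])
    poses = pd.DataFrame(
        rows, columns=["frame", "timestamp_s", "qw", "qx", "qy", "qz", "tx", "ty", "tz"]
    )
    poses.to_csv(path / "poses.csv", index=False, float_format=_FLOAT_FMT)
    manifest = {
        "format": "swemap-frameset-v1",
        "n_frames": len(frames),
        "shape": list(shape),
        "pixel_spacing_mm": list(spacing),
        "channel": channel,
        "files": {"values": "values.tiff", "valid": "valid.tiff", "poses": "poses.csv"},
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def read_frameset(path: str | Path) -> list[SWVFrame]:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    values = tifffile.imread(path / manifest["files"]["values"])
    valid = tifffile.imread(path / manifest["files"]["valid"]).astype(bool)
    values = values.reshape((manifest["n_frames"], *manifest["shape"]))
    valid = valid.reshape(values.shape)
    poses = pd.read_csv(path / manifest["files"]["poses"]).set_index("frame")
    frames = []
    for i in range(manifest["n_frames"]):
        if i not in poses.index:
            raise ValueError(f"pose missing for frame {i}")
        row = poses.loc[i]
        pose = RigidPose.from_quaternion(
            [row.qw, row.qx, row.qy, row.qz], [row.tx, row.ty, row.tz]
        )
        frames.append(
            SWVFrame(
                values=values[i],
                valid=valid[i],
                pixel_spacing=tuple(manifest["pixel_spacing_mm"]),
                pose=pose,
                timestamp=float(row.timestamp_s),
                channel=manifest["channel"],
            )
        )
    return frames


# ---------------------------------------------------------------------------
# volumes and masks (NIfTI-1)
# ---------------------------------------------------------------------------


def _counts_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + "_counts" + suffix)
    raise ValueError("volume path must end in .nii or .nii.gz")


def write_volume(volume: SWVVolume, path: str | Path) -> None:
    """Write values (NaN sentinel) and a companion counts NIfTI."""
    path = Path(path)
    affine = volume.grid.affine()
    nib.save(nib.Nifti1Image(volume.values.astype(np.float64), affine), path)
    nib.save(
        nib.Nifti1Image(volume.counts.astype(np.int32), affine), _counts_path(path)
    )


def read_volume(path: str | Path) -> SWVVolume:
    path = Path(path)
    img = nib.load(path)
    values = np.asarray(img.dataobj, dtype=float)
    grid = VoxelGridSpec.from_affine(img.affine, values.shape)
    cimg = nib.load(_counts_path(path))
    counts = np.asarray(cimg.dataobj).astype(np.int64)
    if counts.shape != values.shape:
        raise ValueError(
            f"counts dims {counts.shape} do not match volume dims {values.shape}"
        )
    return SWVVolume(grid=grid, values=values, counts=counts)


def write_mask(mask: SegmentationMask, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.voxels.astype(np.uint8), mask.grid.affine()), Path(path))


def read_mask(path: str | Path) -> SegmentationMask:
    img = nib.load(Path(path))
    voxels = np.asarray(img.dataobj).astype(bool)
    grid = VoxelGridSpec.from_affine(img.affine, voxels.shape)
    return SegmentationMask(grid=grid, voxels=voxels)


# ---------------------------------------------------------------------------
# parameterized maps (long-format CSV)
# ---------------------------------------------------------------------------


def _map_to_rows(pmap: ParameterizedMap, subject: str, session, muscle: str) -> list:
    rows = []
    S, A, R = pmap.shape
    for s in range(S):
        for a in range(A):
            for r in range(R):
                n = int(pmap.counts[s, a, r])
                mean = pmap.means[s, a, r]
                rows.append(
                    [subject, session, muscle, s, a, r, mean if n > 0 else np.nan, n]
                )
    return rows


def write_param_maps(
    maps: dict[tuple[str, object, str], ParameterizedMap], path: str | Path
) -> None:
    """Write one or more maps keyed by (subject, session, muscle)."""
    rows = []
    for (subject, session, muscle), pmap in maps.items():
        rows.extend(_map_to_rows(pmap, subject, session, muscle))
    df = pd.DataFrame(rows, columns=PARAM_MAP_COLUMNS)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_param_map(
    pmap: ParameterizedMap,
    path: str | Path,
    subject: str = "s01",
    session=1,
    muscle: str = "muscle",
) -> None:
    write_param_maps({(subject, session, muscle): pmap}, path)


def read_param_maps(path: str | Path) -> dict[tuple[str, object, str], ParameterizedMap]:
    df = pd.read_csv(path)
    missing = [c for c in PARAM_MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s) {missing} in parameterized-map file")
    key_cols = PARAM_MAP_COLUMNS[:6]
    if df.duplicated(subset=key_cols).any():
        dup = df[df.duplicated(subset=key_cols)].iloc[0]
        raise ValueError(
            "duplicate cell key "
            f"(subject={dup.subject!r}, session={dup.session!r}, slice={dup.slice_idx}, "
            f"angular={dup.angular_idx}, radial={dup.radial_idx})"
        )
    out: dict[tuple[str, object, str], ParameterizedMap] = {}
    for (subject, session, muscle), grp in df.groupby(["subject", "session", "muscle"], sort=True):
        S = int(grp.slice_idx.max()) + 1
        A = int(grp.angular_idx.max()) + 1
        R = int(grp.radial_idx.max()) + 1
        means = np.full((S, A, R), np.nan)
        counts = np.zeros((S, A, R), dtype=np.int64)
        idx = (grp.slice_idx.to_numpy(), grp.angular_idx.to_numpy(), grp.radial_idx.to_numpy())
        counts[idx] = grp.n_voxels.to_numpy()
        means[idx] = np.where(counts[idx] > 0, grp.mean_swv_mps.to_numpy(), np.nan)
        cfg = MuscleConfig(origin_mode="centroid", n_slices=S, n_angular=A, n_radial=R)
        out[(subject, session, muscle)] = ParameterizedMap(config=cfg, means=means, counts=counts)
    return out


def read_param_map(path: str | Path) -> ParameterizedMap:
    maps = read_param_maps(path)
    if len(maps) != 1:
        raise ValueError(f"expected a single map, found {len(maps)} (subject, session) groups")
    return next(iter(maps.values()))


# ---------------------------------------------------------------------------
# YAML configs
# ---------------------------------------------------------------------------


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return {} if data is None else data


def dump_yaml(data: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
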