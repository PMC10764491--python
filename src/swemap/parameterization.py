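"""Standardized (slice, angular, radial) parameterization of muscle volumes.

The masked volumetric point set is aligned along its distal-proximal axis
by principal component analysis, cut into uniform longitudinal slices,
and each slice is mapped into a polar coordinate system.  Two origin
conventions cover the two muscle archetypes:

* ``circle_fit`` (vastus lateralis style): the polar origin is the centre
  of the least-squares circle fitted to the outer boundary of the slice
  mask, and the angular coordinate is normalized over the mask's angular
  span.
* ``centroid`` (biceps femoris long head style): the polar origin is the
  coordinate centroid of the slice mask and the angular coordinate spans
  the full circle.

Radii are normalized per angular sector relative to the local mask extent
(``r_rel`` in [0, 1]), so cells have uniform *relative* radial and
azimuthal extent.  The sector resolution used for radial normalization is
a fixed internal constant, independent of the requested bin counts; this
makes cell assignment nest exactly across refinements of the output grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .core import MaskedPointSet

__all__ = [
    "MuscleConfig",
    "CircleFit",
    "ParameterizedMap",
    "AggregatedMaps",
    "AxisProfile",
    "principal_axis",
    "slice_partition",
    "fit_circle",
    "outer_boundary",
    "slice_origin",
    "relative_polar",
    "parameterize",
    "aggregate_maps",
    "axis_profile",
    "subject_profiles",
]

ORIGIN_MODES = ("circle_fit", "centroid")
AXES = {"longitudinal": 0, "angular": 1, "radial": 2}

#: Number of fine angular sectors used for per-sector radial normalization.
#: Fixed (not tied to ``n_angular``) so that bin assignment is identical
#: for any requested output resolution.
N_NORM_SECTORS = 64

#: Number of angular bins used when extracting the outer boundary contour.
N_BOUNDARY_BINS = 72


@dataclass(frozen=True)
class MuscleConfig:
    """Parameterization settings for one muscle.

    ``orientation_hint`` resolves the sign of the distal-proximal axis;
    ``secondary_hint`` fixes the in-slice x direction (angular zero) and
    defaults to the world axis most orthogonal to the principal axis.
    """

    origin_mode: str = "circle_fit"
    n_slices: int = 8
    n_angular: int = 6
    n_radial: int = 4
    orientation_hint: tuple[float, float, float] = (0.0, 0.0, 1.0)
    secondary_hint: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.origin_mode not in ORIGIN_MODES:
            raise ValueError(f"origin_mode must be one of {ORIGIN_MODES}")
        for name in ("n_slices", "n_angular", "n_radial"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_slices, self.n_angular, self.n_radial)


VL_CONFIG = MuscleConfig(origin_mode="circle_fit", n_slices=8)
BFLH_CONFIG = MuscleConfig(origin_mode="centroid", n_slices=6)


@dataclass(frozen=True)
class CircleFit:
    center: tuple[float, float]
    radius: float
    rms_residual: float


@dataclass
class ParameterizedMap:
    """Cell array indexed (slice, angular, radial): mean SWV and voxel counts."""

    config: MuscleConfig
    means: np.ndarray  # (S, A, R), NaN where the cell is empty
    counts: np.ndarray  # (S, A, R) int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.means.shape != self.config.shape or self.counts.shape != self.config.shape:
            raise ValueError("map arrays do not match config shape")
        if not np.array_equal(np.isnan(self.means), self.counts == 0):
            raise ValueError("NaN means must appear exactly where counts == 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.config.shape

    @property
    def defined(self) -> np.ndarray:
        return self.counts > 0

    def whole_muscle_mean(self) -> float:
        """Voxel-count-weighted mean SWV over all cells (m/s)."""
        w = self.counts
        if w.sum() == 0:
            raise ValueError("empty map")
        return float(np.nansum(self.means * w) / w.sum())


# ---------------------------------------------------------------------------
# axis alignment
# ---------------------------------------------------------------------------


def principal_axis(
    points: np.ndarray, orientation_hint=(0.0, 0.0, 1.0)
) -> tuple[np.ndarray, np.ndarray]:
    """Dominant principal axis of a 3D point cloud.

    Returns ``(axis, centroid)`` with the axis sign chosen so that
    ``dot(axis, orientation_hint) > 0``.
    """
    p = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(p) < 3:
        raise ValueError("need at least 3 points")
    centroid = p.mean(axis=0)
    cov = np.cov((p - centroid).T)
    w, v = np.linalg.eigh(cov)
    if w[2] <= 0 or (w[2] - w[1]) <= 1e-6 * w[2]:
        raise ValueError("no dominant axis (degenerate covariance)")
    axis = v[:, 2]
    hint = np.asarray(orientation_hint, dtype=float)
    d = float(axis @ hint)
    if abs(d) < 1e-12:
        raise ValueError("orientation hint is orthogonal to the principal axis")
    if d < 0:
        axis = -axis
    return axis, centroid


def _in_slice_basis(axis: np.ndarray, secondary_hint) -> tuple[np.ndarray, np.ndarray]:
    if secondary_hint is None:
        cand = np.eye(3)[np.argmin(np.abs(axis))]
    else:
        cand = np.asarray(secondary_hint, dtype=float)
    e2 = cand - (cand @ axis) * axis
    n = np.linalg.norm(e2)
    if n < 1e-8:
        raise ValueError("secondary hint is parallel to the principal axis")
    e2 /= n
    e3 = np.cross(axis, e2)
    return e2, e3


def slice_partition(z: np.ndarray, n_slices: int) -> np.ndarray:
    """Uniform half-open longitudinal bins over [min(z), max(z)].

    Points exactly on an internal edge go to the higher slice; the
    maximum-z point goes to slice ``n_slices - 1``.
    """
    z = np.asarray(z, dtype=float)
    if len(z) == 0:
        raise ValueError("no points to partition")
    zmin, zmax = z.min(), z.max()
    if zmax == zmin:
        return np.zeros(len(z), dtype=np.int64)
    idx = np.floor((z - zmin) / (zmax - zmin) * n_slices).astype(np.int64)
    return np.clip(idx, 0, n_slices - 1)


# ---------------------------------------------------------------------------
# per-slice polar mapping
# ---------------------------------------------------------------------------


def fit_circle(points2d: np.ndarray) -> CircleFit:
    """Algebraic (Kasa) least-squares circle through 2D points.

    Minimizes ``sum (x^2 + y^2 + D x + E y + F)^2`` via the linear normal
    equations; the residual is reported as the RMS radial distance.
    """
    p = np.asarray(points2d, dtype=float).reshape(-1, 2)
    if len(p) < 3:
        raise ValueError("circle undefined (need at least 3 points)")
    x, y = p[:, 0], p[:, 1]
    A = np.column_stack([x, y, np.ones(len(p))])
    b = -(x**2 + y**2)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise ValueError("circle undefined (collinear points)")
    D, E, F = sol
    cx, cy = -D / 2, -E / 2
    r2 = (D**2 + E**2) / 4 - F
    if r2 <= 0:
        raise ValueError("circle undefined (non-positive radius)")
    r = float(np.sqrt(r2))
    dist = np.hypot(x - cx, y - cy)
    return CircleFit(center=(float(cx), float(cy)), radius=r,
                     rms_residual=float(np.sqrt(np.mean((dist - r) ** 2))))


def outer_boundary(points2d: np.ndarray, n_bins: int = N_BOUNDARY_BINS) -> np.ndarray:
    """Outer boundary of a 2D point cloud: per angular ray (about the
    cloud centroid) the point farthest from the centroid."""
    p = np.asarray(points2d, dtype=float).reshape(-1, 2)
    c = p.mean(axis=0)
    d = p - c
    theta = np.mod(np.arctan2(d[:, 1], d[:, 0]), 2 * np.pi)
    rho = np.hypot(d[:, 0], d[:, 1])
    bins = np.minimum((theta / (2 * np.pi) * n_bins).astype(int), n_bins - 1)
    best = {}
    for i, (b, r) in enumerate(zip(bins, rho)):
        if b not in best or r > rho[best[b]]:
            best[b] = i
    return p[sorted(best.values())]


def slice_origin(points2d: np.ndarray, origin_mode: str) -> np.ndarray:
    """Polar origin of one slice: fitted-circle centre or coordinate centroid."""
    p = np.asarray(points2d, dtype=float).reshape(-1, 2)
    if len(p) < 3:
        raise ValueError("degenerate slice (fewer than 3 points)")
    if origin_mode == "centroid":
        return p.mean(axis=0)
    if origin_mode == "circle_fit":
        return np.asarray(fit_circle(outer_boundary(p)).center)
    raise ValueError(f"origin_mode must be one of {ORIGIN_MODES}")


def relative_polar(
    points2d: np.ndarray,
    origin: np.ndarray,
    origin_mode: str,
    n_norm_sectors: int = N_NORM_SECTORS,
    point_spacing: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Relative polar coordinates ``(r_rel, phi_rel)`` in [0, 1] per point.

    ``phi_rel`` spans the full circle in centroid mode and the mask's
    angular span in circle_fit mode.  ``r_rel`` is normalized per fine
    angular sector between the sector's minimum and maximum radius; flat
    sectors (zero radial extent) map to 0.5 with a warning.

    Each point stands for a sample of finite size ``point_spacing`` (the
    voxel pitch; estimated from the cloud density when not given), so it
    contributes its radius to every sector inside its angular footprint
    ``atan(spacing/2 / rho)``.  Without this, sectors are angularly
    starved near the origin and the per-sector minimum radius is
    systematically inflated by discretization.

    When ``point_spacing`` is given explicitly, each sector's radial
    bounds are additionally extended by half a pitch towards the true
    mask boundary (voxel centres stop half a voxel short of it); without
    an explicit pitch the raw empirical extremes are used, so exact point
    sets normalize exactly to their rims.
    """
    if origin_mode not in ORIGIN_MODES:
        raise ValueError(f"origin_mode must be one of {ORIGIN_MODES}")
    p = np.asarray(points2d, dtype=float).reshape(-1, 2)
    d = p - np.asarray(origin, dtype=float)
    rho = np.hypot(d[:, 0], d[:, 1])
    theta = np.arctan2(d[:, 1], d[:, 0])

    if origin_mode == "centroid":
        phi = np.mod(theta, 2 * np.pi) / (2 * np.pi)
        span = 2 * np.pi
        wrap = True
    else:
        # span-relative angle: locate the largest angular gap and measure
        # from its far edge, so the mask's span maps exactly onto [0, 1]
        th = np.mod(theta, 2 * np.pi)
        ts = np.sort(th)
        gaps = np.diff(ts, append=ts[0] + 2 * np.pi)
        i_gap = int(np.argmax(gaps))
        start = ts[(i_gap + 1) % len(ts)]
        adj = np.mod(th - start, 2 * np.pi)
        span = adj.max()
        phi = adj / span if span > 0 else np.zeros_like(adj)
        wrap = False

    extend_to_boundary = point_spacing is not None
    if point_spacing is None:
        ext = p.max(axis=0) - p.min(axis=0)
        point_spacing = float(np.sqrt(max(ext[0] * ext[1], 1e-12) / len(p)))

    sector = np.minimum((phi * n_norm_sectors).astype(int), n_norm_sectors - 1)
    # angular footprint of each sample, in sector units
    foot = np.arctan(
        (point_spacing / 2) / np.maximum(rho, point_spacing / 2)
    ) / (span if span > 0 else 1.0)
    lo = np.floor((phi - foot) * n_norm_sectors).astype(int)
    hi = np.floor((phi + foot) * n_norm_sectors).astype(int)
    width = np.minimum(hi - lo, n_norm_sectors - 1)

    rmin = np.full(n_norm_sectors, np.inf)
    rmax = np.full(n_norm_sectors, -np.inf)
    for off in range(int(width.max()) + 1):
        m = width >= off
        sec = lo[m] + off
        sec = np.mod(sec, n_norm_sectors) if wrap else np.clip(sec, 0, n_norm_sectors - 1)
        np.minimum.at(rmin, sec, rho[m])
        np.maximum.at(rmax, sec, rho[m])

    if extend_to_boundary:
        half = point_spacing / 2
        finite = np.isfinite(rmin)
        rmin[finite] = np.maximum(rmin[finite] - half, 0.0)
        rmax[finite] = rmax[finite] + half

    extent = rmax - rmin
    flat = extent[sector] <= 0
    r_rel = np.full(len(p), 0.5)
    ok = ~flat
    r_rel[ok] = (rho[ok] - rmin[sector[ok]]) / extent[sector[ok]]
    n_flat_sectors = int(np.sum((extent <= 0) & np.isfinite(rmin)))
    if flat.any() and n_flat_sectors:
        warnings.warn(
            f"{n_flat_sectors} angular sector(s) with zero radial extent; "
            "their points were assigned r_rel = 0.5",
            stacklevel=2,
        )
    return np.clip(r_rel, 0.0, 1.0), np.clip(phi, 0.0, 1.0)


# ---------------------------------------------------------------------------
# end-to-end parameterization and map-level aggregation
# ---------------------------------------------------------------------------


def parameterize(point_set: MaskedPointSet, config: MuscleConfig) -> ParameterizedMap:
    """Map a masked volumetric point set into (slice, angular, radial) cells.

    Every input point lands in exactly one cell; the cell value is the
    arithmetic mean of its member SWV values.
    """
    points, values = point_set.points, point_set.values
    axis, centroid = principal_axis(points, config.orientation_hint)
    e2, e3 = _in_slice_basis(axis, config.secondary_hint)
    rel = points - centroid
    z = rel @ axis
    xy = np.column_stack([rel @ e2, rel @ e3])

    S, A, R = config.shape
    sums = np.zeros((S, A, R))
    r_sums = np.zeros((S, A, R))
    counts = np.zeros((S, A, R), dtype=np.int64)
    s_idx = slice_partition(z, S)
    origins = []
    for s in range(S):
        sel = s_idx == s
        if not sel.any():
            origins.append(None)
            continue
        pts2 = xy[sel]
        origin = slice_origin(pts2, config.origin_mode)
        origins.append(tuple(origin))
        r_rel, phi = relative_polar(
            pts2, origin, config.origin_mode, point_spacing=point_set.spacing
        )
        a = np.minimum((phi * A).astype(int), A - 1)
        r = np.minimum((r_rel * R).astype(int), R - 1)
        np.add.at(sums[s], (a, r), values[sel])
        np.add.at(r_sums[s], (a, r), r_rel)
        np.add.at(counts[s], (a, r), 1)

    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        mean_r_rel = np.where(counts > 0, r_sums / np.maximum(counts, 1), np.nan)
    prov = {
        "axis": axis.tolist(),
        "centroid": centroid.tolist(),
        "in_slice_basis": [e2.tolist(), e3.tolist()],
        "slice_origins": origins,
        "z_range": [float(z.min()), float(z.max())],
        "n_points": int(len(values)),
        "mean_r_rel": mean_r_rel,  # per-cell centroid of the relative radius
    }
    return ParameterizedMap(config=config, means=means, counts=counts, provenance=prov)


def radial_gradient_slope(pmap: ParameterizedMap) -> float:
    """Slope of SWV against relative radius (m/s per unit r_rel).

    Count-weighted least-squares fit of the cell means against each
    cell's empirical mean ``r_rel``.  Using the members' actual radial
    centroids (rather than nominal bin midpoints) removes the binning
    bias that would otherwise shrink the estimate.
    """
    if "mean_r_rel" not in pmap.provenance:
        raise ValueError("map lacks radial centroids; produce it with parameterize()")
    d = pmap.defined
    x = pmap.provenance["mean_r_rel"][d]
    y = pmap.means[d]
    w = pmap.counts[d].astype(float)
    xm = np.average(x, weights=w)
    ym = np.average(y, weights=w)
    return float(np.sum(w * (x - xm) * (y - ym)) / np.sum(w * (x - xm) ** 2))


@dataclass
class AggregatedMaps:
    """Across-subject per-cell mean, SEM and provenance of exclusions."""

    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray  # subjects contributing per cell
    flagged: np.ndarray  # defined in some but not all subjects


def aggregate_maps(maps: list[ParameterizedMap]) -> AggregatedMaps:
    """Unweighted per-cell mean and SEM across subjects.

    Cells empty in a subset of subjects are aggregated over the subjects
    that define them and flagged.
    """
    if not maps:
        raise ValueError("no maps to aggregate")
    arr = np.stack([m.means for m in maps])
    n = np.sum(~np.isnan(arr), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(arr, axis=0)
        sd = np.nanstd(arr, axis=0, ddof=1)
    sem = np.where(n >= 2, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    flagged = (n > 0) & (n < len(maps))
    return AggregatedMaps(mean=mean, sem=sem, n=n, flagged=flagged)


@dataclass
class AxisProfile:
    axis: str
    values: np.ndarray
    sem: np.ndarray | None = None  # None for a single subject


def subject_profiles(maps: list[ParameterizedMap], axis: str) -> np.ndarray:
    """(n_subjects, n_bins) voxel-count-weighted per-subject axis profiles."""
    if axis not in AXES:
        raise ValueError(f"unknown axis {axis!r}; expected one of {sorted(AXES)}")
    collapse = tuple(i for i in range(3) if i != AXES[axis])
    rows = []
    for m in maps:
        w = m.counts
        num = np.nansum(np.where(w > 0, m.means, 0.0) * w, axis=collapse)
        den = w.sum(axis=collapse)
        with np.errstate(invalid="ignore"):
            rows.append(np.where(den > 0, num / np.maximum(den, 1), np.nan))
    return np.array(rows)


def axis_profile(maps: ParameterizedMap | list[ParameterizedMap], axis: str) -> AxisProfile:
    """1D SWV profile along one axis, with across-subject SEM when given
    several maps (within-subject collapse is voxel-count-weighted)."""
    single = isinstance(maps, ParameterizedMap)
    prof = subject_profiles([maps] if single else list(maps), axis)
    if single or prof.shape[0] == 1:
        return AxisProfile(axis=axis, values=prof[0], sem=None)
    n = np.sum(~np.isnan(prof), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(prof, axis=0)
        sd = np.nanstd(prof, axis=0, ddof=1)
    sem = np.where(n >= 2, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    return AxisProfile(axis=axis, values=mean, sem=sem)
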