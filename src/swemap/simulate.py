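"""Simulated freehand elastography scans and test-retest cohorts.

``simulate_scan`` emulates the acquisition: a linear transducer held
parallel to the muscle fibres (image plane spans the long axis and depth)
is swept along the muscle in several laterally offset swipes, producing a
frame every ``frame_spacing_mm`` (sweep speed x the ~2 Hz measurement
rate).  Pixels sample the phantom's ground-truth field at their true world
position plus Gaussian measurement noise; pose jitter models *tracking*
error, i.e. the recorded pose differs from the true sampling pose by an
independent per-frame perturbation.

``simulate_cohort`` is a fast path that skips image formation entirely
and draws parameterized-map cells directly from the additive model

    cell = base + region_offset + subject_effect + session_effect + error,

all Gaussian, under which the expected ICC(2,1) has the closed form
``sigma_subject^2 / (sigma_subject^2 + sigma_error^2)`` when no session
effect is present.

All randomness flows from one integer seed through fixed sub-streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .core import SWVFrame
from .geometry import RigidPose
from .parameterization import MuscleConfig, ParameterizedMap
from .phantom import Phantom

__all__ = ["ScanProtocol", "CohortSpec", "CohortSample", "simulate_scan", "simulate_cohort"]

_STREAM_SCAN = 201
_STREAM_COHORT = 202

#: measurement rate of the elastography device (frames per second)
MEASUREMENT_RATE_HZ = 2.0


@dataclass(frozen=True)
class ScanProtocol:
    """Freehand scan protocol.

    ``frame_spacing_mm`` is the longitudinal distance between consecutive
    frames (sweep speed divided by the 2 Hz measurement rate).
    ``lateral_wobble_mm`` is true, correctly tracked hand motion
    perpendicular to the sweep; ``pose_jitter_*`` are tracking errors
    (recorded pose differs from the true one).
    """

    n_swipes: int = 5
    frame_spacing_mm: float = 2.0
    swipe_lateral_offset_mm: float = 10.0
    pose_jitter_translation_mm: float = 0.0
    pose_jitter_rotation_deg: float = 0.0
    noise_sd_mps: float = 0.0
    frame_width_mm: float = 50.0
    frame_depth_mm: float = 40.0
    pixel_spacing_mm: float = 1.0
    lateral_wobble_mm: float = 0.0
    standoff_mm: float = 2.0
    swipe_length_mm: float | None = None  # default: phantom z extent

    def __post_init__(self) -> None:
        if self.n_swipes < 1:
            raise ValueError("n_swipes must be >= 1")
        for name in ("frame_spacing_mm", "frame_width_mm", "frame_depth_mm", "pixel_spacing_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "swipe_lateral_offset_mm",
            "pose_jitter_translation_mm",
            "pose_jitter_rotation_deg",
            "noise_sd_mps",
            "lateral_wobble_mm",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _base_rotation() -> np.ndarray:
    # frame u axis along world +z (muscle axis), v axis along -y (depth
    # increases downward from the probe face), normal = +x
    e_u = np.array([0.0, 0.0, 1.0])
    e_v = np.array([0.0, -1.0, 0.0])
    return np.column_stack([e_u, e_v, np.cross(e_u, e_v)])


def simulate_scan(
    phantom: Phantom, protocol: ScanProtocol, seed: int = 0, channel: str = "swv"
) -> list[SWVFrame]:
    """Simulate one freehand scan of a phantom.

    Returns ``n_swipes * ceil(swipe_length / frame_spacing)`` frames.  For
    the ``bmode`` channel a simple echogenicity image (bright inside the
    muscle) with all pixels valid is produced instead of SWV samples.

    Raises ``ValueError("empty scan")`` if no frame plane intersects the
    phantom.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _STREAM_SCAN]))
    zmin, zmax = phantom.z_extent
    length = protocol.swipe_length_mm if protocol.swipe_length_mm is not None else zmax - zmin
    n_per_swipe = math.ceil(length / protocol.frame_spacing_mm)
    du = dv = protocol.pixel_spacing_mm
    n_cols = int(round(protocol.frame_width_mm / du))
    n_rows = int(round(protocol.frame_depth_mm / dv))
    jj, ii = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    plane = np.column_stack([jj.ravel() * du, ii.ravel() * dv, np.zeros(n_rows * n_cols)])
    center_uv = np.array([(n_cols - 1) * du / 2, (n_rows - 1) * dv / 2, 0.0])

    y_top = phantom.params.radius_y_mm + protocol.standoff_mm
    x_offsets = (np.arange(protocol.n_swipes) - (protocol.n_swipes - 1) / 2) * (
        protocol.swipe_lateral_offset_mm
    )
    R0 = _base_rotation()

    frames: list[SWVFrame] = []
    t_index = 0
    for x0 in x_offsets:
        z_positions = zmin - protocol.frame_width_mm / 2 + np.arange(n_per_swipe) * (
            protocol.frame_spacing_mm
        )
        if rng.random() < 0.5:  # sweep start randomized distal/proximal
            z_positions = z_positions[::-1]
        for z0 in z_positions:
            wobble = (
                rng.normal(0.0, protocol.lateral_wobble_mm, size=2)
                if protocol.lateral_wobble_mm > 0
                else np.zeros(2)
            )
            actual = RigidPose(R0, np.array([x0 + wobble[0], y_top + wobble[1], z0]))
            world = actual.apply(plane)
            inside = phantom.mask_fn(world)
            if channel == "swv":
                vals = phantom.field_fn(world)
                valid = inside
            elif channel == "bmode":
                vals = np.where(inside, 0.8, 0.1)
                valid = np.ones(len(world), dtype=bool)
            else:
                raise ValueError(f"unknown channel {channel!r}")
            if protocol.noise_sd_mps > 0:
                vals = vals + rng.normal(0.0, protocol.noise_sd_mps, size=len(vals))

            recorded = actual
            if protocol.pose_jitter_translation_mm > 0 or protocol.pose_jitter_rotation_deg > 0:
                rotvec = rng.normal(
                    0.0, np.deg2rad(protocol.pose_jitter_rotation_deg), size=3
                )
                dt = rng.normal(0.0, protocol.pose_jitter_translation_mm, size=3)
                Rj = Rotation.from_rotvec(rotvec).as_matrix()
                c = actual.apply(center_uv)  # jitter rotation pivots on the frame centre
                recorded = RigidPose(
                    Rj @ actual.rotation, Rj @ (actual.translation - c) + c + dt
                )

            frames.append(
                SWVFrame(
                    values=vals.reshape(n_rows, n_cols),
                    valid=valid.reshape(n_rows, n_cols),
                    pixel_spacing=(du, dv),
                    pose=recorded,
                    timestamp=t_index / MEASUREMENT_RATE_HZ,
                    channel=channel,
                )
            )
            t_index += 1

    if not any(f.valid.any() for f in frames):
        raise ValueError("empty scan (no frame plane intersects the phantom)")
    return frames


# ---------------------------------------------------------------------------
# cohort generator (fast path for reliability recovery)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Generative model for a multi-subject test-retest cohort of maps."""

    n_subjects: int = 16
    n_sessions: int = 2
    base_swv: float = 1.6
    sigma_subject: float = 0.2
    sigma_region: float = 0.15
    sigma_error: float = 0.1
    sigma_session: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_sessions < 2:
            raise ValueError("n_sessions must be >= 2 for reliability analysis")
        for name in ("sigma_subject", "sigma_region", "sigma_error", "sigma_session"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def expected_icc(self) -> float:
        """Closed-form ICC(2,1) of the model when sigma_session == 0."""
        den = self.sigma_subject**2 + self.sigma_error**2
        return float("nan") if den == 0 else self.sigma_subject**2 / den


@dataclass
class CohortSample:
    """Simulated cohort plus its ground-truth effects."""

    spec: CohortSpec
    maps: list[list[ParameterizedMap]]  # [subject][session]
    region_offsets: np.ndarray  # (S, A, R)
    subject_effects: np.ndarray  # (n_subjects,)
    session_effects: np.ndarray  # (n_sessions,)

    def session_maps(self, session: int) -> list[ParameterizedMap]:
        return [m[session] for m in self.maps]


def simulate_cohort(
    spec: CohortSpec,
    map_shape: tuple[int, int, int] = (6, 6, 4),
    seed: int | None = None,
    cell_count: int = 100,
) -> CohortSample:
    """Draw per-subject, per-session parameterized maps from the additive
    Gaussian model; every cell carries ``cell_count`` voxels."""
    S, A, R = (int(d) for d in map_shape)
    if min(S, A, R) < 1:
        raise ValueError("map_shape must be positive integers")
    rng = np.random.default_rng(
        np.random.SeedSequence([int(spec.seed if seed is None else seed), _STREAM_COHORT])
    )
    region = rng.normal(0.0, spec.sigma_region, size=(S, A, R))
    subj = rng.normal(0.0, spec.sigma_subject, size=spec.n_subjects)
    sess = (
        rng.normal(0.0, spec.sigma_session, size=spec.n_sessions)
        if spec.sigma_session > 0
        else np.zeros(spec.n_sessions)
    )
    err = rng.normal(0.0, spec.sigma_error, size=(spec.n_subjects, spec.n_sessions, S, A, R))
    cfg = MuscleConfig(origin_mode="centroid", n_slices=S, n_angular=A, n_radial=R)
    counts = np.full((S, A, R), int(cell_count), dtype=np.int64)
    maps = []
    for i in range(spec.n_subjects):
        row = []
        for j in range(spec.n_sessions):
            vals = spec.base_swv + region + subj[i] + sess[j] + err[i, j]
            row.append(ParameterizedMap(config=cfg, means=vals, counts=counts.copy()))
        maps.append(row)
    return CohortSample(
        spec=spec, maps=maps, region_offsets=region, subject_effects=subj, session_effects=sess
    )
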