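"""Configured, reproducible simulate -> reconstruct -> parameterize ->
statistics pipeline.

A single YAML-serializable config (schema-validated, unknown keys
rejected) drives an end-to-end synthetic study: a cohort of subjects with
individual phantoms is scanned twice at rest and once after a simulated
contraction (a uniform SWV increase whose size is coupled to the
subject's simulated eccentric strength), volumes are reconstructed and
parameterized, and the full statistics layer is applied.  Outputs are
NIfTI volumes, long-format map CSVs, tidy statistics CSV/JSON, figure
panels and a run manifest with a config hash; identical config and seed
produce byte-identical CSV outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .core import MaskedPointSet
from .geometry import VoxelGridSpec
from .io_formats import dump_yaml, write_param_maps, write_volume
from .parameterization import (
    MuscleConfig,
    ParameterizedMap,
    aggregate_maps,
    axis_profile,
    parameterize,
)
from .phantom import PhantomParams, make_phantom
from .reconstruction import apply_mask, auto_grid, fill_small_holes, mask_from_phantom, reconstruct
from .reliability import (
    normalized_mehs,
    paired_t,
    regional_association,
    regional_contrast,
    regional_reliability,
    whole_muscle_reliability,
)
from .simulate import ScanProtocol, simulate_scan

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "make_report", "demo_config"]

logger = logging.getLogger(__name__)

_STREAM_PIPELINE = 301

AXES3 = ("radial", "angular", "longitudinal")


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomSection(_Section):
    length_mm: float = 120.0
    radius_x_mm: float = 20.0
    radius_y_mm: float = 15.0
    superellipse_order: float = 2.5
    taper_fraction: float = 0.15
    taper_min_scale: float = 0.4
    base_swv: float = 1.6
    radial_gradient: float = 0.3
    angular_gradient: float = 0.1
    longitudinal_gradient: float = 0.15
    texture_amplitude: float = 0.05
    texture_order: int = 3


class ProtocolSection(_Section):
    n_swipes: int = 5
    frame_spacing_mm: float = 4.0
    swipe_lateral_offset_mm: float = 8.0
    pose_jitter_translation_mm: float = 0.5
    pose_jitter_rotation_deg: float = 0.5
    noise_sd_mps: float = 0.1
    frame_width_mm: float = 50.0
    frame_depth_mm: float = 36.0
    pixel_spacing_mm: float = 1.0
    lateral_wobble_mm: float = 1.0
    standoff_mm: float = 2.0


class MuscleSection(_Section):
    name: str = "vl"
    origin_mode: str = "circle_fit"
    n_slices: int = Field(default=8, ge=1)
    n_angular: int = Field(default=6, ge=1)
    n_radial: int = Field(default=4, ge=1)


class CohortSection(_Section):
    n_subjects: int = Field(default=16, ge=2)
    sigma_subject_mps: float = 0.2  # between-subject SD of base SWV
    contraction_delta_mps: float = 0.2  # mean post-contraction SWV increase
    # strength-linked part of the increase; negative mirrors the observed
    # direction (stronger subjects -> lower post-contraction SWV)
    contraction_coupling_mps: float = -0.1
    mean_force_n: float = 320.0
    force_between_subject_sd_n: float = 40.0
    force_within_subject_sd_n: float = 10.0
    body_mass_kg: float = 67.3
    body_mass_sd_kg: float = 9.2


class PipelineConfig(_Section):
    seed: int = 0
    voxel_spacing_mm: float = Field(default=2.0, gt=0)
    fill_holes: bool = False
    write_volumes: bool = True
    phantom: PhantomSection = PhantomSection()
    protocol: ProtocolSection = ProtocolSection()
    muscle: MuscleSection = MuscleSection()
    cohort: CohortSection = CohortSection()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        from .io_formats import load_yaml

        return cls.model_validate(load_yaml(path))


def demo_config(seed: int = 7) -> PipelineConfig:
    """The bundled synthetic study: 16 subjects, 2 rest sessions, one
    post-contraction session and a strength covariate."""
    return PipelineConfig(seed=seed)


@dataclasses.dataclass
class PipelineResult:
    config: PipelineConfig
    maps_session1: list[ParameterizedMap]
    maps_session2: list[ParameterizedMap]
    maps_post: list[ParameterizedMap]
    covariate: np.ndarray
    stats: dict
    outdir: Path | None = None


def _simulate_subject(cfg: PipelineConfig, subject: int, rng: np.random.Generator):
    """Simulate one subject: phantom, three scans, reconstructions, maps."""
    ph_params = PhantomParams(**cfg.phantom.model_dump())
    subj_base = ph_params.base_swv + rng.normal(0.0, cfg.cohort.sigma_subject_mps)
    strength_z = rng.normal()
    delta = (
        cfg.cohort.contraction_delta_mps + cfg.cohort.contraction_coupling_mps * strength_z
    )
    phantom_seed = int(rng.integers(2**31 - 1))
    phantom = make_phantom(ph_params, seed=phantom_seed, base_swv=subj_base)
    phantom_post = phantom.with_params(base_swv=subj_base + delta)
    protocol = ScanProtocol(**cfg.protocol.model_dump())
    mcfg = MuscleConfig(
        origin_mode=cfg.muscle.origin_mode,
        n_slices=cfg.muscle.n_slices,
        n_angular=cfg.muscle.n_angular,
        n_radial=cfg.muscle.n_radial,
    )

    forces = cfg.cohort.mean_force_n + cfg.cohort.force_between_subject_sd_n * strength_z + (
        rng.normal(0.0, cfg.cohort.force_within_subject_sd_n, size=6)
    )
    mass = max(40.0, cfg.cohort.body_mass_kg + rng.normal(0.0, cfg.cohort.body_mass_sd_kg))
    mehs = normalized_mehs(forces, mass)

    out_maps = []
    volumes = []
    for ph, tag in ((phantom, "pre1"), (phantom, "pre2"), (phantom_post, "post")):
        scan_seed = int(rng.integers(2**31 - 1))
        frames = simulate_scan(ph, protocol, seed=scan_seed)
        grid = auto_grid(frames, cfg.voxel_spacing_mm)
        vol = reconstruct(frames, grid)
        if cfg.fill_holes:
            vol = fill_small_holes(vol)
        mask = mask_from_phantom(ph, grid)
        pts = apply_mask(vol, mask)
        out_maps.append(parameterize(pts, mcfg))
        volumes.append((tag, vol, mask))
    return out_maps, mehs, volumes


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run the full synthetic study; write outputs when ``outdir`` given."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _STREAM_PIPELINE]))
    maps1, maps2, maps_post, mehs_list = [], [], [], []
    volume_records = []
    for subject in range(config.cohort.n_subjects):
        try:
            (m1, m2, mp), mehs, volumes = _simulate_subject(config, subject, rng)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise RuntimeError(f"stage 'simulate' failed for subject {subject}: {exc}") from exc
        maps1.append(m1)
        maps2.append(m2)
        maps_post.append(mp)
        mehs_list.append(mehs)
        volume_records.append(volumes)
    covariate = np.array(mehs_list)

    try:
        stats = _run_statistics(config, maps1, maps2, maps_post, covariate)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'statistics' failed: {exc}") from exc

    result = PipelineResult(
        config=config,
        maps_session1=maps1,
        maps_session2=maps2,
        maps_post=maps_post,
        covariate=covariate,
        stats=stats,
    )
    if outdir is not None:
        outdir = Path(outdir)
        try:
            _write_outputs(result, volume_records, outdir)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage 'write_outputs' failed: {exc}") from exc
        result.outdir = outdir
    return result


def _run_statistics(cfg, maps1, maps2, maps_post, covariate) -> dict:
    whole = whole_muscle_reliability(maps1, maps2)
    regional = {
        domain: regional_reliability(maps1, maps2, domain)
        for domain in ("inter_regional", "inter_subject")
    }
    pre_scalar = np.array([m.whole_muscle_mean() for m in maps1])
    post_scalar = np.array([m.whole_muscle_mean() for m in maps_post])
    global_contrast = paired_t(pre_scalar, post_scalar)
    contrasts = {ax: regional_contrast(maps1, maps_post, ax) for ax in AXES3}
    associations = {ax: regional_association(maps_post, covariate, ax) for ax in AXES3}
    return {
        "whole_muscle_reliability": whole,
        "regional_reliability": regional,
        "global_contrast": global_contrast,
        "regional_contrasts": contrasts,
        "regional_associations": associations,
    }


def _stats_payload(stats: dict) -> dict:
    """JSON-serializable view of the statistics bundle."""
    whole = stats["whole_muscle_reliability"]
    payload = {
        "whole_muscle_reliability": {
            "icc": whole.icc,
            "ci95": list(whole.ci95),
            "sem_mps": whole.sem,
            "band": whole.band,
            "status": whole.status,
        },
        "regional_reliability": {},
        "global_contrast": dataclasses.asdict(stats["global_contrast"]),
        "regional_contrasts": {},
        "regional_associations": {},
    }
    for domain, rr in stats["regional_reliability"].items():
        payload["regional_reliability"][domain] = {
            "icc_median": rr.icc_median,
            "icc_iqr": list(rr.icc_iqr),
            "sem_median_mps": rr.sem_median,
            "sem_iqr_mps": list(rr.sem_iqr),
            "n_undefined": rr.n_undefined,
        }
    for ax, bins in stats["regional_contrasts"].items():
        payload["regional_contrasts"][ax] = [
            {"bin": c.bin, **dataclasses.asdict(c.result)} for c in bins
        ]
    for ax, bins in stats["regional_associations"].items():
        payload["regional_associations"][ax] = [dataclasses.asdict(b) for b in bins]
    return payload


def _write_outputs(result: PipelineResult, volume_records, outdir: Path) -> None:
    cfg = result.config
    outdir.mkdir(parents=True, exist_ok=True)
    config_dict = cfg.model_dump()
    dump_yaml(config_dict, outdir / "config.yaml")

    maps = {}
    for i in range(cfg.cohort.n_subjects):
        sid = f"s{i + 1:02d}"
        maps[(sid, "pre1", cfg.muscle.name)] = result.maps_session1[i]
        maps[(sid, "pre2", cfg.muscle.name)] = result.maps_session2[i]
        maps[(sid, "post", cfg.muscle.name)] = result.maps_post[i]
    write_param_maps(maps, outdir / "maps.csv")

    cov_rows = "subject,normalized_mehs_n_per_kg\n" + "".join(
        f"s{i + 1:02d},{v:.17g}\n" for i, v in enumerate(result.covariate)
    )
    (outdir / "covariates.csv").write_text(cov_rows)

    payload = _stats_payload(result.stats)
    (outdir / "statistics.json").write_text(json.dumps(payload, indent=2, sort_keys=True))

    if cfg.write_volumes:
        voldir = outdir / "volumes"
        voldir.mkdir(exist_ok=True)
        from .io_formats import write_mask

        for i, volumes in enumerate(volume_records):
            sid = f"s{i + 1:02d}"
            for tag, vol, mask in volumes:
                if tag != "pre1":
                    continue  # one representative volume per subject
                write_volume(vol, voldir / f"{sid}_{tag}.nii")
                write_mask(mask, voldir / f"{sid}_{tag}_mask.nii")

    manifest = {
        "tool": "swemap",
        "version": __version__,
        "config_sha256": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
        "numpy": np.__version__,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    make_report(result, outdir / "figures")


def make_report(result: PipelineResult, figdir: str | Path) -> list[Path]:
    """Figure panels: mean-map montage, pre/post axis profiles with SEM
    bands, and per-axis association curves with significant bins solid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not result.maps_session1:
        raise ValueError("empty map set; nothing to report")
    figdir = Path(figdir)
    figdir.mkdir(parents=True, exist_ok=True)
    written = []

    agg = aggregate_maps(result.maps_session1)
    S = agg.mean.shape[0]
    fig, axes = plt.subplots(1, S, figsize=(2.2 * S, 2.6), squeeze=False)
    vmin, vmax = np.nanmin(agg.mean), np.nanmax(agg.mean)
    for s in range(S):
        ax = axes[0, s]
        im = ax.imshow(agg.mean[s], vmin=vmin, vmax=vmax, cmap="viridis", aspect="auto")
        ax.set_title(f"slice {s}", fontsize=8)
        ax.set_xlabel("radial")
        if s == 0:
            ax.set_ylabel("angular")
    fig.colorbar(im, ax=axes.ravel().tolist(), label="SWV (m/s)")
    p = figdir / "mean_map.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    written.append(p)

    fig, axes = plt.subplots(1, 3, figsize=(11, 3.2))
    for ax_name, ax in zip(AXES3, axes):
        for maps, label, color in (
            (result.maps_session1, "pre", "tab:blue"),
            (result.maps_post, "post", "tab:grey"),
        ):
            prof = axis_profile(maps, ax_name)
            x = np.arange(len(prof.values))
            ax.plot(x, prof.values, marker="o", color=color, label=label)
            if prof.sem is not None:
                ax.fill_between(
                    x, prof.values - prof.sem, prof.values + prof.sem,
                    color=color, alpha=0.25, linewidth=0,
                )
        ax.set_xlabel(f"{ax_name} bin")
        ax.set_ylabel("SWV (m/s)")
        ax.legend(fontsize=8)
    fig.tight_layout()
    p = figdir / "axis_profiles.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    written.append(p)

    fig, axes = plt.subplots(1, 3, figsize=(11, 3.2))
    for ax_name, ax in zip(AXES3, axes):
        bins = result.stats["regional_associations"][ax_name]
        x = np.array([b.bin for b in bins])
        rho = np.array([b.rho for b in bins])
        sig = np.array([b.significant for b in bins])
        ax.plot(x, rho, linestyle="--", color="tab:grey", marker="o")
        for i in range(len(x) - 1):  # solid segments where both ends significant
            if sig[i] and sig[i + 1]:
                ax.plot(x[i : i + 2], rho[i : i + 2], linestyle="-", color="black")
        ax.scatter(x[sig], rho[sig], color="black", zorder=3)
        ax.axhline(0, color="k", linewidth=0.5)
        ax.set_xlabel(f"{ax_name} bin")
        ax.set_ylabel("Spearman rho")
    fig.tight_layout()
    p = figdir / "associations.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    written.append(p)
    return written
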