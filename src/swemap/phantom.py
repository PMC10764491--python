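"""Synthetic muscle phantoms with known shear-wave-velocity fields.

A phantom is an elongated muscle-like solid (superellipse cross-section,
linearly tapered over the last 15% of each end, long axis along world z)
plus a smooth, strictly positive SWV field.  The field is the sum of

* a base velocity (m/s),
* a relative-radial gradient ``b_r * r_rel`` where ``r_rel`` is the
  superellipse radius (0 on the axis, 1 on the surface, including taper),
* an angular modulation ``b_phi * r_rel * cos(theta)`` (vanishing on the
  axis so the field stays differentiable),
* a longitudinal gradient ``b_z * (z - z_min) / length``,
* a seeded band-limited random component (low-order 3D cosine series).

Every source of randomness derives from one integer seed through fixed
sub-streams, so identical seeds reproduce identical phantoms bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product

import numpy as np

__all__ = ["PhantomParams", "Phantom", "make_phantom"]

_STREAM_TEXTURE = 101
_STREAM_LIPSCHITZ = 102


@dataclass(frozen=True)
class PhantomParams:
    """Generative coefficients of a phantom.

    Defaults emulate a vastus-lateralis-scale muscle at rest: ~1.6 m/s
    base SWV, stiffer superficially than deep (positive radial gradient),
    a mild angular modulation, a mild proximo-distal gradient and a small
    smooth heterogeneity texture.
    """

    length_mm: float = 200.0
    radius_x_mm: float = 25.0
    radius_y_mm: float = 18.0
    superellipse_order: float = 2.5
    taper_fraction: float = 0.15
    taper_min_scale: float = 0.4
    base_swv: float = 1.6
    radial_gradient: float = 0.3
    angular_gradient: float = 0.1
    longitudinal_gradient: float = 0.15
    texture_amplitude: float = 0.05
    texture_order: int = 3

    def __post_init__(self) -> None:
        if self.base_swv <= 0:
            raise ValueError("base SWV must be positive (shear wave velocity is physical)")
        for name in ("length_mm", "radius_x_mm", "radius_y_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.taper_min_scale <= 1:
            raise ValueError("taper_min_scale must be in (0, 1]")
        if not 0 <= self.taper_fraction < 0.5:
            raise ValueError("taper_fraction must be in [0, 0.5)")
        if self.superellipse_order < 1:
            raise ValueError("superellipse_order must be >= 1")
        if self.texture_amplitude < 0:
            raise ValueError("texture_amplitude must be >= 0")
        low = (
            self.base_swv
            + min(0.0, self.radial_gradient)
            - abs(self.angular_gradient)
            + min(0.0, self.longitudinal_gradient)
            - self.texture_amplitude
        )
        if low <= 0:
            raise ValueError(
                f"field lower bound {low:.3f} m/s is not positive; reduce gradient magnitudes"
            )


class Phantom:
    """Synthetic muscle: geometry predicate + ground-truth SWV field."""

    def __init__(self, params: PhantomParams, seed: int = 0):
        self.params = params
        self.seed = int(seed)
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, _STREAM_TEXTURE]))
        k = params.texture_order
        modes = [m for m in product(range(k), repeat=3) if m != (0, 0, 0)]
        if modes and params.texture_amplitude > 0:
            coeffs = rng.normal(size=len(modes)) / np.array(
                [(1 + sum(m)) ** 2 for m in modes], dtype=float
            )
            coeffs *= params.texture_amplitude / np.sum(np.abs(coeffs))
            phases = rng.uniform(0.0, 2 * np.pi, size=len(modes))
        else:
            coeffs = np.zeros(0)
            phases = np.zeros(0)
        # spatial frequencies (cycles/mm) over the bounding box of the solid
        box = np.array([2 * params.radius_x_mm, 2 * params.radius_y_mm, params.length_mm])
        self._tex_freq = np.array(modes, dtype=float).reshape(-1, 3) / box
        self._tex_coeff = coeffs
        self._tex_phase = phases
        self._lipschitz: float | None = None

    # -- geometry -----------------------------------------------------
    @property
    def z_extent(self) -> tuple[float, float]:
        h = self.params.length_mm / 2
        return (-h, h)

    def _taper_scale(self, z: np.ndarray) -> np.ndarray:
        p = self.params
        half = p.length_mm / 2
        start = half - p.taper_fraction * p.length_mm
        if p.taper_fraction == 0:
            return np.ones_like(z)
        frac = np.clip((np.abs(z) - start) / (p.taper_fraction * p.length_mm), 0.0, 1.0)
        return 1.0 - (1.0 - p.taper_min_scale) * frac

    def relative_radius(self, points: np.ndarray) -> np.ndarray:
        """Superellipse radius: 0 on the long axis, 1 on the (tapered) surface."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        s = self._taper_scale(p[:, 2])
        n = self.params.superellipse_order
        rx = self.params.radius_x_mm * s
        ry = self.params.radius_y_mm * s
        return (np.abs(p[:, 0] / rx) ** n + np.abs(p[:, 1] / ry) ** n) ** (1.0 / n)

    def mask_fn(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        half = self.params.length_mm / 2
        return (self.relative_radius(p) <= 1.0) & (np.abs(p[:, 2]) <= half)

    # -- field --------------------------------------------------------
    def field_fn(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        prm = self.params
        r_rel = self.relative_radius(p)
        theta = np.arctan2(p[:, 1], p[:, 0])
        z_rel = (p[:, 2] + prm.length_mm / 2) / prm.length_mm
        out = (
            prm.base_swv
            + prm.radial_gradient * r_rel
            + prm.angular_gradient * r_rel * np.cos(theta)
            + prm.longitudinal_gradient * z_rel
        )
        if len(self._tex_coeff):
            args = 2 * np.pi * (p @ self._tex_freq.T) + self._tex_phase
            out = out + np.cos(args) @ self._tex_coeff
        return out

    def lipschitz_bound(self, n_samples: int = 20000, safety: float = 1.3) -> float:
        """Conservative bound on the field's spatial gradient (m/s per mm).

        Estimated by central differences at seeded quasi-uniform sample
        points inside the solid, inflated by ``safety``; cached.
        """
        if self._lipschitz is None:
            prm = self.params
            rng = np.random.default_rng(np.random.SeedSequence([self.seed, _STREAM_LIPSCHITZ]))
            lo = np.array([-prm.radius_x_mm, -prm.radius_y_mm, -prm.length_mm / 2])
            hi = -lo
            pts = rng.uniform(lo, hi, size=(n_samples, 3))
            pts = pts[self.mask_fn(pts)]
            h = 0.05
            g2 = np.zeros(len(pts))
            for ax in range(3):
                e = np.zeros(3)
                e[ax] = h
                g2 += ((self.field_fn(pts + e) - self.field_fn(pts - e)) / (2 * h)) ** 2
            self._lipschitz = float(safety * np.sqrt(g2.max()))
        return self._lipschitz

    def with_params(self, **changes) -> "Phantom":
        """New phantom with modified parameters but the same seed."""
        return Phantom(replace(self.params, **changes), seed=self.seed)


def make_phantom(params: PhantomParams | None = None, seed: int = 0, **overrides) -> Phantom:
    """Construct a phantom; keyword overrides patch the default parameters."""
    if params is None:
        params = PhantomParams(**overrides)
    elif overrides:
        params = replace(params, **overrides)
    return Phantom(params, seed=seed)
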