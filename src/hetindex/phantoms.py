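"""Deterministic digital lesion phantoms for validating heterogeneity metrics.

Two families are provided, both bit-reproducible (no randomness):

* **3D spherical phantoms** — a large sphere of radius ``r_max`` (30 voxels
  by default) whose SUV follows a *modified Gaussian* radial profile

      SUV(d) = B + A·exp(−d²/R²),

  with A and B solved so the center reads ``suv_max`` (40 g/ml) and the
  surface ``suv_surface`` (2.0 g/ml); ``R`` is the adjustable size
  parameter, and ``R = 0`` degenerates to the homogeneous baseline
  (constant surface value).  Optionally, small spheres of radius ``r_s``
  at distance ``D`` from the host center model peripheral sub-regions of
  high uptake: each follows its own modified Gaussian from 40 at its
  center down to the host's SUV at its boundary, so the assembly is
  continuous at the r_s surface.

* **2D patterns** — six single-slice distributions exercising features a
  volumetric metric must distinguish: two equal-mean images of different
  roughness, a center-peaked and a center-cold radial profile, quadrants
  and a linear ramp.  They are parameterized analogs that reproduce the
  documented constraints of their graphical counterparts (equal mean of
  5 for patterns 1 and 2, pattern 2 rougher, one ascending profile with
  a negative H), not pixel-for-pixel reproductions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import SUVVolume, TumorMask, ValidationError

FAMILIES = (
    "homogeneous",
    "single_sphere",
    "multi_sphere_N",
    "two_sphere_D",
    "two_sphere_rs",
    "pattern2d",
)

#: Small-sphere placement directions, in order, for N = 1..4: maximally
#: separated axis directions in the central plane.
_DIRECTIONS = np.array(
    [[1.0, 0.0, 0.0], [-1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, -1.0, 0.0]]
)


@dataclass
class PhantomSpec:
    """Parameter record from which a phantom volume is built deterministically.

    ``R`` is the Gaussian size parameter of the large (host) sphere; the
    multi-/two-sphere families fix it at 30 (same as r_max) so the host is a
    smooth broad background.  ``n_spheres``/``D``/``r_s`` describe the
    embedded small spheres; ``background_suv`` fills voxels outside the
    host sphere (0 by default so threshold segmentation at 2.5 recovers the
    sphere interior).
    """

    family: str
    grid_shape: tuple[int, int, int] = (80, 80, 80)
    r_max: float = 30.0
    R: float = 12.0
    suv_max: float = 40.0
    suv_surface: float = 2.0
    n_spheres: int = 1
    D: float = 15.0
    r_s: float = 6.0
    background_suv: float = 0.0
    pattern_id: int = 1

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(
                f"unknown phantom family {self.family!r}; expected one of {FAMILIES}"
            )
        if self.family == "pattern2d":
            return
        if not (self.suv_max > self.suv_surface > 0):
            raise ValidationError(
                f"need suv_max > suv_surface > 0, got {self.suv_max}, {self.suv_surface}"
            )
        if self.R < 0:
            raise ValidationError(f"R must be >= 0, got {self.R}")
        if self.r_max <= 0:
            raise ValidationError(f"r_max must be positive, got {self.r_max}")
        if self.family in ("multi_sphere_N", "two_sphere_D", "two_sphere_rs"):
            if not 1 <= self.n_spheres <= len(_DIRECTIONS):
                raise ValidationError(
                    f"n_spheres must be 1..{len(_DIRECTIONS)}, got {self.n_spheres}"
                )
            if self.r_s <= 0 or self.D < 0:
                raise ValidationError(
                    f"need r_s > 0 and D >= 0, got r_s={self.r_s}, D={self.D}"
                )
            if self.r_s + self.D > self.r_max:
                raise ValidationError(
                    f"small sphere leaves the host: r_s + D = {self.r_s + self.D} "
                    f"> r_max = {self.r_max}"
                )


def homogeneous(grid_shape=(80, 80, 80), **kw) -> PhantomSpec:
    """The R = 0 baseline: constant surface SUV inside the sphere."""
    return PhantomSpec(family="homogeneous", grid_shape=grid_shape, R=0.0, **kw)


def single_sphere(R: float, grid_shape=(80, 80, 80), **kw) -> PhantomSpec:
    return PhantomSpec(family="single_sphere", grid_shape=grid_shape, R=R, **kw)


def multi_sphere(
    n_spheres: int,
    D: float = 15.0,
    r_s: float = 6.0,
    grid_shape=(80, 80, 80),
    family: str = "multi_sphere_N",
    **kw,
) -> PhantomSpec:
    """Host sphere (R = 30) with ``n_spheres`` embedded high-uptake spheres."""
    kw.setdefault("R", 30.0)
    return PhantomSpec(
        family=family, grid_shape=grid_shape, n_spheres=n_spheres, D=D, r_s=r_s, **kw
    )


def gaussian_sphere_profile(
    distance,
    R: float,
    r_max: float = 30.0,
    suv_max: float = 40.0,
    suv_surface: float = 2.0,
):
    """Modified-Gaussian radial SUV profile, pinned at center and surface.

    SUV(d) = B + A·exp(−d²/R²) with SUV(0) = suv_max and
    SUV(r_max) = suv_surface; strictly decreasing on [0, r_max] for R > 0.
    ``R = 0`` returns the homogeneous special case (constant suv_surface).
    Accepts scalars or arrays.
    """
    d = np.asarray(distance, dtype=float)
    if R < 0:
        raise ValidationError(f"R must be >= 0, got {R}")
    if R == 0:
        out = np.full(d.shape, float(suv_surface))
        return out if out.ndim else float(out)
    a = (suv_max - suv_surface) / (1.0 - np.exp(-(r_max**2) / R**2))
    b = suv_max - a
    out = b + a * np.exp(-(d**2) / R**2)
    return out if out.ndim else float(out)


def _center(grid_shape) -> np.ndarray:
    return (np.asarray(grid_shape, dtype=float) - 1.0) / 2.0


def _distance_grid(grid_shape, center) -> np.ndarray:
    axes = [np.arange(n, dtype=float) - c for n, c in zip(grid_shape, center)]
    x = axes[0][:, None, None]
    y = axes[1][None, :, None]
    z = axes[2][None, None, :]
    return np.sqrt(x**2 + y**2 + z**2)


def build_phantom(spec: PhantomSpec) -> SUVVolume:
    """Materialize a spec into an SUV volume (unit voxel spacing).

    The host sphere is centered in the grid.  Small spheres overwrite host
    values inside their radius with a modified Gaussian whose surface value
    equals the host SUV at the boundary point along each voxel's radial
    direction (continuity at r_s); their Gaussian size parameter equals
    r_s.  Raises if a sphere exceeds the grid or small spheres overlap.
    """
    if spec.family == "pattern2d":
        return build_pattern2d(spec.pattern_id, spec.grid_shape[:2])
    shape = tuple(int(n) for n in spec.grid_shape)
    if len(shape) != 3:
        raise ValidationError(f"grid_shape must have 3 axes, got {shape}")
    c = _center(shape)
    if np.any(c - spec.r_max < 0) or np.any(c + spec.r_max > np.asarray(shape) - 1):
        raise ValidationError(
            f"sphere of radius {spec.r_max} exceeds grid of shape {shape}"
        )
    dist = _distance_grid(shape, c)
    values = np.full(shape, float(spec.background_suv))
    inside = dist <= spec.r_max
    r_host = 0.0 if spec.family == "homogeneous" else spec.R
    values[inside] = gaussian_sphere_profile(
        dist[inside], r_host, spec.r_max, spec.suv_max, spec.suv_surface
    )

    if spec.family in ("multi_sphere_N", "two_sphere_D", "two_sphere_rs"):
        centers = c + spec.D * _DIRECTIONS[: spec.n_spheres]
        for i in range(spec.n_spheres):
            for j in range(i + 1, spec.n_spheres):
                if np.linalg.norm(centers[i] - centers[j]) < 2 * spec.r_s:
                    raise ValidationError(
                        f"small spheres {i} and {j} overlap "
                        f"(D={spec.D}, r_s={spec.r_s})"
                    )
        for ck in centers:
            _embed_small_sphere(values, shape, c, ck, spec)
    return SUVVolume(values, spacing=(1.0, 1.0, 1.0))


def _embed_small_sphere(values, shape, host_center, ck, spec: PhantomSpec) -> None:
    """Overwrite host values inside a small sphere at ``ck`` (in place)."""
    dist_s = _distance_grid(shape, ck)
    inside = dist_s <= spec.r_s
    ds = dist_s[inside]
    idx = np.argwhere(inside).astype(float)
    u = idx - ck
    # Boundary point of the small sphere along each voxel's radial direction;
    # voxels at the exact center take the host value at an arbitrary boundary
    # point (the profile there is suv_max regardless).
    norm = np.linalg.norm(u, axis=1, keepdims=True)
    unit = np.divide(u, norm, out=np.tile(_DIRECTIONS[0], (len(u), 1)), where=norm > 0)
    boundary = ck + spec.r_s * unit
    d_host = np.linalg.norm(boundary - host_center, axis=1)
    surface = gaussian_sphere_profile(
        d_host, spec.R, spec.r_max, spec.suv_max, spec.suv_surface
    )
    denom = 1.0 - np.exp(-1.0)  # exp(-r_s^2 / R_s^2) with R_s = r_s
    a = (spec.suv_max - surface) / denom
    b = spec.suv_max - a
    values[inside] = b + a * np.exp(-(ds**2) / spec.r_s**2)


def sphere_mask(spec: PhantomSpec) -> TumorMask:
    """Geometric interior mask (d <= r_max) of a spherical phantom.

    For 2D patterns the full single-slice grid is returned.  This is the
    mask used for phantom feature sweeps: the analytic sphere is the
    lesion by construction, independent of any SUV threshold.
    """
    if spec.family == "pattern2d":
        nx, ny = spec.grid_shape[:2]
        return TumorMask(np.ones((nx, ny, 1), dtype=bool))
    shape = tuple(int(n) for n in spec.grid_shape)
    dist = _distance_grid(shape, _center(shape))
    return TumorMask(dist <= spec.r_max)


def build_pattern2d(pattern_id: int, grid_shape: Sequence[int] = (32, 32)) -> SUVVolume:
    """Six deterministic single-slice SUV patterns.

    1. two equal halves (4 | 6) — mean exactly 5, smooth;
    2. checkerboard of 1 and 9 — mean exactly 5, maximally rough;
    3. center-peaked radial modified Gaussian (descending, H > 0);
    4. four quadrants at 2/4/6/8;
    5. linear ramp from 1 to 9 along the first axis;
    6. center-cold radial parabola rising 2 → 40 toward the rim
       (ascending profile, so its H index is negative).

    Returned as shape ``(nx, ny, 1)`` with unit spacing.
    """
    nx, ny = (int(n) for n in grid_shape[:2])
    if nx < 2 or ny < 2:
        raise ValidationError(f"pattern grid must be at least 2x2, got {(nx, ny)}")
    x = np.arange(nx, dtype=float)[:, None] * np.ones((1, ny))
    y = np.ones((nx, 1)) * np.arange(ny, dtype=float)[None, :]
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    r = np.sqrt((x - cx) ** 2 + (y - cy) ** 2)

    if pattern_id == 1:
        if nx % 2:
            raise ValidationError("pattern 1 needs an even first axis for equal halves")
        img = np.where(x < nx / 2, 4.0, 6.0)
    elif pattern_id == 2:
        img = np.where((x.astype(int) + y.astype(int)) % 2 == 0, 1.0, 9.0)
    elif pattern_id == 3:
        r0 = min(cx, cy)
        img = np.where(
            r <= r0, gaussian_sphere_profile(np.minimum(r, r0), r0 / 2.5, r0), 2.0
        )
    elif pattern_id == 4:
        img = np.where(
            x < nx / 2, np.where(y < ny / 2, 2.0, 4.0), np.where(y < ny / 2, 6.0, 8.0)
        )
    elif pattern_id == 5:
        img = 1.0 + 8.0 * x / (nx - 1)
    elif pattern_id == 6:
        img = 2.0 + 38.0 * (r / r.max()) ** 2
    else:
        raise ValidationError(f"unknown pattern_id {pattern_id}; expected 1..6")
    return SUVVolume(img, spacing=(1.0, 1.0, 1.0))
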