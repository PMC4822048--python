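"""The signed, dimensionless H index of intratumor SUV heterogeneity.

The H index condenses the voxel-wise differential SUV distribution of a
segmented tumor into one number.  Writing ``SUV_i`` for the uptake of the
i-th of the M tumor voxels, ``N_i`` for its number of in-tumor neighbors
(26-connectivity, so 0..26), and ``|ΔSUV|_ij`` for the absolute uptake
difference to its j-th neighbor, the magnitude is

    |H| = (1/M) Σ_i  w_i · (1/N_i) Σ_j |ΔSUV|_ij / SUV_th ,

where ``w_i = d_i / d_max`` is the relative distance of voxel i from the
SUV-weighted tumor center (centroid), so peripheral heterogeneity —
a clinical marker of diffusing, poor-prognosis disease — contributes more
than the same local variation near the center.  Division by the
segmentation threshold ``SUV_th`` makes H dimensionless; the 1/N_i and 1/M
normalizations keep it from growing trivially with tumor size.  Voxels
with no in-mask neighbor contribute 0.

The sign encodes the radial direction of uptake change: the volume-mean
SUV of the whole tumor is compared against that of an inner core (voxels
with ``d_i <= inner_fraction · d_max``, default half the maximal centroid
distance); a descending center-to-periphery profile — whole mean <= inner
mean, ties included — gives +, an ascending profile gives −.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import SUVVolume, TumorMask, ValidationError, check_pair, neighbor_stats


@dataclass
class HConfig:
    """Parameters of the H index.

    suv_th
        Normalizing SUV threshold (g/ml), the same cutoff used for
        segmentation; default 2.5.
    inner_fraction
        Fraction of d_max delimiting the inner core used by the sign rule
        (radial shrink of the tumor toward its center); default 0.5.
    use_physical_spacing
        Measure centroid distances in mm (True, default) or in index units
        (useful for isotropic digital phantom work).  w_i is a ratio, so
        on isotropic grids both choices coincide.
    """

    suv_th: float = 2.5
    inner_fraction: float = 0.5
    use_physical_spacing: bool = True

    def __post_init__(self) -> None:
        if not (self.suv_th > 0 and np.isfinite(self.suv_th)):
            raise ValidationError(f"suv_th must be positive, got {self.suv_th}")
        if not (0 < self.inner_fraction < 1):
            raise ValidationError(
                f"inner_fraction must lie in (0, 1), got {self.inner_fraction}"
            )


@dataclass
class HResult:
    """H index with its intermediates.

    ``h = sign * magnitude``; ``centroid`` is the SUV-weighted tumor center
    (physical mm); ``d_max`` the maximum voxel-to-centroid distance;
    ``d`` and ``w`` the per-voxel distances and weights in the C-scan
    order of the mask's member voxels.
    """

    h: float
    magnitude: float
    sign: int
    centroid: np.ndarray
    d_max: float
    mean_suv_whole: float
    mean_suv_inner: float
    m: int
    d: np.ndarray = field(repr=False, default=None)
    w: np.ndarray = field(repr=False, default=None)


def suv_centroid(volume: SUVVolume, mask: TumorMask) -> np.ndarray:
    """SUV-weighted mean physical position of the tumor voxels.

    Each coordinate is Σ_i SUV_i·x_ni / Σ_i SUV_i over the mask.  Requires
    a non-empty mask with at least one positive SUV.
    """
    check_pair(volume, mask)
    if mask.m < 1:
        raise ValidationError("centroid of an empty mask is undefined")
    suv = volume.values[mask.member]
    total = suv.sum()
    if total <= 0:
        raise ValidationError(
            "all in-mask SUV are zero; the SUV-weighted centroid is undefined"
        )
    pos = volume.positions(mask.indices())
    return (suv[:, np.newaxis] * pos).sum(axis=0) / total


def distance_weights(
    volume: SUVVolume,
    mask: TumorMask,
    centroid: np.ndarray,
    use_physical_spacing: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel centroid distances d_i and weights w_i = d_i / d_max.

    ``centroid`` is in physical units (mm) as returned by
    :func:`suv_centroid`; with ``use_physical_spacing=False`` distances are
    taken in index space instead (the centroid is converted).  For a
    single-voxel mask d_max = 0 and all weights are defined as 0.
    """
    check_pair(volume, mask)
    if mask.m < 1:
        raise ValidationError("distance weights of an empty mask are undefined")
    idx = mask.indices()
    c = np.asarray(centroid, dtype=float)
    if use_physical_spacing:
        pos = volume.positions(idx)
    else:
        pos = idx.astype(float)
        c = c / np.asarray(volume.spacing)
    d = np.linalg.norm(pos - c, axis=1)
    d_max = float(d.max())
    w = d / d_max if d_max > 0 else np.zeros_like(d)
    return d, w


def h_sign(
    volume: SUVVolume,
    mask: TumorMask,
    d: np.ndarray,
    d_max: float,
    inner_fraction: float = 0.5,
) -> int:
    """+1 for a descending, −1 for an ascending radial SUV profile.

    The inner core is {i : d_i <= inner_fraction · d_max}; it is never
    empty (the voxel at minimal d_i always qualifies).  Returns +1 when the
    whole-tumor mean SUV is <= the inner-core mean (ties descending).
    """
    check_pair(volume, mask)
    suv = volume.values[mask.member]
    inner = d <= inner_fraction * d_max
    return 1 if suv.mean() <= suv[inner].mean() else -1


def h_index(
    volume: SUVVolume, mask: TumorMask, config: HConfig | None = None
) -> HResult:
    """Compute the signed H index and its intermediates for one tumor."""
    config = config or HConfig()
    check_pair(volume, mask)
    m = mask.m
    if m < 1:
        raise ValidationError("H index of an empty mask is undefined")
    centroid = suv_centroid(volume, mask)
    d, w = distance_weights(volume, mask, centroid, config.use_physical_spacing)
    d_max = float(d.max())
    suv = volume.values[mask.member]

    sum_abs, counts = neighbor_stats(volume.values, mask.member)
    s_in = sum_abs[mask.member]
    n_in = counts[mask.member]
    term = np.zeros(m)
    has_nb = n_in > 0
    term[has_nb] = w[has_nb] * s_in[has_nb] / (n_in[has_nb] * config.suv_th)
    magnitude = float(term.sum() / m)

    inner = d <= config.inner_fraction * d_max
    mean_whole = float(suv.mean())
    mean_inner = float(suv[inner].mean())
    sign = 1 if mean_whole <= mean_inner else -1
    return HResult(
        h=sign * magnitude,
        magnitude=magnitude,
        sign=sign,
        centroid=centroid,
        d_max=d_max,
        mean_suv_whole=mean_whole,
        mean_suv_inner=mean_inner,
        m=m,
        d=d,
        w=w,
    )
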