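"""Mask-restricted 3D gray-level co-occurrence matrix and Haralick features.

The co-occurrence matrix P(g, h) collects the probability of observing
gray levels g and h at neighboring voxels.  Here the displacement set
covers *all* nearest neighbors at distance d = 1 — 26 offsets in 3D, which
degenerates to 8 on a single-slice grid — and only ordered pairs with both
endpoints inside the tumor mask are counted, so P describes texture within
the tumor alone.  Accumulating every offset together with its negation
makes P symmetric by construction.

Four classic texture statistics are derived from P:

    Energy            Σ p(g,h)²              (uniformity; 1 for constant)
    Contrast          Σ (g−h)²·p(g,h)        (large off-diagonal weight)
    Local Homogeneity Σ p(g,h)/(1+(g−h)²)    (near-diagonal weight)
    Entropy           −Σ p·log p             (randomness; 0 for constant)

SUV is continuous, so it is first quantized to G gray levels (default 64,
the dominant radiomics convention) with equal-width bins spanning the
in-mask min–max range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .core import (
    NEIGHBOR_OFFSETS,
    SUVVolume,
    TumorMask,
    ValidationError,
    _offset_slices,
    check_pair,
)


@dataclass
class QuantizationMap:
    """Equal-width binning of in-mask SUV onto levels 1..G.

    ``edges`` holds the G+1 monotone bin edges over [in-mask min, max];
    the top bin is right-closed so the maximum maps to level G.  A
    constant in-mask SUV maps everything to level 1.
    """

    n_levels: int
    edges: np.ndarray

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValidationError(f"need G >= 2 gray levels, got {self.n_levels}")


def quantize(
    volume: SUVVolume, mask: TumorMask, n_levels: int = 64
) -> tuple[np.ndarray, QuantizationMap]:
    """Quantize in-mask SUV to integer levels 1..G.

    Returns the level grid (0 outside the mask) and the mapping used.
    """
    check_pair(volume, mask)
    if n_levels < 2:
        raise ValidationError(f"need G >= 2 gray levels, got {n_levels}")
    if mask.m < 1:
        raise ValidationError("cannot quantize an empty mask")
    suv = volume.values[mask.member]
    lo, hi = float(suv.min()), float(suv.max())
    levels = np.zeros(volume.shape, dtype=np.int64)
    if hi == lo:
        levels[mask.member] = 1
        edges = np.linspace(lo, lo + 1.0, n_levels + 1)
    else:
        edges = np.linspace(lo, hi, n_levels + 1)
        scaled = (volume.values - lo) / (hi - lo) * n_levels
        lev = np.floor(scaled).astype(np.int64) + 1
        np.clip(lev, 1, n_levels, out=lev)
        levels[mask.member] = lev[mask.member]
    return levels, QuantizationMap(n_levels=n_levels, edges=edges)


@dataclass
class CooccurrenceMatrix:
    """Normalized symmetric co-occurrence probabilities.

    ``p[g-1, h-1]`` is the probability of the ordered level pair (g, h)
    over all in-mask nearest-neighbor displacements; ``total_pairs`` is
    the (even) number of ordered pairs counted, Σ_i N_i.
    """

    p: np.ndarray
    total_pairs: int

    @property
    def n_levels(self) -> int:
        return self.p.shape[0]


def cooccurrence(
    levels: np.ndarray, mask: TumorMask, n_levels: int | None = None
) -> CooccurrenceMatrix:
    """Accumulate the mask-restricted co-occurrence matrix.

    Counts one entry for every ordered in-mask neighbor pair (i → j) over
    all 26 (or, on a single slice, 8) offsets, then normalizes to
    probabilities.  Raises if the mask contains no adjacent voxel pair.
    """
    member = mask.member
    levels = np.asarray(levels)
    if levels.shape != member.shape:
        raise ValidationError(
            f"level grid shape {levels.shape} does not match mask {member.shape}"
        )
    if n_levels is None:
        n_levels = int(levels[member].max()) if mask.m else 0
    if n_levels < 1:
        raise ValidationError("no gray levels present in the mask")
    g = int(n_levels)
    counts = np.zeros(g * g, dtype=np.int64)
    for off in NEIGHBOR_OFFSETS:
        src, dst = _offset_slices(member.shape, off)
        valid = member[dst] & member[src]
        if not valid.any():
            continue
        a = levels[dst][valid] - 1
        b = levels[src][valid] - 1
        counts += np.bincount(a * g + b, minlength=g * g)
    total = int(counts.sum())
    if total == 0:
        raise ValidationError(
            "mask has no adjacent voxel pair; co-occurrence matrix undefined"
        )
    return CooccurrenceMatrix(p=counts.reshape(g, g) / total, total_pairs=total)


class GLCMFeatures(NamedTuple):
    energy: float
    contrast: float
    local_homogeneity: float
    entropy: float


def glcm_features(
    cm: CooccurrenceMatrix, entropy_base: str = "e"
) -> GLCMFeatures:
    """Energy, Contrast, Local Homogeneity and Entropy of a normalized P.

    Entropy uses natural log by default (``entropy_base="2"`` for bits);
    0·log 0 is taken as 0.
    """
    p = cm.p
    g = np.arange(1, cm.n_levels + 1, dtype=float)
    diff2 = (g[:, np.newaxis] - g[np.newaxis, :]) ** 2
    energy = float((p**2).sum())
    contrast = float((diff2 * p).sum())
    homogeneity = float((p / (1.0 + diff2)).sum())
    log = np.log2 if entropy_base == "2" else np.log
    nz = p > 0
    entropy = float(-(p[nz] * log(p[nz])).sum())
    return GLCMFeatures(energy, contrast, homogeneity, entropy)


def texture_features(
    volume: SUVVolume,
    mask: TumorMask,
    n_levels: int = 64,
    entropy_base: str = "e",
) -> GLCMFeatures:
    """Quantize, build the co-occurrence matrix and return the 4 features."""
    levels, qmap = quantize(volume, mask, n_levels)
    cm = cooccurrence(levels, mask, qmap.n_levels)
    return glcm_features(cm, entropy_base=entropy_base)
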