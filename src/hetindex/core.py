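"""Voxel-grid data model: SUV volumes, tumor masks and nearest-neighborhoods.

Coordinate convention
---------------------
Voxel indices are 0-based; the physical position of index ``k`` on an axis
is ``k * spacing`` (mm), i.e. index (0, 0, 0) sits at the physical origin.
Every quantity computed downstream depends only on *relative* distances, so
the origin choice is unobservable; it is fixed here for reproducibility.

Adjacency is 26-connectivity (Chebyshev radius 1) in index space, ignoring
anisotropic spacing: two voxels are neighbors when every index component
differs by at most one and they are not the same voxel.  A single-slice
grid of shape ``(nx, ny, 1)`` automatically degenerates to the planar
8-neighborhood because out-of-grid offsets are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: The 26 index offsets at Chebyshev distance 1 in 3D.
NEIGHBOR_OFFSETS: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
)


class ValidationError(ValueError):
    """An input violates a documented precondition."""


def _as_grid(values: np.ndarray, dtype=None) -> np.ndarray:
    """Coerce to a 3D array, promoting a 2D slice to shape (nx, ny, 1)."""
    arr = np.asarray(values, dtype=dtype)
    if arr.ndim == 2:
        arr = arr[:, :, np.newaxis]
    if arr.ndim != 3:
        raise ValidationError(
            f"expected a 3D (or single-slice 2D) array, got ndim={arr.ndim}"
        )
    if arr.size == 0:
        raise ValidationError("grid must have at least one voxel on every axis")
    return arr


@dataclass
class SUVVolume:
    """A 3D grid of standardized-uptake values with physical voxel spacing.

    Parameters
    ----------
    values
        SUV per voxel (g/ml), shape ``(nx, ny, nz)``; all finite and >= 0.
        A 2D array is accepted and stored as a single-slice 3D grid.
    spacing
        Physical voxel size per axis (mm), strictly positive.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        arr = _as_grid(self.values, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValidationError(
                "SUV values must be finite; clean NaN/Inf voxels before loading"
            )
        if np.any(arr < 0):
            raise ValidationError("SUV values must be non-negative")
        spacing = tuple(float(s) for s in np.atleast_1d(self.spacing))
        if len(spacing) == 2:
            spacing = spacing + (1.0,)
        if len(spacing) != 3 or any(s <= 0 or not np.isfinite(s) for s in spacing):
            raise ValidationError(
                f"spacing must be three positive lengths (mm), got {spacing!r}"
            )
        self.values = arr
        self.spacing = spacing

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def positions(self, indices: np.ndarray) -> np.ndarray:
        """Physical positions (mm) of an ``(M, 3)`` block of voxel indices."""
        return np.asarray(indices, dtype=float) * np.asarray(self.spacing)


@dataclass
class TumorMask:
    """Boolean voxel membership of a segmented tumor / ROI.

    Shape must match the paired :class:`SUVVolume`; ``m`` is the member
    count M.  An empty mask is representable (segmentation may produce one)
    but every feature computation requires M >= 1.
    """

    member: np.ndarray

    def __post_init__(self) -> None:
        self.member = _as_grid(self.member).astype(bool)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.member.shape

    @property
    def m(self) -> int:
        return int(self.member.sum())

    def indices(self) -> np.ndarray:
        """Member voxel indices as an ``(M, 3)`` int array, C-scan order."""
        return np.argwhere(self.member)


def check_pair(volume: SUVVolume, mask: TumorMask) -> None:
    if volume.shape != mask.shape:
        raise ValidationError(
            f"mask shape {mask.shape} does not match volume shape {volume.shape}"
        )


def neighbors(
    index: Sequence[int], mask: TumorMask
) -> list[tuple[int, int, int]]:
    """In-mask voxels adjacent (26-connectivity) to ``index``.

    ``index`` must itself lie inside the grid and inside the mask; the
    result never contains ``index`` and has between 0 and 26 entries.
    """
    idx = tuple(int(k) for k in index)
    if len(idx) != 3:
        raise ValidationError(f"index must be a 3-tuple, got {index!r}")
    shape = mask.shape
    if not all(0 <= k < n for k, n in zip(idx, shape)):
        raise ValidationError(f"index {idx} lies outside grid of shape {shape}")
    if not mask.member[idx]:
        raise ValidationError(f"index {idx} is not inside the mask")
    out = []
    for off in NEIGHBOR_OFFSETS:
        j = tuple(k + o for k, o in zip(idx, off))
        if all(0 <= k < n for k, n in zip(j, shape)) and mask.member[j]:
            out.append(j)
    return out


def _offset_slices(shape, offset):
    """Aligned slice pairs (src, dst) so that ``a[dst]`` and ``a[src]`` are
    the same-size blocks with ``src = dst + offset`` voxel-wise."""
    src, dst = [], []
    for n, o in zip(shape, offset):
        if o >= 0:
            src.append(slice(o, n))
            dst.append(slice(0, n - o))
        else:
            src.append(slice(0, n + o))
            dst.append(slice(-o, n))
    return tuple(src), tuple(dst)


def neighbor_stats(
    values: np.ndarray, member: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel sum of |ΔSUV| to in-mask neighbors and neighbor counts N_i.

    Vectorized over the 26 offsets; returns float and int grids of the same
    shape as the inputs (entries outside the mask are zero).
    """
    values = np.asarray(values, dtype=float)
    member = np.asarray(member, dtype=bool)
    sum_abs = np.zeros(values.shape, dtype=float)
    counts = np.zeros(values.shape, dtype=np.int64)
    for off in NEIGHBOR_OFFSETS:
        src, dst = _offset_slices(values.shape, off)
        valid = member[dst] & member[src]
        if not valid.any():
            continue
        diff = np.abs(values[dst] - values[src])
        sub = sum_abs[dst]
        sub[valid] += diff[valid]
        cnt = counts[dst]
        cnt[valid] += 1
    return sum_abs, counts


def neighbor_counts(mask: TumorMask) -> np.ndarray:
    """Grid of in-mask neighbor counts N_i (0..26; 0 outside the mask)."""
    _, counts = neighbor_stats(np.zeros(mask.shape), mask.member)
    return counts
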