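"""Shared fixtures and independent brute-force oracles.

The oracles re-derive the H index and the co-occurrence counts with plain
Python triple loops, sharing no code with the package's vectorized paths,
so agreement between the two is a genuine cross-check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")

_OFFSETS = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def naive_in_mask_neighbors(member, t):
    """All in-mask 26-neighbors of voxel ``t`` by direct enumeration."""
    shape = member.shape
    out = []
    for off in _OFFSETS:
        j = tuple(a + o for a, o in zip(t, off))
        if all(0 <= a < n for a, n in zip(j, shape)) and member[j]:
            out.append(j)
    return out


def naive_h_index(values, member, suv_th=2.5, inner_fraction=0.5, spacing=(1, 1, 1)):
    """Triple-loop reference for the signed H index."""
    voxels = [tuple(t) for t in np.argwhere(member)]
    m = len(voxels)
    assert m >= 1
    suv = [float(values[t]) for t in voxels]
    total = sum(suv)
    assert total > 0
    centroid = [
        sum(s * t[a] * spacing[a] for s, t in zip(suv, voxels)) / total
        for a in range(3)
    ]
    d = [
        math.sqrt(sum((t[a] * spacing[a] - centroid[a]) ** 2 for a in range(3)))
        for t in voxels
    ]
    d_max = max(d)
    w = [x / d_max if d_max > 0 else 0.0 for x in d]
    magnitude = 0.0
    for t, wi in zip(voxels, w):
        nb = naive_in_mask_neighbors(member, t)
        if nb:
            s = sum(abs(float(values[t]) - float(values[j])) for j in nb)
            magnitude += wi * s / (len(nb) * suv_th)
    magnitude /= m
    inner = [s for x, s in zip(d, suv) if x <= inner_fraction * d_max]
    sign = 1 if total / m <= sum(inner) / len(inner) else -1
    return sign * magnitude


def naive_cooccurrence_counts(levels, member, n_levels):
    """Per-voxel, per-offset loop reference for ordered pair counts."""
    counts = np.zeros((n_levels, n_levels), dtype=np.int64)
    for t in map(tuple, np.argwhere(member)):
        for j in naive_in_mask_neighbors(member, t):
            counts[levels[t] - 1, levels[j] - 1] += 1
    return counts


def random_volume_and_mask(seed, max_edge=8, min_edge=3, mask_p=0.5):
    """A random SUV grid and boolean mask with M >= 1 and positive uptake."""
    rng = np.random.default_rng(seed)
    while True:
        shape = tuple(rng.integers(min_edge, max_edge + 1, size=3))
        values = rng.uniform(0.1, 12.0, size=shape)
        member = rng.random(shape) < mask_p
        if member.sum() >= 1 and values[member].sum() > 0:
            return values, member


@pytest.fixture
def rng():
    return np.random.default_rng(20160128)
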