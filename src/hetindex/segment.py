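"""Threshold-based tumor segmentation.

Clinical FDG-PET practice commonly delineates metabolically active tumor
with a fixed SUV cutoff; 2.5 g/ml is the widely used default adopted here.
The comparison is inclusive (SUV >= SUV_th) so a tumor whose minimum uptake
equals the threshold is kept intact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import SUVVolume, TumorMask, ValidationError


@dataclass
class SegmentationConfig:
    """Threshold segmentation parameters.

    ``suv_th`` is the SUV cutoff in g/ml (> 0).  ``keep_largest_component``
    optionally retains only the largest 26-connected component, for
    multi-focal uptake where a single lesion is wanted; off by default.
    """

    suv_th: float = 2.5
    keep_largest_component: bool = False

    def __post_init__(self) -> None:
        if not (self.suv_th > 0 and np.isfinite(self.suv_th)):
            raise ValidationError(f"suv_th must be positive, got {self.suv_th}")


def segment_by_threshold(
    volume: SUVVolume, config: SegmentationConfig | None = None
) -> TumorMask:
    """Mask of voxels with SUV >= ``config.suv_th``.

    The result may be empty; callers must check ``mask.m >= 1`` before any
    feature computation.
    """
    config = config or SegmentationConfig()
    member = volume.values >= config.suv_th
    if config.keep_largest_component and member.any():
        structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
        labels, n = ndimage.label(member, structure=structure)
        if n > 1:
            sizes = np.bincount(labels.ravel())
            sizes[0] = 0
            member = labels == int(np.argmax(sizes))
    return TumorMask(member)
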