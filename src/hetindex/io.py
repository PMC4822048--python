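"""Reading and writing SUV volumes (NIfTI) and tumor masks.

Inputs must already be SUV-calibrated (g/ml): converting raw PET activity
with injected dose, body mass and decay timing is scanner-workflow
territory and is out of scope here.  NIfTI is the single supported
on-disk dialect; :func:`register_reader` allows plugging in others.
"""

from __future__ import annotations

import os
from typing import Callable

import nibabel as nib
import numpy as np

from .core import SUVVolume, TumorMask, ValidationError, check_pair

_READERS: dict[str, Callable[[str], SUVVolume]] = {}


def register_reader(suffixes: tuple[str, ...], fn: Callable[[str], SUVVolume]) -> None:
    """Register a reader for additional volume formats by file suffix."""
    for s in suffixes:
        _READERS[s] = fn


def _read_nifti(path: str) -> SUVVolume:
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim not in (2, 3):
        raise ValidationError(
            f"{path}: expected a 3D scalar volume, got shape {data.shape}; "
            "time-series/4D inputs must be split into single frames first"
        )
    zooms = img.header.get_zooms()[: data.ndim]
    if len(zooms) < data.ndim or any(z <= 0 for z in zooms):
        raise ValidationError(
            f"{path}: missing or non-positive voxel spacing in the header; "
            "set pixdim to the physical voxel size in mm"
        )
    try:
        return SUVVolume(np.asarray(data, dtype=float), tuple(float(z) for z in zooms))
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def read_volume(path: str) -> SUVVolume:
    """Load an SUV volume with spacing metadata; validates on load."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"volume file not found: {path}")
    for suffix, fn in _READERS.items():
        if path.endswith(suffix):
            return fn(path)
    return _read_nifti(path)


def write_volume(volume: SUVVolume, path: str) -> None:
    """Write a volume as NIfTI with the spacing encoded in the affine."""
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(volume.values.astype(np.float64), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, path)


def read_mask(path: str, volume: SUVVolume) -> TumorMask:
    """Load a binary mask (nonzero = member) and check it matches ``volume``."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"mask file not found: {path}")
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    mask = TumorMask(data != 0)
    check_pair(volume, mask)
    return mask


def write_mask(mask: TumorMask, volume: SUVVolume, path: str) -> None:
    affine = np.diag(list(volume.spacing) + [1.0])
    nib.save(nib.Nifti1Image(mask.member.astype(np.uint8), affine), path)
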