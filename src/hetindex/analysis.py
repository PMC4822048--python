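"""Feature tables, phantom parameter sweeps and outcome correlation.

One row per tumor: voxel count, physical volume, mean/max SUV, the signed
H index and the four GLCM texture features.  ``sweep`` regenerates the
phantom benchmark tables; ``correlate`` is a generic univariate R² utility
for relating any feature column to an outcome column on user-supplied
tables (no patient data ships with the package).
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import SUVVolume, TumorMask, ValidationError, check_pair
from .glcm import texture_features
from .hindex import HConfig, h_index
from .phantoms import PhantomSpec, build_phantom, sphere_mask
from .segment import SegmentationConfig, segment_by_threshold

logger = logging.getLogger("hetindex")

FEATURE_COLUMNS = [
    "tumor_id",
    "m_voxels",
    "volume_ml",
    "mean_suv",
    "max_suv",
    "h_index",
    "h_sign",
    "energy",
    "contrast",
    "local_homogeneity",
    "entropy",
]

SWEEP_COLUMNS = ["family", "R", "N", "D", "r_s"] + FEATURE_COLUMNS


def extract_features(
    volume: SUVVolume,
    mask: TumorMask,
    tumor_id: str = "tumor",
    hconfig: HConfig | None = None,
    glcm_levels: int = 64,
    entropy_base: str = "e",
) -> dict:
    """All per-tumor features as a flat record (one FeatureRecord row)."""
    check_pair(volume, mask)
    if mask.m < 1:
        raise ValidationError(f"{tumor_id}: empty mask; nothing to measure")
    hconfig = hconfig or HConfig()
    res = h_index(volume, mask, hconfig)
    tex = texture_features(volume, mask, glcm_levels, entropy_base)
    suv = volume.values[mask.member]
    logger.info(
        "%s: M=%d centroid=%s d_max=%.3f sign=%+d (whole mean %.3f vs inner %.3f)",
        tumor_id,
        res.m,
        np.round(res.centroid, 3).tolist(),
        res.d_max,
        res.sign,
        res.mean_suv_whole,
        res.mean_suv_inner,
    )
    return {
        "tumor_id": tumor_id,
        "m_voxels": res.m,
        "volume_ml": res.m * volume.voxel_volume_mm3 / 1000.0,
        "mean_suv": float(suv.mean()),
        "max_suv": float(suv.max()),
        "h_index": res.h,
        "h_sign": res.sign,
        "energy": tex.energy,
        "contrast": tex.contrast,
        "local_homogeneity": tex.local_homogeneity,
        "entropy": tex.entropy,
    }


def default_sweep_specs(
    grid: int = 80,
    R_values: Sequence[float] = (0.0, 4.0, 8.0, 12.0),
    N_values: Sequence[int] = (1, 2, 3, 4),
    D_values: Sequence[float] = (10.0, 15.0, 19.0),
    rs_values: Sequence[float] = (6.0, 8.0, 12.0),
) -> list[PhantomSpec]:
    """The benchmark phantom grid: R, N, D and r_s parameter sweeps.

    N varies at r_s = 6, D = 15; D varies at r_s = 6; r_s varies at D = 15;
    the multi-sphere hosts use R = 30.  R = 0 is the homogeneous baseline.
    """
    shape = (grid,) * 3
    specs: list[PhantomSpec] = []
    for R in R_values:
        fam = "homogeneous" if R == 0 else "single_sphere"
        specs.append(PhantomSpec(family=fam, grid_shape=shape, R=float(R)))
    for n in N_values:
        specs.append(
            PhantomSpec(
                family="multi_sphere_N", grid_shape=shape, R=30.0,
                n_spheres=int(n), D=15.0, r_s=6.0,
            )
        )
    for D in D_values:
        specs.append(
            PhantomSpec(
                family="two_sphere_D", grid_shape=shape, R=30.0,
                n_spheres=1, D=float(D), r_s=6.0,
            )
        )
    for rs in rs_values:
        specs.append(
            PhantomSpec(
                family="two_sphere_rs", grid_shape=shape, R=30.0,
                n_spheres=1, D=15.0, r_s=float(rs),
            )
        )
    return specs


def sweep(
    specs: Iterable[PhantomSpec],
    mask_mode: str = "geometric",
    suv_th: float = 2.5,
    hconfig: HConfig | None = None,
    glcm_levels: int = 64,
    entropy_base: str = "e",
) -> pd.DataFrame:
    """Features for a sequence of phantoms, one row each.

    ``mask_mode`` chooses the ROI: ``"geometric"`` (default) uses the
    analytic sphere interior — the lesion by construction — while
    ``"threshold"`` segments at ``suv_th`` like patient data.  An empty
    spec sequence yields an empty table with the full schema.
    """
    if mask_mode not in ("geometric", "threshold"):
        raise ValidationError(f"unknown mask_mode {mask_mode!r}")
    rows = []
    for k, spec in enumerate(specs):
        try:
            volume = build_phantom(spec)
            if mask_mode == "geometric":
                mask = sphere_mask(spec)
            else:
                mask = segment_by_threshold(volume, SegmentationConfig(suv_th=suv_th))
            if mask.m < 1:
                raise ValidationError("segmentation produced an empty mask")
            rec = extract_features(
                volume,
                mask,
                tumor_id=f"{spec.family}_{k}",
                hconfig=hconfig,
                glcm_levels=glcm_levels,
                entropy_base=entropy_base,
            )
        except ValidationError as exc:
            raise ValidationError(
                f"phantom {spec.family} (R={spec.R}, N={spec.n_spheres}, "
                f"D={spec.D}, r_s={spec.r_s}): {exc}"
            ) from exc
        rec.update(
            family=spec.family, R=spec.R, N=spec.n_spheres, D=spec.D, r_s=spec.r_s
        )
        rows.append(rec)
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def write_features_csv(df: pd.DataFrame, path) -> None:
    """Write a feature table so every float round-trips exactly.

    Read back with ``pd.read_csv(..., float_precision="round_trip")`` to
    recover bit-identical values.
    """
    df.to_csv(path, index=False, float_format="%.17g")


def correlate(
    features: pd.DataFrame,
    outcome: Sequence[float],
    feature_cols: Sequence[str] | None = None,
) -> pd.Series:
    """Univariate R² of a linear fit of ``outcome`` on each feature column.

    Requires >= 3 paired observations and non-constant features; returns a
    Series indexed by feature name with values in [0, 1].
    """
    y = np.asarray(outcome, dtype=float)
    if feature_cols is None:
        feature_cols = [
            c
            for c in features.columns
            if c in FEATURE_COLUMNS and c not in ("tumor_id",)
        ]
    if len(y) != len(features):
        raise ValidationError(
            f"{len(features)} feature rows but {len(y)} outcome values"
        )
    if len(y) < 3:
        raise ValidationError("need at least 3 paired observations for R²")
    out = {}
    for col in feature_cols:
        x = np.asarray(features[col], dtype=float)
        if np.ptp(x) == 0:
            raise ValidationError(f"feature {col!r} has zero variance; R² undefined")
        fit = stats.linregress(x, y)
        out[col] = float(fit.rvalue**2)
    return pd.Series(out, name="r_squared")
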