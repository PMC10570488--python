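"""Tract-masked WMH volumetrics and the log-burden predictor table.

WMH volume inside a named fiber tract is the voxelwise AND of the WMH mask
and the (binarized) tract mask, times the voxel volume. Per-tract volumes
are log-transformed (base 10 by default) to form the regression predictor;
zero-volume records are excluded by default, matching the smaller per-tract
Ns a real cohort shows, with an epsilon-offset mode for sensitivity checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InputError, ShapeError

__all__ = [
    "binarize_tract",
    "tract_wmh_volume",
    "log_transform_volumes",
    "tract_volume_table",
]


def binarize_tract(prob_map: np.ndarray, prob_threshold: float = 0.0) -> np.ndarray:
    """Binarize a probabilistic tract map: membership where p > threshold."""
    prob_map = np.asarray(prob_map, dtype=float)
    if prob_map.min() < 0 or prob_map.max() > 1:
        raise InputError(
            f"probability map values must lie in [0,1], got range "
            f"[{prob_map.min():g}, {prob_map.max():g}]"
        )
    return prob_map > prob_threshold


def tract_wmh_volume(wmh_mask: np.ndarray, tract_mask: np.ndarray, voxel_size) -> float:
    """WMH volume (mL) inside a tract: intersection count times voxel volume."""
    wmh_mask = np.asarray(wmh_mask).astype(bool)
    tract_mask = np.asarray(tract_mask).astype(bool)
    if wmh_mask.shape != tract_mask.shape:
        raise ShapeError(f"mask shapes differ: {wmh_mask.shape} vs {tract_mask.shape}")
    vx, vy, vz = (float(v) for v in voxel_size)
    if vx <= 0 or vy <= 0 or vz <= 0:
        raise InputError(f"voxel_size must be positive, got {voxel_size}")
    return float(np.count_nonzero(wmh_mask & tract_mask)) * vx * vy * vz / 1000.0


def log_transform_volumes(
    records: pd.DataFrame,
    base: float = 10.0,
    zero_policy: str = "exclude",
    epsilon: float = 1e-3,
) -> pd.DataFrame:
    """Add ``log_volume`` and ``included`` columns to a per-tract volume table.

    ``records`` must have a ``wmh_volume_ml`` column. With
    ``zero_policy='exclude'`` (default), zero-volume rows get
    ``included=False`` and an undefined (NaN) log volume; with
    ``zero_policy='epsilon'`` every row gets ``log(volume + epsilon)`` and
    stays included.
    """
    if zero_policy not in ("exclude", "epsilon"):
        raise InputError(f"zero_policy must be 'exclude' or 'epsilon', got {zero_policy!r}")
    if base <= 0 or base == 1:
        raise InputError(f"log base must be positive and != 1, got {base}")
    vols = records["wmh_volume_ml"].to_numpy(dtype=float)
    if (vols < 0).any():
        raise InputError("negative WMH volumes in input")
    out = records.copy()
    log_base = np.log(base)
    if zero_policy == "epsilon":
        if epsilon <= 0:
            raise InputError(f"epsilon must be positive, got {epsilon}")
        out["log_volume"] = np.log(vols + epsilon) / log_base
        out["included"] = True
    else:
        log_volume = np.full(vols.shape, np.nan)
        positive = vols > 0
        log_volume[positive] = np.log(vols[positive]) / log_base
        out["log_volume"] = log_volume
        out["included"] = positive
    return out


def tract_volume_table(
    subject_id: str,
    wmh_mask: np.ndarray,
    tract_masks: dict[str, np.ndarray],
    voxel_size,
) -> pd.DataFrame:
    """Per-tract WMH volumes for one subject, in long format."""
    rows = [
        {
            "subject_id": subject_id,
            "tract_name": name,
            "wmh_volume_ml": tract_wmh_volume(wmh_mask, tract, voxel_size),
        }
        for name, tract in tract_masks.items()
    ]
    return pd.DataFrame(rows)
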