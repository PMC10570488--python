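"""Regional amyloid SUVr: composite DMN ROIs normalized to whole cerebellum.

SUVr for a region is the arithmetic mean PET uptake over the region's voxels
divided by the mean uptake over the whole-cerebellum reference mask. Each
composite DMN region is the union of named cortical-parcellation labels
(e.g. MTL = entorhinal + parahippocampal). Subjects whose regional SUVr
falls below an amyloid-positivity floor (default 1.17) are flagged excluded
for that region's analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MappingError, MaskError, ReferenceRegionError, ShapeError
from .image import VolumetricImage

__all__ = [
    "RegionSUVr",
    "composite_dmn_rois",
    "region_mean_uptake",
    "compute_suvr",
    "apply_suvr_floor",
    "suvr_table",
]

DEFAULT_SUVR_FLOOR = 1.17


@dataclass
class RegionSUVr:
    subject_id: str
    region_name: str
    suvr: float
    n_roi_voxels: int
    included: bool = True


def composite_dmn_rois(
    parcellation: np.ndarray,
    label_names: dict[int, str],
    composition: dict[str, list[str]],
) -> dict[str, np.ndarray]:
    """Build one binary mask per composite region from parcellation labels.

    ``composition`` maps region name -> list of label names; each region mask
    is the union of the voxels carrying those labels.

    Raises
    ------
    MappingError
        If a composition references a label name absent from the dictionary,
        or an empty label list.
    """
    parcellation = np.asarray(parcellation)
    value_for_name = {name: value for value, name in label_names.items()}
    masks: dict[str, np.ndarray] = {}
    for region, labels in composition.items():
        if not labels:
            raise MappingError(f"region {region!r} has an empty label list")
        mask = np.zeros(parcellation.shape, dtype=bool)
        for label in labels:
            if label not in value_for_name:
                raise MappingError(
                    f"region {region!r} references unknown parcellation label {label!r}"
                )
            mask |= parcellation == value_for_name[label]
        masks[region] = mask
    return masks


def region_mean_uptake(pet: VolumetricImage | np.ndarray, roi_mask: np.ndarray) -> float:
    """Arithmetic mean uptake over an ROI's voxels."""
    data = pet.data if isinstance(pet, VolumetricImage) else np.asarray(pet)
    roi_mask = np.asarray(roi_mask).astype(bool)
    if data.shape != roi_mask.shape:
        raise ShapeError(f"pet shape {data.shape} != roi shape {roi_mask.shape}")
    if not roi_mask.any():
        raise MaskError("ROI mask is empty")
    return float(data[roi_mask].mean())


def compute_suvr(
    pet: VolumetricImage | np.ndarray,
    roi_mask: np.ndarray,
    reference_mask: np.ndarray,
    subject_id: str = "",
    region_name: str = "",
) -> RegionSUVr:
    """SUVr = mean(ROI uptake) / mean(reference uptake)."""
    roi_mean = region_mean_uptake(pet, roi_mask)
    ref_mean = region_mean_uptake(pet, reference_mask)
    if ref_mean <= 0:
        raise ReferenceRegionError(
            f"reference-region mean uptake must be positive, got {ref_mean:g}"
        )
    return RegionSUVr(
        subject_id=subject_id,
        region_name=region_name,
        suvr=roi_mean / ref_mean,
        n_roi_voxels=int(np.count_nonzero(roi_mask)),
    )


def apply_suvr_floor(records: pd.DataFrame, floor: float = DEFAULT_SUVR_FLOOR) -> pd.DataFrame:
    """Flag records below the amyloid-positivity floor as excluded.

    Strictly-below-floor records are excluded; a record exactly at the floor
    is kept (non-strict boundary).
    """
    if floor < 0:
        raise ValueError(f"floor must be >= 0, got {floor}")
    out = records.copy()
    out["included"] = records["suvr"].to_numpy(dtype=float) >= floor
    return out


def suvr_table(
    subject_id: str,
    pet: VolumetricImage,
    region_masks: dict[str, np.ndarray],
    reference_mask: np.ndarray,
) -> pd.DataFrame:
    """Per-region SUVr for one subject, in long format."""
    rows = []
    for region, mask in region_masks.items():
        r = compute_suvr(pet, mask, reference_mask, subject_id=subject_id, region_name=region)
        rows.append(
            {
                "subject_id": subject_id,
                "region_name": region,
                "suvr": r.suvr,
                "n_roi_voxels": r.n_roi_voxels,
            }
        )
    return pd.DataFrame(rows)
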