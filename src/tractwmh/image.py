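"""Volumetric image container and NIfTI-1 round-trip I/O.

All volumes belonging to one subject live on a single voxel grid, so images
are co-registered by construction and voxelwise operations (masking,
intersection) need no resampling.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .errors import FormatError, ShapeError

__all__ = ["VolumetricImage", "read_volume", "write_volume"]


@dataclass
class VolumetricImage:
    """A 3D scalar grid with physical voxel dimensions in mm.

    Parameters
    ----------
    data
        3D array of voxel values. Stored as float64 for intensity images;
        masks may use any numeric/boolean dtype.
    voxel_size
        Physical edge lengths of one voxel, in mm, per axis.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.2)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ShapeError(f"expected a 3D volume, got ndim={self.data.ndim}")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be three positive mm values, got {self.voxel_size}")
        self.voxel_size = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of a single voxel in cubic millimetres."""
        vx, vy, vz = self.voxel_size
        return vx * vy * vz

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of a single voxel in millilitres (1 mL = 1000 mm^3)."""
        return self.voxel_volume_mm3 / 1000.0

    def same_grid(self, other: "VolumetricImage") -> bool:
        return self.shape == other.shape and np.allclose(self.voxel_size, other.voxel_size)


def write_volume(img: VolumetricImage, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-1, encoding voxel size in the affine."""
    affine = np.diag(list(img.voxel_size) + [1.0])
    data = img.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, affine), os.fspath(path))


def read_volume(path: str | os.PathLike) -> VolumetricImage:
    """Read a NIfTI-1 volume, preserving array values and voxel sizes.

    Raises
    ------
    FormatError
        If the file is missing or not parseable as NIfTI.
    """
    path = os.fspath(path)
    try:
        nii = nib.load(path)
        data = np.asanyarray(nii.dataobj)
        zooms = nii.header.get_zooms()[:3]
    except FileNotFoundError:
        raise FormatError(f"volume file not found: {path}") from None
    except Exception as exc:  # nibabel raises several parser errors
        raise FormatError(f"not a readable NIfTI-1 volume: {path} ({exc})") from exc
    if data.ndim != 3:
        raise FormatError(f"expected a 3D NIfTI volume at {path}, got ndim={data.ndim}")
    return VolumetricImage(data=data, voxel_size=tuple(float(z) for z in zooms))
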