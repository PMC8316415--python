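"""3-D image volumes on a regular grid, with NIfTI round-trip.

Every stage of the pipeline (activity concentration, Hounsfield units,
dose rate) shares one container: a scalar array plus voxel spacing and a
declared unit.  All volumes belonging to one subject must live on the same
grid; co-registration/resampling happens before anything enters the
dosimetry chain.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume", "load_nifti", "save_nifti"]

#: units a volume may declare
_KNOWN_UNITS = {"Bq/ml", "HU", "Gy/s", "Gy", "unitless"}


@dataclass
class ImageVolume:
    """A 3-D scalar field on a regular grid.

    Parameters
    ----------
    values
        3-D array of voxel values.
    spacing
        Voxel edge length per axis in mm; all entries must be positive.
    unit
        One of ``Bq/ml``, ``HU``, ``Gy/s``, ``Gy``, ``unitless``.
    origin
        World-space offset of the first voxel centre, mm.
    frame_start, frame_duration
        For PET frames: acquisition start and duration in seconds.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    unit: str = "unitless"
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    frame_start: float | None = None
    frame_duration: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.values.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        if self.unit not in _KNOWN_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {sorted(_KNOWN_UNITS)}")
        if self.unit == "Bq/ml" and np.any(self.values < 0):
            raise ValueError("activity concentration must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_ml(self) -> float:
        """Voxel volume in ml (= cm^3)."""
        return self.voxel_volume_mm3 / 1000.0

    def same_grid(self, other: "ImageVolume | np.ndarray") -> bool:
        if isinstance(other, ImageVolume):
            return self.shape == other.shape and np.allclose(self.spacing, other.spacing)
        return self.shape == np.asarray(other).shape

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "ImageVolume":
        return replace(self, values=np.asarray(values, dtype=np.float64),
                       unit=self.unit if unit is None else unit)


def save_nifti(volume: ImageVolume, path: str | Path) -> Path:
    """Write a volume to NIfTI; spacing goes into the affine diagonal."""
    path = Path(path)
    affine = np.diag(list(volume.spacing) + [1.0])
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(volume.values.astype(np.float32), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))
    return path


def load_nifti(path: str | Path, unit: str = "unitless") -> ImageVolume:
    """Read a NIfTI file into an :class:`ImageVolume` with a declared unit."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(x) for x in np.asarray(img.affine)[:3, 3])
    return ImageVolume(values=data, spacing=tuple(float(z) for z in zooms),
                       unit=unit, origin=origin)
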