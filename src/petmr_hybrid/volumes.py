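"""In-memory containers for multiparametric lesion volumes and masks.

Volumes are small 3-D grids (axis order x, y, z) with isotropic-or-not voxel
spacing in mm and a physical origin; masks are boolean grids aligned to a
reference volume. NIfTI round-trips go through nibabel with a diagonal affine
built from spacing/origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

MODALITIES = ("PET_SUV", "DCE_SI", "DWI", "ADC")


@dataclass
class ImageVolume:
    """A 3-D scalar volume with physical metadata.

    Invalid voxels (e.g. non-physical ADC values) are stored as NaN.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "PET_SUV"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("volume grid must be a non-empty 3-D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be strictly positive")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def same_grid(self, other: "ImageVolume | LesionMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff


@dataclass
class DceSeries:
    """Six-phase dynamic contrast-enhanced series (index 0 = pre-contrast)."""

    phases: Sequence[ImageVolume]
    phase_interval_s: float = 90.0

    def __post_init__(self) -> None:
        self.phases = list(self.phases)
        if len(self.phases) != 6:
            raise ValueError("a DCE series has exactly 6 phases (1 pre + 5 post)")
        if self.phase_interval_s <= 0:
            raise ValueError("phase interval must be positive")
        ref = self.phases[0]
        for ph in self.phases[1:]:
            if not ref.same_grid(ph):
                raise ValueError("all DCE phases must share grid, spacing and origin")

    @property
    def grid(self) -> ImageVolume:
        return self.phases[0]


@dataclass
class LesionMask:
    """Binary lesion VOI on the grid of a reference volume."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    provenance: str = "manual"  # PET_threshold | manual | truth | transferred

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3-D")
        if not self.data.any():
            raise ValueError("mask is empty")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff


def _grid_from_affine(affine: np.ndarray) -> tuple[tuple, tuple]:
    spacing = tuple(float(s) for s in np.abs(np.diag(affine)[:3]))
    origin = tuple(float(o) for o in affine[:3, 3])
    return spacing, origin


def save_volume(vol: ImageVolume | LesionMask, path: str | Path) -> Path:
    path = Path(path)
    if isinstance(vol, LesionMask):
        data = vol.data.astype(np.uint8)
    else:
        data = vol.data
    img = nib.Nifti1Image(data, vol.affine)
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path, modality: str = "PET_SUV") -> ImageVolume:
    img = nib.load(str(path))
    spacing, origin = _grid_from_affine(img.affine)
    return ImageVolume(np.asarray(img.get_fdata()), spacing, origin, modality)


def load_mask(path: str | Path, provenance: str = "manual") -> LesionMask:
    img = nib.load(str(path))
    spacing, origin = _grid_from_affine(img.affine)
    return LesionMask(np.asarray(img.get_fdata()) > 0.5, spacing, origin, provenance)


def mask_like(volume: ImageVolume, data: np.ndarray, provenance: str) -> LesionMask:
    return LesionMask(data, volume.spacing, volume.origin, provenance)


def volume_like(volume: ImageVolume, data: np.ndarray, modality: str | None = None) -> ImageVolume:
    return replace(volume, data=data, modality=modality or volume.modality)
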