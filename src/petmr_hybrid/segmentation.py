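"""Lesion VOI definition on each modality.

PET lesions are segmented with a fixed fraction-of-maximum threshold (default
40%) restricted to a search region, keeping only the 26-connected component
that contains the regional maximum. DCE subtraction images, rigid
nearest-neighbour mask transfer and two-point mono-exponential ADC maps cover
the MRI side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import DceSeries, ImageVolume, LesionMask, mask_like, volume_like

#: 26-neighbour connectivity in 3-D (all voxels sharing a face, edge or corner)
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class RigidTransform:
    """Rigid body motion: intrinsic rotations about x, y, z (degrees) applied
    about ``center_mm`` (defaults to the physical centre of the target grid),
    followed by a translation in mm."""

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_mm: tuple[float, float, float] | None = None

    @property
    def is_identity(self) -> bool:
        return not np.any(self.rotation_deg) and not np.any(self.translation_mm)

    def matrix(self) -> np.ndarray:
        """3x3 rotation matrix R = Rz @ Ry @ Rx."""
        ax, ay, az = np.deg2rad(self.rotation_deg)
        cx, sx = np.cos(ax), np.sin(ax)
        cy, sy = np.cos(ay), np.sin(ay)
        cz, sz = np.cos(az), np.sin(az)
        rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return rz @ ry @ rx


def _region_to_bool(pet: ImageVolume, search_region) -> np.ndarray:
    """Accept a LesionMask, a boolean array, or an index bounding box
    ((x0,x1),(y0,y1),(z0,z1)) with half-open ranges."""
    if isinstance(search_region, LesionMask):
        if search_region.shape != pet.shape:
            raise ValueError("search region is not on the PET grid")
        return search_region.data
    arr = np.asarray(search_region)
    if arr.dtype == bool and arr.shape == pet.shape:
        return arr
    if arr.shape == (3, 2):
        region = np.zeros(pet.shape, dtype=bool)
        (x0, x1), (y0, y1), (z0, z1) = arr.astype(int)
        region[x0:x1, y0:y1, z0:z1] = True
        return region
    raise ValueError("search region must be a mask, boolean array or 3x2 bounding box")


def segment_pet_voi(
    pet: ImageVolume,
    search_region,
    threshold_fraction: float = 0.40,
) -> LesionMask:
    """Fixed-threshold PET VOI.

    Voxels inside the search region with uptake >= ``threshold_fraction`` times
    the regional maximum are kept, then reduced to the single 26-connected
    component containing the maximum voxel (first maximal voxel in
    lexicographic index order when tied). Deterministic.
    """
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold fraction must be in (0, 1]")
    region = _region_to_bool(pet, search_region)
    if not region.any():
        raise ValueError("empty search region")
    vals = pet.data[region]
    if not np.all(np.isfinite(vals)):
        raise ValueError("PET values inside the search region must be finite")
    vmax = vals.max()
    above = region & (pet.data >= threshold_fraction * vmax)
    if not above.any():  # unreachable: the max always qualifies; guard anyway
        raise ValueError("no voxel reaches the threshold")
    labels, _ = ndimage.label(above, structure=_STRUCT_26)
    # seed: first maximal voxel in lexicographic (C-order) index order
    flat = np.flatnonzero((pet.data == vmax) & region)
    seed = np.unravel_index(flat[0], pet.shape)
    voi = labels == labels[seed]
    return mask_like(pet, voi, provenance="PET_threshold")


def dce_subtraction(series: DceSeries, post_index: int = 2) -> ImageVolume:
    """Voxel-wise post-contrast minus pre-contrast volume.

    The default second post-contrast phase gives the subtraction image lesions
    are outlined on.
    """
    if not 1 <= post_index <= 5:
        raise ValueError("post_index must be between 1 and 5")
    pre = series.phases[0]
    post = series.phases[post_index]
    return volume_like(pre, post.data - pre.data, modality="DCE_SI")


def apply_rigid_to_mask(
    mask: LesionMask, t: RigidTransform, target: ImageVolume
) -> LesionMask:
    """Resample a binary mask onto the target grid after rigid motion, with
    nearest-neighbour interpolation.

    The forward transform maps source physical coordinates p to
    ``R @ (p - c) + c + t``; resampling pulls each target voxel back through
    the inverse. Identity transform on an identical grid returns the mask
    unchanged.
    """
    if (
        t.is_identity
        and mask.shape == target.shape
        and np.allclose(mask.spacing, target.spacing)
        and np.allclose(mask.origin, target.origin)
    ):
        return LesionMask(mask.data.copy(), target.spacing, target.origin, "transferred")
    center = (
        np.asarray(t.center_mm, dtype=float)
        if t.center_mm is not None
        else np.asarray(target.origin) + (np.asarray(target.shape) - 1) * np.asarray(target.spacing) / 2.0
    )
    rot = t.matrix()
    shift = np.asarray(t.translation_mm, dtype=float)
    src_spacing = np.asarray(mask.spacing, dtype=float)
    src_origin = np.asarray(mask.origin, dtype=float)
    tgt_spacing = np.asarray(target.spacing, dtype=float)
    tgt_origin = np.asarray(target.origin, dtype=float)

    # target index -> physical -> inverse rigid -> source physical -> source index
    # i_src = S_src^-1 (R^-1 (S_tgt i_tgt + o_tgt - c - t) + c - o_src)
    rinv = rot.T
    mat = np.diag(1.0 / src_spacing) @ rinv @ np.diag(tgt_spacing)
    off = (1.0 / src_spacing) * (rinv @ (tgt_origin - center - shift) + center - src_origin)
    out = ndimage.affine_transform(
        mask.data.astype(np.uint8),
        mat,
        offset=off,
        output_shape=target.shape,
        order=0,
        mode="constant",
        cval=0,
    ).astype(bool)
    if not out.any():
        raise ValueError("transform moved the entire mask off the target grid")
    return LesionMask(out, target.spacing, target.origin, "transferred")


def adc_map(
    dwi_low: ImageVolume,
    dwi_high: ImageVolume,
    b_low: float = 0.0,
    b_high: float = 1000.0,
) -> ImageVolume:
    """Two-point mono-exponential ADC map in units of 1e-6 mm^2/s.

    ADC = ln(S_low / S_high) / (b_high - b_low), scaled to 1e-6 mm^2/s.
    Voxels with a non-positive signal in either volume, or with a negative
    ADC (signal increase with b), are flagged invalid (NaN).
    """
    if b_high <= b_low:
        raise ValueError("b_high must exceed b_low")
    if not dwi_low.same_grid(dwi_high):
        raise ValueError("DWI volumes must share one grid")
    s_low = dwi_low.data
    s_high = dwi_high.data
    valid = (s_low > 0) & (s_high > 0)
    adc = np.full(s_low.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        adc[valid] = np.log(s_low[valid] / s_high[valid]) / (b_high - b_low) * 1e6
    adc[adc < 0] = np.nan  # non-physical: excluded from VOI statistics
    return volume_like(dwi_low, adc, modality="ADC")
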