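"""Dose-guided ROI construction and dose-volume features.

Builds the region set used throughout the pipeline:

* ``body`` -- external contour from an HU threshold (largest connected
  component, per-slice hole fill),
* ``skin5mm`` -- the subcutaneous layer: body voxels whose anisotropic
  Euclidean distance to the nearest non-body voxel center is <= 5 mm,
* ``ptv100_region`` / ``ptv105_region`` -- PTV sub-volumes receiving
  >= 100% / 105% of the prescription,
* ``v5gy`` -- the dose-guided ROI: skin5mm intersected with the region
  receiving >= 10% of the prescription (5 Gy at 50 Gy).

Thresholds are inclusive (">= x Gy").  DVH volumes are in cc.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from dosederm.core import ImageGrid, StructureMask

DVH_LEVELS_GY = (5, 10, 15, 20, 25, 30, 35, 40, 45, 50)


@dataclass
class RoiSet:
    """Named region masks on the CT grid."""

    body: StructureMask
    skin5mm: StructureMask
    ptv: StructureMask
    ptv100_region: StructureMask
    isodose5: StructureMask
    v5gy: StructureMask

    def as_dict(self) -> dict[str, StructureMask]:
        return {
            "body": self.body, "skin5mm": self.skin5mm, "ptv": self.ptv,
            "ptv100_region": self.ptv100_region, "isodose5": self.isodose5,
            "v5gy": self.v5gy,
        }


@dataclass
class DvhFeatures:
    """Skin V5-V50 plus PTV100%/PTV105% absolute volumes (cc)."""

    skin5mm_v: dict[int, float]
    ptv100: float
    ptv105: float

    def as_dict(self) -> dict[str, float]:
        d = {f"skin5mm_V{x}Gy": v for x, v in self.skin5mm_v.items()}
        d["ptv100"] = self.ptv100
        d["ptv105"] = self.ptv105
        return d


def build_body_mask(ct: ImageGrid, hu_threshold: float = -300.0) -> StructureMask:
    """Patient external mask: threshold, keep largest 3-D component, fill holes.

    Hole filling runs per slice so internal air (lung) is retained inside
    the body even when it opens axially across the stack boundary.
    """
    fg = ct.values > hu_threshold
    if not fg.any():
        raise ValueError("no body found above threshold")
    labels, n = ndimage.label(fg, structure=np.ones((3, 3, 3), dtype=bool))
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    body = labels == np.argmax(counts)
    for k in range(body.shape[0]):
        body[k] = ndimage.binary_fill_holes(body[k])
    return StructureMask("body", body)


def build_skin5mm(body: StructureMask, spacing, depth_mm: float = 5.0) -> StructureMask:
    """Inner margin of the body surface, anisotropic Euclidean distance."""
    mask = body.mask
    if not mask.any():
        return StructureMask("skin5mm", np.zeros_like(mask))
    dist = ndimage.distance_transform_edt(mask, sampling=spacing)
    return StructureMask("skin5mm", mask & (dist <= depth_mm + 1e-9))


def resample_dose_to_ct(dose: ImageGrid, ct: ImageGrid) -> ImageGrid:
    """Trilinear interpolation of the dose grid at CT voxel centers.

    CT voxel centers outside the dose extent evaluate to 0 Gy.  Raises if
    the world extents are disjoint.
    """
    lo_d = np.asarray(dose.origin)
    hi_d = lo_d + (np.asarray(dose.shape) - 1) * np.asarray(dose.spacing)
    lo_c = np.asarray(ct.origin)
    hi_c = lo_c + (np.asarray(ct.shape) - 1) * np.asarray(ct.spacing)
    if np.any(hi_d < lo_c) or np.any(lo_d > hi_c):
        raise ValueError("no overlap between dose and CT extents")
    axes = [
        (ct.origin[a] + ct.spacing[a] * np.arange(ct.shape[a]) - dose.origin[a])
        / dose.spacing[a]
        for a in range(3)
    ]
    coords = np.meshgrid(*axes, indexing="ij")
    values = ndimage.map_coordinates(dose.values, coords, order=1,
                                     mode="constant", cval=0.0)
    return ImageGrid(values, spacing=ct.spacing, origin=ct.origin,
                     frame_id=ct.frame_id)


def build_v5gy_roi(skin5mm: StructureMask, dose_on_ct: ImageGrid,
                   prescription: float, fraction: float = 0.10) -> StructureMask:
    """Dose-guided ROI: skin layer receiving >= fraction x prescription."""
    if not (0 < fraction <= 1):
        raise ValueError("invalid fraction: must lie in (0,1]")
    if skin5mm.mask.shape != dose_on_ct.shape:
        raise ValueError("grid mismatch")
    return StructureMask(
        "v5gy", skin5mm.mask & (dose_on_ct.values >= fraction * prescription)
    )


def build_roi_set(ct: ImageGrid, ptv: StructureMask, dose_on_ct: ImageGrid,
                  prescription: float, hu_threshold: float = -300.0,
                  skin_depth_mm: float = 5.0) -> RoiSet:
    """Derive the full region set from CT, PTV and aligned dose."""
    body = build_body_mask(ct, hu_threshold)
    skin = build_skin5mm(body, ct.spacing, skin_depth_mm)
    isodose5 = StructureMask("isodose5",
                             dose_on_ct.values >= 0.10 * prescription)
    v5gy = build_v5gy_roi(skin, dose_on_ct, prescription)
    ptv100 = StructureMask("ptv100_region",
                           ptv.mask & (dose_on_ct.values >= prescription))
    return RoiSet(body=body, skin5mm=skin, ptv=ptv, ptv100_region=ptv100,
                  isodose5=isodose5, v5gy=v5gy)


def compute_dvh_features(dose_on_ct: ImageGrid, skin5mm: StructureMask,
                         ptv: StructureMask, prescription: float) -> DvhFeatures:
    """V_xGy (cc) over the skin layer plus PTV100%/PTV105% volumes (cc)."""
    if skin5mm.mask.shape != dose_on_ct.shape or ptv.mask.shape != dose_on_ct.shape:
        raise ValueError("grid mismatch")
    vv = dose_on_ct.voxel_volume_cc
    dose = dose_on_ct.values
    skin_dose = dose[skin5mm.mask]
    v = {x: float(np.sum(skin_dose >= x) * vv) for x in DVH_LEVELS_GY}
    ptv_dose = dose[ptv.mask]
    ptv100 = float(np.sum(ptv_dose >= prescription) * vv)
    ptv105 = float(np.sum(ptv_dose >= 1.05 * prescription) * vv)
    return DvhFeatures(skin5mm_v=v, ptv100=ptv100, ptv105=ptv105)
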