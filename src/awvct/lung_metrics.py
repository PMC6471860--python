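"""Lung segmentation, left/right split, lung volumes and LAV%.

Lungs are segmented by attenuation thresholding (< -320 HU), connected
components, slice-wise hole filling and retention of the two largest
lung-sized components; the airway lumen mask is subtracted so tracheal and
bronchial air is not counted as lung or as emphysema.  LAV% is the strict
percentage of region voxels below -950 HU.  Volumes are voxel counts times
voxel volume, reported in ml.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import (
    GeometryError,
    SegmentationFailedError,
    UndefinedMeasureError,
)
from .imaging_io import BinaryMask, CTVolume

#: lung attenuation threshold (HU)
LUNG_THRESHOLD_HU = -320.0
#: emphysema (low attenuation) threshold (HU); strict "<"
LAV_THRESHOLD_HU = -950.0
#: minimum plausible lung component volume (ml)
MIN_LUNG_COMPONENT_ML = 10.0


@dataclass
class LungMeasure:
    """CT lung volumes and low-attenuation percentages for one subject."""

    ct_tlv_ml: float
    rlv_ml: float
    lav_percent_both: float
    lav_percent_right: float
    threshold_hu: float = LAV_THRESHOLD_HU

    def __post_init__(self) -> None:
        if not (0.0 <= self.lav_percent_both <= 100.0):
            raise ValueError("LAV% out of [0, 100]")
        if self.rlv_ml > self.ct_tlv_ml + 1e-6 or min(self.rlv_ml, self.ct_tlv_ml) < 0:
            raise ValueError("need 0 <= rLV <= CT-TLV")


def segment_lungs(
    ct: CTVolume,
    airway_mask: BinaryMask | None = None,
    threshold_hu: float = LUNG_THRESHOLD_HU,
    min_component_ml: float = MIN_LUNG_COMPONENT_ML,
) -> BinaryMask:
    """Segment the lungs; airway lumen (if given) is excluded.

    Air below ``threshold_hu`` that touches the volume border or is smaller
    than a lung is discarded; interior holes (vessels, airway walls) are
    filled slice-wise; the two largest components are kept.
    """
    if airway_mask is not None:
        airway_mask.check_alignment(ct)
    low = ct.values < threshold_hu
    if airway_mask is not None:
        # tracheal/bronchial air would otherwise bridge the two lungs
        low &= ~airway_mask.values
    labels, n = ndimage.label(low)
    if n == 0:
        raise SegmentationFailedError("no voxels below the lung threshold")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    min_vox = min_component_ml * 1000.0 / ct.voxel_volume_mm3
    # drop components touching the in-plane border (outside air)
    border = np.zeros(ct.shape, dtype=bool)
    border[0, :, :] = border[-1, :, :] = True
    border[:, 0, :] = border[:, -1, :] = True
    border_labels = set(np.unique(labels[border])) - {0}
    order = np.argsort(counts)[::-1]
    keep = [lab for lab in order if counts[lab] >= min_vox and lab not in border_labels][:2]
    if not keep:
        raise SegmentationFailedError("no lung-sized air component found")
    lung = np.isin(labels, keep)
    # fill interior holes (axial slice-wise keeps the trachea lumen out)
    for k in range(lung.shape[2]):
        lung[:, :, k] = ndimage.binary_fill_holes(lung[:, :, k])
    if airway_mask is not None:
        lung &= ~airway_mask.values
    if not lung.any():
        raise SegmentationFailedError("lung mask empty after airway subtraction")
    return BinaryMask(lung, ct.spacing, ct.origin)


def split_left_right(lung_mask: BinaryMask) -> tuple[BinaryMask, BinaryMask]:
    """Split a lung mask into (right, left) by centroid x position.

    In the canonical orientation the patient's right lung has the smaller
    x centroid.  A fused mask is cut at the minimum-area sagittal plane
    near the midline; if no cut is possible the split fails.
    """
    vals = lung_mask.values
    if not vals.any():
        raise SegmentationFailedError("empty lung mask")
    labels, n = ndimage.label(vals)
    if n >= 2:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        two = np.argsort(counts)[::-1][:2]
        m1, m2 = labels == two[0], labels == two[1]
        c1 = ndimage.center_of_mass(m1)[0]
        c2 = ndimage.center_of_mass(m2)[0]
        right, left = (m1, m2) if c1 < c2 else (m2, m1)
        # fold any residual small components into the nearer side
        for lab in range(1, n + 1):
            if lab in two:
                continue
            comp = labels == lab
            cx = ndimage.center_of_mass(comp)[0]
            if abs(cx - min(c1, c2)) < abs(cx - max(c1, c2)):
                right |= comp
            else:
                left |= comp
    else:
        # fused: cut at the sagittal plane of minimum cross-section near midline
        nx = vals.shape[0]
        lo, hi = nx // 3, 2 * nx // 3
        per_plane = vals.sum(axis=(1, 2))
        cut = lo + int(np.argmin(per_plane[lo:hi]))
        if per_plane[cut] == np.max(per_plane[lo:hi]):
            raise SegmentationFailedError("fused lungs cannot be split at a sagittal minimum")
        right = vals.copy()
        right[cut:, :, :] = False
        left = vals & ~right
        if not right.any() or not left.any():
            raise SegmentationFailedError("sagittal cut produced an empty side")
    return (
        BinaryMask(right, lung_mask.spacing, lung_mask.origin),
        BinaryMask(left, lung_mask.spacing, lung_mask.origin),
    )


def lav_percent(ct: CTVolume, region: BinaryMask, threshold_hu: float = LAV_THRESHOLD_HU) -> float:
    """Percentage of region voxels strictly below ``threshold_hu``."""
    region.check_alignment(ct)
    n = int(region.values.sum())
    if n == 0:
        raise UndefinedMeasureError("LAV% undefined over an empty region")
    n_low = int(np.count_nonzero(ct.values[region.values] < threshold_hu))
    return 100.0 * n_low / n


def lung_volumes(right: BinaryMask, left: BinaryMask) -> tuple[float, float]:
    """(CT-TLV, rLV) in ml from disjoint right/left masks on a common grid."""
    right.check_alignment(left)
    if np.any(right.values & left.values):
        raise GeometryError("right and left lung masks overlap")
    rlv = right.volume_ml()
    return rlv + left.volume_ml(), rlv


def measure_lungs(
    ct: CTVolume,
    airway_mask: BinaryMask | None = None,
    lav_threshold_hu: float = LAV_THRESHOLD_HU,
) -> tuple[LungMeasure, BinaryMask, BinaryMask]:
    """Full lung pipeline: segment, split, volumes, LAV% (both + right)."""
    lungs = segment_lungs(ct, airway_mask)
    right, left = split_left_right(lungs)
    ct_tlv, rlv = lung_volumes(right, left)
    measure = LungMeasure(
        ct_tlv_ml=ct_tlv,
        rlv_ml=rlv,
        lav_percent_both=lav_percent(ct, lungs, lav_threshold_hu),
        lav_percent_right=lav_percent(ct, right, lav_threshold_hu),
        threshold_hu=lav_threshold_hu,
    )
    return measure, right, left
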