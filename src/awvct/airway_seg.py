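"""Airway-tree segmentation by seeded iterative-threshold region growing.

The air-filled lumen is grown from a trachea seed: starting at a
conservative HU threshold, the connected component containing the seed is
extracted, then the threshold is relaxed stepwise toward a maximum.  When a
step multiplies the region volume by more than the leakage factor the
region has escaped into the parenchyma, and the previous (last safe)
threshold is kept — the standard "volume explosion rollback".  The output
is always a single connected component containing the seed; the segmented
tree is the lumen, not the wall.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import (
    InvalidParameterError,
    InvalidSeedError,
    SeedNotFoundError,
    SegmentationFailedError,
)
from .imaging_io import BinaryMask, CTVolume

log = logging.getLogger(__name__)

#: minimum plausible tracheal cross-sectional area (mm^2)
MIN_TRACHEA_AREA_MM2 = 20.0
#: air threshold used when hunting for the trachea (HU)
TRACHEA_AIR_HU = -900.0


@dataclass
class SegParams:
    """Region-growing parameters (all HU thresholds are upper bounds)."""

    initial_threshold_hu: float = -960.0
    step_hu: float = 4.0
    max_threshold_hu: float = -850.0
    leakage_factor: float = 2.0
    connectivity: int = 26
    max_iterations: int = 200

    def __post_init__(self) -> None:
        if self.step_hu <= 0:
            raise InvalidParameterError("threshold step must be > 0")
        if self.leakage_factor <= 1:
            raise InvalidParameterError("leakage factor must be > 1")
        if self.connectivity not in (6, 26):
            raise InvalidParameterError("connectivity must be 6 or 26")

    @property
    def structure(self) -> np.ndarray:
        return ndimage.generate_binary_structure(3, 1 if self.connectivity == 6 else 3)

    def thresholds(self) -> np.ndarray:
        if self.initial_threshold_hu > self.max_threshold_hu:
            return np.array([self.max_threshold_hu])
        t = np.arange(self.initial_threshold_hu, self.max_threshold_hu + 1e-9, self.step_hu)
        return t[: self.max_iterations]


def find_trachea_seed(ct: CTVolume) -> tuple[int, int, int]:
    """Locate a voxel inside the trachea near the cranial end of the scan.

    Within the top 10% of axial slices, air components (< -900 HU) of
    plausible tracheal area (> 20 mm^2 mean in-plane area) and roughly
    circular shape are candidates; the one whose centroid is nearest the
    in-plane center wins.
    """
    nz = ct.shape[2]
    slab_lo = max(0, int(np.ceil(nz * 0.9)) - 1)
    slab = ct.values[:, :, slab_lo:] < TRACHEA_AIR_HU
    if not slab.any():
        raise SeedNotFoundError("no air voxels below -900 HU in the cranial slab")
    labels, n = ndimage.label(slab, structure=ndimage.generate_binary_structure(3, 3))
    in_plane_area = ct.spacing[0] * ct.spacing[1]
    center = np.array([(ct.shape[0] - 1) / 2.0, (ct.shape[1] - 1) / 2.0])
    best = None
    for lab in range(1, n + 1):
        comp = labels == lab
        n_slices = int(np.count_nonzero(comp.any(axis=(0, 1))))
        mean_area = comp.sum() / n_slices * in_plane_area
        if mean_area <= MIN_TRACHEA_AREA_MM2:
            continue
        idx = np.argwhere(comp)
        centroid = idx[:, :2].mean(axis=0)
        # near-circular: in-plane bounding box aspect ratio below 3
        spans = idx[:, :2].max(axis=0) - idx[:, :2].min(axis=0) + 1
        if max(spans) / max(min(spans), 1) > 3.0:
            continue
        dist = float(np.linalg.norm(centroid - center))
        if best is None or dist < best[0]:
            best = (dist, lab, idx)
    if best is None:
        raise SeedNotFoundError("no plausible tracheal air component in the cranial slab")
    _, lab, idx = best
    # take the voxel nearest the in-plane centroid at the component's median
    # slice — interior to the lumen, away from blurred end caps
    mid_k = int(np.median(idx[:, 2]))
    mid = idx[idx[:, 2] == mid_k]
    centroid = mid[:, :2].mean(axis=0)
    j = int(np.argmin(np.linalg.norm(mid[:, :2] - centroid, axis=1)))
    i0, j0, k0 = mid[j]
    return int(i0), int(j0), int(k0 + slab_lo)


def grow_airway_tree(
    ct: CTVolume,
    seed: tuple[int, int, int],
    params: SegParams | None = None,
    return_info: bool = False,
):
    """Grow the airway lumen from ``seed`` with leakage rollback.

    Returns the final :class:`BinaryMask` (and, with ``return_info``, a dict
    recording the accepted threshold and whether rollback fired).
    """
    params = params or SegParams()
    seed = tuple(int(s) for s in seed)
    thresholds = params.thresholds()
    seed_hu = float(ct.values[seed])
    if seed_hu >= thresholds[0]:
        raise InvalidSeedError(
            f"seed HU {seed_hu:.0f} is not below the initial threshold {thresholds[0]:.0f}"
        )
    structure = params.structure
    prev_mask = None
    prev_vol = 0
    accepted = None
    rollback = False
    for t in thresholds:
        below = ct.values < t
        labels, _ = ndimage.label(below, structure=structure)
        lab = labels[seed]
        if lab == 0:
            continue
        mask = labels == lab
        vol = int(mask.sum())
        if prev_mask is not None and vol > params.leakage_factor * prev_vol:
            rollback = True
            log.info("leakage rollback at %.0f HU (volume %d -> %d)", t, prev_vol, vol)
            break
        prev_mask, prev_vol, accepted = mask, vol, float(t)
    if prev_mask is None or prev_vol == 0:
        raise SegmentationFailedError("region growing produced an empty mask")
    log.info("accepted threshold %.0f HU, %d voxels", accepted, prev_vol)
    out = BinaryMask(prev_mask, ct.spacing, ct.origin)
    if return_info:
        return out, {"accepted_threshold_hu": accepted, "rollback": rollback, "voxels": prev_vol}
    return out
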