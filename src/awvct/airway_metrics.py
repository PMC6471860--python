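"""Airway-tree volume and FWHM cross-sectional lumen/wall measures.

AWV (airway volume) is the lumen volume attributed to the RUL and RMLL
subtrees: every lumen voxel is assigned to the nearest centerline point's
branch, and the RUL- plus RMLL-assigned voxel volume is summed.

Cross-sectional measures follow the full-width-half-maximum principle.  A
plane orthogonal to the smoothed centerline is resampled at sub-voxel
resolution; rays cast from the center locate, per ray, the lumen HU
minimum and the wall HU peak.  The inner (lumen) boundary sits where the
profile first crosses half-way between minimum and peak going outward; the
outer wall boundary where it crosses half-way between the peak and the
outer plateau beyond it.  Lumen area Ai is the area of the inner-boundary
polygon, wall area WA the outer polygon area minus Ai, and
WA% = 100*WA/(Ai+WA).  Rays with no distinct wall peak (e.g. an abutting
structure) are excluded; a section fails if more than a quarter of rays do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import (
    EmptyInputError,
    InvalidCenterError,
    InvalidParameterError,
    QualityError,
)
from .imaging_io import BinaryMask, CTVolume
from .skeleton_graph import AirwayGraph

#: default number of rays per cross-section
N_RAYS = 64
#: default in-plane resample resolution (mm)
PLANE_RES_MM = 0.1
#: minimum HU excursion between lumen minimum and wall peak for a valid ray
MIN_WALL_CONTRAST_HU = 150.0
#: a measure is invalid when more than this fraction of rays fail
MAX_FAILED_RAY_FRACTION = 0.25


@dataclass
class CrossSectionMeasure:
    branch_id: int
    position_mm: float
    ai_mm2: float
    wa_mm2: float
    wa_percent: float
    valid: bool
    n_rays: int
    n_failed_rays: int


@dataclass
class PathMeasure:
    """Per-path (e.g. RB1, RB10) averaged lumen/wall measures."""

    name: str
    segmental_ai_mm2: float | None
    segmental_wa_percent: float | None
    subsegmental_ai_mm2: float | None
    subsegmental_wa_percent: float | None

    @property
    def mean_ai_mm2(self) -> float | None:
        vals = [v for v in (self.segmental_ai_mm2, self.subsegmental_ai_mm2) if v is not None]
        return float(np.mean(vals)) if vals else None

    @property
    def mean_wa_percent(self) -> float | None:
        vals = [v for v in (self.segmental_wa_percent, self.subsegmental_wa_percent) if v is not None]
        return float(np.mean(vals)) if vals else None


# ---------------------------------------------------------------------------
# Airway volume
# ---------------------------------------------------------------------------

def assign_voxels_to_branches(mask: BinaryMask, graph: AirwayGraph) -> dict[int, int]:
    """Assign every mask voxel to the branch of its nearest centerline point.

    Returns a voxel count per branch id.
    """
    idx = np.argwhere(mask.values)
    if len(idx) == 0:
        return {}
    pts_mm, branch_ids = graph.centerline_points_mm()
    tree = cKDTree(pts_mm)
    _, nearest = tree.query(idx * np.asarray(mask.spacing), workers=-1)
    assigned = branch_ids[nearest]
    counts: dict[int, int] = {}
    for bid in np.unique(assigned):
        counts[int(bid)] = int(np.count_nonzero(assigned == bid))
    return counts


def airway_volume_ml(
    mask: BinaryMask,
    graph: AirwayGraph,
    labels: set[str] = frozenset({"RUL", "RMLL"}),
) -> float:
    """AWV: volume (ml) of lumen voxels assigned to branches carrying one
    of ``labels``.  Returns 0 (with a warning) for an empty labelled set."""
    import warnings

    wanted = {b.id for b in graph.branches.values() if b.label in labels}
    if not wanted:
        warnings.warn(f"no branches labelled {sorted(labels)}; AWV = 0", stacklevel=2)
        return 0.0
    counts = assign_voxels_to_branches(mask, graph)
    n = sum(c for bid, c in counts.items() if bid in wanted)
    return n * mask.voxel_volume_mm3 / 1000.0


# ---------------------------------------------------------------------------
# Cross-section extraction
# ---------------------------------------------------------------------------

def _smoothed_points_mm(graph: AirwayGraph, branch_id: int, window: int = 5) -> np.ndarray:
    b = graph.branches[branch_id]
    pts = b.points * np.asarray(graph.spacing, dtype=float)
    if len(pts) >= window:
        kernel = np.ones(window) / window
        sm = np.column_stack(
            [np.convolve(np.pad(pts[:, a], window // 2, mode="edge"), kernel, mode="valid") for a in range(3)]
        )
        # keep the exact ends so position 0 / L stay meaningful
        sm[0], sm[-1] = pts[0], pts[-1]
        return sm
    return pts


def _point_and_tangent(points: np.ndarray, position_mm: float) -> tuple[np.ndarray, np.ndarray]:
    seglen = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seglen)])
    total = float(arc[-1])
    if position_mm < -1e-9 or position_mm > total + 1e-9:
        raise InvalidParameterError(f"position {position_mm:.2f} mm outside branch length {total:.2f} mm")
    position_mm = min(max(position_mm, 0.0), total)
    center = np.array([np.interp(position_mm, arc, points[:, a]) for a in range(3)])
    # central-difference tangent over a +-2 mm window
    h = 2.0
    p_lo = np.array([np.interp(max(position_mm - h, 0.0), arc, points[:, a]) for a in range(3)])
    p_hi = np.array([np.interp(min(position_mm + h, total), arc, points[:, a]) for a in range(3)])
    tangent = p_hi - p_lo
    norm = np.linalg.norm(tangent)
    if norm == 0:
        tangent = points[-1] - points[0]
        norm = np.linalg.norm(tangent)
    return center, tangent / norm


def extract_cross_section(
    ct: CTVolume,
    graph: AirwayGraph,
    branch_id: int,
    position_mm: float,
    plane_res_mm: float = PLANE_RES_MM,
    plane_size_mm: float = 20.0,
) -> np.ndarray:
    """Resample a 2-D plane orthogonal to the centerline tangent.

    The plane is centered on the centerline point at ``position_mm`` along
    the branch and trilinearly interpolated at ``plane_res_mm``.
    """
    points = _smoothed_points_mm(graph, branch_id)
    if len(points) < 2:
        raise InvalidParameterError("branch too short for a cross-section")
    center, tangent = _point_and_tangent(points, position_mm)
    ref = np.array([1.0, 0.0, 0.0]) if abs(tangent[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = ref - np.dot(ref, tangent) * tangent
    u /= np.linalg.norm(u)
    v = np.cross(tangent, u)
    half = plane_size_mm / 2.0
    coords_1d = np.arange(-half, half + plane_res_mm / 2, plane_res_mm)
    A, B = np.meshgrid(coords_1d, coords_1d, indexing="ij")
    world = center[None, None, :] + A[..., None] * u[None, None, :] + B[..., None] * v[None, None, :]
    voxel = (world - np.asarray(ct.origin)) / np.asarray(ct.spacing)
    section = ndimage.map_coordinates(
        ct.values.astype(np.float32),
        [voxel[..., 0], voxel[..., 1], voxel[..., 2]],
        order=1,
        mode="nearest",
    )
    return section


# ---------------------------------------------------------------------------
# FWHM measurement
# ---------------------------------------------------------------------------

def fwhm_measure(
    section: np.ndarray,
    center: tuple[float, float] | None = None,
    pixel_mm: float = PLANE_RES_MM,
    n_rays: int = N_RAYS,
    branch_id: int = -1,
    position_mm: float = float("nan"),
) -> CrossSectionMeasure:
    """Measure Ai, WA and WA% on a resampled cross-section.

    ``center`` is in pixel coordinates (defaults to the image center, which
    is where :func:`extract_cross_section` puts the centerline).
    """
    section = np.asarray(section, dtype=float)
    if center is None:
        center = ((section.shape[0] - 1) / 2.0, (section.shape[1] - 1) / 2.0)
    ci, cj = center
    # the center must sit in a low-HU lumen: below the section median
    c_hu = section[int(round(ci)), int(round(cj))]
    if not np.isfinite(c_hu) or c_hu > np.percentile(section, 40):
        raise InvalidCenterError(f"center HU {c_hu:.0f} is not a local low-attenuation region")

    max_len_px = int(min(ci, cj, section.shape[0] - 1 - ci, section.shape[1] - 1 - cj))
    inner_pts, outer_pts = [], []
    n_failed = 0
    angles = np.linspace(0.0, 2.0 * math.pi, n_rays, endpoint=False)
    steps = np.arange(max_len_px)
    for ang in angles:
        di, dj = math.cos(ang), math.sin(ang)
        ii = ci + steps * di
        jj = cj + steps * dj
        profile = ndimage.map_coordinates(section, [ii, jj], order=1, mode="nearest")
        res = _fwhm_ray(profile, step_mm=pixel_mm)
        if res is None:
            n_failed += 1
            continue
        r_in, r_out = res
        inner_pts.append((ci + r_in * di, cj + r_in * dj))
        outer_pts.append((ci + r_out * di, cj + r_out * dj))
    if n_failed > MAX_FAILED_RAY_FRACTION * n_rays:
        raise QualityError(f"{n_failed}/{n_rays} rays failed; measure rejected")
    ai = _polygon_area(np.asarray(inner_pts)) * pixel_mm**2
    a_outer = _polygon_area(np.asarray(outer_pts)) * pixel_mm**2
    wa = max(a_outer - ai, 0.0)
    wa_pct = 100.0 * wa / (ai + wa) if (ai + wa) > 0 else 0.0
    return CrossSectionMeasure(
        branch_id=branch_id,
        position_mm=position_mm,
        ai_mm2=float(ai),
        wa_mm2=float(wa),
        wa_percent=float(wa_pct),
        valid=True,
        n_rays=n_rays,
        n_failed_rays=n_failed,
    )


def _fwhm_ray(profile: np.ndarray, step_mm: float = PLANE_RES_MM) -> tuple[float, float] | None:
    """Locate inner and outer wall boundaries (in pixels) on one ray.

    Returns None when the ray has no usable wall peak.
    """
    if len(profile) < 8:
        return None
    # lumen minimum: lowest value in the inner half of the ray
    k_min = int(np.argmin(profile[: max(len(profile) // 2, 4)]))
    lumen_min = float(profile[k_min])
    # wall peak: the FIRST local maximum beyond the lumen with sufficient
    # contrast — not the global max, which may sit in unrelated structures
    # (mediastinum, chest wall) further out along the ray
    k_peak = None
    for k in range(k_min + 1, len(profile) - 1):
        if profile[k] - lumen_min < MIN_WALL_CONTRAST_HU:
            continue
        if profile[k] >= profile[k + 1]:
            k_peak = k
            break
    if k_peak is None:
        return None
    peak = float(profile[k_peak])
    # outer plateau: the attenuation floor just beyond the wall — the first
    # local minimum within a few mm past the peak.  (A fixed "far end of the
    # ray" estimate breaks for sections near the pleura, where rays leave
    # the lung and climb back to soft-tissue values.)
    window = profile[k_peak + 1 : k_peak + 1 + max(int(round(4.0 / step_mm)), 4)]
    if len(window) < 3:
        return None
    k_floor = k_peak + 1 + int(np.argmin(window))
    lo = max(k_floor - 2, k_peak + 1)
    plateau = float(np.median(profile[lo : k_floor + 3]))
    if peak - plateau < MIN_WALL_CONTRAST_HU / 2:
        return None
    inner_level = 0.5 * (lumen_min + peak)
    outer_level = 0.5 * (peak + plateau)
    r_in = _first_crossing(profile, k_min, k_peak, inner_level, rising=True)
    r_out = _first_crossing(profile, k_peak, k_floor, outer_level, rising=False)
    if r_in is None or r_out is None:
        return None
    return r_in, r_out


def _first_crossing(profile: np.ndarray, k0: int, k1: int, level: float, rising: bool) -> float | None:
    for k in range(k0, k1):
        a, b = profile[k], profile[k + 1]
        if (rising and a < level <= b) or (not rising and a > level >= b):
            frac = (level - a) / (b - a) if b != a else 0.0
            return k + float(frac)
    return None


def _polygon_area(pts: np.ndarray) -> float:
    if len(pts) < 3:
        return 0.0
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


# ---------------------------------------------------------------------------
# Path-level measurement
# ---------------------------------------------------------------------------

#: fractions of branch length where cross-sections are sampled
SAMPLING_FRACTIONS = (0.25, 0.5, 0.75)


def measure_branch(
    ct: CTVolume,
    graph: AirwayGraph,
    branch_id: int,
    fractions: tuple[float, ...] = SAMPLING_FRACTIONS,
    plane_res_mm: float = PLANE_RES_MM,
    plane_size_mm: float | None = None,
) -> list[CrossSectionMeasure]:
    """FWHM-measure one branch at the stated fractions of its length."""
    if branch_id not in graph.branches:
        raise KeyError(f"branch {branch_id} not in graph")
    b = graph.branches[branch_id]
    out = []
    size = plane_size_mm or 20.0
    for f in fractions:
        pos = f * b.length_mm
        section = extract_cross_section(ct, graph, branch_id, pos, plane_res_mm, size)
        try:
            m = fwhm_measure(section, pixel_mm=plane_res_mm, branch_id=branch_id, position_mm=pos)
        except (InvalidCenterError, QualityError):
            m = CrossSectionMeasure(branch_id, pos, float("nan"), float("nan"), float("nan"), False, N_RAYS, N_RAYS)
        out.append(m)
    return out


def measure_paths(
    ct: CTVolume,
    graph: AirwayGraph,
    path_specs: list[tuple[str, list[int], list[int]]],
    fractions: tuple[float, ...] = SAMPLING_FRACTIONS,
) -> tuple[list[PathMeasure], dict[str, float | None]]:
    """Measure named airway paths and average them.

    ``path_specs`` entries are ``(name, segmental branch ids,
    sub-segmental branch ids)`` — e.g. the RB1 and RB10 paths.  Per-branch
    values are the mean over its valid cross-sections; the overall means
    weight the listed paths equally, skipping paths with no valid measure.
    """
    results: list[PathMeasure] = []
    for name, seg_ids, subseg_ids in path_specs:
        seg = _mean_over_branches(ct, graph, seg_ids, fractions)
        subseg = _mean_over_branches(ct, graph, subseg_ids, fractions)
        results.append(
            PathMeasure(
                name=name,
                segmental_ai_mm2=seg[0],
                segmental_wa_percent=seg[1],
                subsegmental_ai_mm2=subseg[0],
                subsegmental_wa_percent=subseg[1],
            )
        )
    ai_vals = [p.mean_ai_mm2 for p in results if p.mean_ai_mm2 is not None]
    wa_vals = [p.mean_wa_percent for p in results if p.mean_wa_percent is not None]
    overall = {
        "mean_ai_mm2": float(np.mean(ai_vals)) if ai_vals else None,
        "mean_wa_percent": float(np.mean(wa_vals)) if wa_vals else None,
        "segmental_ai_mm2": _safe_mean([p.segmental_ai_mm2 for p in results]),
        "segmental_wa_percent": _safe_mean([p.segmental_wa_percent for p in results]),
        "subsegmental_ai_mm2": _safe_mean([p.subsegmental_ai_mm2 for p in results]),
        "subsegmental_wa_percent": _safe_mean([p.subsegmental_wa_percent for p in results]),
    }
    return results, overall


def _mean_over_branches(ct, graph, branch_ids, fractions) -> tuple[float | None, float | None]:
    if not branch_ids:
        return None, None
    ai, wa = [], []
    for bid in branch_ids:
        measures = [m for m in measure_branch(ct, graph, bid, fractions) if m.valid]
        if measures:
            ai.append(np.mean([m.ai_mm2 for m in measures]))
            wa.append(np.mean([m.wa_percent for m in measures]))
    if not ai:
        return None, None
    return float(np.mean(ai)), float(np.mean(wa))


def _safe_mean(vals) -> float | None:
    good = [v for v in vals if v is not None]
    return float(np.mean(good)) if good else None
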