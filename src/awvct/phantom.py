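"""Digital chest phantoms with analytically known ground truth.

A phantom is a CT-like volume containing a bifurcating, air-filled airway
tree with finite-thickness soft-tissue walls, embedded between two
ellipsoidal "lungs" of configurable parenchymal attenuation.  Branches are
straight cylinders, so lumen volume (sum of pi*r^2*L), per-branch lumen
area (pi*r^2) and wall area percent have closed forms, and every downstream
stage — segmentation, skeletonization/branch counting, FWHM wall
measurement, emphysema quantification — can be checked against analytic
truth without patient data.

A cohort simulator generates per-subject CT-index / lung-function tables
with a known linear generating model, providing the same kind of ground
truth for the statistics layer.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import GeometryError, InvalidParameterError, SimulationError
from .imaging_io import BinaryMask, CTVolume


# ---------------------------------------------------------------------------
# Tree geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TreeBranch:
    """One straight cylindrical branch of the airway tree (all mm)."""

    id: int
    parent_id: int | None
    proximal: tuple[float, float, float]
    distal: tuple[float, float, float]
    lumen_radius: float
    wall_thickness: float
    generation: int

    @property
    def length_mm(self) -> float:
        return float(np.linalg.norm(np.subtract(self.distal, self.proximal)))

    @property
    def lumen_area_mm2(self) -> float:
        return math.pi * self.lumen_radius**2

    @property
    def wall_area_percent(self) -> float:
        r, t = self.lumen_radius, self.wall_thickness
        return 100.0 * ((r + t) ** 2 - r**2) / (r + t) ** 2


@dataclass
class TreeGeometry:
    """A rooted tree of cylindrical branches with monotone radius taper."""

    branches: list[TreeBranch]
    root_id: int

    def __post_init__(self) -> None:
        by_id = {b.id: b for b in self.branches}
        if len(by_id) != len(self.branches):
            raise InvalidParameterError("duplicate branch ids")
        roots = [b for b in self.branches if b.parent_id is None]
        if len(roots) != 1 or roots[0].id != self.root_id:
            raise InvalidParameterError("exactly one parentless branch (the root) is required")
        for b in self.branches:
            if b.lumen_radius <= 0 or b.wall_thickness <= 0:
                raise InvalidParameterError(f"branch {b.id}: radius and wall thickness must be > 0")
            if b.parent_id is not None:
                parent = by_id.get(b.parent_id)
                if parent is None:
                    raise InvalidParameterError(f"branch {b.id} references missing parent {b.parent_id}")
                if b.lumen_radius > parent.lumen_radius + 1e-9:
                    raise InvalidParameterError(f"branch {b.id} radius exceeds its parent's (taper must be monotone)")
        # cycle check: walking parents must terminate at the root
        for b in self.branches:
            seen = set()
            cur: TreeBranch | None = b
            while cur is not None:
                if cur.id in seen:
                    raise InvalidParameterError("branch parent links contain a cycle")
                seen.add(cur.id)
                cur = by_id.get(cur.parent_id) if cur.parent_id is not None else None

    def branch(self, branch_id: int) -> TreeBranch:
        return next(b for b in self.branches if b.id == branch_id)

    def children(self, branch_id: int) -> list[TreeBranch]:
        return [b for b in self.branches if b.parent_id == branch_id]

    def descendants(self, branch_id: int) -> list[TreeBranch]:
        """Descendants of ``branch_id`` inclusive, in BFS order."""
        out, queue = [], [branch_id]
        while queue:
            cur = queue.pop(0)
            out.append(self.branch(cur))
            queue.extend(c.id for c in self.children(cur))
        return out

    def extent_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned bounds of the tree including the outer wall."""
        lo = np.full(3, np.inf)
        hi = np.full(3, -np.inf)
        for b in self.branches:
            m = b.lumen_radius + b.wall_thickness
            for p in (b.proximal, b.distal):
                lo = np.minimum(lo, np.asarray(p) - m)
                hi = np.maximum(hi, np.asarray(p) + m)
        return lo, hi

    def to_json(self) -> str:
        return json.dumps(
            {
                "root_id": self.root_id,
                "branches": [
                    {
                        "id": b.id,
                        "parent_id": b.parent_id,
                        "proximal_mm": list(b.proximal),
                        "distal_mm": list(b.distal),
                        "lumen_radius_mm": b.lumen_radius,
                        "wall_thickness_mm": b.wall_thickness,
                        "generation": b.generation,
                    }
                    for b in self.branches
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "TreeGeometry":
        d = json.loads(text)
        branches = [
            TreeBranch(
                id=b["id"],
                parent_id=b["parent_id"],
                proximal=tuple(b["proximal_mm"]),
                distal=tuple(b["distal_mm"]),
                lumen_radius=b["lumen_radius_mm"],
                wall_thickness=b["wall_thickness_mm"],
                generation=b["generation"],
            )
            for b in d["branches"]
        ]
        return cls(branches=branches, root_id=d["root_id"])


def build_tree_spec(
    depth: int,
    root_radius: float = 4.0,
    taper: float = 0.75,
    branch_length: float = 24.0,
    angle: float = 35.0,
    wall_fraction: float = 0.3,
    min_wall_mm: float = 1.0,
    seed: int = 0,
) -> TreeGeometry:
    """Build a full binary airway tree of ``2**depth - 1`` straight branches.

    Generation ``g`` has radius ``root_radius * taper**g`` and length
    ``branch_length * taper**g``; children deflect from the parent axis by
    ``angle`` degrees in a branching plane whose azimuth advances 90 degrees
    per generation (plus a small seeded jitter) so the tree fills 3-D space
    without sibling overlap.  Wall thickness is ``wall_fraction * radius``
    floored at ``min_wall_mm`` — small airways have proportionally thick
    walls, and a sub-voxel wall would not be watertight once rasterized.
    The root points caudally (toward decreasing z) from the origin.
    """
    if depth < 1:
        raise InvalidParameterError("depth must be >= 1")
    if root_radius <= 0 or branch_length <= 0:
        raise InvalidParameterError("root_radius and branch_length must be > 0")
    if not (0 < taper <= 1):
        raise InvalidParameterError("taper must lie in (0, 1]")
    if wall_fraction <= 0:
        raise InvalidParameterError("wall_fraction must be > 0")
    rng = np.random.default_rng(seed)
    theta = math.radians(angle)
    branches: list[TreeBranch] = []
    next_id = 0
    # (parent_id, proximal, direction, generation)
    queue: list[tuple[int | None, np.ndarray, np.ndarray, int]] = [
        (None, np.zeros(3), np.array([0.0, 0.0, -1.0]), 0)
    ]
    while queue:
        parent_id, prox, direction, g = queue.pop(0)
        if g >= depth:
            continue
        radius = root_radius * taper**g
        length = branch_length * taper**g
        distal = prox + direction * length
        bid = next_id
        next_id += 1
        branches.append(
            TreeBranch(
                id=bid,
                parent_id=parent_id,
                proximal=tuple(prox),
                distal=tuple(distal),
                lumen_radius=radius,
                wall_thickness=max(wall_fraction * radius, min_wall_mm),
                generation=g,
            )
        )
        if g + 1 < depth:
            u, v = _perpendicular_basis(direction)
            azimuth = math.radians(90.0 * g + rng.uniform(-8.0, 8.0))
            w = math.cos(azimuth) * u + math.sin(azimuth) * v
            for sign in (+1.0, -1.0):
                child_dir = math.cos(theta) * direction + sign * math.sin(theta) * w
                child_dir = child_dir / np.linalg.norm(child_dir)
                queue.append((bid, distal, child_dir, g + 1))
    return TreeGeometry(branches=branches, root_id=0)


def _perpendicular_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = direction / np.linalg.norm(direction)
    ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = ref - np.dot(ref, d) * d
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


# ---------------------------------------------------------------------------
# Phantom rasterization
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Raster and attenuation model for a digital chest phantom.

    HU defaults straddle the -950 HU emphysema threshold: lumen air -1000,
    wall soft tissue 0, normal parenchyma -870, emphysematous parenchyma
    -980.  Gaussian blur (in mm, applied before noise) mimics the scanner
    point-spread function; truth masks are never blurred.
    """

    shape: tuple[int, int, int] = (192, 192, 160)
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    hu_lumen: float = -1000.0
    hu_wall: float = 0.0
    hu_parenchyma: float = -870.0
    hu_emphysema: float = -980.0
    hu_background: float = 50.0
    emphysema_fraction: float = 0.0
    blur_sigma_mm: float = 0.6
    noise_sd_hu: float = 0.0
    clustered_emphysema: bool = False
    n_emphysema_clusters: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.hu_lumen < -950.0 < self.hu_parenchyma):
            raise InvalidParameterError("need lumen HU < -950 < parenchyma HU")
        if self.hu_wall <= -500.0:
            raise InvalidParameterError("wall HU must be > -500")
        if self.hu_emphysema >= -950.0:
            raise InvalidParameterError("emphysema HU must be < -950")
        if not (0.0 <= self.emphysema_fraction <= 1.0):
            raise InvalidParameterError("emphysema fraction must lie in [0, 1]")
        if self.blur_sigma_mm < 0 or self.noise_sd_hu < 0:
            raise InvalidParameterError("blur sigma and noise SD must be >= 0")
        if any(n < 8 for n in self.shape) or any(s <= 0 for s in self.spacing):
            raise InvalidParameterError("implausible phantom grid")


# relative lung ellipsoid geometry (fractions of the grid extent);
# the right lung sits at smaller x in the canonical orientation
_LUNG_CENTERS = ((0.30, 0.52, 0.44), (0.70, 0.52, 0.44))
_LUNG_SEMIAXES = (0.18, 0.33, 0.42)


def _lung_masks(spec: PhantomSpec) -> np.ndarray:
    nx, ny, nz = spec.shape
    ext = np.array([(n - 1) * s for n, s in zip(spec.shape, spec.spacing)])
    x = np.arange(nx) * spec.spacing[0]
    y = np.arange(ny) * spec.spacing[1]
    z = np.arange(nz) * spec.spacing[2]
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    lungs = np.zeros(spec.shape, dtype=bool)
    semi = np.asarray(_LUNG_SEMIAXES) * ext
    for cx, cy, cz in _LUNG_CENTERS:
        c = np.array([cx, cy, cz]) * ext
        d = ((X - c[0]) / semi[0]) ** 2 + ((Y - c[1]) / semi[1]) ** 2 + ((Z - c[2]) / semi[2]) ** 2
        lungs |= d <= 1.0
    return lungs


def tree_root_position_mm(spec: PhantomSpec, tree: TreeGeometry) -> np.ndarray:
    """Grid position (mm) where the tree root proximal point is planted:
    in-plane center, just far enough below the top slice that the outer
    wall cap fits — the trachea still enters the cranial slab."""
    nx, ny, nz = spec.shape
    root = tree.branch(tree.root_id)
    cap = root.lumen_radius + root.wall_thickness + 2 * spec.spacing[2]
    # integer-voxel center: a perfectly even-symmetric cylinder is a
    # degenerate input for 3-D thinning
    return np.array(
        [
            (nx // 2) * spec.spacing[0],
            (ny // 2) * spec.spacing[1],
            (nz - 1) * spec.spacing[2] - cap,
        ]
    )


def rasterize_phantom(
    tree: TreeGeometry, spec: PhantomSpec
) -> tuple[CTVolume, BinaryMask, BinaryMask, BinaryMask]:
    """Voxelize a tree into a CT phantom.

    Returns ``(ct, lumen_mask, wall_mask, lung_mask)``.  The truth masks are
    crisp (pre-blur); blur and noise are applied to the CT volume only.  The
    lung mask is parenchyma only — airway lumen and wall voxels are excluded
    — and exactly ``round(fraction * n_parenchyma)`` of its voxels are set
    to the emphysema HU by seeded sampling.
    """
    offset = tree_root_position_mm(spec, tree)
    lo, hi = tree.extent_mm()
    ext = np.array([(n - 1) * s for n, s in zip(spec.shape, spec.spacing)])
    if np.any(lo + offset < -1e-6) or np.any(hi + offset > ext + 1e-6):
        raise GeometryError(
            f"tree extent {lo + offset} .. {hi + offset} mm exceeds grid extent {ext} mm"
        )

    lumen = np.zeros(spec.shape, dtype=bool)
    wall = np.zeros(spec.shape, dtype=bool)
    spacing = np.asarray(spec.spacing)
    for b in tree.branches:
        p0 = np.asarray(b.proximal) + offset
        p1 = np.asarray(b.distal) + offset
        r_out = b.lumen_radius + b.wall_thickness
        lo_idx = np.maximum(np.floor((np.minimum(p0, p1) - r_out) / spacing - 1), 0).astype(int)
        hi_idx = np.minimum(
            np.ceil((np.maximum(p0, p1) + r_out) / spacing + 1), np.asarray(spec.shape) - 1
        ).astype(int)
        sl = tuple(slice(a, b_ + 1) for a, b_ in zip(lo_idx, hi_idx))
        coords = np.meshgrid(
            *[np.arange(a, b_ + 1) * s for a, b_, s in zip(lo_idx, hi_idx, spacing)],
            indexing="ij",
        )
        pts = np.stack(coords, axis=-1)
        # lumen: exact finite cylinder so voxel volume -> pi r^2 L;
        # wall: capsule (rounded ends) so bifurcation elbows stay sealed
        d_axis, t_par = _axis_distance(pts, p0, p1)
        lumen[sl] |= (d_axis <= b.lumen_radius) & (t_par >= 0.0) & (t_par <= 1.0)
        wall[sl] |= _dist_to_segment(pts, p0, p1) <= r_out
    wall &= ~lumen

    lungs = _lung_masks(spec)
    lung_truth = lungs & ~lumen & ~wall

    rng = np.random.default_rng(spec.seed)
    vol = np.full(spec.shape, spec.hu_background, dtype=np.float32)
    vol[lung_truth] = spec.hu_parenchyma
    n_par = int(lung_truth.sum())
    n_emph = int(round(spec.emphysema_fraction * n_par))
    emph_idx = _sample_emphysema(lung_truth, n_emph, rng, spec)
    if n_emph:
        vol[emph_idx] = spec.hu_emphysema
    vol[wall] = spec.hu_wall
    vol[lumen] = spec.hu_lumen

    if spec.blur_sigma_mm > 0:
        vol = ndimage.gaussian_filter(vol, sigma=[spec.blur_sigma_mm / s for s in spacing])
    if spec.noise_sd_hu > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd_hu, size=vol.shape).astype(np.float32)

    ct = CTVolume(vol.astype(np.float32), spec.spacing)
    return (
        ct,
        BinaryMask(lumen, spec.spacing),
        BinaryMask(wall, spec.spacing),
        BinaryMask(lung_truth, spec.spacing),
    )


def emphysema_truth_mask(ct_spec: PhantomSpec, lung_mask: BinaryMask) -> BinaryMask:
    """Recompute the exact emphysema voxel set for a rasterized phantom.

    Uses the same seeded sampling as :func:`rasterize_phantom`, so the
    returned mask matches the voxels that were set to the emphysema HU.
    """
    rng = np.random.default_rng(ct_spec.seed)
    lung = lung_mask.values
    n_par = int(lung.sum())
    n_emph = int(round(ct_spec.emphysema_fraction * n_par))
    out = np.zeros(lung.shape, dtype=bool)
    idx = _sample_emphysema(lung, n_emph, rng, ct_spec)
    if n_emph:
        out[idx] = True
    return BinaryMask(out, lung_mask.spacing, lung_mask.origin)


def _axis_distance(pts: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Radial distance to the (infinite) branch axis and the unclamped
    projection parameter t (0 at proximal, 1 at distal)."""
    seg = p1 - p0
    L2 = float(np.dot(seg, seg))
    rel = pts - p0
    t = np.tensordot(rel, seg, axes=([-1], [0])) / L2
    proj = p0 + t[..., None] * seg
    return np.linalg.norm(pts - proj, axis=-1), t


def _dist_to_segment(pts: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    seg = p1 - p0
    L2 = float(np.dot(seg, seg))
    rel = pts - p0
    if L2 == 0:
        return np.linalg.norm(rel, axis=-1)
    t = np.clip(np.tensordot(rel, seg, axes=([-1], [0])) / L2, 0.0, 1.0)
    proj = p0 + t[..., None] * seg
    return np.linalg.norm(pts - proj, axis=-1)


def _sample_emphysema(lung: np.ndarray, n_emph: int, rng: np.random.Generator, spec: PhantomSpec):
    """Pick exactly ``n_emph`` parenchymal voxels, scattered or clustered."""
    if n_emph == 0:
        return None
    cand = np.flatnonzero(lung)
    if spec.clustered_emphysema:
        coords = np.column_stack(np.unravel_index(cand, lung.shape)).astype(float)
        centers = coords[rng.choice(len(cand), size=min(spec.n_emphysema_clusters, len(cand)), replace=False)]
        d2 = np.min(
            ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2), axis=1
        ) if len(cand) * len(centers) < 5e7 else _chunked_min_d2(coords, centers)
        order = np.argsort(d2, kind="stable")
        chosen = cand[order[:n_emph]]
    else:
        chosen = rng.choice(cand, size=n_emph, replace=False)
    return np.unravel_index(chosen, lung.shape)


def _chunked_min_d2(coords: np.ndarray, centers: np.ndarray) -> np.ndarray:
    out = np.empty(len(coords))
    step = 200000
    for i in range(0, len(coords), step):
        blk = coords[i : i + step]
        out[i : i + step] = ((blk[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2).min(axis=1)
    return out


# ---------------------------------------------------------------------------
# Analytic truth
# ---------------------------------------------------------------------------

@dataclass
class TruthMetrics:
    """Closed-form counterparts of the CT measures for one tree phantom."""

    branch_count: int
    lumen_volume_total_ml: float
    trachea_volume_ml: float
    #: keyed by the branch id of each child of the root (the "lobar" roots)
    lumen_volume_by_subtree_ml: dict[int, float]
    ai_mm2: dict[int, float]
    wa_percent: dict[int, float]
    emphysema_fraction: float


def analytic_truth(tree: TreeGeometry, spec: PhantomSpec | None = None) -> TruthMetrics:
    """Cylinder-model ground truth: volumes Σ pi r^2 L (ml), Ai = pi r^2,
    WA% = 100 ((r+t)^2 - r^2)/(r+t)^2."""
    vol_ml = {b.id: b.lumen_area_mm2 * b.length_mm / 1000.0 for b in tree.branches}
    by_subtree = {}
    for child in tree.children(tree.root_id):
        by_subtree[child.id] = sum(vol_ml[d.id] for d in tree.descendants(child.id))
    return TruthMetrics(
        branch_count=len(tree.branches),
        lumen_volume_total_ml=sum(vol_ml.values()),
        trachea_volume_ml=vol_ml[tree.root_id],
        lumen_volume_by_subtree_ml=by_subtree,
        ai_mm2={b.id: b.lumen_area_mm2 for b in tree.branches},
        wa_percent={b.id: b.wall_area_percent for b in tree.branches},
        emphysema_fraction=spec.emphysema_fraction if spec is not None else 0.0,
    )


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

#: default predictor scales: (mean, SD) per CT index / covariate
DEFAULT_PREDICTOR_SCALES: dict[str, tuple[float, float]] = {
    "awv_percent": (0.52, 0.14),
    "lav_percent": (29.0, 9.0),
    "wa_percent": (58.0, 5.0),
    "tac": (212.0, 51.0),
    "age_yr": (71.0, 9.0),
    "bmi": (22.0, 3.0),
    "pack_years": (63.0, 35.0),
}

#: default standardized coefficients of the generating model
DEFAULT_COEFFICIENTS: dict[str, dict[str, float]] = {
    "pct_fev1": {"lav_percent": -0.50, "wa_percent": -0.26, "tac": 0.21, "awv_percent": 0.35},
    "rv_tlc": {"lav_percent": 0.24, "wa_percent": -0.17, "tac": -0.17, "awv_percent": -0.28},
}

DEFAULT_OUTCOME_SCALES: dict[str, tuple[float, float]] = {
    "pct_fev1": (61.0, 20.0),
    "rv_tlc": (42.0, 7.0),
}


@dataclass
class CohortSimSpec:
    """Linear generating model for a simulated cohort.

    Predictors are drawn from a multivariate normal with the given means,
    SDs and correlation matrix; each outcome (on the z scale) is the stated
    linear combination of z-scored predictors plus Gaussian noise of SD
    ``noise_sd``, then rescaled to its clinical mean/SD.
    """

    n: int = 147
    predictor_scales: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PREDICTOR_SCALES)
    )
    correlation: np.ndarray | None = None  # identity if None
    coefficients: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COEFFICIENTS.items()}
    )
    outcome_scales: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_SCALES)
    )
    noise_sd: float = 0.72
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InvalidParameterError("cohort size n must be >= 2")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise SD must be >= 0")
        p = len(self.predictor_scales)
        if self.correlation is not None:
            R = np.asarray(self.correlation, dtype=float)
            if R.shape != (p, p) or not np.allclose(R, R.T, atol=1e-10):
                raise SimulationError("correlation matrix must be symmetric p x p")
            if np.min(np.linalg.eigvalsh(R)) < -1e-10:
                raise SimulationError("correlation matrix is not positive semi-definite")
            self.correlation = R
        for outcome, coef in self.coefficients.items():
            unknown = set(coef) - set(self.predictor_scales)
            if unknown:
                raise InvalidParameterError(f"{outcome}: unknown predictors {sorted(unknown)}")


def simulate_cohort(spec: CohortSimSpec) -> pd.DataFrame:
    """Simulate a per-subject cohort table with a known generating model.

    Besides the predictors and outcomes of the linear model, the table
    carries height (for pTLC), a CAT symptom score negatively coupled to
    %FEV1 (so lower lung function means more symptoms), FEV1 in litres, and
    weakly-informative %TLC / %DLCO / DLCO-VA columns, giving the cohort
    summary and statistics layers a complete playground.
    """
    rng = np.random.default_rng(spec.seed)
    names = list(spec.predictor_scales)
    p = len(names)
    R = np.eye(p) if spec.correlation is None else spec.correlation
    try:
        L = np.linalg.cholesky(R + 1e-12 * np.eye(p))
    except np.linalg.LinAlgError as exc:
        raise SimulationError(f"correlation matrix not factorizable: {exc}") from exc
    z = rng.standard_normal((spec.n, p)) @ L.T
    data: dict[str, np.ndarray] = {"subject_id": np.arange(1, spec.n + 1)}
    for j, name in enumerate(names):
        mean, sd = spec.predictor_scales[name]
        col = mean + sd * z[:, j]
        data[name] = col
    z_out: dict[str, np.ndarray] = {}
    for outcome, coef in spec.coefficients.items():
        beta = np.array([coef.get(name, 0.0) for name in names])
        zy = z @ beta + spec.noise_sd * rng.standard_normal(spec.n)
        z_out[outcome] = zy
        mean, sd = spec.outcome_scales.get(outcome, (0.0, 1.0))
        data[outcome] = mean + sd * zy

    if "tac" in data:
        data["tac"] = np.clip(np.round(data["tac"]), 10, None).astype(int)
    if "pct_fev1" in data:
        data["pct_fev1"] = np.clip(data["pct_fev1"], 10.0, None)
    if "rv_tlc" in data:
        data["rv_tlc"] = np.clip(data["rv_tlc"], 15.0, 80.0)

    data["height_m"] = 1.67 + 0.06 * rng.standard_normal(spec.n)
    zy1 = z_out.get("pct_fev1", rng.standard_normal(spec.n))
    cat_latent = 11.0 + 8.0 * (-0.3 * zy1 + math.sqrt(1 - 0.09) * rng.standard_normal(spec.n))
    data["cat_score"] = np.clip(np.round(cat_latent), 0, 40).astype(int)
    if "pct_fev1" in data:
        data["fev1_l"] = np.round(data["pct_fev1"] / 100.0 * 2.9, 3)
    data["pct_tlc"] = 96.0 + 13.0 * rng.standard_normal(spec.n)
    data["pct_dlco"] = np.clip(53.0 + 14.0 * rng.standard_normal(spec.n), 5.0, None)
    data["dlco_va"] = np.clip(3.5 + 1.0 * rng.standard_normal(spec.n), 0.3, None)
    return pd.DataFrame(data)
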