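"""CT volumes, binary masks and metric tables: containers and file I/O.

Conventions
-----------
Internal volumes are indexed ``values[i, j, k]`` with the canonical LPS-like
axis order used throughout the package:

* axis 0 (``i``/x): increases toward the patient's **left** — the right lung
  therefore has the smaller x centroid;
* axis 1 (``j``/y): increases toward **posterior**;
* axis 2 (``k``/z): increases toward **superior** — the trachea enters the
  volume near the largest z indices.

World coordinates are millimetres: ``world = origin + index * spacing``.
Voxel indices are 0-based; volumes are reported in ml (mm^3 / 1000).

NIfTI is the primary on-disk format (spacing and origin in the affine);
DICOM series are read-only.  Metrics go to JSON or CSV with a sidecar
column dictionary documenting units.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    AmbiguousSeriesError,
    HeaderError,
    InvalidParameterError,
    ValidationError,
)

HU_MIN_PLAUSIBLE = -1024.0
HU_MAX_PLAUSIBLE = 3071.0

#: spacing agreement required between a mask and its reference CT (mm)
SPACING_TOL_MM = 1e-4
#: origin agreement required between a mask and its reference CT (mm)
ORIGIN_TOL_MM = 1e-3


@dataclass
class CTVolume:
    """A 3-D grid of Hounsfield units with voxel spacing and world origin.

    Parameters
    ----------
    values:
        HU array of shape ``(nx, ny, nz)`` in the canonical axis order.
    spacing:
        Voxel spacing ``(sx, sy, sz)`` in mm, all strictly positive.
    origin:
        World position (mm) of voxel ``(0, 0, 0)``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.size == 0:
            raise InvalidParameterError("CT volume must be a non-empty 3-D grid")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise InvalidParameterError(f"spacing must be positive on all axes, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices to world mm coordinates."""
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * np.asarray(self.spacing)

    def check_hu_plausible(self) -> None:
        lo, hi = float(self.values.min()), float(self.values.max())
        if lo < HU_MIN_PLAUSIBLE - 200 or hi > HU_MAX_PLAUSIBLE + 200:
            raise ValidationError(f"HU range [{lo:.0f}, {hi:.0f}] is not plausible CT attenuation")


@dataclass
class BinaryMask:
    """A boolean mask on the same grid as an associated :class:`CTVolume`."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3 or self.values.size == 0:
            raise InvalidParameterError("mask must be a non-empty 3-D grid")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise InvalidParameterError("mask spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def volume_ml(self) -> float:
        return float(self.values.sum()) * self.voxel_volume_mm3 / 1000.0

    def check_alignment(self, reference: "CTVolume | BinaryMask") -> None:
        """Raise :class:`AlignmentError` unless geometry matches ``reference``."""
        if self.shape != reference.shape:
            raise AlignmentError(f"shape mismatch: {self.shape} vs {reference.shape}")
        ds = np.abs(np.asarray(self.spacing) - np.asarray(reference.spacing))
        if np.any(ds > SPACING_TOL_MM):
            raise AlignmentError(f"spacing mismatch beyond {SPACING_TOL_MM} mm: {self.spacing} vs {reference.spacing}")
        do = np.abs(np.asarray(self.origin) - np.asarray(reference.origin))
        if np.any(do > ORIGIN_TOL_MM):
            raise AlignmentError(f"origin mismatch beyond {ORIGIN_TOL_MM} mm: {self.origin} vs {reference.origin}")


# ---------------------------------------------------------------------------
# NIfTI / DICOM readers and writers
# ---------------------------------------------------------------------------

def _affine_from_geometry(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def _geometry_from_affine(aff: np.ndarray, shape) -> tuple[np.ndarray | None, tuple, tuple]:
    """Extract spacing/origin from a diagonal (possibly sign-flipped) affine.

    Returns (flips, spacing, origin); ``flips`` lists axes whose direction was
    inverted so that internal spacing is positive.
    """
    rot = aff[:3, :3]
    off = np.abs(rot - np.diag(np.diag(rot)))
    if np.any(off > 1e-3 * np.max(np.abs(rot))):
        raise HeaderError("only axis-aligned (diagonal affine) volumes are supported")
    diag = np.diag(rot)
    if np.any(diag == 0):
        raise HeaderError("affine has a zero spacing entry")
    flips = [ax for ax in range(3) if diag[ax] < 0]
    spacing = tuple(abs(float(d)) for d in diag)
    origin = list(aff[:3, 3])
    for ax in flips:
        origin[ax] = float(origin[ax] + diag[ax] * (shape[ax] - 1))
    return flips, spacing, tuple(origin)


def read_ct(path: str | os.PathLike) -> CTVolume:
    """Read a CT volume from a NIfTI file or a DICOM series directory.

    HU rescale slope/intercept are applied; spacing comes from the header.
    Slices are ordered so that axis 2 increases toward superior.
    """
    p = Path(path)
    if p.is_dir():
        return _read_dicom_series(p)
    img = nib.load(str(p))
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim != 3:
        raise HeaderError(f"expected a 3-D volume, got shape {data.shape}")
    flips, spacing, origin = _geometry_from_affine(img.affine, data.shape)
    for ax in flips:
        data = np.flip(data, axis=ax)
    return CTVolume(np.ascontiguousarray(data), spacing, origin)


def _read_dicom_series(directory: Path) -> CTVolume:
    import pydicom

    files = sorted(f for f in directory.iterdir() if f.is_file() and f.suffix.lower() in {".dcm", ""})
    if not files:
        raise HeaderError(f"no DICOM files found in {directory}")
    datasets = [pydicom.dcmread(str(f)) for f in files]
    uids = {getattr(d, "SeriesInstanceUID", None) for d in datasets}
    if len(uids) != 1:
        raise AmbiguousSeriesError(f"directory holds {len(uids)} series; expected exactly one")
    try:
        datasets.sort(key=lambda d: float(d.ImagePositionPatient[2]))
        z_positions = [float(d.ImagePositionPatient[2]) for d in datasets]
        px = [float(v) for v in datasets[0].PixelSpacing]
    except AttributeError as exc:
        raise HeaderError(f"missing spacing/position information: {exc}") from exc
    if len(datasets) > 1:
        dz = float(np.median(np.diff(z_positions)))
        if dz <= 0:
            raise HeaderError("non-increasing slice positions")
    else:
        dz = float(getattr(datasets[0], "SliceThickness", 1.0))
    slices = []
    for d in datasets:
        arr = d.pixel_array.astype(np.float32)
        slope = float(getattr(d, "RescaleSlope", 1.0))
        intercept = float(getattr(d, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    # pydicom pixel_array is (rows, cols) = (y, x); transpose to (x, y)
    vol = np.stack([s.T for s in slices], axis=2)
    ipp = datasets[0].ImagePositionPatient
    origin = (float(ipp[0]), float(ipp[1]), float(z_positions[0]))
    # PixelSpacing is (row spacing, col spacing) = (dy, dx)
    return CTVolume(np.ascontiguousarray(vol), (px[1], px[0], dz), origin)


def write_ct(ct: CTVolume, path: str | os.PathLike) -> None:
    """Write a CT volume as NIfTI with geometry in the affine."""
    img = nib.Nifti1Image(np.asarray(ct.values, dtype=np.float32), _affine_from_geometry(ct.spacing, ct.origin))
    nib.save(img, str(path))


def write_mask(mask: BinaryMask, path: str | os.PathLike) -> None:
    """Write a binary mask as a uint8 NIfTI (lossless round-trip)."""
    img = nib.Nifti1Image(mask.values.astype(np.uint8), _affine_from_geometry(mask.spacing, mask.origin))
    nib.save(img, str(path))


def read_mask(path: str | os.PathLike, reference: CTVolume | None = None) -> BinaryMask:
    """Read a mask; if ``reference`` is given, verify geometry against it."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    flips, spacing, origin = _geometry_from_affine(img.affine, data.shape)
    for ax in flips:
        data = np.flip(data, axis=ax)
    mask = BinaryMask(np.ascontiguousarray(data) > 0, spacing, origin)
    if reference is not None:
        mask.check_alignment(reference)
    return mask


# ---------------------------------------------------------------------------
# Metric tables
# ---------------------------------------------------------------------------

#: units for every metric/cohort column this package emits
COLUMN_DICTIONARY: dict[str, str] = {
    "subject_id": "identifier",
    "awv_ml": "ml (airway lumen volume, RUL+RMLL)",
    "rlv_ml": "ml (right lung volume)",
    "awv_percent": "% (100*AWV/rLV)",
    "ct_tlv_ml": "ml (CT total lung volume, both lungs)",
    "lav_percent": "% (lung voxels < -950 HU)",
    "lav_percent_right": "% (right-lung voxels < -950 HU)",
    "tac": "count (RUL+RMLL skeleton branches)",
    "mean_ai_mm2": "mm^2 (lumen area, RB1/RB10 average)",
    "segmental_ai_mm2": "mm^2",
    "subsegmental_ai_mm2": "mm^2",
    "mean_wa_percent": "% (wall area percent)",
    "segmental_wa_percent": "%",
    "subsegmental_wa_percent": "%",
    "ptlc_ml": "ml (predicted total lung capacity)",
    "awv_over_ptlc_percent": "%",
    "rlv_over_ptlc_percent": "%",
    "ai_over_ptlc23_percent": "% (100*Ai/(pTLC in mm^3)^(2/3))",
    "ai_over_rlv23_percent": "% (100*Ai/(rLV in mm^3)^(2/3))",
    "fev1_l": "L",
    "pct_fev1": "% predicted",
    "fev1_fvc": "%",
    "rv_tlc": "%",
    "pct_tlc": "% predicted",
    "pct_dlco": "% predicted",
    "dlco_va": "ml/min/mmHg/L",
    "cat_score": "score 0-40",
    "age_yr": "years",
    "bmi": "kg/m^2",
    "height_m": "m",
    "pack_years": "pack-years",
    "gold_grade": "grade 1-4",
    "symptomatic": "bool (CAT >= 10)",
}

#: columns that must never contain missing values on write
REQUIRED_KEY_COLUMNS = ("subject_id",)


def write_metrics(metrics, path: str | os.PathLike, format: str = "json") -> None:
    """Write per-subject metrics (mapping) or a cohort table (DataFrame).

    Column units are documented in a ``<path>.dict.json`` sidecar.  Missing
    values are written as explicit nulls / empty fields, never silently
    defaulted.  A NaN in a required key column is a validation error.
    """
    p = Path(path)
    if format not in {"json", "csv"}:
        raise InvalidParameterError(f"unsupported metrics format: {format!r}")
    if isinstance(metrics, pd.DataFrame):
        table = metrics
        for col in REQUIRED_KEY_COLUMNS:
            if col in table.columns and table[col].isna().any():
                raise ValidationError(f"NaN in required key column {col!r}")
        if format == "csv":
            table.to_csv(p, index=False)
        else:
            p.write_text(table.to_json(orient="records", indent=2))
        used = [c for c in table.columns]
    else:
        record = dict(metrics)
        for col in REQUIRED_KEY_COLUMNS:
            if col in record and record[col] is not None and (
                isinstance(record[col], float) and math.isnan(record[col])
            ):
                raise ValidationError(f"NaN in required key column {col!r}")
        clean = {k: (None if _is_nan(v) else v) for k, v in record.items()}
        if format == "json":
            p.write_text(json.dumps(clean, indent=2, sort_keys=True) + "\n")
        else:
            pd.DataFrame([clean]).to_csv(p, index=False)
        used = list(clean)
    sidecar = {c: COLUMN_DICTIONARY.get(c, "undocumented") for c in used}
    Path(str(p) + ".dict.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")


def read_metrics_table(path: str | os.PathLike) -> pd.DataFrame:
    p = Path(path)
    if p.suffix == ".json":
        return pd.read_json(p)
    return pd.read_csv(p)


def _is_nan(v) -> bool:
    return isinstance(v, float) and math.isnan(v)
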