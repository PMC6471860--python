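"""Derived CT indices and clinical classifications.

The central index is the airway volume percent,

    AWV% = 100 * AWV / rLV,

the percentage ratio of the right-lung airway-tree volume (ml) to right
lung volume (ml).  Because central airway size scales with the natural size
of the lung, AWV and rLV are additionally normalized by the predicted total
lung capacity (pTLC) from a demographic reference equation, and lumen area
Ai (mm^2) by the 2/3 power of a volume (all lengths in mm before
exponentiation, so the ratio is dimensionless and reported x100 as %).
GOLD spirometric grade and the CAT >= 10 symptomatic flag follow their
standard cut-offs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError, EmptyInputError


@dataclass
class SubjectMetrics:
    """Per-subject CT measures and derived indices (None = not measured)."""

    subject_id: str = "subject"
    awv_ml: float | None = None
    rlv_ml: float | None = None
    awv_percent: float | None = None
    ct_tlv_ml: float | None = None
    lav_percent: float | None = None
    lav_percent_right: float | None = None
    tac: int | None = None
    mean_ai_mm2: float | None = None
    segmental_ai_mm2: float | None = None
    subsegmental_ai_mm2: float | None = None
    mean_wa_percent: float | None = None
    segmental_wa_percent: float | None = None
    subsegmental_wa_percent: float | None = None
    ptlc_ml: float | None = None
    awv_over_ptlc_percent: float | None = None
    rlv_over_ptlc_percent: float | None = None
    ai_over_ptlc23_percent: float | None = None
    ai_over_rlv23_percent: float | None = None

    def as_dict(self) -> dict:
        return asdict(self)


def awv_percent(awv_ml: float, rlv_ml: float) -> float:
    """Airway volume percent: 100 * AWV / rLV."""
    if rlv_ml <= 0:
        raise DomainError(f"rLV must be > 0, got {rlv_ml}")
    if awv_ml < 0:
        raise DomainError(f"AWV must be >= 0, got {awv_ml}")
    return 100.0 * awv_ml / rlv_ml


# ---------------------------------------------------------------------------
# Predicted TLC reference equations
# ---------------------------------------------------------------------------

#: registry of male TLC reference equations, liters from (height m, age yr)
_PTLC_EQUATIONS: dict[str, Callable[[float, float], float]] = {}


def register_ptlc_equation(name: str, fn: Callable[[float, float], float]) -> None:
    """Register (or replace) a pTLC reference equation under ``name``."""
    _PTLC_EQUATIONS[name] = fn


register_ptlc_equation("ecsc_male", lambda height_m, age_yr: 7.99 * height_m - 7.08)
# Quanjer/GLI-era male alternative kept as a second registry entry so
# swapping equations never requires code changes
register_ptlc_equation("quanjer_male", lambda height_m, age_yr: 7.99 * height_m - 7.08)


def predicted_tlc(height_m: float, age_yr: float = 65.0, equation: str = "ecsc_male") -> float:
    """Predicted total lung capacity (liters) for a male of given height/age.

    The default is the ECSC male reference 7.99 * height(m) - 7.08 L.
    Alternative equations can be registered by id.
    """
    if height_m <= 0:
        raise DomainError(f"height must be > 0 m, got {height_m}")
    fn = _PTLC_EQUATIONS.get(equation)
    if fn is None:
        raise ConfigError(f"pTLC equation {equation!r} is not registered (have {sorted(_PTLC_EQUATIONS)})")
    return float(fn(height_m, age_yr))


def normalized_indices(metrics: SubjectMetrics, ptlc_ml: float) -> SubjectMetrics:
    """Fill size-normalized indices into ``metrics`` (in place, returned).

    AWV/pTLC and rLV/pTLC are plain percentage volume ratios; Ai over a
    volume^(2/3) converts the volume to mm^3 first so the ratio is
    dimensionless, then reports x100.  Missing inputs leave explicit None.
    """
    if ptlc_ml <= 0:
        raise DomainError("pTLC must be > 0 ml")
    metrics.ptlc_ml = float(ptlc_ml)
    if metrics.awv_ml is not None:
        metrics.awv_over_ptlc_percent = 100.0 * metrics.awv_ml / ptlc_ml
    if metrics.rlv_ml is not None:
        metrics.rlv_over_ptlc_percent = 100.0 * metrics.rlv_ml / ptlc_ml
    if metrics.mean_ai_mm2 is not None:
        metrics.ai_over_ptlc23_percent = 100.0 * metrics.mean_ai_mm2 / (ptlc_ml * 1000.0) ** (2.0 / 3.0)
        if metrics.rlv_ml is not None and metrics.rlv_ml > 0:
            metrics.ai_over_rlv23_percent = 100.0 * metrics.mean_ai_mm2 / (metrics.rlv_ml * 1000.0) ** (2.0 / 3.0)
    if metrics.awv_ml is not None and metrics.rlv_ml is not None and metrics.rlv_ml > 0:
        metrics.awv_percent = awv_percent(metrics.awv_ml, metrics.rlv_ml)
    return metrics


# ---------------------------------------------------------------------------
# Clinical classifications
# ---------------------------------------------------------------------------

def gold_grade(pct_fev1: float) -> int:
    """GOLD spirometric grade from %predicted FEV1.

    Standard cut-offs with inclusive lower bounds: >= 80 grade 1,
    50-79.99 grade 2, 30-49.99 grade 3, < 30 grade 4.
    """
    if not pct_fev1 > 0:
        raise DomainError(f"%FEV1 must be > 0, got {pct_fev1}")
    if pct_fev1 >= 80:
        return 1
    if pct_fev1 >= 50:
        return 2
    if pct_fev1 >= 30:
        return 3
    return 4


def symptomatic_flag(cat_score: float) -> bool:
    """Symptomatic iff CAT score >= 10 (inclusive); CAT range is 0-40."""
    if not (0 <= cat_score <= 40):
        raise DomainError(f"CAT score must lie in [0, 40], got {cat_score}")
    return cat_score >= 10


# ---------------------------------------------------------------------------
# Cohort summary
# ---------------------------------------------------------------------------

#: columns summarized as a count and rounded percent instead of mean +- SD
FLAG_COLUMNS = ("symptomatic",)


def cohort_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean +- SD (sample SD, n-1) per numeric variable; flags as n (%).

    Returns a tidy table with columns variable / n / mean / sd / display.
    A CAT-score column is summarized both ways: distribution and the
    fraction with CAT >= 10.
    """
    if len(table) == 0:
        raise EmptyInputError("cannot summarize an empty cohort")
    rows = []
    n_total = len(table)
    work = table.copy()
    if "cat_score" in work.columns and "symptomatic" not in work.columns:
        work["symptomatic"] = work["cat_score"] >= 10
    for col in work.columns:
        if col == "subject_id":
            continue
        series = work[col].dropna()
        n = len(series)
        if col in FLAG_COLUMNS or series.dtype == bool:
            count = int(series.astype(bool).sum())
            pct = round(100.0 * count / n) if n else None
            rows.append({"variable": col, "n": n, "mean": None, "sd": None, "display": f"{count} ({pct}%)"})
            continue
        if not np.issubdtype(series.dtype, np.number):
            continue
        mean = float(series.mean())
        sd = float(series.std(ddof=1)) if n > 1 else None
        disp = f"{mean:.1f} ± {sd:.1f}" if sd is not None else f"{mean:.1f} ± null"
        rows.append({"variable": col, "n": n, "mean": mean, "sd": sd, "display": disp})
    out = pd.DataFrame(rows)
    out.attrs["n_subjects"] = n_total
    return out
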