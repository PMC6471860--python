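"""End-to-end orchestration: CT -> segmentation -> graph -> metrics -> indices.

``run_subject`` executes every imaging stage for one CT volume and writes
all artifacts (masks, graph, cross-section table, metrics JSON) plus a
provenance record (config hash, package version, accepted segmentation
threshold).  ``run_cohort`` aggregates per-subject metrics with lung
function into the three cohort reports: summary (mean ± SD), correlation
and standardized-beta regression tables.

Right-lung-only analysis is the default: the airway tree is partitioned
into RUL/RMLL subtrees and AWV counts only those branches.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import airway_metrics, airway_seg, imaging_io, indices, lung_metrics, skeleton_graph
from .cohort_stats import anova_across_gold, fit_standardized_ols, group_compare, pearson_matrix
from .errors import ConfigError, EmptyInputError, PipelineStageError

log = logging.getLogger(__name__)

#: default stage parameter blocks; unknown keys in a user config are errors
DEFAULT_CONFIG: dict = {
    "seg": {
        "initial_threshold_hu": -960.0,
        "step_hu": 4.0,
        "max_threshold_hu": -850.0,
        "leakage_factor": 2.0,
        "connectivity": 26,
    },
    "skeleton": {
        "prune_mm": 2.0,
        "rul_root": "auto",   # branch id, or "auto" = first child of the root branch
        "rmll_root": "auto",
    },
    "fwhm": {
        "plane_res_mm": 0.1,
        "plane_size_mm": 14.0,
        "sampling_fractions": [0.25, 0.5, 0.75],
        "segmental_generation": 2,
        "subsegmental_generation": 3,
    },
    "lung": {"lav_threshold_hu": -950.0},
    "indices": {"height_m": 1.67, "age_yr": 65.0, "ptlc_equation": "ecsc_male"},
    "stats": {
        "ct_predictors": ["awv_percent", "lav_percent", "wa_percent", "mean_wa_percent", "tac"],
        "outcomes": ["pct_fev1", "rv_tlc"],
        "covariates": ["age_yr", "bmi", "pack_years"],
    },
    "seed": 0,
    "log_level": "INFO",
}


def load_config(path: str | None = None, overrides: dict | None = None) -> dict:
    """Merge a YAML config file and overrides onto the defaults.

    Unknown keys anywhere in the tree raise :class:`ConfigError`.
    """
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for source in (yaml.safe_load(Path(path).read_text()) if path else None, overrides):
        if not source:
            continue
        _merge_checked(cfg, source, trail="")
    return cfg


def _merge_checked(base: dict, update: dict, trail: str) -> None:
    for key, value in update.items():
        if key not in base:
            raise ConfigError(f"unknown config key {trail + key!r}")
        if isinstance(base[key], dict) and isinstance(value, dict):
            _merge_checked(base[key], value, trail=f"{trail}{key}.")
        else:
            base[key] = value


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Per-subject pipeline
# ---------------------------------------------------------------------------

def run_subject(
    ct_path: str | Path,
    config: dict | None = None,
    out_dir: str | Path | None = None,
    subject_id: str = "subject",
    airway_mask_path: str | Path | None = None,
) -> indices.SubjectMetrics:
    """Run the full imaging pipeline for one CT volume.

    Stages: read CT, trachea seed + region growing (or import an external
    airway mask), skeletonize, branch graph + spur pruning, RUL/RMLL
    partition, TAC, AWV, lung segmentation + volumes + LAV%, FWHM path
    measures, derived indices.  Artifacts land in ``out_dir`` when given;
    any stage failure is re-raised as :class:`PipelineStageError` naming
    the stage, leaving earlier artifacts in place with a failure marker.
    """
    cfg = config or load_config()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    info: dict = {}

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            if out is not None:
                (out / "FAILED").write_text(f"{name}: {exc}\n")
            raise PipelineStageError(name, exc) from exc

    ct = stage("read_ct", lambda: imaging_io.read_ct(ct_path))

    if airway_mask_path is not None:
        airway = stage("read_mask", lambda: imaging_io.read_mask(airway_mask_path, reference=ct))
        info["seg"] = {"imported": True}
    else:
        def _segment():
            seed = airway_seg.find_trachea_seed(ct)
            params = airway_seg.SegParams(**cfg["seg"])
            mask, seg_info = airway_seg.grow_airway_tree(ct, seed, params, return_info=True)
            seg_info["seed"] = list(seed)
            return mask, seg_info

        airway, info["seg"] = stage("airway_seg", _segment)

    def _graph():
        sk = skeleton_graph.skeletonize_mask(airway)
        g = skeleton_graph.build_branch_graph(sk, ct.spacing, keep_largest=True)
        g = skeleton_graph.prune_spurs(g, cfg["skeleton"]["prune_mm"])
        rul = cfg["skeleton"]["rul_root"]
        rmll = cfg["skeleton"]["rmll_root"]
        if rul == "auto" or rmll == "auto":
            rul, rmll = skeleton_graph.main_bifurcation_children(g)
        skeleton_graph.partition_subtrees(g, rul, rmll)
        return g

    graph = stage("skeleton_graph", _graph)
    tac = stage("tac", lambda: skeleton_graph.total_airway_count(graph))
    awv = stage("awv", lambda: airway_metrics.airway_volume_ml(airway, graph))

    def _lung():
        return lung_metrics.measure_lungs(ct, airway, cfg["lung"]["lav_threshold_hu"])

    lung_measure, right, left = stage("lung_metrics", _lung)

    def _paths():
        fw = cfg["fwhm"]
        specs = []
        for label, name in (("RUL", "RB1"), ("RMLL", "RB10")):
            seg_ids = [
                b.id
                for b in graph.branches.values()
                if b.label == label and b.generation == fw["segmental_generation"]
            ]
            sub_ids = [
                b.id
                for b in graph.branches.values()
                if b.label == label and b.generation == fw["subsegmental_generation"]
            ]
            if seg_ids or sub_ids:
                specs.append((name, seg_ids, sub_ids))
        if not specs:
            return [], {}
        return airway_metrics.measure_paths(
            ct, graph, specs, fractions=tuple(fw["sampling_fractions"])
        )

    path_measures, overall = stage("fwhm_paths", _paths)

    metrics = indices.SubjectMetrics(
        subject_id=subject_id,
        awv_ml=awv,
        rlv_ml=lung_measure.rlv_ml,
        ct_tlv_ml=lung_measure.ct_tlv_ml,
        lav_percent=lung_measure.lav_percent_both,
        lav_percent_right=lung_measure.lav_percent_right,
        tac=tac,
        mean_ai_mm2=overall.get("mean_ai_mm2"),
        segmental_ai_mm2=overall.get("segmental_ai_mm2"),
        subsegmental_ai_mm2=overall.get("subsegmental_ai_mm2"),
        mean_wa_percent=overall.get("mean_wa_percent"),
        segmental_wa_percent=overall.get("segmental_wa_percent"),
        subsegmental_wa_percent=overall.get("subsegmental_wa_percent"),
    )
    ptlc_l = indices.predicted_tlc(
        cfg["indices"]["height_m"], cfg["indices"]["age_yr"], cfg["indices"]["ptlc_equation"]
    )
    indices.normalized_indices(metrics, ptlc_l * 1000.0)

    if out is not None:
        imaging_io.write_mask(airway, out / "airway_mask.nii.gz")
        imaging_io.write_mask(right, out / "right_lung_mask.nii.gz")
        imaging_io.write_mask(left, out / "left_lung_mask.nii.gz")
        (out / "airway_graph.json").write_text(graph.to_json())
        imaging_io.write_metrics(metrics.as_dict(), out / "metrics.json")
        prov = {
            "config_hash": config_hash(cfg),
            "package_version": _pkg_version("awvct"),
            "stages": info,
        }
        (out / "provenance.json").write_text(json.dumps(prov, indent=2, sort_keys=True) + "\n")
    return metrics


# ---------------------------------------------------------------------------
# Cohort pipeline
# ---------------------------------------------------------------------------

def run_cohort(
    table: pd.DataFrame,
    config: dict | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Emit the three cohort reports from a per-subject table.

    The table must hold CT indices plus lung function; GOLD grades and the
    symptomatic flag are derived if absent.  With a single subject only the
    summary is produced (statistics stages are skipped with a log notice).
    """
    cfg = config or load_config()
    if len(table) == 0:
        raise EmptyInputError("empty cohort")
    work = table.copy()
    if "gold_grade" not in work.columns and "pct_fev1" in work.columns:
        work["gold_grade"] = [indices.gold_grade(v) for v in work["pct_fev1"]]
    if "symptomatic" not in work.columns and "cat_score" in work.columns:
        work["symptomatic"] = [indices.symptomatic_flag(v) for v in work["cat_score"]]

    reports: dict[str, pd.DataFrame] = {"summary": indices.cohort_summary(work)}

    stats_cfg = cfg["stats"]
    predictors = [c for c in stats_cfg["ct_predictors"] if c in work.columns]
    outcomes = [c for c in stats_cfg["outcomes"] if c in work.columns]
    covariates = [c for c in stats_cfg["covariates"] if c in work.columns]
    if len(work) < 4 or not predictors or not outcomes:
        log.info("cohort too small or no variables for statistics; summary only")
    else:
        corr = pearson_matrix(work, predictors + outcomes)
        reports["correlations"] = pd.DataFrame(
            [dataclasses.asdict(c) for c in corr]
        )
        reg_rows = []
        for outcome in outcomes:
            try:
                res = fit_standardized_ols(work, outcome, predictors, covariates)
            except Exception as exc:  # insufficient data / collinearity
                log.warning("regression for %s skipped: %s", outcome, exc)
                continue
            reg_rows.append(res.to_frame())
        if reg_rows:
            reports["regressions"] = pd.concat(reg_rows, ignore_index=True)

    if out_dir is not None:
        outp = Path(out_dir)
        outp.mkdir(parents=True, exist_ok=True)
        for name, df in reports.items():
            df.to_csv(outp / f"{name}.csv", index=False)
    return reports
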