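"""End-to-end analysis pipeline and companion statistics.

Orchestrates the full reanalysis workflow on a migration dataset: marker QC
filtering, outlier screening, the doubly repeated-measures mixed model on
both the original cohort and the cohort without outliers (joint 3D group
test, per-axis effect slices, LS-means), and the routine companion tests
reported alongside the core model (Levene variance comparison at the final
visit, Fisher exact test on outlier counts, post hoc Pearson correlations).
The report is a plain serializable structure with a provenance block, and
report generation is pure: identical inputs give an identical report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .config import AXES
from .quality import (
    QcMetrics,
    flag_outliers,
    flag_unacceptable,
    iqr_cutoffs,
    trial_outlier_rules,
)
from .lmm import (
    build_model_frame,
    fit_mv_lmm,
    lsmeans,
    simplify_model,
    slice_by_axis,
    standardize_by_axis,
    test_3d_group_effect,
)

__all__ = ["PipelineConfig", "AnalysisReport", "run_pipeline", "companion_tests"]

log = logging.getLogger("rsamix.pipeline")


class PipelineError(ValueError):
    """Input-validation failure with a named stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the end-to-end analysis."""

    screened_axes: tuple = ("ty", "ry")
    recompute_cutoffs: bool = False   # derive IQR rules from the data instead
    cutoff_week: int | None = None    # week used when recomputing (None = all)
    formula: str = "value ~ group * week * axis"
    cov_structure: str = "kronecker_un"
    simplify: bool = True
    alpha_keep: float = 0.05
    companion_week: int = 48
    seed: int | None = None

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """Serializable analysis report (two cohorts + companion tests)."""

    outliers: dict
    cohorts: dict
    companion: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "outliers": self.outliers,
            "cohorts": self.cohorts,
            "companion": self.companion,
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True,
                          default=_jsonify)
        if path is not None:
            Path(path).write_text(text)
        return text

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


def _jsonify(x: Any):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.bool_,)):
        return bool(x)
    raise TypeError(f"not JSON serializable: {type(x)}")


def _validate_observations(obs: pd.DataFrame) -> pd.DataFrame:
    required = {"subject", "group", "week"}
    if not required <= set(obs.columns):
        raise PipelineError(
            f"observations missing columns {sorted(required - set(obs.columns))}"
        )
    unknown = [a for a in obs.columns if a.startswith(("t", "r"))
               and len(a) == 2 and a not in AXES]
    if unknown:
        raise PipelineError(f"unknown axis columns: {unknown}")
    present = [a for a in AXES if a in obs.columns]
    if not present:
        raise PipelineError("no migration axis columns found")
    return obs


def _qc_filter(obs: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    if not {"me", "cn"} <= set(obs.columns):
        return obs, 0
    bad = obs.apply(
        lambda r: flag_unacceptable(QcMetrics(r["me"], r["cn"])), axis=1
    )
    return obs[~bad].copy(), int(bad.sum())


def _fit_cohort(obs, cfg: PipelineConfig, exclude: set, name: str) -> dict:
    frame = build_model_frame(obs, exclude=exclude)
    n_subj = frame["subject"].nunique()
    counts = frame.groupby("group", observed=True)["subject"].nunique()
    if (counts < 2).any():
        raise PipelineError(
            f"cohort {name!r} has a group with fewer than 2 subjects"
        )
    log.info("cohort %s: %d subjects, %d cells", name, n_subj, len(frame))
    fit = fit_mv_lmm(frame, cfg.formula, cfg.cov_structure)
    if cfg.simplify:
        fit = simplify_model(fit, cfg.alpha_keep)
    joint = test_3d_group_effect(fit)
    slices = slice_by_axis(fit)
    ls_axis = lsmeans(fit, ("group", "axis", "week"))
    frame_std = standardize_by_axis(frame)
    fit_std = fit_mv_lmm(frame_std, fit.formula, cfg.cov_structure)
    ls_blend = lsmeans(fit_std, ("group", "week"))
    return {
        "n_subjects": int(n_subj),
        "n_cells": int(len(frame)),
        "model": fit.formula,
        "covariance": fit.structure.name,
        "reml_loglik": float(fit.loglik),
        "joint_3d_test": {
            "F": joint.F, "num_df": joint.num_df,
            "denom_df": joint.denom_df, "p": joint.p,
        },
        "axis_slices": slices.to_dict(orient="records"),
        "lsmeans_axis": ls_axis.to_dict(orient="records"),
        "lsmeans_3d_standardized": ls_blend.to_dict(orient="records"),
    }


def run_pipeline(observations: pd.DataFrame, cfg: PipelineConfig | None = None,
                 roster: pd.DataFrame | None = None) -> AnalysisReport:
    """Run QC, outlier screening and both cohort analyses; build the report.

    Parameters
    ----------
    observations
        Wide per-visit table (``subject``, ``group``, ``week``, axis
        columns, optional ``bmd_class`` and QC ``me``/``cn`` columns).
    roster
        Optional subject table used only for group sizes in the Fisher
        outlier-count test; derived from observations when absent.
    """
    cfg = cfg or PipelineConfig()
    obs = _validate_observations(observations).copy()
    obs, n_qc_dropped = _qc_filter(obs)
    log.info("QC filter: dropped %d examinations", n_qc_dropped)

    if cfg.recompute_cutoffs:
        rules = {}
        for ax in cfg.screened_axes:
            sub = obs if cfg.cutoff_week is None else obs[obs["week"] == cfg.cutoff_week]
            rules[ax] = iqr_cutoffs(sub[ax].to_numpy(float), ax)
    else:
        rules = trial_outlier_rules()
    outlier_ids, flag_report = flag_outliers(obs, rules, cfg.screened_axes)
    log.info("outlier screen: %d subjects flagged", len(outlier_ids))

    cohorts = {
        "original": _fit_cohort(obs, cfg, set(), "original"),
        "without_outliers": _fit_cohort(obs, cfg, outlier_ids, "without_outliers"),
    }

    companion = companion_tests(
        obs, outlier_ids=outlier_ids, roster=roster, week=cfg.companion_week
    )

    provenance = {
        "software": "rsamix",
        "version": __import__("rsamix").__version__,
        "config": asdict(cfg),
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "n_input_rows": int(len(observations)),
        "n_qc_dropped": n_qc_dropped,
        "outlier_rules": {
            ax: {"lower": r.lower, "upper": r.upper} for ax, r in rules.items()
        },
    }
    return AnalysisReport(
        outliers={
            "subjects": sorted(map(str, outlier_ids)),
            "flags": flag_report.to_dict(orient="records"),
        },
        cohorts=cohorts,
        companion=companion,
        provenance=provenance,
    )


def companion_tests(
    observations: pd.DataFrame,
    outlier_ids: set | None = None,
    roster: pd.DataFrame | None = None,
    week: int = 48,
) -> dict:
    """Routine companion statistics via standard library routines.

    * Levene's test for equality of group variances of final-visit
      subsidence, total translation and total rotation;
    * Fisher's exact test on per-group outlier counts;
    * post hoc Pearson correlation between early z-axis rotation and
      subsidence (and BMD change when a ``bmd_change`` column is present).
    """
    out: dict[str, Any] = {}
    last = observations[observations["week"] == week]
    groups = list(pd.unique(observations["group"]))
    if len(groups) == 2:
        metrics = {
            "ty": last["ty"],
            "total_translation": np.sqrt(
                last[["tx", "ty", "tz"]].pow(2).sum(axis=1)
            ),
            "total_rotation": np.sqrt(
                last[["rx", "ry", "rz"]].pow(2).sum(axis=1)
            ),
        }
        lev = {}
        for name, series in metrics.items():
            a = series[last["group"] == groups[0]].dropna()
            b = series[last["group"] == groups[1]].dropna()
            if len(a) > 1 and len(b) > 1:
                st, p = stats.levene(a, b)
                lev[name] = {"statistic": float(st), "p": float(p)}
        out["levene_week%d" % week] = lev

    if outlier_ids is not None and len(groups) == 2:
        if roster is None:
            roster = observations[["subject", "group"]].drop_duplicates()
        tab = []
        for g in groups:
            subj = set(roster.loc[roster["group"] == g, "subject"])
            k = len(subj & set(outlier_ids))
            tab.append([k, len(subj) - k])
        odds, p = stats.fisher_exact(tab)
        out["fisher_outliers"] = {
            "table": tab, "odds_ratio": float(odds), "p": float(p),
        }

    first_week = sorted(observations["week"].unique())[0]
    early = observations[observations["week"] == first_week]
    pears = {}
    pairs = [("rz", "ty")]
    if "bmd_change" in observations.columns:
        pairs.append(("rz", "bmd_change"))
    for a, b in pairs:
        sub = early[[a, b]].dropna()
        if len(sub) > 3:
            res = stats.pearsonr(sub[a], sub[b])
            lo, hi = res.confidence_interval()
            pears[f"{a}_vs_{b}"] = {
                "r": float(res.statistic), "p": float(res.pvalue),
                "ci_lower": float(lo), "ci_upper": float(hi),
                "week": int(first_week), "n": int(len(sub)),
            }
    out["pearson"] = pears
    return out
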