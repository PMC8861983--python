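"""Marker-based quality control and outlier screening.

Two examinations of the same bone-marker rigid body should differ only by a
rigid motion; the residual of the optimal (Kabsch) superposition — the mean
error of rigid-body fitting, ME — measures marker instability, and the
condition number CN of the marker configuration measures how degenerate the
marker scatter is.  Examinations exceeding configurable ME/CN thresholds are
discarded.  Separately, subjects with extreme migration are screened with the
standard quartile +/- 1.5*IQR rule; outlier handling is a non-destructive
*view* of the dataset so analyses can run on the original cohort and on the
cohort without outliers side by side.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.transform import Rotation

from .config import CN_MAX, CN_SCALE_MM, ME_MAX_MM, TRIAL_OUTLIER_CUTOFFS
from .geometry import MarkerSet

__all__ = [
    "QcMetrics",
    "OutlierRule",
    "rigid_fit_error",
    "condition_number",
    "flag_unacceptable",
    "iqr_cutoffs",
    "trial_outlier_rules",
    "flag_outliers",
]


@dataclass(frozen=True)
class QcMetrics:
    """Marker QC metrics: ME (mm) and CN (dimensionless, >= 1 in practice)."""

    me: float
    cn: float

    def __post_init__(self) -> None:
        if self.me < 0:
            raise ValueError("ME must be non-negative")


@dataclass(frozen=True)
class OutlierRule:
    """Per-axis (lower, upper) cut-offs; values strictly beyond either flag."""

    axis: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower <= self.upper:
            raise ValueError("lower cut-off must not exceed upper")

    def is_outlier(self, value: float) -> bool:
        return bool(value < self.lower or value > self.upper)


def rigid_fit_error(markers_ref: MarkerSet, markers_obs: MarkerSet) -> float:
    """Mean error of rigid-body fitting (ME) between two marker examinations.

    Least-squares rigid superposition (Kabsch) of the observed onto the
    reference configuration, matched by label; the residual distances d_i are
    summarised as sqrt(sum d_i^2 / (n - 1)), the RMS convention common in
    RSA.  Exactly rigid motion gives ME = 0.
    """
    if set(markers_ref.labels) != set(markers_obs.labels):
        raise ValueError("marker label sets differ between examinations")
    obs = markers_obs.reorder(markers_ref.labels)
    if markers_ref.is_collinear() or obs.is_collinear():
        raise ValueError("collinear marker configuration cannot be fitted")
    a = markers_ref.points - markers_ref.points.mean(axis=0)
    b = obs.points - obs.points.mean(axis=0)
    rot, _ = Rotation.align_vectors(a, b)  # rotates b onto a
    resid = a - rot.apply(b)
    n = len(a)
    return float(np.sqrt(np.sum(resid**2) / (n - 1)))


def condition_number(
    markers: MarkerSet, scale_mm: float = CN_SCALE_MM
) -> float:
    """Condition number (CN) of a marker configuration.

    The centred marker matrix is scaled by 1/sqrt(n) so its singular values
    are per-marker RMS spreads (mm) along the principal axes; CN is
    ``scale_mm`` divided by the smallest spread.  Poor (flat or clustered)
    scatter gives a large CN; collinear markers give +inf.  The numerator
    ships as a config constant so the conventional acceptability threshold
    of 150 is meaningful in mm units.
    """
    c = markers.points - markers.points.mean(axis=0)
    s = np.linalg.svd(c / np.sqrt(len(c)), compute_uv=False)
    if s[-1] <= 1e-12 * max(s[0], 1.0):
        return float("inf")
    return float(scale_mm / s[-1])


def flag_unacceptable(
    q: QcMetrics, me_max: float = ME_MAX_MM, cn_max: float = CN_MAX
) -> bool:
    """True when an examination fails QC: ME > me_max or CN > cn_max."""
    return bool(q.me > me_max or q.cn > cn_max)


def iqr_cutoffs(values: np.ndarray, axis: str = "") -> OutlierRule:
    """Quartile +/- 1.5*IQR outlier cut-offs for one migration axis.

    Quartiles use linear interpolation (the type-7 estimator, the numpy
    default).  Values strictly beyond a cut-off are flagged.
    """
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if v.size < 4:
        raise ValueError("need at least 4 values to estimate quartiles")
    q1, q3 = np.quantile(v, [0.25, 0.75])  # type-7 linear interpolation
    iqr = q3 - q1
    return OutlierRule(axis, q1 - 1.5 * iqr, q3 + 1.5 * iqr)


def trial_outlier_rules() -> dict[str, OutlierRule]:
    """The frozen cut-offs published for the trial cohort.

    Subsidence beyond 5.44 mm (ty below -5.44) and y-axis rotation beyond
    5.52 deg internal or 4.32 deg external.  These derive from the original
    patient-level data and cannot be recomputed here, so they ship as
    constants.
    """
    return {
        ax: OutlierRule(ax, lo, hi)
        for ax, (lo, hi) in TRIAL_OUTLIER_CUTOFFS.items()
    }


def flag_outliers(
    observations: pd.DataFrame,
    rules: dict[str, OutlierRule] | None = None,
    axes: tuple[str, ...] | None = None,
) -> tuple[set, pd.DataFrame]:
    """Flag subjects whose migration exceeds the cut-offs on any visit.

    Parameters
    ----------
    observations
        Wide per-visit table with columns ``subject``, ``week`` and one
        column per migration axis.
    rules
        Mapping axis -> :class:`OutlierRule`; defaults to the shipped trial
        cut-offs.
    axes
        Axes to screen; defaults to every axis with a rule.

    Returns
    -------
    (subjects, report)
        The set of flagged subject ids and a tidy report with one row per
        offending (subject, axis, week) cell.
    """
    if rules is None:
        rules = trial_outlier_rules()
    if axes is None:
        axes = tuple(rules)
    rows = []
    for ax in axes:
        if ax not in rules:
            raise KeyError(f"no outlier rule for axis {ax!r}")
        if ax not in observations.columns:
            raise KeyError(f"axis column {ax!r} missing from observations")
        rule = rules[ax]
        vals = observations[ax].to_numpy(float)
        mask = np.isfinite(vals) & ((vals < rule.lower) | (vals > rule.upper))
        for _, rec in observations.loc[mask].iterrows():
            rows.append(
                {
                    "subject": rec["subject"],
                    "axis": ax,
                    "week": rec["week"],
                    "value": rec[ax],
                    "lower": rule.lower,
                    "upper": rule.upper,
                }
            )
    report = pd.DataFrame(
        rows, columns=["subject", "axis", "week", "value", "lower", "upper"]
    )
    return set(report["subject"]), report


def rules_to_yaml(rules: dict[str, OutlierRule], path: str | Path) -> None:
    payload = {
        ax: {"lower": float(r.lower), "upper": float(r.upper)}
        for ax, r in rules.items()
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def rules_from_yaml(path: str | Path) -> dict[str, OutlierRule]:
    payload = yaml.safe_load(Path(path).read_text())
    return {
        ax: OutlierRule(ax, float(d["lower"]), float(d["upper"]))
        for ax, d in payload.items()
    }
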