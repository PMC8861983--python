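"""Synthetic trial generator.

Emulates the statistical structure of a two-arm RSA migration trial in
postmenopausal women: 33 treated and 32 placebo subjects followed at 12, 22
and 48 weeks; change-from-baseline migration following an early-settling
saturating trajectory A(1 - exp(-t/tau)); between-subject variation in the
settling asymptotes (smaller in the treated arm, emulating the observed
variance reduction); measurement noise at the published RSA precision
limits; a BMD-status mixture in which low-BMD subjects subside more; ~12%
of subjects injected as migration outliers beyond the shipped screening
cut-offs; and ~2.1% of visit records missing.  Everything is reproducible
from a seed.

The generator defines the conditions under which the analysis pipeline is
exercised and tested; it is deliberately simple (normal components, a
two-point outlier mixture) so that every injected feature is individually
recoverable by the corresponding pipeline stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AXES, PRECISION_95, PRECISION_TO_SD, TRIAL_OUTLIER_CUTOFFS
from .geometry import MarkerSet, RigidTransform, dof6_to_transform, Dof6

__all__ = [
    "TrialConfig",
    "TrialDataset",
    "MarkerFixture",
    "mean_trajectory",
    "generate_trial",
    "generate_marker_fixture",
]

BMD_CLASSES = ("normal", "osteopenia", "osteoporosis")


def _default_noise_sd() -> dict[str, float]:
    return {a: PRECISION_95[a] / PRECISION_TO_SD for a in AXES}


@dataclass(frozen=True)
class TrialConfig:
    """Generator configuration; defaults mirror the emulated trial.

    ``asymptote`` holds the per-axis settling asymptotes for a normal-BMD
    placebo subject (mm / degrees); ``low_bmd_ty_penalty`` adds extra
    subsidence for osteopenic/osteoporotic subjects; ``group_effect`` is
    added to treated-arm asymptotes (zero by default: the null).
    ``variance_reduction_treated`` multiplies the treated arm's
    between-subject asymptote *variance*.
    """

    n_treated: int = 33
    n_control: int = 32
    treated_label: str = "denosumab"
    control_label: str = "placebo"
    weeks: tuple = (12, 22, 48)
    tau_weeks: float = 8.0
    asymptote: dict = field(
        default_factory=lambda: {
            "tx": 0.05, "ty": -0.60, "tz": 0.05,
            "rx": 0.30, "ry": 0.80, "rz": -0.10,
        }
    )
    low_bmd_ty_penalty: float = -0.90
    group_effect: dict = field(default_factory=dict)
    between_sd: dict = field(
        default_factory=lambda: {
            "tx": 0.08, "ty": 0.50, "tz": 0.15,
            "rx": 0.30, "ry": 1.20, "rz": 0.15,
        }
    )
    variance_reduction_treated: float = 0.6
    bmd_mixture: tuple = (0.50, 0.46, 0.04)  # normal / osteopenia / osteoporosis
    noise_sd: dict = field(default_factory=_default_noise_sd)
    outlier_rate: float = 0.12
    outlier_scale: tuple = (1.15, 1.8)
    missing_rate: float = 0.021

    def __post_init__(self):
        if self.n_treated < 2 or self.n_control < 2:
            raise ValueError("each arm needs at least 2 subjects")
        if self.tau_weeks <= 0:
            raise ValueError("settling time tau must be positive")
        for r in (self.outlier_rate, self.missing_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if not np.isclose(sum(self.bmd_mixture), 1.0):
            raise ValueError("BMD mixture must sum to 1")


@dataclass
class TrialDataset:
    """Roster (one row per subject) plus wide per-visit observations.

    ``roster`` columns: subject, group, bmd_class, plus generator truth
    columns ``injected_outlier`` and ``outlier_axis`` for testing.
    ``observations`` columns: subject, group, bmd_class, week, tx..rz.
    """

    roster: pd.DataFrame
    observations: pd.DataFrame
    config: TrialConfig | None = None
    seed: int | None = None

    def to_csv(self, roster_path: str | Path, obs_path: str | Path) -> None:
        self.roster.to_csv(roster_path, index=False)
        self.observations.to_csv(obs_path, index=False)

    @classmethod
    def from_csv(cls, roster_path, obs_path) -> "TrialDataset":
        return cls(pd.read_csv(roster_path), pd.read_csv(obs_path))


def mean_trajectory(
    cfg: TrialConfig, axis: str, group: str, bmd_class: str, week: float
) -> float:
    """Expected change from baseline: A (1 - exp(-week / tau)).

    The asymptote A depends on axis, treatment arm and BMD class (low-BMD
    subjects subside more).
    """
    A = cfg.asymptote[axis]
    if axis == "ty" and bmd_class in ("osteopenia", "osteoporosis"):
        A += cfg.low_bmd_ty_penalty
    if group == cfg.treated_label:
        A += cfg.group_effect.get(axis, 0.0)
    return float(A * (1.0 - np.exp(-week / cfg.tau_weeks)))


def _draw_outlier_asymptote(rng: np.random.Generator, cfg: TrialConfig):
    """Outlier mechanism: inflate one principal axis beyond its cut-off."""
    lo, hi = cfg.outlier_scale
    s = rng.uniform(lo, hi)
    if rng.random() < 0.5:
        return "ty", TRIAL_OUTLIER_CUTOFFS["ty"][0] * s       # deep subsidence
    if rng.random() < 0.5:
        return "ry", TRIAL_OUTLIER_CUTOFFS["ry"][1] * s       # internal rot.
    return "ry", TRIAL_OUTLIER_CUTOFFS["ry"][0] * s           # external rot.


def generate_trial(cfg: TrialConfig, seed: int = 0) -> TrialDataset:
    """Generate a reproducible trial-like dataset.

    Each subject gets a random asymptote vector (between-subject scatter,
    reduced variance in the treated arm), an early-settling trajectory
    evaluated at each visit, and per-visit measurement noise.  With
    probability ``outlier_rate`` a subject's principal-axis asymptote is
    replaced by a value beyond the shipped screening cut-off; whole visit
    records are deleted with probability ``missing_rate``.
    """
    rng = np.random.default_rng(seed)
    subjects = []
    for arm, n in (
        (cfg.treated_label, cfg.n_treated),
        (cfg.control_label, cfg.n_control),
    ):
        for i in range(n):
            subjects.append((f"{arm[:1].upper()}{i + 1:03d}", arm))

    # the settling fraction never exceeds 1, so asymptotes beyond a cut-off
    # must clear it after multiplying by the 48-week fraction
    frac = {w: 1.0 - np.exp(-w / cfg.tau_weeks) for w in cfg.weeks}

    roster_rows = []
    obs_rows = []
    for sid, arm in subjects:
        bmd = BMD_CLASSES[rng.choice(3, p=np.asarray(cfg.bmd_mixture))]
        var_fac = (
            cfg.variance_reduction_treated if arm == cfg.treated_label else 1.0
        )
        asym = {}
        for ax in AXES:
            mean_a = cfg.asymptote[ax]
            if ax == "ty" and bmd != "normal":
                mean_a += cfg.low_bmd_ty_penalty
            if arm == cfg.treated_label:
                mean_a += cfg.group_effect.get(ax, 0.0)
            asym[ax] = mean_a + np.sqrt(var_fac) * cfg.between_sd[ax] * rng.standard_normal()
        injected = rng.random() < cfg.outlier_rate
        out_axis = ""
        if injected:
            out_axis, val = _draw_outlier_asymptote(rng, cfg)
            asym[out_axis] = val / frac[max(cfg.weeks)]
        roster_rows.append(
            {
                "subject": sid,
                "group": arm,
                "bmd_class": bmd,
                "injected_outlier": injected,
                "outlier_axis": out_axis,
            }
        )
        for w in cfg.weeks:
            if rng.random() < cfg.missing_rate:
                continue
            rec = {"subject": sid, "group": arm, "bmd_class": bmd, "week": w}
            for ax in AXES:
                rec[ax] = asym[ax] * frac[w] + cfg.noise_sd[ax] * rng.standard_normal()
            obs_rows.append(rec)

    roster = pd.DataFrame(roster_rows)
    obs = pd.DataFrame(
        obs_rows, columns=["subject", "group", "bmd_class", "week", *AXES]
    )
    return TrialDataset(roster, obs, cfg, seed)


@dataclass
class MarkerFixture:
    """A marker configuration observed at two examinations."""

    markers_baseline: MarkerSet
    markers_followup: MarkerSet
    baseline: RigidTransform
    followup: RigidTransform


def generate_marker_fixture(
    rng: np.random.Generator,
    n_markers: int = 6,
    jitter_sd: float = 0.0,
    radius_mm: float = 50.0,
) -> MarkerFixture:
    """Trochanteric-scale marker set plus a baseline/follow-up pose pair.

    Markers are drawn inside a sphere of the given radius (re-drawn if
    nearly collinear); the follow-up pose applies a small random migration.
    Optional isotropic per-marker jitter (SD in mm) emulates marker
    instability for ME testing.
    """
    if n_markers < 4:
        raise ValueError("need at least 4 markers")
    while True:
        pts = rng.uniform(-radius_mm, radius_mm, size=(n_markers, 3))
        pts = pts[np.linalg.norm(pts, axis=1) <= radius_mm + 1e-9]
        if len(pts) < n_markers:
            extra = rng.normal(scale=radius_mm / 2.0, size=(n_markers, 3))
            pts = np.vstack([pts, extra])[:n_markers]
        ms = MarkerSet(pts)
        if not ms.is_collinear(tol=1e-3):
            break
    baseline = RigidTransform.identity()
    mig = Dof6(
        *rng.normal(scale=0.5, size=3), *rng.normal(scale=1.0, size=3)
    )
    followup = dof6_to_transform(mig)
    moved = followup.compose(baseline.inverse()).apply(ms.points)
    if jitter_sd > 0:
        moved = moved + rng.normal(scale=jitter_sd, size=moved.shape)
    return MarkerFixture(ms, MarkerSet(moved, ms.labels), baseline, followup)
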