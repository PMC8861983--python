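"""Shared fixtures: seeded RNGs and synthetic datasets reused across tests."""

import numpy as np
import pandas as pd
import pytest

from rsamix.config import AXES
from rsamix.synthetic import TrialConfig, generate_trial


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def trial_dataset():
    """One default synthetic trial (65 subjects, outliers + missingness)."""
    return generate_trial(TrialConfig(), seed=3)


def make_single_visit_obs(
    n1: int, n2: int, seed: int = 0, shift: dict | None = None,
    sigma: np.ndarray | None = None,
) -> pd.DataFrame:
    """Wide single-visit observations: two groups, all six axes."""
    rng = np.random.default_rng(seed)
    sigma = np.eye(6) if sigma is None else sigma
    L = np.linalg.cholesky(sigma)
    rows = []
    for g, n in (("denosumab", n1), ("placebo", n2)):
        for i in range(n):
            y = L @ rng.standard_normal(6)
            if shift and g == "denosumab":
                y = y + np.array([shift.get(a, 0.0) for a in AXES])
            rec = {"subject": f"{g[:1]}{i}", "group": g, "week": 12}
            rec.update(dict(zip(AXES, y)))
            rows.append(rec)
    return pd.DataFrame(rows)


def make_multivisit_obs(
    n_per_group: int, seed: int = 0, axes=("ty", "rz"), weeks=(12, 48),
    shift: dict | None = None, sd: float = 1.0,
) -> pd.DataFrame:
    """Small multi-visit dataset with independent cells (fast to fit)."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in ("denosumab", "placebo"):
        for i in range(n_per_group):
            for w in weeks:
                rec = {"subject": f"{g[:1]}{i}", "group": g, "week": w}
                for ax in axes:
                    v = sd * rng.standard_normal()
                    if shift and g == "denosumab":
                        v += shift.get(ax, 0.0)
                    rec[ax] = v
                rows.append(rec)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def session_pipeline_report(trial_dataset):
    """Full two-cohort pipeline run on the default synthetic trial."""
    from rsamix.pipeline import PipelineConfig, run_pipeline

    return run_pipeline(
        trial_dataset.observations, PipelineConfig(), roster=trial_dataset.roster
    )
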