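"""The doubly repeated-measures mixed model: REML, Kenward-Roger, LS-means.

The key correctness anchors are classical equivalences that the KR-adjusted
model must reproduce *exactly* in balanced complete designs: the pooled
two-sample t-test for a single response and the two-sample Hotelling T^2
test for a complete multivariate response.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_multivisit_obs, make_single_visit_obs
from rsamix.config import AXES
from rsamix.inference import kenward_roger_test, satterthwaite_df
from rsamix.lmm import (
    ConvergenceError,
    build_model_frame,
    fit_mv_lmm,
    hotelling_two_sample,
    hotelling_two_sample_batch,
    lsmeans,
    simplify_model,
    slice_by_axis,
    standardize_by_axis,
    test_3d_group_effect as joint_group_test,
)


def _kron_frame(n, seed=7, T=None, A=None, group_shift=None):
    rng = np.random.default_rng(seed)
    if T is None:
        T = np.array([[1.0, 0.7, 0.5], [0.7, 1.3, 0.8], [0.5, 0.8, 1.6]])
    if A is None:
        A0 = rng.normal(size=(6, 6))
        A = A0 @ A0.T / 6 + np.eye(6) * 0.3
    L = np.linalg.cholesky(np.kron(T, A))
    rows = []
    for i in range(n):
        g = "denosumab" if i < n // 2 else "placebo"
        y = L @ rng.standard_normal(18)
        if group_shift is not None and g == "denosumab":
            y = y + np.tile(group_shift, 3)
        k = 0
        for w in (12, 22, 48):
            for ax in AXES:
                rows.append({"subject": f"s{i:03d}", "group": g, "week": w,
                             "axis": ax, "value": y[k]})
                k += 1
    obs = (
        pd.DataFrame(rows)
        .pivot_table(index=["subject", "group", "week"], columns="axis",
                     values="value")
        .reset_index()
    )
    return build_model_frame(obs), np.kron(T, A)


class TestModelFrame:
    def test_complete_cell_count(self, trial_dataset):
        obs = trial_dataset.observations
        frame = build_model_frame(obs)
        assert len(frame) == 6 * len(obs)  # one row per observed visit x axis

    def test_cohort_view_drops_subjects(self, trial_dataset):
        obs = trial_dataset.observations
        drop = set(obs["subject"].unique()[:8])
        frame = build_model_frame(obs, exclude=drop)
        assert set(frame["subject"]) == set(obs["subject"]) - drop

    def test_missing_cells_dropped_not_imputed(self):
        obs = make_single_visit_obs(5, 5, seed=1)
        obs.loc[0, "ty"] = np.nan
        frame = build_model_frame(obs)
        assert len(frame) == 60 - 1

    def test_reference_group_is_placebo(self, trial_dataset):
        frame = build_model_frame(trial_dataset.observations)
        assert frame["group"].cat.categories[0] == "placebo"


class TestClassicalEquivalence:
    def test_single_axis_single_visit_equals_pooled_t(self):
        """F = t^2 and denominator df = n1 + n2 - 2, to within 1e-9."""
        obs = make_single_visit_obs(12, 14, seed=2)
        frame = build_model_frame(obs, axes=("ty",))
        fit = fit_mv_lmm(frame, "value ~ group", cov_structure="diagonal")
        res = fit.test_terms(["group"])
        y1 = obs.loc[obs.group == "denosumab", "ty"]
        y2 = obs.loc[obs.group == "placebo", "ty"]
        t, p = stats.ttest_ind(y1, y2)
        assert res.F == pytest.approx(t**2, abs=1e-9)
        assert res.denom_df == pytest.approx(24.0, abs=1e-9)
        assert res.p == pytest.approx(p, abs=1e-9)

    def test_balanced_six_axis_matches_hotelling(self):
        """Joint KR group test equals the Hotelling T^2 F-test within 1e-6."""
        obs = make_single_visit_obs(15, 15, seed=3, shift={"ty": 0.6})
        frame = build_model_frame(obs)
        fit = fit_mv_lmm(frame, "value ~ group * axis",
                         cov_structure="unstructured")
        res = joint_group_test(fit)
        Y1 = obs.loc[obs.group == "denosumab", list(AXES)].to_numpy()
        Y2 = obs.loc[obs.group == "placebo", list(AXES)].to_numpy()
        F, d1, d2, p = hotelling_two_sample(Y1, Y2)
        assert res.num_df == d1 == 6
        assert res.denom_df == pytest.approx(d2, abs=1e-6)
        assert res.F == pytest.approx(F, abs=1e-6)
        assert res.p == pytest.approx(p, abs=1e-6)

    def test_kronecker_reduces_to_unstructured_single_visit(self):
        obs = make_single_visit_obs(10, 11, seed=4)
        frame = build_model_frame(obs)
        fa = fit_mv_lmm(frame, "value ~ group * axis", cov_structure="unstructured")
        fb = fit_mv_lmm(frame, "value ~ group * axis", cov_structure="kronecker_un")
        ra, rb = joint_group_test(fa), joint_group_test(fb)
        assert ra.F == pytest.approx(rb.F, abs=1e-5)
        assert ra.denom_df == pytest.approx(rb.denom_df, abs=1e-4)

    def test_identical_groups_give_zero_f(self):
        rng = np.random.default_rng(0)
        Y = rng.standard_normal((12, 6))
        rows = []
        for g in ("denosumab", "placebo"):
            for i, y in enumerate(Y):  # exact copy of the other group
                rec = {"subject": f"{g}{i}", "group": g, "week": 12}
                rec.update(dict(zip(AXES, y)))
                rows.append(rec)
        frame = build_model_frame(pd.DataFrame(rows))
        fit = fit_mv_lmm(frame, "value ~ group * axis",
                         cov_structure="unstructured")
        res = joint_group_test(fit)
        assert res.F == pytest.approx(0.0, abs=1e-9)


class TestReml:
    def test_kronecker_covariance_recovery(self):
        """T (x) A recovered within 10% relative Frobenius error at n=200."""
        frame, V = _kron_frame(200)
        fit = fit_mv_lmm(frame, cov_structure="kronecker_un")
        err = np.linalg.norm(fit.V - V) / np.linalg.norm(V)
        assert err < 0.10
        assert fit.grad_norm < 1e-4

    def test_unstructured_nests_kronecker(self):
        frame, _ = _kron_frame(60, seed=12)
        fk = fit_mv_lmm(frame, cov_structure="kronecker_un")
        fu = fit_mv_lmm(frame, cov_structure="unstructured")
        assert fu.loglik >= fk.loglik - 1e-6

    def test_objective_trace_monotone(self):
        frame, _ = _kron_frame(60, seed=13)
        fit = fit_mv_lmm(frame, cov_structure="kronecker_un")
        tr = np.array(fit.objective_trace)
        assert np.all(np.diff(tr) >= -1e-8)  # REML loglik never decreases

    def test_needs_two_subjects_per_group(self):
        obs = make_single_visit_obs(1, 5, seed=0)
        frame = build_model_frame(obs)
        with pytest.raises(ValueError):
            fit_mv_lmm(frame, "value ~ group * axis")

    def test_nonconvergence_raises_diagnostic(self):
        frame, _ = _kron_frame(30, seed=14)
        with pytest.raises(ConvergenceError) as exc:
            fit_mv_lmm(frame, cov_structure="kronecker_un", max_iter=1,
                       fail_tol=1e-9)
        assert exc.value.grad_norm > 0

    def test_joint_test_size_calibrated(self):
        """Null rejection rate of the joint 6-axis group test at alpha=0.05
        over 1000 simulated balanced trials: 5% +/- 1.5%.

        Uses the closed-form balanced path, which equals the REML+KR joint
        test in this design (TestClassicalEquivalence)."""
        rng = np.random.default_rng(99)
        A0 = rng.normal(size=(6, 6))
        sigma = A0 @ A0.T / 6 + np.eye(6)
        L = np.linalg.cholesky(sigma)
        y1 = rng.standard_normal((1000, 30, 6)) @ L.T
        y2 = rng.standard_normal((1000, 30, 6)) @ L.T
        pvals = hotelling_two_sample_batch(y1, y2)
        assert np.mean(pvals < 0.05) == pytest.approx(0.05, abs=0.015)

    def test_permuted_labels_give_uniform_p(self):
        """Group-label permutation calibration: joint-test p-values are
        uniform under exchangeability (KS test at alpha = 0.01)."""
        rng = np.random.default_rng(5)
        Y = rng.standard_normal((40, 6)) @ np.diag([1, 2, 1, 0.5, 3, 1])
        pvals = []
        for _ in range(500):
            perm = rng.permutation(40)
            pvals.append(hotelling_two_sample(Y[perm[:20]], Y[perm[20:]])[3])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_injected_shift_detected(self):
        """Large all-axis group shift at n=30/group: rejection in nearly all
        simulations."""
        rng = np.random.default_rng(17)
        rej = 0
        reps = 200
        for _ in range(reps):
            y1 = rng.standard_normal((30, 6)) + 0.8
            y2 = rng.standard_normal((30, 6))
            rej += hotelling_two_sample(y1, y2)[3] < 0.05
        assert rej / reps > 0.95


class TestKenwardRoger:
    def test_satterthwaite_close_to_kr(self):
        frame, _ = _kron_frame(80, seed=21)
        fit = fit_mv_lmm(frame, cov_structure="kronecker_un")
        l = fit.contrast_for_terms(["group"])[0]
        kr = kenward_roger_test(fit, l[None, :])
        sat = satterthwaite_df(fit, l)
        assert sat == pytest.approx(kr.denom_df, rel=0.05)

    def test_rank_deficient_contrast_rejected(self):
        obs = make_single_visit_obs(8, 8, seed=6)
        frame = build_model_frame(obs)
        fit = fit_mv_lmm(frame, "value ~ group * axis",
                         cov_structure="diagonal")
        L = np.zeros((2, len(fit.beta)))
        L[0, 1] = 1.0
        L[1, 1] = 1.0  # duplicate row
        with pytest.raises(ValueError):
            kenward_roger_test(fit, L)

    def test_affine_invariance_of_joint_test(self):
        """Applying an invertible linear map to the 6-axis response block
        leaves the joint group test invariant (single visit, complete data,
        unstructured covariance) — the property that makes the multivariate
        test rotation-proof."""
        rng = np.random.default_rng(8)
        obs = make_single_visit_obs(14, 14, seed=8, shift={"ty": 0.5})
        M = rng.normal(size=(6, 6)) + np.eye(6) * 2
        obs2 = obs.copy()
        obs2[list(AXES)] = obs[list(AXES)].to_numpy() @ M.T
        # closed-form balanced path: exact invariance
        Y1 = obs.loc[obs.group == "denosumab", list(AXES)].to_numpy()
        Y2 = obs.loc[obs.group == "placebo", list(AXES)].to_numpy()
        p0 = hotelling_two_sample(Y1, Y2)[3]
        p1 = hotelling_two_sample(Y1 @ M.T, Y2 @ M.T)[3]
        assert p1 == pytest.approx(p0, abs=1e-10)
        # general REML route: invariant to optimizer precision
        fa = fit_mv_lmm(build_model_frame(obs), "value ~ group * axis",
                        cov_structure="unstructured")
        fb = fit_mv_lmm(build_model_frame(obs2), "value ~ group * axis",
                        cov_structure="unstructured")
        pa, pb = joint_group_test(fa).p, joint_group_test(fb).p
        assert pb == pytest.approx(pa, abs=2e-6)
        assert pa == pytest.approx(p0, abs=1e-6)


class TestSlicesAndLsmeans:
    def test_lsmeans_equal_cell_means_in_balanced_data(self):
        obs = make_multivisit_obs(10, seed=30, shift={"rz": 0.5})
        frame = build_model_frame(obs, axes=("ty", "rz"))
        fit = fit_mv_lmm(frame, cov_structure="kronecker_un")
        lm = lsmeans(fit, ("group", "week", "axis"))
        cells = (
            frame.groupby(["group", "week", "axis"], observed=True)["value"]
            .mean().reset_index()
        )
        merged = lm.merge(cells, on=["group", "week", "axis"])
        assert np.allclose(merged["estimate"], merged["value"], atol=1e-8)

    def test_slice_estimate_equals_raw_difference_when_balanced(self):
        obs = make_multivisit_obs(10, seed=31, shift={"rz": 0.7})
        frame = build_model_frame(obs, axes=("ty", "rz"))
        fit = fit_mv_lmm(frame, cov_structure="kronecker_un")
        sl = slice_by_axis(fit).set_index("axis")
        raw = frame.groupby(["axis", "group"], observed=True)["value"].mean().unstack()
        diff = raw["denosumab"] - raw["placebo"]
        for ax in ("ty", "rz"):
            assert sl.loc[ax, "estimate"] == pytest.approx(diff[ax], abs=1e-8)

    def test_signal_on_rz_only_flags_rz_slice(self):
        """Injected rz-only effect: the rz slice is significant and the
        other slices are not, in the large majority of simulations."""
        hits, false = 0, 0
        reps = 25
        for s in range(reps):
            obs = make_multivisit_obs(15, seed=100 + s, shift={"rz": 0.9},
                                      sd=0.8)
            frame = build_model_frame(obs, axes=("ty", "rz"))
            fit = fit_mv_lmm(frame, cov_structure="kronecker_un")
            sl = slice_by_axis(fit).set_index("axis")
            hits += sl.loc["rz", "p"] < 0.05
            false += sl.loc["ty", "p"] < 0.05
        assert hits / reps >= 0.9
        assert false / reps <= 0.2

    def test_ci_width_shrinks_with_sqrt_n(self):
        widths = []
        for n in (20, 80, 320):
            obs = make_multivisit_obs(n // 2, seed=40 + n, axes=("ty",),
                                      weeks=(12,))
            frame = build_model_frame(obs, axes=("ty",))
            fit = fit_mv_lmm(frame, "value ~ group", cov_structure="diagonal")
            lm = lsmeans(fit, ("group",))
            widths.append(float((lm["ci_upper"] - lm["ci_lower"]).mean()))
        assert widths[0] / widths[1] == pytest.approx(2.0, rel=0.25)
        assert widths[1] / widths[2] == pytest.approx(2.0, rel=0.25)

    def test_lsmean_coverage_near_nominal(self):
        """95% KR confidence intervals for group x week LS-means cover the
        true cell means at close to nominal rate."""
        rng = np.random.default_rng(55)
        truth = {("denosumab", 12): 0.4, ("denosumab", 48): 0.8,
                 ("placebo", 12): 0.0, ("placebo", 48): 0.1}
        covered = total = 0
        for s in range(60):
            rows = []
            for g in ("denosumab", "placebo"):
                for i in range(12):
                    base = rng.standard_normal() * 0.4  # subject effect
                    for w in (12, 48):
                        rows.append({
                            "subject": f"{g}{i}", "group": g, "week": w,
                            "ty": truth[(g, w)] + base + 0.6 * rng.standard_normal(),
                        })
            frame = build_model_frame(pd.DataFrame(rows), axes=("ty",))
            fit = fit_mv_lmm(frame, "value ~ group * week",
                             cov_structure="unstructured")
            lm = lsmeans(fit, ("group", "week"))
            for _, r in lm.iterrows():
                total += 1
                mu = truth[(r["group"], r["week"])]
                covered += r["ci_lower"] <= mu <= r["ci_upper"]
        assert covered / total >= 0.93


class TestSimplify:
    def test_main_effects_only_returned_unchanged(self):
        obs = make_multivisit_obs(8, seed=60)
        frame = build_model_frame(obs, axes=("ty", "rz"))
        fit = fit_mv_lmm(frame, "value ~ group + week + axis",
                         cov_structure="diagonal")
        out = simplify_model(fit)
        assert out is fit

    def test_null_interactions_usually_dropped(self):
        """With no true interactions, backward elimination ends at main
        effects only in most replicates."""
        kept_main_only = 0
        reps = 20
        for s in range(reps):
            obs = make_multivisit_obs(10, seed=200 + s)
            frame = build_model_frame(obs, axes=("ty", "rz"))
            fit = fit_mv_lmm(frame, cov_structure="diagonal")
            out = simplify_model(fit)
            if all(":" not in t for t in out.term_names):
                kept_main_only += 1
        assert kept_main_only / reps >= 0.7

    def test_strong_interaction_retained(self):
        """A strong group x axis interaction survives elimination."""
        retained = 0
        reps = 10
        for s in range(reps):
            obs = make_multivisit_obs(15, seed=300 + s, shift={"rz": 1.5},
                                      sd=0.6)
            frame = build_model_frame(obs, axes=("ty", "rz"))
            fit = fit_mv_lmm(frame, cov_structure="diagonal")
            out = simplify_model(fit)
            retained += any(
                set(t.split(":")) == {"group", "axis"} for t in out.term_names
            )
        assert retained >= 9

    def test_marginality_preserved(self):
        """A term contained in a retained higher-order interaction is never
        dropped, whatever its own p-value."""
        obs = make_multivisit_obs(15, seed=77, shift={"rz": 1.5}, sd=0.5)
        frame = build_model_frame(obs, axes=("ty", "rz"))
        fit = fit_mv_lmm(frame, cov_structure="diagonal")
        out = simplify_model(fit)
        terms = out.term_names
        for t in terms:
            parts = set(t.split(":"))
            if len(parts) > 1:
                for sub in parts:
                    assert sub in terms


class TestStandardizedBlend:
    def test_unit_pooled_sd_per_axis(self, trial_dataset):
        frame = build_model_frame(trial_dataset.observations)
        std = standardize_by_axis(frame)
        sds = std.groupby("axis", observed=True)["value"].std()
        assert np.allclose(sds, 1.0, atol=1e-12)
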