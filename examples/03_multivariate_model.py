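"""Fit the doubly repeated-measures mixed model to a synthetic trial.

Both the follow-up visit (12/22/48 weeks) and the migration axis (six
degrees of freedom) are treated as repeated measures with a separable
unstructured covariance; the treatment comparison is a single joint
Kenward-Roger F-test of all group-involving terms ("3D migration"),
followed by per-axis effect slices.
"""

from rsamix import (
    build_model_frame, fit_mv_lmm, lsmeans, slice_by_axis,
    test_3d_group_effect,
)
from rsamix.synthetic import TrialConfig, generate_trial

# inject a small valgus (rz) treatment effect so there is something to find
cfg = TrialConfig(group_effect={"rz": 0.5}, outlier_rate=0.0)
ds = generate_trial(cfg, seed=11)

frame = build_model_frame(ds.observations)
fit = fit_mv_lmm(frame, "value ~ group * week * axis",
                 cov_structure="kronecker_un")
print(f"REML converged: loglik = {fit.loglik:.1f}, "
      f"|grad| = {fit.grad_norm:.1e}")

joint = test_3d_group_effect(fit)
print(f"\njoint 3D group test: {joint}")
print("(tests all treatment-involving terms at once — one p-value for the "
      "whole 3D migration comparison)")

print("\nper-axis effect slices (group difference, averaged over visits):")
sl = slice_by_axis(fit)
print(sl[["axis", "estimate", "ci_lower", "ci_upper", "p"]]
      .round(3).to_string(index=False))
print("the injected rz effect should surface here, the other axes not")

print("\nLS-means of subsidence by group and visit:")
lm = lsmeans(fit, ("group", "week", "axis"))
print(lm[lm["axis"] == "ty"][["group", "week", "estimate", "ci_lower",
                              "ci_upper"]].round(3).to_string(index=False))
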