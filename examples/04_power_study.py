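"""Rotation-offset Monte Carlo power study.

The y-translation group difference is calibrated to 80% univariate t-test
power, then the data are rotated to offset angles from the y-axis before
analysis.  The univariate test decays as the signal leaves the tested axis;
the multivariate joint test is affine invariant and stays flat; the scalar
surrogate metrics (total translation/rotation) lose most of the power.
"""

from rsamix import SimConfig, power_sweep

cfg = SimConfig(n_per_group=30, n_iter=1000, seed=0,
                angles_deg=tuple(range(0, 91, 15)))
print(f"calibrated y-translation shift: {cfg.delta:.3f} mm "
      f"(80% t-test power at n = 30/group)\n")

curve = power_sweep(cfg)
table = curve.table.pivot(index="angle_deg", columns="method", values="power")
print(table[["t_y", "lmm_joint", "t_total_translation",
             "t_total_rotation"]].round(3).to_string())

print("\nangle-averaged power:")
for method, p in curve.angle_average().items():
    print(f"  {method:22s} {100 * p:5.1f}%")
print("\nthe multivariate joint test beats the univariate test on average "
      "because it does not depend on how the coordinate frame is aligned")
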