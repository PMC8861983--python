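"""Size a trial powered to compare migration-outlier rates.

With 2/33 outliers under treatment and 6/32 under placebo, the pooled
normal-approximation two-proportion formula gives the per-group sample size
needed for 80% power at two-sided alpha 0.05.
"""

from rsamix import sample_size_two_proportions

p_treated = 2 / 33
p_placebo = 6 / 32
n = sample_size_two_proportions(p_placebo, p_treated, alpha=0.05, power=0.80)
print(f"outlier rate treated:  {p_treated:.3f}")
print(f"outlier rate placebo:  {p_placebo:.3f}")
print(f"required group size:   {n}")
print("\na trial aiming to show outlier prevention needs about "
      f"{n} subjects per arm — roughly three times the size of a typical "
      "RSA migration trial")
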