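"""Minimal detectable effect size for a two-group anatomical comparison.

For 9 deprived vs 10 control animals the one-tailed two-sample t-test at
alpha 0.05 and power 0.8 resolves effects of about d = 1.2 — anything a
study of this size can rule out must be a large effect.
"""

from pialnet import PowerSpec, detectable_effect_size, normal_approx_effect_size

spec = PowerSpec(n1=10, n2=9, alpha=0.05, power=0.8, tails=1)
d = detectable_effect_size(spec)
print(f"noncentral-t minimal detectable d: {d:.4f} (~{d:.1f})")
print(f"normal-approximation shortcut:     {normal_approx_effect_size(spec):.4f}")
# the exact noncentral-t answer is always a bit larger than the normal
# shortcut because the pooled SD must itself be estimated from 17 df.

for n in (10, 20, 40):
    s = PowerSpec(n1=n, n2=n, alpha=0.05, power=0.8, tails=1)
    print(f"n = {n:>2} per group -> detectable d = {detectable_effect_size(s):.3f}")
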