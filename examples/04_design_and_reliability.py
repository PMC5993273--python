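"""Study design numbers and observer reliability.

Shows the normality screen + Johnson transformation + one-sample t on the
embedded cohort's laterality indices, the sample size needed to detect a
small population-level side bias, and Cronbach's alpha on a toy two-rater
lead-scoring matrix.
"""

import numpy as np

from equilat import (
    anderson_darling_normality,
    assess_cohort,
    cronbach_alpha,
    johnson_transform,
    load_focal_fixture,
    one_sample_t,
    power_one_proportion,
    sample_size_one_proportion,
)

li = [r.li for r in assess_cohort(load_focal_fixture())]
normality = anderson_darling_normality(li)
print(f"raw LI: A^2={normality.a_squared:.3f} p={normality.p_value:.3f}")

fit, transformed = johnson_transform(li)
print(f"Johnson fit: family={fit.family} z={fit.z_value:.2f} "
      f"AD p after transform={fit.selection_score:.3f}")
t, df, p = one_sample_t(transformed, 0.0)
print(f"one-sample t on transformed LI: t={t:.2f} df={df} p={p:.2f}")

print()
n = sample_size_one_proportion(0.5, 0.54, alpha=0.05, power=0.8)
print(f"starts needed to detect 54% vs 50% at 80% power: {n}")
print(f"power at that n: {power_one_proportion(0.5, 0.54, n):.3f}")

print()
rng = np.random.default_rng(0)
truth = rng.integers(0, 2, 100)            # 100 starts, true lead 0/1
rater_b = np.where(rng.random(100) < 0.95, truth, 1 - truth)  # 5% disagreement
alpha = cronbach_alpha(np.column_stack([truth, rater_b]))
print(f"two raters, 5% disagreement: Cronbach's alpha = {alpha:.3f}")
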