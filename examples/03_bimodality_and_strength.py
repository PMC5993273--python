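"""Is the laterality-index distribution bimodal, and which side is stronger?

Splits the embedded cohort by LI sign, applies the two-normal-mixture
separation criterion, and compares the strength of laterality (|LI|)
between the left- and right-biased groups with a variance-pretested t test.
"""

from equilat import (
    assess_bimodality,
    assess_cohort,
    group_moments,
    load_focal_fixture,
    split_by_sign,
    two_sample_t,
)

results = assess_cohort(load_focal_fixture())
right, left = split_by_sign(results)

mr = group_moments([r.li for r in right])
ml = group_moments([r.li for r in left])
print(f"right-biased: n={mr.n} mean={mr.mean:.2f} sd={mr.sd:.2f}")
print(f"left-biased:  n={ml.n} mean={ml.mean:.2f} sd={ml.sd:.2f}")

verdict = assess_bimodality(mr, ml)
print(
    f"sigma ratio {verdict.sigma_ratio:.2f} -> separation factor "
    f"{verdict.separation_factor:.3f}; threshold {verdict.lhs:.2f} vs "
    f"mean difference {verdict.rhs:.2f} -> "
    f"{'BIMODAL' if verdict.is_bimodal else 'unimodal'}"
)

cmp = two_sample_t([abs(r.li) for r in left], [abs(r.li) for r in right])
print(
    f"|LI| left vs right: {cmp.method} t={cmp.t:.2f} df={cmp.df} "
    f"p={cmp.p_value:.3f} (pretest p={cmp.pretest_p:.4f})"
)
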