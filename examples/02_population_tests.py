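"""Population-level side bias from race-start count tables.

Runs the one-proportion z test over published-scale start counts, reports
the lead ratio and the Wald interval, and shows a logistic-regression
association test on a simulated start table with a built-in direction
effect.
"""

from equilat import (
    SimulationConfig,
    fit_binary_logit,
    lead_ratio,
    one_proportion_normal,
    simulate_race_cohort,
)

# counts of left/right leads: pooled and clockwise-course examples
for name, n_left, n_right in [("pooled", 1074, 1021), ("clockwise", 604, 527)]:
    test = one_proportion_normal(n_right, n_left + n_right, 0.5)
    print(
        f"{name}: L={n_left} R={n_right}  L:R={lead_ratio(n_left, n_right):.2f}  "
        f"z={test.z:.2f} p={test.p_value:.3f} "
        f"CI=({test.ci_low:.4f}, {test.ci_high:.4f})"
    )

# association of lead with course direction on a synthetic table where
# clockwise starts shift the right-lead log-odds by 0.4
cohort = simulate_race_cohort(
    SimulationConfig(seed=11, n_races=200, direction_effect=0.4)
)
result = fit_binary_logit(
    [o.lead for o in cohort],
    [o.direction for o in cohort],
    reference_level="AC",
)
print()
print(
    f"lead ~ direction: chi2={result.chi_square:.2f} df={result.df} "
    f"p={result.p_value:.4f} OR(C)={result.odds_ratios['C']:.2f}"
)
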