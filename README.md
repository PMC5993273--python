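# equilat

Statistical analysis of motor laterality in racehorses — which foreleg a
horse leads with at the gallop, whether individual horses are significantly
lateralized, and whether a population of horses shows a side bias or a
bimodal split into left- and right-preferring subgroups.

The package implements, as a reusable library with a thin CLI on top:

- **Laterality index (LI)** for repeated binary side observations:
  `LI = 100 (nR − nL) / (nR + nL)`, ranging from −100 (always left) to
  +100 (always right).
- **Per-horse significance tests** of the null "no side preference"
  (p = 0.5): exact binomial (doubled smaller tail) for small start counts,
  normal approximation otherwise, with a five-way classification
  (significantly left/right, non-significant trend left/right,
  ambilateral).
- **Population-level tests**: one-proportion z tests with Wald intervals
  over race-start tables, left:right lead ratios, and binary logistic
  regression of lead on categorical covariates (course direction, sex,
  age, stall position) with likelihood-ratio chi-square tests.
- **Bimodality of the LI distribution** via the two-normal-mixture
  separation criterion: the split into right- and left-biased groups is
  declared bimodal when `S(σ1/σ2)·(σ1+σ2) < μ1 − μ2`, where S is the
  minimum-separation factor of an equal-weight two-normal mixture.
- **Strength-of-laterality comparisons** on |LI| with an equal-variance
  pretest (Bonett / Brown–Forsythe) selecting a pooled or Welch t test,
  plus one-way ANOVA of LI on sex groupings.
- **Distributional machinery**: Anderson–Darling normality test, Johnson
  transformation selected by the percentile method, one-sample t test on
  the transformed scale.
- **Design numbers**: power and sample size for a one-proportion z test,
  and Cronbach's alpha for inter-observer reliability of lead scoring.
- **A synthetic cohort generator** (mixture of left-biased, right-biased
  and ambilateral horses with Beta-distributed bias magnitudes) for
  calibration and power studies of the whole pipeline.

A 44-horse focal data set of real lead sequences ships with the package
(`equilat.load_focal_fixture()`), together with a `reproduce-paper`
command that recomputes every published headline number from it and flags
each printed-versus-computed comparison.

## Quick start

```python
from equilat import (
    load_focal_fixture, assess_cohort, median_li,
    split_by_sign, group_moments, assess_bimodality, two_sample_t,
)

records = load_focal_fixture()          # 44 horses, raw lead sequences
results = assess_cohort(records)        # LI + test + classification each

horse_a = next(r for r in results if r.horse_id == "A")
print(horse_a.li, horse_a.test.p_value, horse_a.classification.value)
# 42.857142857142854 0.02349... S(R)

print(median_li(results, "L"), median_li(results, "R"))
# -60.0 42.857142857142854

right, left = split_by_sign(results)
verdict = assess_bimodality(
    group_moments([r.li for r in right]),
    group_moments([r.li for r in left]),
)
print(verdict.is_bimodal)               # True: two lateralized subgroups

cmp = two_sample_t([abs(r.li) for r in left], [abs(r.li) for r in right])
print(round(cmp.t, 2), cmp.df, cmp.method)
# 2.28 34 welch — left-biased horses are more strongly lateralized
```

The same pipeline is available in one call:

```python
from equilat import run_full_analysis, render_report
report = run_full_analysis(focal=records)
print(render_report(report))
```

## Command line

```sh
equilat reproduce-paper --out out/repro      # printed-vs-computed table
equilat analyze --focal my_horses.csv --out out/run
equilat simulate --seed 7 --out out/sim      # synthetic focal + race CSVs
equilat design --p1 0.54                     # n_required=1225
equilat reliability --ratings ratings.csv    # Cronbach's alpha
```

## Layout

- `src/equilat/cohort.py` — data model, CSV I/O, lead-sequence parsing,
  embedded focal fixture
- `src/equilat/individual.py` — LI, one-proportion tests, classification
- `src/equilat/population.py` — population tests, logistic regression, ANOVA
- `src/equilat/subgroups.py` — bimodality criterion, variance pretest,
  pooled/Welch comparisons
- `src/equilat/design.py` — normality, Johnson transform, power/sample
  size, Cronbach's alpha
- `src/equilat/simulate.py` — synthetic cohort generator and recovery study
- `src/equilat/pipeline.py` — orchestration, reporting, reproduction run
- `src/equilat/cli.py` — command-line entry points
- `examples/` — narrative walkthroughs of each analysis stage
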