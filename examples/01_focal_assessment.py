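"""Per-horse laterality assessment of the embedded 44-horse cohort.

Computes each horse's laterality index, runs the appropriate one-proportion
test (exact for n <= 25, normal otherwise) and prints the classification
table plus the group medians.
"""

from equilat import Classification, assess_cohort, load_focal_fixture, median_li

records = load_focal_fixture()
results = assess_cohort(records)

print(f"{'horse':>6} {'n':>4} {'LI':>8} {'z':>6} {'p':>7} {'method':>7}  class")
for r in results:
    print(
        f"{r.horse_id:>6} {r.n_left + r.n_right:>4} {r.li:>8.2f} "
        f"{r.test.z:>6.2f} {r.test.p_value:>7.3f} {r.test.method:>7}  "
        f"{r.classification.value}"
    )

n_sig_l = sum(r.classification is Classification.SIG_L for r in results)
n_sig_r = sum(r.classification is Classification.SIG_R for r in results)
print()
print(f"significantly left-lateralized:  {n_sig_l}")
print(f"significantly right-lateralized: {n_sig_r}")
print(f"median LI, left-trending horses:  {median_li(results, 'L'):.2f}")
print(f"median LI, right-trending horses: {median_li(results, 'R'):.2f}")
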