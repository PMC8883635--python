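"""Right-vs-left orbital asymmetry: why the within-individual test matters.

First runs the dependent (paired) t-test, the ratio test and the
sex-adjusted robust regression on a simulated cohort with a 0.5% right
excess.  Then constructs a dataset where the between-subject spread hides
that excess from the independent two-sample t-test while the paired test
still finds it.
"""

import numpy as np
from scipy import stats

from orbigrow.asymmetry import asymmetry_from_records, paired_difference_test
from orbigrow.cohort import replicate_study_structure, simulate_cohort

records = simulate_cohort(replicate_study_structure(), seed=1)

for test in ("difference", "ratio", "regression"):
    res = asymmetry_from_records(records, test=test)
    print(
        f"{test:>10}: n={res.n}  mean diff={res.mean_diff:+.1f} mm^3  "
        f"mean ratio={res.mean_ratio:.4f}  t={res.t_stat:+.2f}  p={res.p_value:.4f}"
    )
print(
    "\nAll three within-individual tests detect the ~0.5% right-orbit excess\n"
    "(one observation per patient; scans averaged within patient).\n"
)

# paired vs independent: same data, different question
rng = np.random.default_rng(17)
left = 22000.0 + rng.normal(0, 2000.0, 40)       # large between-subject spread
right = left + 110.0 + rng.normal(0, 40.0, 40)   # small consistent excess
_, p_ind = stats.ttest_ind(right, left)
paired = paired_difference_test(right, left)
print(f"independent two-sample t-test: p = {p_ind:.3f}  (misses the excess)")
print(f"dependent (paired) t-test:     p = {paired.p_value:.2e}")
print(
    "\nThe independent test compares the average right orbit with the average\n"
    "left orbit, so the 2000 mm^3 between-subject spread swamps a 110 mm^3\n"
    "within-subject excess; pairing differences it out."
)
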