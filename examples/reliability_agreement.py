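"""Operator agreement on repeated volume measurements.

Simulates two operators independently re-measuring 30 orbits under
lognormal operator noise, then summarizes agreement with the intraclass
correlation coefficient and Bland-Altman limits of agreement.
"""

import numpy as np

from orbigrow.cohort import simulate_reliability_measurements
from orbigrow.reliability import bland_altman, icc, long_to_wide

rng = np.random.default_rng(1)
true_volumes = 22000.0 * np.exp(rng.normal(0.0, 0.10, 30))  # 30 orbits

table = simulate_reliability_measurements(
    true_volumes, sd_operator=0.024, n_operators=2, seed=1
)
wide = long_to_wide(table, design="inter")

res = icc(wide)
print(f"ICC ({res.icc_model}, single measurement): {res.icc:.3f}")
print(f"Pearson r between operators:              {res.pearson_r:.3f}")

ba = bland_altman(wide[:, 0], wide[:, 1])
print(
    f"Bland-Altman: bias = {ba.bias:+.0f} mm^3, "
    f"95% limits of agreement [{ba.loa_low:+.0f}, {ba.loa_high:+.0f}] mm^3"
)
print(
    "\nWith 10% between-orbit spread and 2.4% operator noise the two-way\n"
    "random-effects absolute-agreement ICC sits near 0.95: almost all\n"
    "measurement variance is real between-orbit variation. The limits of\n"
    "agreement bound the disagreement expected for 95% of repeat pairs."
)
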