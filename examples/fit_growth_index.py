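"""Fit the weighted repeat-scan growth index on a simulated panel.

Runs the full three-stage estimator (OLS on pair growth, squared-residual
variance model, interval-weighted WLS) with patient-clustered standard
errors, and prints the age-class index next to the generating schedule.
"""

from orbigrow.cohort import (
    POOLED_GROWTH_SCHEDULE,
    replicate_study_structure,
    simulate_cohort,
)
from orbigrow.panel import build_panel
from orbigrow.wrs import fit_wrs_index

panel = build_panel(simulate_cohort(replicate_study_structure(), seed=1))
result = fit_wrs_index(panel, base_age=12)
fit = result.fit

print(f"pairs: {fit.n_obs}   patients contributing: {fit.n_clusters}")
print(f"variance model: alpha={fit.alpha:.2e}  beta={fit.beta:.2e} per year")
print(f"weighted R^2: {fit.r_squared:.3f}")
print()
print("age   gamma-hat   (truth)      SE     p       level mm^3")
for age in sorted(fit.gamma):
    g = fit.gamma[age]
    truth = POOLED_GROWTH_SCHEDULE[age]
    se = fit.se.get(age)
    p = fit.p_values.get(age)
    level = result.index.levels[age]
    se_s = f"{se:.4f}" if se is not None else "  --  "
    p_s = f"{p:.3f}" if p is not None else " -- "
    print(f"{age:3d}   {g:+.4f}   ({truth:+.4f})   {se_s}  {p_s}   {level:8.0f}")
print()
print(
    "gamma is the cumulative log-volume offset from the base class (age 12,\n"
    "fixed at 0); levels = base-class mean volume x exp(gamma). Standard\n"
    "errors are clustered by patient; p-values are two-sided t-tests of\n"
    "gamma = 0. The spread gamma(18) - gamma(7) of ~0.13 over 11 years is\n"
    "the ~1-2%/yr orbital growth the index is designed to resolve."
)
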