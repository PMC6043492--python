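"""Incidence rates and overlap-corrected pooling of two database estimates.

Reproduces the published incidence-rate arithmetic for one drug comparison
(events and person-years are the printed cohort counts) and pools a pair
of simulated per-database log hazard ratios with the 20%-overlap variance
correction.
"""

from netprox.epimeta import (
    CohortCount,
    incidence_rate,
    pool_two_databases,
)
from netprox.fixtures import make_study_pair

print("Incidence rates per 100 person-years (exact Poisson 95% CI):")
for label, events, py in [
    ("carbamazepine / database 1", 124, 27050),
    ("levetiracetam / database 1", 105, 31826),
]:
    r = incidence_rate(CohortCount(label, events, py))
    rate, lo, hi = r.rounded(2)
    print(f"  {label}: {rate:.2f} ({lo:.2f}, {hi:.2f})")

true_log_hr = 0.44  # generating value for the simulated pair
pair = make_study_pair(true_log_hr, variances=(0.02, 0.05), ns=(58686, 17359), seed=4)
print(f"\nsimulated per-database log HRs: "
      f"{pair[0].log_hr:+.3f} (var {pair[0].variance}), "
      f"{pair[1].log_hr:+.3f} (var {pair[1].variance})")

pooled = pool_two_databases(pair, p_overlap=0.2)
print(f"pooled HR {pooled.hr:.2f} (95% CI {pooled.ci_low:.2f}-{pooled.ci_high:.2f})")
print(f"tau^2 {pooled.tau2:.4f}, corrected variance {pooled.corrected_variance:.4f}")
print(
    "\nThe correction inflates the pooled variance for the ~20% of patients\n"
    "assumed to appear in both insurance databases, widening the CI relative\n"
    "to naive independent pooling."
)
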