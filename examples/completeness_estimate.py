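"""Estimate survey completeness from stratified rare-event label counts.

Each detection category (no-detection / low-confidence) gets a stratified
exact-binomial interval for its positive-tile proportion; the upper bounds
scale to unobserved-image counts, convert to facilities through the
images-per-facility ratio, and yield a completeness percentage with a CI.
"""

from cafomap import Stratum, estimate_population, waller_interval

# A compact survey: tile totals N, labeled n, positives x per stratum.
strata = [
    Stratum("no_detection/1", "no_detection", total=40_000, labeled=2_000, positives=0),
    Stratum("no_detection/2", "no_detection", total=25_000, labeled=1_500, positives=1),
    Stratum("no_detection/3", "no_detection", total=15_000, labeled=1_000, positives=0),
    Stratum("low_confidence/1", "low_confidence", total=4_000, labeled=800, positives=2),
    Stratum("low_confidence/2", "low_confidence", total=2_500, labeled=600, positives=1),
]

for cat in ("no_detection", "low_confidence"):
    iv = waller_interval([s for s in strata if s.category == cat])
    print(f"{cat:15s}: p_hat={iv.p_hat:.2e}  95% CI [{iv.lb:.2e}, {iv.ub:.2e}]"
          f"  (R={iv.r:.3f})")

report = estimate_population(
    strata, observed_facilities=500, images_per_facility=1.44
)
est = report["estimate"]
print(f"unobserved images   : {est['unobserved_images_point']}"
      f" (ub {est['unobserved_images_ub']})")
print(f"total facilities    : {est['total_facilities_point']}"
      f" (ub {est['total_facilities_ub']})")
print(f"completeness        : {est['completeness_point_pct']}%"
      f"  95% CI {est['completeness_ci_pct']}")
# The CI lower bound divides the observed count by the upper-bound total:
# the interval's operative guarantee for rare events is this upper side.
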