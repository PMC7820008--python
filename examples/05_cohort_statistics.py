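"""Cohort-level statistics: planted effects, Rüger areas, slope-free pivot.

Simulates a 170-subject cohort with planted age/sex/IQ effects, runs the
hypothesis battery with Rüger-area multiple-testing control, and locates
the slope-free intercept anchor.
"""

import nremspec as ns
from nremspec.powerlaw import PowerLawFit
from nremspec.synthetic import CohortSpec, synth_cohort

params, covars, truth = synth_cohort(CohortSpec(n_subjects=170, seed=14))
results = ns.run_hypotheses(params, covars)

print("hypothesis battery (significant Rüger area?):")
for name, res in results.items():
    print(f"  {name:18s} {res.any_significant_area!s:5s}  {res.description}")

# slope-free intercept: anchor where intercept and slope decorrelate
c3 = params[params["channel"] == "C3"]
fits = [PowerLawFit(alpha=a, lnC0=c, r2=1.0, alt_intercepts={})
        for a, c in zip(c3["alpha"], c3["lnC0"])]
report = ns.slope_free_pivot(fits)
print("\nalpha-intercept correlation profile across anchors:")
for x, r in sorted(report.correlations.items()):
    print(f"  ln f = {x:.1f}: r = {r:+.3f}")
print(f"slope-free pivot at ln f = {report.pivot} "
      f"(r with lnC0: {report.r_alpha_lnC0:+.3f})")

# The age-slope, sex-intercept and sex-frequency effects planted by the
# generator survive the conjunctive Rüger control; the peak-amplitude sex
# companion, planted null, stays null.  The pivot lands at the anchor the
# generator used to decouple intercepts from slopes (ln f = 2.5, ~12.2 Hz).
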