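"""Fit the 1/f background of a synthetic NREM spectrum and read the intercepts.

Generates a noiseless model spectrum (known slope and intercept, one spindle
bump), resamples it to the equidistant log-log grid, fits the line with the
oscillatory band excluded, and prints the recovered parameters.
"""

import nremspec as ns

spec, truth = ns.synth_spectrum(
    ns.SpectrumSpec(alpha=-2.7, lnC=5.2, bumps=((13.2, 0.9, 0.5),),
                    noise_sd=0.0))

ll = ns.to_equidistant_loglog(spec)
fit = ns.fit_background(ll)

print(f"log-grid step        : {ll.step:.4f} ln-Hz  ({len(ll.lnf)} points)")
print(f"spectral exponent a  : {fit.alpha:.4f}  (planted {truth['alpha']})")
print(f"intercept lnC0       : {fit.lnC0:.4f}  (planted {truth['lnC']})")
print(f"goodness of fit R^2  : {fit.r2:.6f}")
for x, v in sorted(fit.alt_intercepts.items()):
    print(f"  lnC_{x:.1f} (~{2.718281828**x:5.1f} Hz) = {v:8.4f}")

# The slope and intercept come back exactly because the spindle bump lies
# inside the excluded 6.0052-17.9948 Hz band; the alternative intercepts are
# the fitted line evaluated at the ln f anchors.
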