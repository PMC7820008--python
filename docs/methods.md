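# Methods

## The model

`nremspec` parametrizes the average Fourier power spectrum of NREM (N2/N3)
sleep EEG as a power-law (colored-noise) background times a whitened peak
multiplier:

    P(f) = C · f^α · P_Peak(f)
    ln P(f) = ln C + α ln f + ln P_Peak(f)

with power `P ≥ 0` in µV²/Hz, frequency `f` in Hz, and all logarithms
natural. `α` (the spectral exponent, typically −4 < α < −1 in NREM sleep) is
the slope of the log–log spectrum; `ln C` is its frequency-independent
amplitude term; `P_Peak(f) ≥ 1` is 1 wherever no oscillatory peak rides on
the background, so `ln P_Peak(f) ≥ 0` is a whitened measure of rhythmic
activity. The package reduces a ~191-bin spectrum per channel to four
numbers: `α`, an intercept, and the frequency (`f_maxPeak`) and whitened
amplitude (`ln P_Peak(f_maxPeak)`) of the largest spectral peak in the
9–18 Hz sleep-spindle range. No knee parameter is modeled anywhere: the
0–2 Hz range where a knee would matter is excluded from fitting (sweating
artifacts and electrode high-pass behavior dominate it).

## Spectral estimation

Average PSDs are computed from 4 s Hann-tapered windows with 50 % overlap
(fixed 2 s hop; a trailing partial window is dropped). A 4 s window gives
exactly Δf = 0.25 Hz at any sampling rate whose product with 4 s is an
integer (996 samples at 249 Hz are handled by the mixed-radix FFT without
zero padding). Windows must lie inside scoring epochs (20 s by default) that
all carry one eligible stage — a stage change breaks continuity even between
two eligible stages — and must not intersect any artifact-marked 4 s
segment. The one-sided PSD is normalized as `2|X|²/(sfreq · Σw²)` (DC and
Nyquist bins not doubled), which conserves white-noise variance (Parseval);
the tests verify this to 5 %. Device frequency responses are corrected by
dividing power by the squared amplitude-reduction rate of the recording
system; the rate curve is the mean of two test-amplitude conditions at the
measured anchors, cubic-spline interpolated between anchors and clamped to
the boundary values outside their span. Mastoid re-referencing and notch
filtering are assumed done upstream (optional preprocessing is out of
scope); DC and Nyquist bins are computed but never used downstream.

## Background fit and intercepts

A log frequency axis crowds points at high frequencies, biasing a direct
line fit toward them. The spectrum is therefore resampled onto an
equidistant `ln f` grid by monotone piecewise-cubic Hermite (PCHIP)
interpolation of the (ln f, ln P) pairs; the grid step is the smallest
consecutive ln-spacing of the source 0.25 Hz grid within the fit range,
`ln 48 − ln 47.75 ≈ 0.0052` for the default 2–48 Hz. (The step is a
natural-log spacing; it is recorded as such even though it is commonly
quoted as a frequency step of 0.0052 Hz.) Ordinary least squares of `ln P`
on `ln f` over this grid, with the closed interval 6.0052–17.9948 Hz
excluded (alpha and spindle oscillations), gives `α` and `ln C_0`. R² is the
squared Pearson correlation between the fitted line and the included
points. Exactness: a noiseless model spectrum is recovered to 1e-9 in both
parameters, and a perturbation compactly supported inside the excluded band
(support within the 6.5–17.5 Hz source knots, so that no PCHIP cell touched
by the fit changes) shifts neither parameter by more than 1e-9.

Because `ln C_0` (the crossing at ln f = 0, i.e. 1 Hz) is strongly
anti-correlated with `α` across subjects, alternative intercepts
`ln C_x = ln C_0 + αx` are evaluated at anchors
x ∈ {2, 2.3, 2.5, 2.6, 2.7, 3} (7.4, 10, 12.2, 13.5, 15, 20 Hz).
`slope_free_pivot` computes the between-subject Pearson correlation of `α`
with each `ln C_x` and reports the anchor minimizing |r| — the "slope-free"
intercept, typically near 12.2–13.5 Hz, with negative correlations below the
pivot and positive above it. A profile whose |r| never exceeds 0.1 is
flagged flat rather than assigned a meaningful pivot.

## Peak detection and whitening

Within 9–18 Hz, local maxima of `ln P` (as a function of linear f) are found
by classic derivative tests built from exact second-degree polynomial fits
to successive bin triplets (0.75 Hz span, 2-bin overlap, hence a 1-bin hop):
the parabola's slope at the middle bin is the derivative there, which
reduces in closed form to the central difference. Re-applying the scheme to
the first-derivative series yields the second derivative. Both series are
interpolated by natural cubic splines; sign-change roots of the
first-derivative spline (bracketed on a 1 mHz scan, refined by Brent's
method to 1e-9 Hz) where the second-derivative spline is negative are
accepted as peaks. Each derivative pass trims one bin per edge, so
candidates live in [9.5, 17.5] Hz — a documented detection dead-zone.

Whether the derivative tests run on raw or log power only affects numerics,
not which points are maxima (the log is strictly increasing); ln P is the
default and the raw-power mode is available. Because the finite-difference
chain carries an O(h²) localization bias that grows for shallow, wide peaks,
the reported frequency of each *accepted* peak is read out as the local
maximum of the interpolated log–log spectrum within one bin of the zero
crossing (`refine_readout=True` by default); the derivative tests alone
still decide existence. This keeps the frequency within 0.02 Hz and the
amplitude within 2 % of the dense-grid values for the planted-bump sweep.

Amplitudes are whitened per `ln P_Peak(f) = ln P(f) − (ln C_0 + α ln f)`,
with `ln P(f)` spline-interpolated in the double-log plane. An optional
positivity shift (adding a constant to `ln P` before subtraction) exists for
compatibility experiments and defaults to 0: at accepted maxima of well-fit
spectra the whitened value is positive anyway. Peaks are ranked by whitened
amplitude (ties broken toward the lower frequency); only the maximal peak
(`f_maxPeak`, `ln P_Peak(f_maxPeak)`) feeds downstream analyses, and an
empty set propagates as missing data. Joint slow+fast two-peak modeling is
deliberately out of scope.

## Topography

Per-channel `f_maxPeak` values are averaged within sagittal regions —
frontopolar (Fp1, Fp2), frontal (F3, F4, Fz), central (C3, C4, Cz), parietal
(P3, P4; the 18-channel montage carries no Pz), occipital (O1, O2) — and
serially subtracted front-to-back (F−Fp, C−F, P−C, O−P). The total shift
telescopes to O−Fp when all regions are present; a shift touching a missing
region is missing. The location of the maximal upward shift splits the scalp
into a rostral slow-spindle and a caudal fast-spindle territory (most of the
antero-posterior frequency increase concentrates in that single step). Ties
resolve toward the most anterior boundary with a warning; a profile with no
upward shift is still classified (least negative shift) under a warning.
Temporal channels sit outside the averaged regions; they are classified by
their antero-posterior row (F7/F8 frontal, T3/T4 central, T5/T6 parietal)
and flagged as extrapolated, since no convention for them is established.

## Group statistics

* **Fisher averaging (Silver–Dunlap):** correlations are averaged as
  `tanh(mean(atanh r))`; the SD is likewise computed on the transformed
  scale and back-transformed.
* **Normality-gated tests:** Shapiro–Wilk at 0.05 on each variable/group
  selects Pearson/t-test (Gaussian) versus Spearman/Mann–Whitney. η² is
  `t²/(t²+df)` for the t-test and `z²/(n−1)` for the rank test (z recovered
  from the two-sided p); the rank-test conversion is a convention, not a
  published definition.
* **Rüger areas (Descriptive Data Analysis):** channels with descriptive
  p < 0.05 are grouped into connected components of a fixed, documented
  scalp-neighborhood graph over the 18-channel 10–20 montage (lateral
  neighbors within a row plus nearest channels of adjacent rows; shipped as
  data and overridable). An area of size k is globally significant when at
  least ⌈k/3⌉ members have p ≤ 0.05/3 *and* at least ⌈k/2⌉ have p ≤ 0.05/2
  (conjunctive criterion; a disjunctive mode exists for sensitivity
  analysis). Thresholds are the exact fractions, not the rounded 0.017 /
  0.025; boundary p-values count (≤). Singleton areas are allowed.
* **Correlation differences:** independent correlations are compared by the
  Fisher z-test `z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3))`, applied
  to rank correlations as well — flagged as an approximation.
* **Hypothesis battery:** H1 age–α, H2 age–peak amplitude, H3 age–peak
  frequency (per-channel gated correlations); H4 sex–intercept (slope-free
  anchor by default) with a peak-amplitude companion expected null; H5
  sex–peak frequency; H6 IQ–peak amplitude separately by sex; H7 age–α
  correlations compared between IQ groups. Every per-channel p-map passes
  through the Rüger control. Significance maps are emitted as channel × p
  tables; no topographic graphics are produced.

## Synthetic data

The generator realizes the model it is meant to test, with known truth:

* **Spectra:** `ln P = ln C + α ln f + Σ bumps + ε` on the 0.25 Hz grid,
  bumps Gaussian in linear frequency on the ln P axis (keeps the maximizer
  analytic and matches the visual shape of empirical spindle peaks), noise
  Gaussian on ln P (the log of an averaged periodogram is near-Gaussian for
  large window counts; a scaled-χ²₂ₖ mode exists for realism checks).
  Default noise SD 0.04 ≈ 1/√600 windows.
* **Time series:** colored noise by spectral shaping — each Fourier
  component gets the amplitude of the target one-sided PSD `C f^α` with an
  independent random phase (exact target slope up to windowing, unlike AR
  approximations) — plus Poisson-placed, Hann-enveloped spindle sinusoids
  (default 6/min, 13.5 Hz, 10 µV, 1 s), staged as continuous N2. Defaults:
  20 min at 250 Hz, α = −2.5, ln C = 4.75 (≈ 115 µV²/Hz at 1 Hz).
* **Cohorts:** per-subject Gaussian latent factors coupled to age and IQ at
  planted correlations (sex enters as mean shifts in SD units), per-channel
  values adding fixed topographic offsets plus small channel noise so that
  channels are strongly intercorrelated, as on a real scalp. Defaults are
  the adult-cohort conditions the package is aimed at: n = 175, 46 % women,
  ages 17–60 (uniform via a Gaussian copula, which attenuates planted
  Pearson correlations by ≈ 2 %), IQ ~ N(117, 14) split at 120; planted
  effects age–α +0.45, age–amplitude −0.35, age–frequency −0.25, sex
  differences d = 0.6 on intercept and peak frequency (matching η² ≈ 0.09),
  none on peak amplitude, IQ–amplitude +0.30 in women only. Each subject's
  maximal antero-posterior frequency jump (1.67 Hz of a 1.99 Hz total) is
  planted at a boundary drawn from the observed distribution (F–Fp 37 %,
  C–F 55 %, P–C 6 %, O–P 2 %), which also makes frontal channels bimodal —
  the realistic slow/fast mixture. Infeasible effect combinations (implied
  correlation matrix not positive semidefinite) are rejected. Peak fields
  are set missing at a 3 % rate.

What the generator does *not* emulate: non-Gaussian marginals of real
parameters (so the gated tests mostly take the parametric branch, unlike on
real data), inter-subject differences in window counts and artifact load,
non-stationarity across the night, reference/montage effects, and genuinely
multi-peaked spindle spectra beyond the planted bumps. Passing tests
therefore demonstrate correctness of the estimators and statistics under
the model's own assumptions, not robustness to every property of real
recordings.

## Numerical choices and problem sizes

Roots are bracketed by sign changes on a 1 mHz scan and refined to 1e-9 Hz;
peak frequencies are reported at the 0.0052 readout resolution of the
log-grid. The default test/acceptance problem sizes — 20 min of 250 Hz
signal for end-to-end recovery, 100-case peak sweeps, 170-subject cohorts,
200 null cohorts for type-I control — were chosen as the smallest sizes at
which the stochastic checks are stable; all complete in about a minute on
one CPU. Degenerate inputs (constant series, all-missing regions, empty
stages, infeasible effect matrices) raise structured `ValueError`s rather
than propagating NaNs.

## Known limitations

* No slow/fast spindle two-peak adjudication; the second-ranked peak is
  reported but not modeled.
* The exclusion band and fit range require a-priori knowledge of where the
  oscillatory peaks live.
* Below 2 Hz nothing is modeled at all.
* The p-value method for correlation differences and the η² convention for
  rank tests are documented choices; numerical equality with any published
  cohort table is not claimed (those depend on recordings this package does
  not ship).
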