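"""Power-law (colored-noise) background model of the NREM sleep EEG spectrum.

The background obeys P(f) = C f^alpha, i.e. ln P = ln C + alpha ln f in the
double-natural-log plane.  Because a log frequency axis crowds data points at
high frequencies, the spectrum is first resampled onto an *equidistant*
ln f grid (monotone piecewise-cubic Hermite interpolation, step equal to the
smallest consecutive ln-spacing of the source 0.25 Hz grid, ~0.0052 for a
2-48 Hz range).  A line is then fitted by ordinary least squares over
2-48 Hz with the oscillatory alpha/spindle band (6.0052-17.9948 Hz) excluded,
yielding the spectral exponent alpha and intercept ln C_0.

Because ln C_0 (the crossing at ln f = 0, i.e. 1 Hz) is strongly
anti-correlated with alpha across subjects, alternative intercepts
ln C_x = ln C_0 + alpha*x are evaluated at anchors
x = ln f in {2, 2.3, 2.5, 2.6, 2.7, 3} (7.4-20 Hz); the anchor whose
between-subject correlation with alpha is closest to zero is the
"slope-free" intercept.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.stats import pearsonr

from .spectral import Spectrum

DEFAULT_FIT_RANGE = (2.0, 48.0)
DEFAULT_EXCLUDE = (6.0052, 17.9948)
ALT_INTERCEPT_ANCHORS = (2.0, 2.3, 2.5, 2.6, 2.7, 3.0)


@dataclass
class LogLogSpectrum:
    """A spectrum resampled to an equidistant natural-log frequency grid."""

    lnf: np.ndarray
    lnp: np.ndarray
    step: float
    source_range: tuple[float, float]
    interpolant: PchipInterpolator = field(repr=False, default=None)

    def __post_init__(self) -> None:
        d = np.diff(self.lnf)
        if np.any(d <= 0) or (len(d) and not np.allclose(d, self.step, atol=1e-12)):
            raise ValueError("lnf must increase with the constant declared step")


@dataclass
class PowerLawFit:
    """Fitted background parameters and the derived alternative intercepts."""

    alpha: float
    lnC0: float
    r2: float
    alt_intercepts: dict[float, float]
    excluded_band: tuple[float, float] = DEFAULT_EXCLUDE
    channel: str = ""

    def __post_init__(self) -> None:
        if not -10.0 < self.alpha < 0.0:
            warnings.warn(
                f"fitted spectral exponent {self.alpha:.3f} is outside the "
                "plausible (-10, 0) range; typical NREM values are -4 < alpha < -1"
            )

    def to_json(self, grid_step: float | None = None) -> str:
        obj = {
            "channel": self.channel,
            "alpha": self.alpha,
            "lnC0": self.lnC0,
            "r2": self.r2,
            "alt_intercepts": {f"{k:.1f}": v for k, v in self.alt_intercepts.items()},
            "excluded_band": list(self.excluded_band),
        }
        if grid_step is not None:
            obj["grid_step"] = grid_step
        return json.dumps(obj)

    @classmethod
    def from_json(cls, text: str) -> "PowerLawFit":
        obj = json.loads(text)
        return cls(
            alpha=obj["alpha"], lnC0=obj["lnC0"], r2=obj["r2"],
            alt_intercepts={float(k): v for k, v in obj["alt_intercepts"].items()},
            excluded_band=tuple(obj["excluded_band"]), channel=obj.get("channel", ""),
        )


def loglog_grid_step(fmin: float = 2.0, fmax: float = 48.0, df: float = 0.25) -> float:
    """Smallest consecutive ln-spacing of the 0.25 Hz grid inside [fmin, fmax].

    The spacing ln(f + df) - ln f shrinks with f, so the minimum sits at the
    top of the range: ln(fmax) - ln(fmax - df) (~0.0052 for 2-48 Hz).
    """
    return float(np.log(fmax) - np.log(fmax - df))


def to_equidistant_loglog(
    spec: Spectrum, fmin: float = 2.0, fmax: float = 48.0
) -> LogLogSpectrum:
    """Resample (ln f, ln P) onto an equidistant ln f grid by PCHIP.

    The monotone Hermite interpolant passes through every source knot exactly
    and introduces no spurious oscillation between bins.
    """
    f, p = spec.band(fmin, fmax)
    if f.size < 2 or f[0] > fmin + 1e-9 or f[-1] < fmax - 1e-9:
        raise ValueError(f"spectrum grid does not cover [{fmin}, {fmax}] Hz")
    bad = np.nonzero(p <= 0)[0]
    if bad.size:
        raise ValueError(
            f"non-positive power at f={f[bad[0]]:.2f} Hz; log-log resampling "
            "requires strictly positive power"
        )
    lnf_knots, lnp_knots = np.log(f), np.log(p)
    interp = PchipInterpolator(lnf_knots, lnp_knots)
    step = loglog_grid_step(fmin, fmax, df=spec.df)
    n = int(np.floor((np.log(fmax) - np.log(fmin)) / step)) + 1
    lnf = np.log(fmin) + step * np.arange(n)
    return LogLogSpectrum(lnf, interp(lnf), step=step, source_range=(fmin, fmax),
                          interpolant=interp)


def fit_background(
    ll: LogLogSpectrum,
    exclude: tuple[float, float] = DEFAULT_EXCLUDE,
    channel: str = "",
) -> PowerLawFit:
    """Ordinary least squares of ln P on ln f with the oscillatory band excluded.

    Points with frequency in the closed interval ``exclude`` (Hz) are dropped;
    R² is the squared Pearson correlation between the fitted line and the
    included data.
    """
    f = np.exp(ll.lnf)
    keep = (f < exclude[0]) | (f > exclude[1])
    x, y = ll.lnf[keep], ll.lnp[keep]
    if x.size < 10:
        raise ValueError(f"only {x.size} grid points outside the excluded band")
    if np.ptp(x) < 1e-12:
        raise ValueError("degenerate design: all ln f values equal")
    alpha, lnC0 = np.polyfit(x, y, 1)
    fitted = lnC0 + alpha * x
    if np.ptp(y) < 1e-12:
        r2 = 1.0  # perfectly flat data: the constant fit reproduces it exactly
    elif np.ptp(fitted) < 1e-12:
        r2 = 0.0  # flat fitted line explains none of the observed variation
    else:
        r2 = float(pearsonr(fitted, y).statistic ** 2)
    fit = PowerLawFit(alpha=float(alpha), lnC0=float(lnC0), r2=r2,
                      alt_intercepts={}, excluded_band=tuple(exclude),
                      channel=channel)
    fit.alt_intercepts = {x0: evaluate_background(fit, x0)
                          for x0 in ALT_INTERCEPT_ANCHORS}
    return fit


def evaluate_background(fit: PowerLawFit, lnf_query: float | np.ndarray):
    """Background log-power on the fitted line: ln C_0 + alpha * ln f."""
    return fit.lnC0 + fit.alpha * np.asarray(lnf_query, dtype=float)


def fit_spectrum(
    spec: Spectrum,
    fmin: float = 2.0,
    fmax: float = 48.0,
    exclude: tuple[float, float] = DEFAULT_EXCLUDE,
) -> PowerLawFit:
    """Convenience: equidistant log-log resampling followed by the line fit."""
    return fit_background(to_equidistant_loglog(spec, fmin, fmax), exclude,
                          channel=spec.channel)


@dataclass
class PivotReport:
    """Between-subject slope/intercept correlation profile over anchor candidates."""

    candidates: tuple[float, ...]
    correlations: dict[float, float]
    pivot: float
    sign_change: tuple[float, float] | None
    flat_profile: bool
    r_alpha_lnC0: float


def slope_free_pivot(
    fits: list[PowerLawFit],
    candidate_lnf: tuple[float, ...] = ALT_INTERCEPT_ANCHORS,
    flat_threshold: float = 0.1,
) -> PivotReport:
    """Locate the anchor whose intercept is least correlated with the slope.

    For each candidate x, the Pearson correlation across subjects between
    alpha and ln C_x is computed; the pivot minimizes |r|.  Below the pivot
    the correlations are typically negative (steeper slopes -> higher
    low-frequency intercepts) and positive above it; the bracket where the
    sign flips is reported when present.
    """
    if len(fits) < 10:
        raise ValueError(f"need at least 10 subjects, got {len(fits)}")
    alphas = np.array([f.alpha for f in fits])
    if np.ptp(alphas) < 1e-12:
        raise ValueError("alpha is constant across subjects; correlation undefined")
    profile: dict[float, float] = {}
    for x in candidate_lnf:
        lnCx = np.array([f.lnC0 + f.alpha * x for f in fits])
        if np.ptp(lnCx) < 1e-12:
            profile[x] = 0.0
        else:
            profile[x] = float(pearsonr(alphas, lnCx).statistic)
    pivot = min(profile, key=lambda x: abs(profile[x]))
    sign_change = None
    cands = tuple(sorted(candidate_lnf))
    for lo, hi in zip(cands, cands[1:]):
        if profile[lo] < 0 <= profile[hi] or profile[lo] <= 0 < profile[hi]:
            sign_change = (lo, hi)
            break
    lnC0s = np.array([f.lnC0 for f in fits])
    r0 = float(pearsonr(alphas, lnC0s).statistic) if np.ptp(lnC0s) > 1e-12 else 0.0
    return PivotReport(
        candidates=cands,
        correlations=profile,
        pivot=pivot,
        sign_change=sign_change,
        flat_profile=max(abs(r) for r in profile.values()) < flat_threshold,
        r_alpha_lnC0=r0,
    )
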