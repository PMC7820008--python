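"""Synthetic spectra, time series, and cohorts with known ground truth.

Everything the analysis side estimates can be generated here with planted
parameters, so parameter recovery is testable without any recordings:

* spectra following ln P(f) = ln C + alpha ln f plus Gaussian-in-frequency
  log-power bumps (the spectral signature of spindle oscillations) and
  multiplicative periodogram noise;
* 1/f^|alpha| colored-noise time series (spectral shaping with random
  phases) with Poisson-placed, Hann-enveloped spindle events;
* cohorts of per-subject/channel parameter tables with planted age, sex and
  IQ effects (Gaussian latent factors), emulating the structure of a
  175-subject adult sleep study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import RecordingBundle
from .montage import CHANNEL_ROW, CHANNELS_18
from .spectral import Spectrum

# ---------------------------------------------------------------------------
# spectra


@dataclass
class SpectrumSpec:
    """Description of one synthetic average spectrum.

    ``bumps`` is a list of (center_f Hz, height in ln-power units, width Hz);
    ``noise_sd`` is the SD of additive Gaussian noise on ln P (the log of an
    averaged periodogram is near-Gaussian for large window counts; a chi²
    mode is available for realism checks).
    """

    alpha: float = -2.5
    lnC: float = 4.75
    bumps: tuple[tuple[float, float, float], ...] = ((13.0, 0.8, 0.5),)
    noise_sd: float = 0.04
    grid: tuple[float, float, float] = (0.25, 48.0, 0.25)
    seed: int = 0
    noise_model: str = "gaussian"   # or "chi2"
    n_windows: int = 600            # chi²_2k degrees of freedom source

    def __post_init__(self) -> None:
        fmin, fmax, df = self.grid
        if df != 0.25 or fmin <= 0 or fmax <= fmin:
            raise ValueError(f"grid must be (fmin>0, fmax>fmin, 0.25), got {self.grid}")
        for c, h, w in self.bumps:
            if h < 0 or w <= 0:
                raise ValueError("bump heights must be >= 0 and widths > 0")
            if not fmin <= c <= fmax:
                raise ValueError(f"bump center {c} Hz outside the grid")


def bump_field(freqs: np.ndarray, bumps) -> np.ndarray:
    """Sum of Gaussian-in-frequency log-power bumps (the planted ln P_Peak)."""
    f = np.asarray(freqs, dtype=float)
    out = np.zeros_like(f)
    for center, height, width in bumps:
        out += height * np.exp(-((f - center) ** 2) / (2.0 * width**2))
    return out


def synth_spectrum(spec: SpectrumSpec, channel: str = "") -> tuple[Spectrum, dict]:
    """Generate a Spectrum from the log-linear background + bump model.

    Returns the spectrum and a truth record holding every planted parameter
    and the noiseless bump field on the grid.
    """
    fmin, fmax, df = spec.grid
    freqs = fmin + df * np.arange(int(round((fmax - fmin) / df)) + 1)
    lnp = spec.lnC + spec.alpha * np.log(freqs) + bump_field(freqs, spec.bumps)
    rng = np.random.default_rng(spec.seed)
    if spec.noise_model == "gaussian":
        lnp = lnp + rng.normal(0.0, spec.noise_sd, size=freqs.size) \
            if spec.noise_sd > 0 else lnp
        power = np.exp(lnp)
    elif spec.noise_model == "chi2":
        k = 2 * spec.n_windows
        power = np.exp(lnp) * rng.chisquare(k, size=freqs.size) / k
    else:
        raise ValueError(f"unknown noise_model {spec.noise_model!r}")
    truth = {
        "alpha": spec.alpha, "lnC": spec.lnC, "bumps": list(spec.bumps),
        "noise_sd": spec.noise_sd, "seed": spec.seed,
        "bump_field": bump_field(freqs, spec.bumps),
    }
    return Spectrum(freqs, power, channel=channel), truth


# ---------------------------------------------------------------------------
# time series


@dataclass
class SpindleSpec:
    """Poisson-placed spindle events added to the colored-noise background."""

    rate_per_min: float = 6.0
    freq_hz: float = 13.5
    amp_uV: float = 10.0
    duration_s: float = 1.0

    def __post_init__(self) -> None:
        if self.rate_per_min < 0:
            raise ValueError("spindle rate must be >= 0")
        if not 9.0 <= self.freq_hz <= 18.0:
            raise ValueError("spindle frequency must lie in 9-18 Hz")


def synth_timeseries(
    alpha: float = -2.5,
    lnC: float = 4.75,
    spindles: SpindleSpec | None = SpindleSpec(),
    duration_s: float = 1200.0,
    sfreq: float = 250.0,
    seed: int = 0,
    channel_names: tuple[str, ...] = ("C3",),
    epoch_length_s: float = 20.0,
) -> tuple[RecordingBundle, dict]:
    """Colored-noise EEG with embedded spindles, staged as continuous N2.

    The background is built by assigning every Fourier component the
    amplitude of the target one-sided PSD C f^alpha (in µV²/Hz) with an
    independent uniform random phase and inverse-transforming, so the
    realized spectrum matches the target power law exactly up to windowing.
    """
    if duration_s < 60:
        raise ValueError("duration must be >= 60 s")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sfreq))
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    target_psd = np.zeros_like(freqs)
    target_psd[1:] = np.exp(lnC) * freqs[1:] ** alpha
    mag = np.sqrt(target_psd * sfreq * n / 2.0)
    phase = np.exp(2j * np.pi * rng.random(freqs.size))
    spec = mag * phase
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = mag[-1]  # Nyquist component must be real
    signal = np.fft.irfft(spec, n=n)

    events = []
    if spindles is not None and spindles.rate_per_min > 0:
        n_events = rng.poisson(spindles.rate_per_min * duration_s / 60.0)
        n_dur = int(round(spindles.duration_s * sfreq))
        t_local = np.arange(n_dur) / sfreq
        envelope = np.hanning(n_dur)
        for _ in range(n_events):
            start = rng.integers(0, n - n_dur)
            phi = rng.uniform(0, 2 * np.pi)
            signal[start:start + n_dur] += (
                spindles.amp_uV * envelope
                * np.sin(2 * np.pi * spindles.freq_hz * t_local + phi)
            )
            events.append(start / sfreq)

    n_epochs = int(duration_s // epoch_length_s)
    bundle = RecordingBundle(
        np.tile(signal, (len(channel_names), 1)),
        sfreq, list(channel_names), ["N2"] * n_epochs,
        epoch_length_s=epoch_length_s,
    )
    truth = {"alpha": alpha, "lnC": lnC, "seed": seed,
             "spindle_starts_s": events,
             "spindle_freq_hz": spindles.freq_hz if spindles else None}
    return bundle, truth


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class PlantedEffects:
    """Target effect sizes for the cohort generator.

    Correlations are on latent (Gaussian-copula) scales; group differences
    are Cohen's d in units of the between-subject SD.  Defaults mirror the
    direction and rough size of the age/sex/IQ findings in adult NREM sleep
    EEG: older age flattens the slope, lowers peak amplitude and frontal
    peak frequency; women have higher intercepts and faster spindles; peak
    amplitude relates to IQ in women only.
    """

    age_alpha: float = 0.45
    age_peak_amp: float = -0.35
    age_fmax: float = -0.25
    sex_intercept_d: float = 0.6
    sex_fmax_d: float = 0.6
    sex_peak_amp_d: float = 0.0
    iq_peak_amp_female: float = 0.30
    iq_peak_amp_male: float = 0.0

    @classmethod
    def null(cls) -> "PlantedEffects":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


#: Observed distribution of the maximal antero-posterior shift location.
BOUNDARY_PROBS = {"F-Fp": 0.3694, "C-F": 0.5477, "P-C": 0.0636, "O-P": 0.0191}

#: Fixed per-channel deviations of the mean exponent (frontal midline steepest,
#: posterior temporal flattest).
_ALPHA_CHANNEL_OFFSET = {
    "Fp1": -0.05, "Fp2": -0.05, "F3": -0.10, "F4": -0.10, "Fz": -0.20,
    "F7": 0.00, "F8": 0.00, "C3": -0.05, "C4": -0.05, "Cz": -0.10,
    "P3": 0.00, "P4": 0.00, "T3": 0.10, "T4": 0.10, "T5": 0.17, "T6": 0.15,
    "O1": 0.05, "O2": 0.05,
}


@dataclass
class CohortSpec:
    """Synthetic-cohort description (sizes, distributions, planted effects)."""

    n_subjects: int = 175
    female_ratio: float = 81 / 175
    age_range: tuple[float, float] = (17.0, 60.0)
    iq_mean: float = 117.0
    iq_sd: float = 14.0
    iq_split: float = 120.0
    effects: PlantedEffects = field(default_factory=PlantedEffects)
    channels: tuple[str, ...] = CHANNELS_18
    alpha_mean: float = -2.5
    alpha_sd: float = 0.22
    intercept_anchor: float = 2.5    # ln f where the slope-free intercept lives
    slope_free_mean: float = -1.5
    slope_free_sd: float = 0.35
    peak_amp_mean: float = 0.8
    peak_amp_sd: float = 0.30
    fmax_base: float = 11.6          # frontopolar regional mean (Hz)
    fmax_sd: float = 0.40
    max_shift_hz: float = 1.67
    minor_shift_hz: float = 0.107    # the remaining upward drift per boundary
    channel_noise: dict = field(default_factory=lambda: {
        "alpha": 0.05, "intercept": 0.07, "peak_amp": 0.06, "fmax": 0.12})
    missing_peak_rate: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        e = self.effects
        for name, v in (("age_alpha", e.age_alpha), ("age_peak_amp", e.age_peak_amp),
                        ("age_fmax", e.age_fmax),
                        ("iq_peak_amp_female", e.iq_peak_amp_female),
                        ("iq_peak_amp_male", e.iq_peak_amp_male)):
            if abs(v) >= 1:
                raise ValueError(f"|planted correlation| must be < 1 ({name}={v})")
        # latent loadings on the independent age and IQ factors must leave a
        # non-negative residual variance, else the implied correlation matrix
        # is not positive semidefinite
        for label, load in (("female", (e.age_peak_amp, e.iq_peak_amp_female)),
                            ("male", (e.age_peak_amp, e.iq_peak_amp_male))):
            if sum(v * v for v in load) >= 1.0:
                raise ValueError(
                    "infeasible planted effects: implied correlation matrix for "
                    f"the {label} peak-amplitude latent is not positive semidefinite"
                )


def synth_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Draw a cohort parameter table, covariates, and the truth record.

    Subject-level parameters are Gaussian latents coupled to age/IQ factors
    at the planted correlations (sex enters as mean shifts); channel values
    add fixed topographic offsets plus small channel noise, so channels are
    strongly intercorrelated, as on a real scalp.  Each subject's maximal
    antero-posterior peak-frequency jump is planted at a boundary drawn from
    the observed boundary distribution.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    e = spec.effects

    z_age = rng.standard_normal(n)
    age = spec.age_range[0] + (spec.age_range[1] - spec.age_range[0]) * _phi(z_age)
    n_f = int(round(n * spec.female_ratio))
    sex = np.array(["F"] * n_f + ["M"] * (n - n_f))
    rng.shuffle(sex)
    female = (sex == "F").astype(float)
    z_iq = rng.standard_normal(n)
    iq = spec.iq_mean + spec.iq_sd * z_iq
    iq_group = np.where(iq >= spec.iq_split, "HIQ", "AIQ")

    def coupled(rho: float) -> np.ndarray:
        return rho * z_age + np.sqrt(1 - rho**2) * rng.standard_normal(n)

    alpha_s = spec.alpha_mean + spec.alpha_sd * coupled(e.age_alpha)
    u_s = (spec.slope_free_mean + spec.slope_free_sd * rng.standard_normal(n)
           + e.sex_intercept_d * spec.slope_free_sd * female)
    rho_iq = np.where(female == 1, e.iq_peak_amp_female, e.iq_peak_amp_male)
    resid = np.sqrt(np.clip(1 - e.age_peak_amp**2 - rho_iq**2, 0, None))
    amp_s = (spec.peak_amp_mean + spec.peak_amp_sd
             * (e.age_peak_amp * z_age + rho_iq * z_iq
                + resid * rng.standard_normal(n))
             + e.sex_peak_amp_d * spec.peak_amp_sd * female)
    fmax_level = (spec.fmax_base + spec.fmax_sd * coupled(e.age_fmax)
                  + e.sex_fmax_d * spec.fmax_sd * female)

    boundary_names = list(BOUNDARY_PROBS)
    probs = np.array(list(BOUNDARY_PROBS.values()))
    boundaries = rng.choice(boundary_names, size=n, p=probs / probs.sum())

    cn = spec.channel_noise
    rows = []
    for i in range(n):
        region_level = _regional_levels(fmax_level[i], boundaries[i],
                                        spec.max_shift_hz, spec.minor_shift_hz)
        for ch in spec.channels:
            a = alpha_s[i] + _ALPHA_CHANNEL_OFFSET.get(ch, 0.0) \
                + cn["alpha"] * rng.standard_normal()
            u = u_s[i] + cn["intercept"] * rng.standard_normal()
            lnC0 = u - spec.intercept_anchor * a
            missing = rng.random() < spec.missing_peak_rate
            fmax = (np.nan if missing else
                    region_level[CHANNEL_ROW[ch]]
                    + cn["fmax"] * rng.standard_normal())
            amp = (np.nan if missing else
                   amp_s[i] + cn["peak_amp"] * rng.standard_normal())
            row = {"subject_id": f"S{i:03d}", "channel": ch,
                   "alpha": a, "lnC0": lnC0,
                   "r2": min(0.9999, 0.995 + 0.003 * rng.standard_normal()),
                   "f_maxPeak": fmax, "lnPPeak": amp,
                   "n_peaks": 0 if missing else int(1 + (rng.random() < 0.3))}
            for x in (2.0, 2.3, 2.5, 2.6, 2.7, 3.0):
                row[f"lnC_{x:.1f}"] = lnC0 + a * x
            rows.append(row)
    params = pd.DataFrame(rows)
    covariates = pd.DataFrame({
        "subject_id": [f"S{i:03d}" for i in range(n)],
        "age_years": age, "sex": sex,
        "iq_score": iq, "iq_group": iq_group,
    })
    truth = {
        "effects": e, "seed": spec.seed, "n_subjects": n,
        "boundary": dict(zip(covariates["subject_id"], boundaries)),
        "subject_alpha": alpha_s, "subject_peak_amp": amp_s,
        "subject_fmax_level": fmax_level, "subject_slope_free": u_s,
    }
    return params, covariates, truth


def _phi(z: np.ndarray) -> np.ndarray:
    from scipy.stats import norm
    return norm.cdf(z)


def _regional_levels(base: float, boundary: str, max_shift: float,
                     minor_shift: float) -> dict[str, float]:
    """Antero-posterior regional means with the big jump at ``boundary``."""
    names = ("F-Fp", "C-F", "P-C", "O-P")
    levels = {"Fp": base}
    current = base
    for name, region in zip(names, ("F", "C", "P", "O")):
        current += max_shift if name == boundary else minor_shift
        levels[region] = current
    return levels


def null_cohort(n_subjects: int = 175, seed: int = 0) -> CohortSpec:
    """A cohort with every planted effect zeroed (global null)."""
    return CohortSpec(n_subjects=n_subjects, seed=seed,
                      effects=PlantedEffects.null())
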