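"""Averaged-periodogram spectral estimation for staged, artifact-masked sleep EEG.

Power spectral densities are computed from 4 s Hann-tapered windows with 50 %
overlap, restricted to scoring epochs in the requested sleep stages and to
artifact-free 4 s segments, then averaged.  A 4 s window yields an exact
0.25 Hz bin width for every sampling rate with an integral number of samples
per window (mixed-radix FFT; no zero padding).  Device frequency responses
are undone by dividing power by the squared amplitude-reduction rate of the
recording system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .io import RecordingBundle

ARTIFACT_SEGMENT_S = 4.0
DEFAULT_STAGES = frozenset({"N2", "N3"})


@dataclass
class Spectrum:
    """Average one-sided power spectral density on a uniform 0.25 Hz grid.

    ``power`` is in µV²/Hz; ``freqs`` in Hz with constant 0.25 Hz spacing.
    ``n_windows`` counts the averaged 4 s windows (1 for externally supplied
    spectra of unknown provenance).
    """

    freqs: np.ndarray
    power: np.ndarray
    channel: str = ""
    n_windows: int = 1

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape or self.freqs.ndim != 1:
            raise ValueError("freqs and power must be 1-D arrays of equal length")
        steps = np.diff(self.freqs)
        if len(steps) and not np.allclose(steps, 0.25, atol=1e-9):
            raise ValueError(
                f"frequency grid must have a constant 0.25 Hz step; observed steps "
                f"in [{steps.min():.6g}, {steps.max():.6g}]"
            )
        if np.any(self.power < 0):
            idx = int(np.argmax(self.power < 0))
            raise ValueError(f"negative power at bin {idx} (f={self.freqs[idx]:.2f} Hz)")
        if self.n_windows < 1:
            raise ValueError("n_windows must be >= 1")

    @property
    def df(self) -> float:
        return 0.25

    def band(self, fmin: float, fmax: float) -> tuple[np.ndarray, np.ndarray]:
        """Return (freqs, power) restricted to the closed interval [fmin, fmax]."""
        m = (self.freqs >= fmin - 1e-9) & (self.freqs <= fmax + 1e-9)
        return self.freqs[m], self.power[m]


@dataclass
class CalibrationCurve:
    """Frequency response of a recording system as amplitude-reduction rates.

    Anchors hold the measured/generated sinusoid amplitude ratio (averaged over
    the two test amplitudes); a cubic spline interpolates between anchors and
    is clamped to the boundary rate outside the measured span.
    """

    anchor_freqs: np.ndarray
    anchor_rates: np.ndarray
    _spline: CubicSpline = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self.anchor_freqs = np.asarray(self.anchor_freqs, dtype=float)
        self.anchor_rates = np.asarray(self.anchor_rates, dtype=float)
        if self.anchor_freqs.size < 4:
            raise ValueError("need at least 4 calibration anchors for a cubic spline")
        if np.any(np.diff(self.anchor_freqs) <= 0):
            raise ValueError("anchor frequencies must be strictly increasing")
        if np.any(self.anchor_rates <= 0) or np.any(self.anchor_rates > 1.5):
            raise ValueError("amplitude reduction rates must lie in (0, 1.5]")
        if self._spline is None:
            self._spline = CubicSpline(self.anchor_freqs, self.anchor_rates)

    def rate(self, freqs: np.ndarray) -> np.ndarray:
        """Reduction rate at ``freqs``, clamped to the anchor span."""
        f = np.clip(np.asarray(freqs, dtype=float),
                    self.anchor_freqs[0], self.anchor_freqs[-1])
        return np.asarray(self._spline(f), dtype=float)


def build_calibration(anchor_freqs, rates_40uV, rates_355uV) -> CalibrationCurve:
    """Average the two test-amplitude conditions and spline the anchors.

    Each recording system's amplitude reduction was measured with sinusoids of
    two amplitudes at a fixed set of frequencies; the per-anchor rate is the
    mean of the two conditions and intermediate frequencies are spline
    interpolated.
    """
    anchor_freqs = np.asarray(anchor_freqs, dtype=float)
    r1 = np.asarray(rates_40uV, dtype=float)
    r2 = np.asarray(rates_355uV, dtype=float)
    if r1.shape != anchor_freqs.shape or r2.shape != anchor_freqs.shape:
        raise ValueError("rate vectors must match the anchor frequencies in length")
    if np.any(r1 <= 0) or np.any(r2 <= 0):
        raise ValueError("reduction rates must be positive")
    return CalibrationCurve(anchor_freqs, (r1 + r2) / 2.0)


def apply_calibration(spec: Spectrum, cal: CalibrationCurve) -> Spectrum:
    """Correct a spectrum for the device response: P_out(f) = P_in(f) / rate(f)²."""
    rate = cal.rate(spec.freqs)
    if np.any(rate <= 0):
        raise ValueError("calibration rate is non-positive on the spectrum grid")
    return Spectrum(spec.freqs, spec.power / rate**2,
                    channel=spec.channel, n_windows=spec.n_windows)


def select_windows(
    bundle: RecordingBundle,
    stages: frozenset[str] | set[str] = DEFAULT_STAGES,
    window_s: float = 4.0,
    overlap: float = 0.5,
) -> np.ndarray:
    """Start times (s) of analysis windows inside the requested sleep stages.

    Windows advance by ``window_s * (1 - overlap)``.  A window is eligible when
    it lies entirely inside scored epochs that all carry one and the same stage
    from ``stages`` (a stage change breaks continuity), fits inside the signal,
    and intersects no artifact-marked 4 s segment.
    """
    if not stages:
        raise ValueError("stages must be non-empty")
    sfreq = bundle.sfreq
    if abs(window_s * sfreq - round(window_s * sfreq)) > 1e-9:
        raise ValueError(f"window_s * sfreq must be integral (got {window_s * sfreq})")
    hop = window_s * (1.0 - overlap)
    if hop <= 0:
        raise ValueError("overlap must be < 1")

    n_samples = bundle.n_samples
    signal_dur = n_samples / sfreq
    epoch_len = bundle.epoch_length_s
    scored_dur = len(bundle.epoch_stages) * epoch_len
    usable = min(signal_dur, scored_dur)

    mask = bundle.artifact_mask
    eps = 1e-9
    starts = []
    t = 0.0
    while t + window_s <= usable + eps:
        e0 = int(t / epoch_len + eps)
        e1 = int((t + window_s - eps) / epoch_len)
        epoch_ok = e1 < len(bundle.epoch_stages)
        if epoch_ok:
            window_stages = {bundle.epoch_stages[e] for e in range(e0, e1 + 1)}
            epoch_ok = len(window_stages) == 1 and window_stages <= set(stages)
        if epoch_ok:
            s0 = int(t / ARTIFACT_SEGMENT_S + eps)
            s1 = int((t + window_s - eps) / ARTIFACT_SEGMENT_S)
            s1 = min(s1, len(mask) - 1)
            if not any(mask[s0:s1 + 1]):
                starts.append(t)
        t += hop
    if not starts:
        raise ValueError("no artifact-free NREM data: zero eligible windows")
    return np.asarray(starts)


def average_periodogram(
    signal: np.ndarray,
    sfreq: float,
    windows: np.ndarray,
    window_s: float = 4.0,
    channel: str = "",
) -> Spectrum:
    """Hann-tapered averaged periodogram (one-sided PSD, 0.25 Hz bins).

    The taper-power normalization ``2 |X|² / (sfreq Σw²)`` conserves white-noise
    variance (Parseval); DC and Nyquist bins are not doubled.  Window lengths
    need not be powers of two (numpy's FFT is mixed-radix).
    """
    signal = np.asarray(signal, dtype=float)
    n = int(round(window_s * sfreq))
    starts = np.asarray(windows, dtype=float)
    if starts.size == 0:
        raise ValueError("need at least one window")
    idx = np.rint(starts * sfreq).astype(int)
    if np.any(idx < 0) or np.any(idx + n > signal.size):
        bad = idx[(idx < 0) | (idx + n > signal.size)][0]
        raise ValueError(f"window starting at sample {bad} exceeds signal bounds")

    taper = np.hanning(n)  # symmetric Hann
    norm = sfreq * np.sum(taper**2)
    segs = np.stack([signal[i:i + n] for i in idx])
    spec = np.fft.rfft(segs * taper, axis=1)
    psd = (np.abs(spec) ** 2) / norm
    psd[:, 1:] *= 2.0
    if n % 2 == 0:
        psd[:, -1] /= 2.0  # Nyquist bin is not duplicated in the two-sided spectrum
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    return Spectrum(freqs, psd.mean(axis=0), channel=channel, n_windows=len(idx))


def bundle_to_spectra(
    bundle: RecordingBundle,
    stages: frozenset[str] | set[str] = DEFAULT_STAGES,
    calibration: CalibrationCurve | None = None,
    window_s: float = 4.0,
    overlap: float = 0.5,
) -> list[Spectrum]:
    """Full per-channel pipeline: window selection, averaging, calibration."""
    starts = select_windows(bundle, stages, window_s=window_s, overlap=overlap)
    out = []
    for name, sig in zip(bundle.channel_names, bundle.signals):
        spec = average_periodogram(sig, bundle.sfreq, starts, window_s=window_s,
                                   channel=name)
        if calibration is not None:
            spec = apply_calibration(spec, calibration)
        out.append(spec)
    return out
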