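"""End-to-end convenience wrappers: spectrum -> fit -> peaks -> parameter rows."""

from __future__ import annotations

import numpy as np

from .peaks import DEFAULT_BAND, SpectralPeakSet, detect_peaks
from .powerlaw import DEFAULT_EXCLUDE, PowerLawFit, fit_spectrum
from .spectral import Spectrum


def parametrize_spectrum(
    spec: Spectrum,
    subject_id: str = "",
    fmin: float = 2.0,
    fmax: float = 48.0,
    exclude: tuple[float, float] = DEFAULT_EXCLUDE,
    band: tuple[float, float] = DEFAULT_BAND,
) -> tuple[dict, PowerLawFit, SpectralPeakSet]:
    """Fit the background, detect whitened peaks, and emit one parameter row.

    The row follows the parameter-table schema; a spectrum with no peak in
    the spindle band carries NaN peak fields (missing data).
    """
    fit = fit_spectrum(spec, fmin=fmin, fmax=fmax, exclude=exclude)
    peakset = detect_peaks(spec, fit, band=band)
    row = {
        "subject_id": subject_id,
        "channel": spec.channel,
        "alpha": fit.alpha,
        "lnC0": fit.lnC0,
        "r2": fit.r2,
        "f_maxPeak": peakset.f_maxPeak,
        "lnPPeak": peakset.lnPPeak_max,
        "n_peaks": peakset.n_detected,
        "spindle_class": "",
    }
    for x, v in fit.alt_intercepts.items():
        row[f"lnC_{x:.1f}"] = v
    return row, fit, peakset


def parametrize_spectra(spectra, subject_id: str = "", **kwargs) -> list[dict]:
    """Parameter rows for a list of per-channel spectra of one subject."""
    rows = []
    f_max = {}
    for spec in spectra:
        row, _, peakset = parametrize_spectrum(spec, subject_id, **kwargs)
        rows.append(row)
        f_max[spec.channel] = peakset.f_maxPeak
    # attach the slow/fast classification when the montage allows it
    try:
        from .topography import subject_topography
        profile = subject_topography(f_max)
        for row in rows:
            row["spindle_class"] = profile.spindle_class.get(row["channel"], "")
    except ValueError:
        pass
    return rows
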