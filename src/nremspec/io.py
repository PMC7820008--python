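"""Readers and writers for every external format the pipeline touches.

Signals come in as EDF/EDF+ (read through mne), sleep staging as a plain-text
hypnogram (one stage code per scoring epoch, default 20 s), and artifacts as a
4 s-grid mask or an interval list.  Precomputed average spectra and fitted
parameters travel as CSV tables; fits additionally as JSON bundles.
All frequencies are Hz, powers µV²/Hz, logarithms natural.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import canonical_channel

logger = logging.getLogger(__name__)

STAGE_CODES = ("W", "N1", "N2", "N3", "R")

#: Accepted spellings per canonical AASM stage code (case-insensitive).
#: Numeric codes follow the usual 0=wake .. 5=REM convention, with the legacy
#: stage 4 folded into N3.
DEFAULT_STAGE_ALIASES: dict[str, tuple[str, ...]] = {
    "W": ("w", "wake", "0"),
    "N1": ("n1", "s1", "1"),
    "N2": ("n2", "s2", "2"),
    "N3": ("n3", "s3", "s4", "sws", "3", "4"),
    "R": ("r", "rem", "5"),
}

ARTIFACT_SEGMENT_S = 4.0

PARAMETER_COLUMNS = (
    "subject_id", "channel", "alpha", "lnC0",
    "lnC_2.0", "lnC_2.3", "lnC_2.5", "lnC_2.6", "lnC_2.7", "lnC_3.0",
    "r2", "f_maxPeak", "lnPPeak", "n_peaks", "spindle_class",
)


@dataclass
class RecordingBundle:
    """A polysomnography recording with staging and artifact annotations.

    ``signals`` is channels x samples in µV; ``epoch_stages`` holds one AASM
    code per ``epoch_length_s`` scoring epoch; ``artifact_mask`` is one boolean
    per 4 s segment (True = artifactual).
    """

    signals: np.ndarray
    sfreq: float
    channel_names: list[str]
    epoch_stages: list[str]
    epoch_length_s: float = 20.0
    artifact_mask: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.signals.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.signals.shape[0]} signal rows for "
                f"{len(self.channel_names)} channel names"
            )
        unknown = [s for s in self.epoch_stages if s not in STAGE_CODES]
        if unknown:
            raise ValueError(
                f"unknown stage code(s) {sorted(set(unknown))}; accepted: {STAGE_CODES}"
            )
        n_seg = math.ceil(self.duration_s / ARTIFACT_SEGMENT_S)
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(n_seg, dtype=bool)
        else:
            self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
            if self.artifact_mask.size != n_seg:
                raise ValueError(
                    f"artifact mask has {self.artifact_mask.size} segments, "
                    f"expected ceil({self.duration_s:g}/4) = {n_seg}"
                )
        scored = len(self.epoch_stages) * self.epoch_length_s
        if scored > self.duration_s + self.epoch_length_s + 1e-9:
            raise ValueError(
                f"hypnogram covers {scored:g} s but the signal lasts only "
                f"{self.duration_s:g} s"
            )

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sfreq


def _alias_map(aliases: dict[str, tuple[str, ...]]) -> dict[str, str]:
    table = {}
    for canon, names in aliases.items():
        table[canon.lower()] = canon
        for a in names:
            table[a.lower()] = canon
    return table


def read_hypnogram(path, stage_aliases: dict | None = None) -> list[str]:
    """Parse a hypnogram file into canonical stage codes.

    Two dialects: one stage code per line, or CSV with columns
    ``epoch_index,stage`` (a header line is tolerated).
    """
    table = _alias_map(stage_aliases or DEFAULT_STAGE_ALIASES)
    stages: list[tuple[int, str]] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines()):
        line = raw.strip()
        if not line:
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) == 2:
            if parts[0].lower() in ("epoch_index", "epoch"):
                continue
            idx, code = int(parts[0]), parts[1]
        else:
            idx, code = len(stages), parts[0]
        key = code.lower()
        if key not in table:
            raise ValueError(
                f"unknown stage code {code!r} on line {lineno + 1}; "
                f"accepted aliases: {sorted(table)}"
            )
        stages.append((idx, table[key]))
    stages.sort(key=lambda t: t[0])
    return [code for _, code in stages]


def read_artifact_mask(path, duration_s: float) -> np.ndarray:
    """Parse an artifact file into one boolean per 4 s segment.

    Two dialects: one 0/1 per line on the 4 s grid, or interval lines
    ``start_s,end_s`` snapped outward to the 4 s grid.
    """
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    n_seg = math.ceil(duration_s / ARTIFACT_SEGMENT_S)
    mask = np.zeros(n_seg, dtype=bool)
    if all(ln in ("0", "1") for ln in lines):
        vals = np.array([int(ln) for ln in lines], dtype=bool)
        if vals.size > n_seg:
            vals = vals[:n_seg]
        mask[: vals.size] = vals
        return mask
    for lineno, ln in enumerate(lines):
        parts = ln.split(",")
        if len(parts) != 2:
            raise ValueError(
                f"artifact line {lineno + 1} is neither 0/1 nor 'start_s,end_s': {ln!r}"
            )
        start, end = float(parts[0]), float(parts[1])
        if end <= start:
            raise ValueError(f"empty artifact interval on line {lineno + 1}")
        s0 = int(math.floor(start / ARTIFACT_SEGMENT_S))
        s1 = int(math.ceil(end / ARTIFACT_SEGMENT_S))
        mask[max(s0, 0): min(s1, n_seg)] = True
    return mask


def read_recording(
    edf_path,
    hypnogram_path,
    artifact_path=None,
    channels: list[str] | None = None,
    epoch_length_s: float = 20.0,
    stage_aliases: dict | None = None,
) -> RecordingBundle:
    """Assemble a RecordingBundle from an EDF file plus staging/artifact files.

    ``channels`` restricts (and orders) the montage subset; omitted channels in
    the file are an error naming the channel.  A missing artifact file yields
    an all-false mask.  If the hypnogram is shorter than the recording, the
    signal is truncated to the scored duration with a logged warning.
    """
    import mne

    raw = mne.io.read_raw_edf(str(edf_path), preload=True, verbose="error")
    data = raw.get_data(units="uV")
    names = [canonical_channel(n) for n in raw.ch_names]
    sfreq = float(raw.info["sfreq"])

    if channels is not None:
        want = [canonical_channel(c) for c in channels]
        missing = [c for c in want if c not in names]
        if missing:
            raise ValueError(
                f"channel(s) {missing} requested but absent from the EDF "
                f"(available: {names})"
            )
        sel = [names.index(c) for c in want]
        data, names = data[sel], want

    stages = read_hypnogram(hypnogram_path, stage_aliases)
    scored_s = len(stages) * epoch_length_s
    duration_s = data.shape[1] / sfreq
    if scored_s < duration_s - 1e-9:
        logger.warning(
            "hypnogram covers %.0f s of a %.0f s recording; truncating signal "
            "to the scored duration", scored_s, duration_s,
        )
        data = data[:, : int(round(scored_s * sfreq))]
        duration_s = data.shape[1] / sfreq
    elif scored_s > duration_s + epoch_length_s:
        stages = stages[: math.ceil(duration_s / epoch_length_s)]
        warnings.warn("hypnogram longer than recording by more than one epoch; "
                      "extra epochs dropped")

    mask = None
    if artifact_path is not None and Path(artifact_path).exists():
        mask = read_artifact_mask(artifact_path, duration_s)
    return RecordingBundle(data, sfreq, list(names), stages,
                           epoch_length_s=epoch_length_s, artifact_mask=mask)


def read_spectra_table(csv_path) -> list:
    """Read a CSV of average power spectra (one channel per column).

    The first column must be ``frequency_hz``, strictly increasing with a
    constant 0.25 Hz step; powers must be non-negative.
    """
    from .spectral import Spectrum

    df = pd.read_csv(csv_path, float_precision="round_trip")
    if df.columns[0] != "frequency_hz":
        raise ValueError(
            f"first column must be 'frequency_hz', got {df.columns[0]!r}"
        )
    freqs = df["frequency_hz"].to_numpy(dtype=float)
    steps = np.diff(freqs)
    if len(steps) == 0 or not np.allclose(steps, 0.25, atol=1e-9):
        raise ValueError(
            f"frequency grid must step by exactly 0.25 Hz; observed steps in "
            f"[{steps.min():.6g}, {steps.max():.6g}]" if len(steps)
            else "spectra table needs at least two frequency rows"
        )
    spectra = []
    for col in df.columns[1:]:
        power = df[col].to_numpy(dtype=float)
        if np.any(power < 0):
            row = int(np.argmax(power < 0))
            raise ValueError(f"negative power for channel {col!r} at row {row}")
        spectra.append(Spectrum(freqs, power, channel=canonical_channel(col)))
    return spectra


def write_spectra_table(spectra, path) -> None:
    """Write spectra sharing one grid to CSV (column per channel)."""
    base = spectra[0].freqs
    for s in spectra[1:]:
        if s.freqs.shape != base.shape or not np.allclose(s.freqs, base):
            raise ValueError("all spectra must share one frequency grid")
    df = pd.DataFrame({"frequency_hz": base})
    for s in spectra:
        df[s.channel or f"ch{len(df.columns)}"] = s.power
    df.to_csv(path, index=False)


def write_parameter_table(rows, path) -> None:
    """Write per-subject/channel fitted parameters to CSV.

    ``rows`` is an iterable of dicts (or a DataFrame) carrying the columns in
    ``PARAMETER_COLUMNS``.  A spectrum with no detected peak in the spindle
    range carries empty ``f_maxPeak``/``lnPPeak`` cells (missing data).
    """
    df = pd.DataFrame(list(rows) if not isinstance(rows, pd.DataFrame) else rows)
    for col in PARAMETER_COLUMNS:
        if col not in df.columns:
            df[col] = pd.Series(dtype=object)
    df = df[list(PARAMETER_COLUMNS)]
    df.to_csv(path, index=False)


def read_parameter_table(path) -> pd.DataFrame:
    """Reparse a parameter table; empty peak cells come back as NaN."""
    return pd.read_csv(path, float_precision="round_trip")
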