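"""Minimal EDF writer for synthetic recordings.

Writes plain EDF (16-bit, one data record per second) sufficient for
round-tripping the package's own synthetic signals through standard EDF
readers.  Only what the simulator needs is implemented: identical sampling
rate across channels, µV physical units, integer samples per record.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np


def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, signals: np.ndarray, sfreq: float, channel_names,
              patient: str = "X", recording: str = "nremspec synthetic") -> None:
    """Write channels x samples µV data to an EDF file.

    ``sfreq`` must be integral (samples per 1 s data record).  Data are scaled
    channel-wise to the full 16-bit digital range; a trailing partial second
    is dropped.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    n_ch, n_samp = signals.shape
    if len(channel_names) != n_ch:
        raise ValueError("channel_names length must match signal rows")
    spr = int(round(sfreq))
    if abs(sfreq - spr) > 1e-9:
        raise ValueError("EDF writer requires an integral sampling rate")
    n_rec = n_samp // spr
    if n_rec < 1:
        raise ValueError("signal shorter than one 1 s data record")
    signals = signals[:, : n_rec * spr]

    # Per-channel symmetric physical range, padded so extremes stay in range.
    phys_max = np.maximum(np.max(np.abs(signals), axis=1) * 1.01, 1e-6)
    dig_min, dig_max = -32768, 32767

    now = _dt.datetime(2000, 1, 1, 0, 0, 0)
    header = b"".join([
        _ascii("0", 8),
        _ascii(patient, 80),
        _ascii(recording, 80),
        _ascii(now.strftime("%d.%m.%y"), 8),
        _ascii(now.strftime("%H.%M.%S"), 8),
        _ascii(256 + 256 * n_ch, 8),
        _ascii("", 44),
        _ascii(n_rec, 8),
        _ascii("1", 8),          # record duration (s)
        _ascii(n_ch, 4),
    ])
    header += b"".join(_ascii(name, 16) for name in channel_names)
    header += b"".join(_ascii("EEG", 80) for _ in range(n_ch))
    header += b"".join(_ascii("uV", 8) for _ in range(n_ch))
    header += b"".join(_ascii(f"{-m:.6g}"[:8], 8) for m in phys_max)
    header += b"".join(_ascii(f"{m:.6g}"[:8], 8) for m in phys_max)
    header += b"".join(_ascii(dig_min, 8) for _ in range(n_ch))
    header += b"".join(_ascii(dig_max, 8) for _ in range(n_ch))
    header += b"".join(_ascii("", 80) for _ in range(n_ch))   # prefiltering
    header += b"".join(_ascii(spr, 8) for _ in range(n_ch))
    header += b"".join(_ascii("", 32) for _ in range(n_ch))   # reserved

    # The header's physical min/max fields are truncated ASCII; quantize with
    # the values as written so readers recover exactly what we intended.
    written_max = np.array([float(f"{m:.6g}"[:8]) for m in phys_max])
    scale = (dig_max - dig_min) / (2 * written_max)
    digital = np.rint((signals + written_max[:, None]) * scale[:, None]) + dig_min
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_rec):
            chunk = digital[:, rec * spr:(rec + 1) * spr]
            fh.write(chunk.tobytes())
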