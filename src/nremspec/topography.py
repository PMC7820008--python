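"""Antero-posterior topography of the dominant spindle spectral peak.

Per-channel f_maxPeak values are averaged within sagittal regions
(frontopolar, frontal, central, parietal, occipital), the regional means are
serially subtracted front-to-back, and the location of the maximal upward
frequency shift splits the scalp into a rostral slow-spindle and a caudal
fast-spindle territory.  Most of the total antero-posterior frequency
increase concentrates in that single maximal step, which motivates the
single-boundary classification.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .montage import CHANNEL_ROW, REGION_ORDER, REGIONS, TEMPORAL_CHANNELS

SHIFT_NAMES = ("F-Fp", "C-F", "P-C", "O-P")
#: Region pair per shift, posterior region first.
_SHIFT_PAIRS = tuple(zip(REGION_ORDER[1:], REGION_ORDER[:-1]))


@dataclass
class RegionalProfile:
    region_means: dict[str, float]
    shifts: dict[str, float]
    total_shift: float
    max_shift_location: str
    spindle_class: dict[str, str]
    extrapolated: tuple[str, ...] = ()


def regional_means(f_max_by_channel: dict[str, float]) -> dict[str, float]:
    """Mean f_maxPeak per sagittal region over the available channels.

    Missing channels (absent or NaN) are dropped; a region with no channel at
    all yields NaN.  Temporal channels belong to no region.
    """
    means: dict[str, float] = {}
    any_present = False
    for region in REGION_ORDER:
        vals = [f_max_by_channel[ch] for ch in REGIONS[region]
                if ch in f_max_by_channel
                and not math.isnan(f_max_by_channel[ch])]
        if vals:
            means[region] = float(np.mean(vals))
            any_present = True
        else:
            means[region] = float("nan")
    if not any_present:
        raise ValueError("no region has any non-missing f_maxPeak value")
    return means


def antero_posterior_profile(
    means: dict[str, float],
    channels: tuple[str, ...] | None = None,
) -> RegionalProfile:
    """Serial front-to-back differences of regional means and the boundary rule.

    A shift touching a missing region is missing; the maximum is taken over
    the non-missing shifts (ties resolved toward the most anterior shift with
    a warning).  Channels whose antero-posterior row lies rostral to the
    maximal-shift boundary are labeled "slow", the rest "fast"; temporal
    channels, which sit outside the averaged regions, are classified by their
    row and flagged as extrapolated.
    """
    shifts: dict[str, float] = {}
    for name, (post, ant) in zip(SHIFT_NAMES, _SHIFT_PAIRS):
        shifts[name] = means.get(post, float("nan")) - means.get(ant, float("nan"))
    finite = {k: v for k, v in shifts.items() if not math.isnan(v)}
    if len(finite) < 1:
        raise ValueError("need at least 2 consecutive non-missing regions")
    total = float(sum(finite.values()))
    best = max(finite.values())
    winners = [k for k in SHIFT_NAMES if finite.get(k) == best]
    if len(winners) > 1:
        warnings.warn(f"tie for the maximal shift among {winners}; "
                      "most anterior wins")
    location = winners[0]
    if best <= 0:
        warnings.warn("no upward antero-posterior frequency shift; "
                      "classification uses the least negative shift")

    # Boundary sits between the two regions of the winning shift name.
    posterior_region = dict(zip(SHIFT_NAMES, _SHIFT_PAIRS))[location][0]
    boundary_idx = REGION_ORDER.index(posterior_region)
    if channels is None:
        channels = tuple(CHANNEL_ROW)
    klass = {
        ch: "slow" if REGION_ORDER.index(CHANNEL_ROW[ch]) < boundary_idx else "fast"
        for ch in channels if ch in CHANNEL_ROW
    }
    extrapolated = tuple(ch for ch in klass if ch in TEMPORAL_CHANNELS)
    return RegionalProfile(
        region_means=dict(means),
        shifts=shifts,
        total_shift=total,
        max_shift_location=location,
        spindle_class=klass,
        extrapolated=extrapolated,
    )


def subject_topography(f_max_by_channel: dict[str, float]) -> RegionalProfile:
    """Regional averaging plus the antero-posterior profile for one subject."""
    return antero_posterior_profile(
        regional_means(f_max_by_channel),
        channels=tuple(f_max_by_channel),
    )
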