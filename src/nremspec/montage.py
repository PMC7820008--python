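"""The 18-channel 10-20 scalp montage used throughout the package.

Channel names, sagittal region membership, the antero-posterior row of every
channel, and a fixed scalp-neighborhood graph used to form contiguous
electrode areas in the multiple-testing procedure.
"""

from __future__ import annotations

# Canonical order: frontopolar -> frontal -> central -> parietal/temporal -> occipital.
CHANNELS_18: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "Fz", "F7", "F8",
    "C3", "C4", "Cz", "P3", "P4",
    "T3", "T4", "T5", "T6", "O1", "O2",
)

# Sagittal regions for antero-posterior averaging of peak frequencies.
# The montage carries no Pz, so the parietal region averages P3/P4 only.
REGIONS: dict[str, tuple[str, ...]] = {
    "Fp": ("Fp1", "Fp2"),
    "F": ("F3", "F4", "Fz"),
    "C": ("C3", "C4", "Cz"),
    "P": ("P3", "P4"),
    "O": ("O1", "O2"),
}

REGION_ORDER: tuple[str, ...] = ("Fp", "F", "C", "P", "O")

# Antero-posterior row of every channel, including the temporal chain, which
# sits outside the five sagittal regions but still needs a row for the
# slow/fast classification relative to the maximal-shift boundary.
CHANNEL_ROW: dict[str, str] = {
    "Fp1": "Fp", "Fp2": "Fp",
    "F7": "F", "F3": "F", "Fz": "F", "F4": "F", "F8": "F",
    "T3": "C", "C3": "C", "Cz": "C", "C4": "C", "T4": "C",
    "T5": "P", "P3": "P", "P4": "P", "T6": "P",
    "O1": "O", "O2": "O",
}

TEMPORAL_CHANNELS: tuple[str, ...] = ("F7", "F8", "T3", "T4", "T5", "T6")

# Scalp neighborhood: lateral neighbors within each row plus the nearest
# electrode(s) in the adjacent rows.  Symmetric by construction.
ADJACENCY_EDGES: tuple[tuple[str, str], ...] = (
    ("Fp1", "Fp2"),
    ("Fp1", "F7"), ("Fp1", "F3"), ("Fp1", "Fz"),
    ("Fp2", "Fz"), ("Fp2", "F4"), ("Fp2", "F8"),
    ("F7", "F3"), ("F3", "Fz"), ("Fz", "F4"), ("F4", "F8"),
    ("F7", "T3"), ("F3", "C3"), ("Fz", "Cz"), ("F4", "C4"), ("F8", "T4"),
    ("T3", "C3"), ("C3", "Cz"), ("Cz", "C4"), ("C4", "T4"),
    ("T3", "T5"), ("C3", "P3"), ("Cz", "P3"), ("Cz", "P4"),
    ("C4", "P4"), ("T4", "T6"),
    ("T5", "P3"), ("P3", "P4"), ("P4", "T6"),
    ("T5", "O1"), ("P3", "O1"), ("P4", "O2"), ("T6", "O2"),
    ("O1", "O2"),
)

_CANONICAL = {name.lower(): name for name in CHANNELS_18}
_CANONICAL.update({"a1": "A1", "a2": "A2", "m1": "A1", "m2": "A2"})


def canonical_channel(name: str) -> str:
    """Normalize a channel label to the montage's canonical spelling.

    Matching is case-insensitive; mastoid aliases M1/M2 map to A1/A2.
    Unknown labels are returned stripped but otherwise unchanged.
    """
    return _CANONICAL.get(name.strip().lower(), name.strip())
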