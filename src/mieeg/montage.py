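"""Electrode montage constants for the 10-20 system.

The analysis montage is the 21-electrode subset commonly used for
full-scalp motor-imagery studies; two mastoid channels (M1/M2) are carried
for re-referencing.  Positions are schematic 2-D head coordinates (unit
circle at the ear line) used for spatial smoothing in the simulator and for
scalp-ordered map output.
"""

from __future__ import annotations

from itertools import combinations

#: The 21 scalp electrodes entering every analysis stage.
ANALYSIS_CHANNELS: tuple[str, ...] = (
    "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2", "F7", "F8",
    "Fz", "Cz", "Pz", "FC1", "FC2", "CP1", "CP2", "FC5", "FC6", "CP5", "CP6",
)

#: Mastoid reference channels (average of the two rebuilds the reference).
MASTOID_CHANNELS: tuple[str, ...] = ("M1", "M2")

#: Default simulation montage: analysis channels plus mastoids.
DEFAULT_MONTAGE: tuple[str, ...] = ANALYSIS_CHANNELS + MASTOID_CHANNELS

#: Reduced 13-electrode subset used for display-oriented maps.
DISPLAY_SUBSET_13: tuple[str, ...] = (
    "F7", "F3", "Fz", "F4", "F8", "C3", "Cz", "C4", "P3", "Pz", "P4",
    "O1", "O2",
)

#: Schematic (x, y) positions; x grows to the right, y to the front.
POSITIONS_2D: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.40, 0.52), "Fz": (0.0, 0.50),
    "F4": (0.40, 0.52), "F8": (0.81, 0.59),
    "FC5": (-0.65, 0.27), "FC1": (-0.20, 0.25), "FC2": (0.20, 0.25),
    "FC6": (0.65, 0.27),
    "T7": (-1.0, 0.0), "C3": (-0.50, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.50, 0.0), "T8": (1.0, 0.0),
    "CP5": (-0.65, -0.27), "CP1": (-0.20, -0.25), "CP2": (0.20, -0.25),
    "CP6": (0.65, -0.27),
    "P7": (-0.81, -0.59), "P3": (-0.40, -0.52), "Pz": (0.0, -0.50),
    "P4": (0.40, -0.52), "P8": (0.81, -0.59),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
    "M1": (-1.10, -0.25), "M2": (1.10, -0.25),
}


def channel_pairs(labels) -> list[tuple[str, str]]:
    """All unordered channel pairs in a fixed, documented order."""
    return list(combinations(labels, 2))


def directed_pairs(labels) -> list[tuple[str, str]]:
    """All ordered (source, target) pairs with source != target."""
    return [(a, b) for a in labels for b in labels if a != b]
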