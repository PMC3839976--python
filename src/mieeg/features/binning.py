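"""Frequency binning of raw spectra into twelve 2.44 Hz-wide bins.

All spectral feature vectors (power, coherence, directed connectivity,
Granger) are reduced from their raw frequency grid to 12 values per
channel or pair: bin centers at 1 + 2.44*j Hz for j = 0..11 (last center
27.84 Hz), edges at center +- 1.22 Hz, half-open on the right.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BIN_STEP_HZ = 2.44
N_BINS = 12


@dataclass(frozen=True)
class FrequencyBinning:
    """Centers and half-open edges of the 12 analysis bins."""

    centers: np.ndarray = field(
        default_factory=lambda: 1.0 + BIN_STEP_HZ * np.arange(N_BINS)
    )

    @property
    def n_bins(self) -> int:
        return len(self.centers)

    def edges(self) -> np.ndarray:
        """(n_bins, 2) array of [low, high) edges."""
        half = BIN_STEP_HZ / 2.0
        return np.stack([self.centers - half, self.centers + half], axis=1)

    def bin_average(self, freqs: np.ndarray, values: np.ndarray) -> np.ndarray:
        """Average ``values`` (..., n_freqs) within each bin -> (..., n_bins).

        Empty bins (possible on very coarse grids) yield NaN so degeneracy
        is visible rather than silently zero.
        """
        freqs = np.asarray(freqs)
        values = np.asarray(values)
        out = np.full(values.shape[:-1] + (self.n_bins,), np.nan)
        for j, (lo, hi) in enumerate(self.edges()):
            sel = (freqs >= lo) & (freqs < hi)
            if sel.any():
                out[..., j] = values[..., sel].mean(axis=-1)
        return out

    def bin_of(self, freq: float) -> int:
        """Index of the bin containing ``freq`` (-1 if outside all bins)."""
        for j, (lo, hi) in enumerate(self.edges()):
            if lo <= freq < hi:
                return j
        return -1


def default_binning() -> FrequencyBinning:
    return FrequencyBinning()
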