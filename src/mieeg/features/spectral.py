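"""Spectral features: binned FFT magnitude, Welch magnitude-squared
coherence, brainrate, and the Wackermann global descriptors."""

from __future__ import annotations

import numpy as np

from .binning import FrequencyBinning, default_binning

#: Zero-padded transform length for per-trial spectra (0.2441 Hz steps at
#: 250 Hz).
NFFT_POWER = 1024

#: Welch settings for per-trial coherence: 8 segments, 50% overlap,
#: Hamming window, 256-point transforms.
WELCH_SEGMENTS = 8
WELCH_OVERLAP = 0.5
NFFT_COHERENCE = 256

#: Classical EEG bands used by brainrate: [low, high) Hz and midpoints.
BRAINRATE_BANDS = ((1.0, 4.0), (4.0, 8.0), (8.0, 13.0), (13.0, 20.0),
                   (20.0, 30.0))
BRAINRATE_MIDPOINTS = (2.5, 6.0, 10.5, 16.5, 25.0)


def fft_binned_power(
    epoch: np.ndarray, rate: float, binning: FrequencyBinning | None = None
) -> np.ndarray:
    """Binned FFT magnitude spectrum, (channels, 12).

    Magnitude (not squared) of a zero-padded NFFT_POWER-point transform,
    averaged within each analysis bin.
    """
    binning = binning or default_binning()
    x = np.atleast_2d(np.asarray(epoch, dtype=np.float64))
    spec = np.abs(np.fft.rfft(x, n=NFFT_POWER, axis=1))
    freqs = np.fft.rfftfreq(NFFT_POWER, d=1.0 / rate)
    return binning.bin_average(freqs, spec)


def welch_csd_matrix(
    epoch: np.ndarray,
    rate: float,
    n_segments: int = WELCH_SEGMENTS,
    overlap: float = WELCH_OVERLAP,
    nfft: int = NFFT_COHERENCE,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Welch auto-/cross-spectral matrix of one epoch.

    Returns (freqs, S, n_segments_used) with S of shape
    (channels, channels, n_freqs); S is the average over Hamming-windowed
    half-overlapping segments of X_a(f) X_b(f)*.  Scaling constants cancel
    in every coherence ratio built from S.
    """
    x = np.atleast_2d(np.asarray(epoch, dtype=np.float64))
    n = x.shape[1]
    nperseg = int(np.floor(2 * n / (n_segments + 1)))
    nperseg = min(nperseg, n)
    step = nperseg - int(np.floor(nperseg * overlap))
    starts = list(range(0, n - nperseg + 1, step))
    window = np.hamming(nperseg)
    segs = np.stack([x[:, s:s + nperseg] * window for s in starts])
    fft = np.fft.rfft(segs, n=max(nfft, nperseg), axis=2)
    freqs = np.fft.rfftfreq(max(nfft, nperseg), d=1.0 / rate)
    s = np.einsum("taf,tbf->abf", fft, np.conj(fft)) / len(starts)
    return freqs, s, len(starts)


def msc_from_csd(s: np.ndarray) -> np.ndarray:
    """Magnitude-squared coherence (channels, channels, freqs) from a CSD."""
    auto = np.real(np.einsum("aaf->af", s))
    denom = auto[:, None, :] * auto[None, :, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        msc = np.abs(s) ** 2 / denom
    return np.clip(np.real(msc), 0.0, 1.0, out=np.real(msc))


def coherence_binned(
    epoch: np.ndarray, rate: float, binning: FrequencyBinning | None = None
) -> np.ndarray:
    """Binned magnitude-squared coherence for all unordered pairs.

    Welch estimate (8 segments, 50% overlap, Hamming) averaged within each
    analysis bin; output shape (n_pairs, 12) with pairs in upper-triangle
    order.  Pairs involving a zero-variance channel come out NaN.
    """
    binning = binning or default_binning()
    freqs, s, _ = welch_csd_matrix(epoch, rate)
    msc = msc_from_csd(s)
    iu = np.triu_indices(msc.shape[0], k=1)
    return binning.bin_average(freqs, msc[iu])


def brainrate(epoch: np.ndarray, rate: float) -> np.ndarray:
    """Spectral-centroid-like brainrate per channel.

    Weighted mean of the five classical band midpoints (delta..beta2) with
    weights equal to the relative spectral power in each band.  Constant
    channels return NaN (degenerate).
    """
    x = np.atleast_2d(np.asarray(epoch, dtype=np.float64))
    spec = np.abs(np.fft.rfft(x, n=NFFT_POWER, axis=1)) ** 2
    freqs = np.fft.rfftfreq(NFFT_POWER, d=1.0 / rate)
    band_power = np.stack([
        spec[:, (freqs >= lo) & (freqs < hi)].sum(axis=1)
        for lo, hi in BRAINRATE_BANDS
    ], axis=1)
    total = band_power.sum(axis=1)
    mid = np.array(BRAINRATE_MIDPOINTS)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (band_power * mid).sum(axis=1) / total
    out[total == 0] = np.nan
    return out


def wackermann(epoch: np.ndarray, rate: float) -> tuple[float, float, float]:
    """Wackermann global field descriptors (sigma, phi, omega).

    sigma: RMS over channels and time (global field strength, uV).
    phi: global frequency (Hz), (1/2pi) sqrt(m2/m0) with m0 the total
    power and m2 the first-difference derivative power (scaled by the
    sampling rate), both summed over channels.
    omega: spatial complexity, exp of the eigenvalue entropy of the
    channel covariance normalized to unit trace; 1 for rank-one data, up
    to K for K independent equal-variance channels.
    """
    x = np.atleast_2d(np.asarray(epoch, dtype=np.float64))
    m0 = float((x**2).sum())
    sigma = float(np.sqrt((x**2).mean()))
    if m0 == 0:
        return 0.0, np.nan, np.nan
    dx = np.diff(x, axis=1) * rate
    phi = float(np.sqrt((dx**2).mean() / (x**2).mean()) / (2.0 * np.pi))
    cov = (x @ x.T) / x.shape[1]
    eig = np.linalg.eigvalsh(cov)
    eig = np.clip(eig, 0.0, None)
    tr = eig.sum()
    if tr == 0:
        return sigma, phi, np.nan
    lam = eig / tr
    nz = lam > 0
    omega = float(np.exp(-(lam[nz] * np.log(lam[nz])).sum()))
    return sigma, phi, omega
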