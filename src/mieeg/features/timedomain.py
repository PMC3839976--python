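"""Time-domain per-channel descriptors: Hjorth parameters and the
rescaled-range Hurst exponent."""

from __future__ import annotations

import numpy as np

#: Smallest dyadic block length of the rescaled-range ladder.
HURST_MIN_BLOCK = 16


def hjorth(epoch: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hjorth activity, mobility and complexity per channel.

    activity = var(x); mobility = sqrt(var(dx)/var(x));
    complexity = mobility(dx)/mobility(x), with dx the first difference.
    Zero-variance channels yield activity 0 and NaN (flagged-undefined)
    mobility/complexity.
    """
    x = np.atleast_2d(np.asarray(epoch, dtype=np.float64))
    if x.shape[1] < 3:
        raise ValueError("hjorth needs >= 3 samples per channel")
    d1 = np.diff(x, axis=1)
    d2 = np.diff(d1, axis=1)
    v0 = x.var(axis=1)
    v1 = d1.var(axis=1)
    v2 = d2.var(axis=1)
    activity = v0
    with np.errstate(divide="ignore", invalid="ignore"):
        mobility = np.sqrt(v1 / v0)
        complexity = np.sqrt(v2 / v1) / mobility
    mobility[v0 == 0] = np.nan
    complexity[(v0 == 0) | (v1 == 0)] = np.nan
    return activity, mobility, complexity


def _rs_one_scale(x: np.ndarray, block: int) -> float:
    """Mean rescaled range over non-overlapping blocks of one length."""
    n = x.size
    n_blocks = n // block
    if n_blocks == 0:
        return np.nan
    blocks = x[: n_blocks * block].reshape(n_blocks, block)
    centered = blocks - blocks.mean(axis=1, keepdims=True)
    z = np.cumsum(centered, axis=1)
    r = z.max(axis=1) - z.min(axis=1)
    s = blocks.std(axis=1)
    ok = s > 0
    if not ok.any():
        return np.nan
    return float((r[ok] / s[ok]).mean())


def hurst_rs(epoch: np.ndarray) -> np.ndarray:
    """Rescaled-range (R/S) Hurst exponent per channel.

    Least-squares slope of log(R/S) against log(block length) over a
    dyadic ladder from HURST_MIN_BLOCK up to half the epoch length.  The
    estimator is biased upward at short epochs (white noise reads ~0.55
    rather than 0.5), which is inherent to R/S analysis.  Constant
    channels return NaN.
    """
    x = np.atleast_2d(np.asarray(epoch, dtype=np.float64))
    n = x.shape[1]
    if n < 4 * HURST_MIN_BLOCK:
        raise ValueError("hurst_rs needs >= 64 samples")
    scales = []
    block = HURST_MIN_BLOCK
    while block <= n // 2:
        scales.append(block)
        block *= 2
    out = np.empty(x.shape[0])
    log_n = np.log(scales)
    for ch in range(x.shape[0]):
        if x[ch].std() == 0:
            out[ch] = np.nan
            continue
        rs = np.array([_rs_one_scale(x[ch], b) for b in scales])
        ok = np.isfinite(rs) & (rs > 0)
        if ok.sum() < 2:
            out[ch] = np.nan
            continue
        out[ch] = np.polyfit(log_n[ok], np.log(rs[ok]), 1)[0]
    return out
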