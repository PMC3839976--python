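"""Entropy and divergence estimators applied per channel.

Approximate entropy (Pincus), Vasicek m-spacing Shannon/Renyi entropy,
Leonenko-type k-nearest-neighbor Tsallis entropy, a kNN plug-in
Bhattacharyya distance between two samples, and Gaussian-kernel
correntropy of lag-1 sample pairs.
"""

from __future__ import annotations

import logging

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import cdist
from scipy.special import gammaln

logger = logging.getLogger(__name__)

APEN_M = 2
APEN_R_FACTOR = 0.2
RENYI_ALPHA = 2.0
TSALLIS_Q = 1.5
KNN_K = 3
#: Larger neighborhood for the Bhattacharyya density-ratio plug-in, which
#: is noticeably biased at small k.
BHATT_K = 10

_JITTER_SCALE = 1e-10


def approximate_entropy(
    epoch: np.ndarray, m: int = APEN_M, r_factor: float = APEN_R_FACTOR
) -> np.ndarray:
    """Pincus approximate entropy ApEn(m, r) per channel, r = r_factor*SD.

    Self-matches are included (the classical definition).  Constant
    channels return 0 (defined, but degenerate: every template matches).
    """
    x = np.atleast_2d(np.asarray(epoch, dtype=np.float64))
    n = x.shape[1]
    if n < 50:
        raise ValueError("approximate_entropy needs >= 50 samples")
    out = np.empty(x.shape[0])
    for ch in range(x.shape[0]):
        sd = x[ch].std()
        if sd == 0:
            out[ch] = 0.0
            continue
        r = r_factor * sd
        out[ch] = _phi(x[ch], m, r) - _phi(x[ch], m + 1, r)
    return out


def _phi(x: np.ndarray, m: int, r: float) -> float:
    emb = sliding_window_view(x, m)
    d = cdist(emb, emb, metric="chebyshev")
    c = (d <= r).mean(axis=1)
    return float(np.log(c).mean())


def _sorted_with_jitter(x: np.ndarray, context: str) -> np.ndarray:
    """Sorted copy; exact ties are broken by a tiny deterministic jitter."""
    xs = np.sort(x)
    if np.any(np.diff(xs) == 0):
        scale = max(xs.std(), 1.0) * _JITTER_SCALE
        jit = np.random.default_rng(0).uniform(-scale, scale, size=xs.size)
        logger.info("%s: tied samples, jitter of scale %.3g applied",
                    context, scale)
        xs = np.sort(x + jit)
    return xs


def spacing_entropy(
    epoch: np.ndarray, kind: str = "shannon", alpha: float = RENYI_ALPHA
) -> np.ndarray:
    """Vasicek-type m-spacing entropy per channel (nats), m = floor(sqrt(n)).

    The Shannon variant is the classical Vasicek estimator built on the
    approximate slope of the inverse distribution function; the Renyi
    variant generalizes the same spacings to order ``alpha``.  Spacings
    are clamped at the sample extremes; estimates are invariant to
    location shifts.
    """
    if kind not in ("shannon", "renyi"):
        raise ValueError(f"kind must be 'shannon' or 'renyi', got {kind!r}")
    if kind == "renyi" and alpha == 1.0:
        raise ValueError("renyi spacing entropy needs alpha != 1")
    x = np.atleast_2d(np.asarray(epoch, dtype=np.float64))
    n = x.shape[1]
    if n < 100:
        raise ValueError("spacing_entropy needs >= 100 samples")
    m = int(np.floor(np.sqrt(n)))
    out = np.empty(x.shape[0])
    for ch in range(x.shape[0]):
        if x[ch].std() == 0:
            out[ch] = np.nan
            continue
        xs = _sorted_with_jitter(x[ch], f"spacing_entropy[{kind}]")
        upper = xs[np.minimum(np.arange(n) + m, n - 1)]
        lower = xs[np.maximum(np.arange(n) - m, 0)]
        slope = (n / (2.0 * m)) * (upper - lower)
        slope = np.clip(slope, 1e-300, None)
        if kind == "shannon":
            out[ch] = float(np.log(slope).mean())
        else:
            out[ch] = float(
                np.log((slope ** (1.0 - alpha)).mean()) / (1.0 - alpha)
            )
    return out


def _knn_distances(a: np.ndarray, b: np.ndarray, k: int,
                   exclude_self: bool) -> np.ndarray:
    """Distance from each point of ``a`` to its k-th nearest point of ``b``."""
    d = np.abs(a[:, None] - b[None, :])
    if exclude_self:
        np.fill_diagonal(d, np.inf)
    return np.partition(d, k - 1, axis=1)[:, k - 1]


def knn_entropy_tsallis(
    epoch: np.ndarray, q: float = TSALLIS_Q, k: int = KNN_K
) -> np.ndarray:
    """Leonenko-type kNN Tsallis entropy of order ``q`` per channel."""
    if q == 1.0:
        raise ValueError("tsallis entropy of order 1 is the shannon limit")
    if k + 1 - q <= 0:
        raise ValueError(f"need k + 1 - q > 0, got k={k}, q={q}")
    x = np.atleast_2d(np.asarray(epoch, dtype=np.float64))
    n = x.shape[1]
    if n < 100:
        raise ValueError("knn_entropy_tsallis needs >= 100 samples")
    log_ck = (gammaln(k) - gammaln(k + 1 - q)) / (1.0 - q)
    out = np.empty(x.shape[0])
    for ch in range(x.shape[0]):
        if x[ch].std() == 0:
            out[ch] = np.nan
            continue
        xs = _sorted_with_jitter(x[ch], "knn_entropy_tsallis")
        rho = _knn_distances(xs, xs, k, exclude_self=True)
        rho = np.clip(rho, 1e-300, None)
        # I_hat = mean of [(n-1) C_k V_d rho^d]^(1-q), d = 1, V_1 = 2
        log_term = (1.0 - q) * (
            np.log(n - 1) + log_ck + np.log(2.0 * rho)
        )
        i_hat = float(np.exp(log_term).mean())
        out[ch] = (1.0 - i_hat) / (q - 1.0)
    return out


def bhattacharyya_knn(
    sample_a: np.ndarray, sample_b: np.ndarray, k: int = BHATT_K
) -> float:
    """Symmetrized kNN plug-in Bhattacharyya distance of two 1-D samples.

    The Bhattacharyya coefficient integral(sqrt(p q)) is estimated from
    both directions (E_p sqrt(q/p) and E_q sqrt(p/q)) with kNN density
    estimates and averaged, making the result exactly symmetric in its
    arguments; the distance is -log of the coefficient, clipped at 0.
    """
    a = np.asarray(sample_a, dtype=np.float64).ravel()
    b = np.asarray(sample_b, dtype=np.float64).ravel()
    if a.size < 100 or b.size < 100:
        raise ValueError("bhattacharyya_knn needs >= 100 points per sample")
    bc = (_bc_one_direction(a, b, k) + _bc_one_direction(b, a, k)) / 2.0
    return float(max(-np.log(max(bc, 1e-300)), 0.0))


def _bc_one_direction(a: np.ndarray, b: np.ndarray, k: int) -> float:
    """E_a[sqrt(q_b / p_a)] with kNN density estimates."""
    rho_a = np.clip(_knn_distances(a, a, k, exclude_self=True), 1e-300, None)
    rho_b = np.clip(_knn_distances(a, b, k, exclude_self=False), 1e-300, None)
    p_hat = k / ((a.size - 1) * 2.0 * rho_a)
    q_hat = k / (b.size * 2.0 * rho_b)
    return float(np.sqrt(q_hat / p_hat).mean())


def bhattacharyya_split_halves(epoch: np.ndarray, k: int = BHATT_K) -> np.ndarray:
    """Bhattacharyya distance between the two halves of each channel."""
    x = np.atleast_2d(np.asarray(epoch, dtype=np.float64))
    half = x.shape[1] // 2
    out = np.empty(x.shape[0])
    for ch in range(x.shape[0]):
        if x[ch].std() == 0:
            out[ch] = np.nan
            continue
        out[ch] = bhattacharyya_knn(x[ch, :half], x[ch, half:2 * half], k=k)
    return out


def correntropy_kde(
    epoch: np.ndarray, kernel_width: float | None = None
) -> np.ndarray:
    """Gaussian-kernel correntropy of lag-1 pairs (x_t, x_{t+1}) per channel.

    V = mean of exp(-(x_t - x_{t+1})^2 / (2 sigma^2)); the kernel maximum
    is 1, so a constant channel returns exactly 1.  With
    ``kernel_width=None`` the width follows Silverman's rule on the lag-1
    differences.  The value is invariant to adding a constant.
    """
    x = np.atleast_2d(np.asarray(epoch, dtype=np.float64))
    if x.shape[1] < 100:
        raise ValueError("correntropy_kde needs >= 100 samples")
    out = np.empty(x.shape[0])
    for ch in range(x.shape[0]):
        d = np.diff(x[ch])
        if kernel_width is None:
            sd = d.std()
            if sd == 0:
                out[ch] = 1.0
                continue
            sigma = 1.06 * sd * d.size ** (-1.0 / 5.0)
        else:
            sigma = kernel_width
        out[ch] = float(np.exp(-(d**2) / (2.0 * sigma**2)).mean())
    return out
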