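"""Per-trial feature extraction: the 20-name registry and dispatcher.

Each feature maps a TrialSet to a trials x d matrix with per-dimension
labels.  For the 21-channel analysis montage the dimensions are:
per-channel scalars (d=21) for the Hjorth parameters, brainrate, Hurst,
and the entropy features; global scalars (d=1) for the three Wackermann
descriptors; 21x12=252 for binned FFT power and the pairwise-Granger
power spectra; 210x12=2520 for coherence; 420x12=5040 for the directed
measures (Granger GW, PDC, DTF).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..preprocess import TrialSet
from .binning import FrequencyBinning, default_binning
from . import connectivity, entropy, spectral, timedomain

FEATURE_NAMES: tuple[str, ...] = (
    "hjorth_activity", "hjorth_mobility", "hjorth_complexity",
    "brainrate",
    "wackermann_sigma", "wackermann_phi", "wackermann_omega",
    "hurst",
    "fft", "coherence",
    "granger_gw", "granger_pp", "pdc", "dtf",
    "apen", "shannon_spacing", "renyi_spacing", "tsallis_knn",
    "bhattacharyya_knn", "correntropy",
)


class RegistryError(KeyError):
    """Unknown feature name."""


@dataclass
class FeatureMatrix:
    """Per-trial feature vectors for one subject and one feature.

    ``degenerate_flag`` is set when all rows are identical or any value is
    non-finite; such matrices are excluded from classification (this
    mirrors real failure modes, e.g. a quantized brainrate collapsing to
    a single value on every trial).
    """

    values: np.ndarray
    feature_name: str
    dim_labels: list[str]
    conditions: list[str]
    subject_id: str = "S00"
    group_tag: str = "responsive"
    degenerate_flag: bool = field(default=False)
    degenerate_reason: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be trials x dimensions")
        if self.values.shape[0] != len(self.conditions):
            raise ValueError("row count must equal trial count")
        if self.values.shape[1] != len(self.dim_labels):
            raise ValueError("dim_labels must match feature dimension")
        if not self.degenerate_flag:
            if not np.isfinite(self.values).all():
                self.degenerate_flag = True
                self.degenerate_reason = "non-finite values"
            elif self.values.shape[0] > 1 and np.all(
                self.values == self.values[0]
            ):
                self.degenerate_flag = True
                self.degenerate_reason = "all trial rows identical"

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    def labels_array(self) -> np.ndarray:
        return np.array(self.conditions)


def feature_dimension(feature_name: str, n_channels: int) -> int:
    """Expected dimensionality of a feature for a given channel count."""
    k = n_channels
    n_pairs = k * (k - 1) // 2
    n_directed = k * (k - 1)
    n_bins = default_binning().n_bins
    table = {
        "hjorth_activity": k, "hjorth_mobility": k, "hjorth_complexity": k,
        "brainrate": k,
        "wackermann_sigma": 1, "wackermann_phi": 1, "wackermann_omega": 1,
        "hurst": k,
        "fft": k * n_bins,
        "coherence": n_pairs * n_bins,
        "granger_gw": n_directed * n_bins,
        "granger_pp": k * n_bins,
        "pdc": n_directed * n_bins,
        "dtf": n_directed * n_bins,
        "apen": k, "shannon_spacing": k, "renyi_spacing": k,
        "tsallis_knn": k, "bhattacharyya_knn": k, "correntropy": k,
    }
    if feature_name not in table:
        raise RegistryError(f"unknown feature: {feature_name!r}")
    return table[feature_name]


def _channel_labels(trials: TrialSet) -> list[str]:
    return list(trials.channel_labels)


def _binned_labels(units: list[str], binning: FrequencyBinning) -> list[str]:
    return [f"{u}@{c:.2f}Hz" for u in units for c in binning.centers]


def _pair_names(labels: list[str]) -> list[str]:
    return [f"{a}-{b}" for i, a in enumerate(labels)
            for b in labels[i + 1:]]


def _directed_names(labels: list[str]) -> list[str]:
    return [f"{a}->{b}" for a in labels for b in labels if a != b]


def extract_feature_matrix(
    trials: TrialSet,
    feature_name: str,
    binning: FrequencyBinning | None = None,
) -> FeatureMatrix:
    """Compute one feature for every retained trial of a subject."""
    if feature_name not in FEATURE_NAMES:
        raise RegistryError(f"unknown feature: {feature_name!r}")
    binning = binning or default_binning()
    rate = trials.rate
    chans = _channel_labels(trials)
    rows: list[np.ndarray] = []
    for epoch in trials.epochs:
        rows.append(_one_trial(epoch, feature_name, rate, binning))
    values = (
        np.stack(rows) if rows
        else np.empty((0, feature_dimension(feature_name, len(chans))))
    )
    dim_labels = _dim_labels(feature_name, chans, binning)
    return FeatureMatrix(
        values=values, feature_name=feature_name, dim_labels=dim_labels,
        conditions=list(trials.conditions), subject_id=trials.subject_id,
        group_tag=trials.group_tag,
    )


def _one_trial(
    epoch: np.ndarray, name: str, rate: float, binning: FrequencyBinning
) -> np.ndarray:
    if name == "hjorth_activity":
        return timedomain.hjorth(epoch)[0]
    if name == "hjorth_mobility":
        return timedomain.hjorth(epoch)[1]
    if name == "hjorth_complexity":
        return timedomain.hjorth(epoch)[2]
    if name == "brainrate":
        return spectral.brainrate(epoch, rate)
    if name.startswith("wackermann"):
        sigma, phi, omega = spectral.wackermann(epoch, rate)
        return np.array([{
            "wackermann_sigma": sigma,
            "wackermann_phi": phi,
            "wackermann_omega": omega,
        }[name]])
    if name == "hurst":
        return timedomain.hurst_rs(epoch)
    if name == "fft":
        return spectral.fft_binned_power(epoch, rate, binning).ravel()
    if name == "coherence":
        return spectral.coherence_binned(epoch, rate, binning).ravel()
    if name in ("granger_gw", "granger_pp"):
        gw, pp = connectivity.granger_spectral(epoch, rate, binning)
        return (gw if name == "granger_gw" else pp).ravel()
    if name in ("pdc", "dtf"):
        model = connectivity.fit_mvar(epoch, rate)
        return connectivity.directed_spectral(model, binning, name).ravel()
    if name == "apen":
        return entropy.approximate_entropy(epoch)
    if name == "shannon_spacing":
        return entropy.spacing_entropy(epoch, "shannon")
    if name == "renyi_spacing":
        return entropy.spacing_entropy(epoch, "renyi")
    if name == "tsallis_knn":
        return entropy.knn_entropy_tsallis(epoch)
    if name == "bhattacharyya_knn":
        return entropy.bhattacharyya_split_halves(epoch)
    if name == "correntropy":
        return entropy.correntropy_kde(epoch)
    raise RegistryError(f"unknown feature: {name!r}")


def _dim_labels(
    name: str, chans: list[str], binning: FrequencyBinning
) -> list[str]:
    if name in ("wackermann_sigma", "wackermann_phi", "wackermann_omega"):
        return [name]
    if name in ("fft", "granger_pp"):
        return _binned_labels(chans, binning)
    if name == "coherence":
        return _binned_labels(_pair_names(chans), binning)
    if name in ("granger_gw", "pdc", "dtf"):
        return _binned_labels(_directed_names(chans), binning)
    return list(chans)
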