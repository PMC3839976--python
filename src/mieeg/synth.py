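"""Synthetic motor-imagery EEG cohorts.

Generates continuous multichannel recordings with the statistical structure
the downstream analysis assumes: 1/f^beta background noise, a spatially
smoothed common component (so baseline inter-channel coherence is neither 0
nor 1), an 8-13 Hz mu rhythm over central channels whose power drops during
imagery (event-related desynchronization, ERD), and an optional
imagery-locked increase of frontal coherence.  Null subjects (no ERD, no
coupling) are produced by an exactly condition-exchangeable process.
Artifact injection (voltage steps, flat stretches) exercises the automatic
rejection rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import signal

from .montage import DEFAULT_MONTAGE, POSITIONS_2D

CONDITIONS = ("imagery", "rest")

#: Timing of the simulated protocol (seconds).  One trial = verbal
#: instruction followed by a 5 s response window; the epoch used for
#: analysis is the first 4 s of the response window.
INSTRUCTION_SECONDS = 6.5
RESPONSE_SECONDS = 5.0
PRE_ROLL_SECONDS = 2.0
POST_ROLL_SECONDS = 2.0

#: Background per-channel RMS in microvolts.
BACKGROUND_RMS_UV = 10.0
#: RMS of the spatially smoothed common component relative to background.
COMMON_RMS_FRACTION = 0.6
#: Spatial kernel width (schematic head units) of the common component.
COMMON_KERNEL_WIDTH = 0.45
#: Common-component source locations (schematic coordinates).
COMMON_SOURCE_XY = ((0.0, 0.5), (0.0, 0.0), (0.0, -0.5), (0.0, -0.95))

#: SD of the per-subject ERD-depth jitter applied by ``generate_cohort``.
ERD_JITTER_SD = 0.10

#: Frequency band of the imagery-locked frontal coupling.  Executive
#: task-related fronto-frontal synchronization is broad-band (theta to
#: beta), unlike the narrow sensorimotor mu rhythm carrying the ERD.
COUPLING_BAND = (4.0, 24.0)


class MontageError(ValueError):
    """A channel named in an EffectSpec is absent from the montage."""


@dataclass(frozen=True)
class EffectSpec:
    """Parameters of the simulated imagery effect.

    ``erd_depth`` is the fraction by which mu power is reduced during
    imagery on ``erd_channels``; ``coh_gain`` is the approximate
    magnitude-squared coherence added within ``mu_band`` on ``coh_pairs``
    during imagery.  ``snr`` is the ratio of mu-rhythm RMS to background
    RMS on the ERD channels.
    """

    mu_band: tuple[float, float] = (8.0, 13.0)
    erd_depth: float = 0.4
    erd_channels: tuple[str, ...] = ("C3", "C4", "CP1", "CP2")
    coh_gain: float = 0.3
    coh_pairs: tuple[tuple[str, str], ...] = (
        ("F3", "F4"), ("F3", "Fz"), ("F3", "F7"), ("F3", "F8"),
        ("F4", "Fz"), ("F4", "F7"), ("F4", "F8"),
        ("Fz", "F7"), ("Fz", "F8"), ("F7", "F8"),
    )
    noise_exponent: float = 1.0
    snr: float = 0.75
    rate: float = 250.0
    n_trials_per_condition: int = 24
    #: SD (log scale) of the slow multiplicative per-channel amplitude
    #: drift.  Real EEG power wanders over tens of seconds; this degrades
    #: absolute-power features while leaving normalized coherence intact.
    amplitude_drift_sd: float = 0.15

    def __post_init__(self) -> None:
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError(f"erd_depth must be in [0, 1], got {self.erd_depth}")
        if not 0.0 <= self.coh_gain < 1.0:
            raise ValueError(f"coh_gain must be in [0, 1), got {self.coh_gain}")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.noise_exponent < 0:
            raise ValueError("noise_exponent must be >= 0")
        if self.n_trials_per_condition < 0:
            raise ValueError("n_trials_per_condition must be >= 0")

    def validate_montage(self, montage: Sequence[str]) -> None:
        present = set(montage)
        missing = [ch for ch in self.erd_channels if ch not in present]
        missing += [ch for pair in self.coh_pairs for ch in pair if ch not in present]
        if missing:
            raise MontageError(f"channels not in montage: {sorted(set(missing))}")


@dataclass
class Recording:
    """A continuous multichannel recording with condition event markers.

    ``samples`` is channels x time in microvolts; ``events`` holds
    (sample_index, condition) pairs with strictly increasing indices.
    """

    samples: np.ndarray
    rate: float
    channel_labels: list[str]
    events: list[tuple[int, str]]
    subject_id: str = "S00"
    group_tag: str = "responsive"
    components: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be channels x time")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("channel_labels must match samples rows")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel_labels must be unique")
        idx = [s for s, _ in self.events]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("event sample indices must be strictly increasing")
        if idx and (idx[0] < 0 or idx[-1] >= self.samples.shape[1]):
            raise ValueError("event sample indices must lie inside the signal")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def channel_index(self, label: str) -> int:
        return self.channel_labels.index(label)

    def copy(self) -> "Recording":
        return Recording(
            samples=self.samples.copy(),
            rate=self.rate,
            channel_labels=list(self.channel_labels),
            events=list(self.events),
            subject_id=self.subject_id,
            group_tag=self.group_tag,
        )


def one_over_f_noise(
    rng: np.random.Generator, beta: float, n_samples: int, n_series: int,
    rate: float, knee_hz: float = 1.0,
) -> np.ndarray:
    """Gaussian noise with a 1/f^beta power spectrum, unit sample SD per row.

    The spectrum flattens below ``knee_hz``: EEG acquisition high-passes
    the signal, and an unbounded 1/f divergence at DC would let a handful
    of random very-low-frequency components dominate each row's variance
    (making the unit normalization erratic across channels).  Above
    ``rolloff_hz`` a second-order roll-off is applied: scalp EEG has
    little broadband power in the gamma range, and without the roll-off
    the sample-to-sample differences of the synthetic signal would be
    dominated by near-Nyquist hiss no real recording shows.
    """
    rolloff_hz = 40.0
    n_freq = n_samples // 2 + 1
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / rate)
    scale = np.maximum(freqs, knee_hz) ** (-beta / 2.0)
    scale = scale / np.sqrt(1.0 + (freqs / rolloff_hz) ** 4)
    scale[0] = 0.0
    spec = (
        rng.standard_normal((n_series, n_freq))
        + 1j * rng.standard_normal((n_series, n_freq))
    ) * scale
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _bandpass_noise(
    rng: np.random.Generator, band: tuple[float, float], n_samples: int,
    n_series: int, rate: float,
) -> np.ndarray:
    """Band-limited Gaussian noise, unit sample SD per row."""
    sos = signal.butter(4, band, btype="bandpass", fs=rate, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal((n_series, n_samples)), axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _common_mixing(montage: Sequence[str]) -> np.ndarray:
    """Spatial mixing matrix (channels x sources) of the common component."""
    pos = np.array([POSITIONS_2D.get(ch, (0.0, 0.0)) for ch in montage])
    src = np.array(COMMON_SOURCE_XY)
    d2 = ((pos[:, None, :] - src[None, :, :]) ** 2).sum(axis=2)
    a = np.exp(-d2 / (2.0 * COMMON_KERNEL_WIDTH**2))
    norm = np.sqrt((a**2).sum(axis=1, keepdims=True))
    norm[norm == 0] = 1.0
    return a / norm


def _event_schedule(
    spec: EffectSpec, rng: np.random.Generator
) -> tuple[list[tuple[int, str]], int]:
    """Pseudo-randomly interleaved events and total sample count."""
    n = spec.n_trials_per_condition
    labels = np.array(["imagery"] * n + ["rest"] * n)
    labels = labels[rng.permutation(labels.size)]
    rate = spec.rate
    spacing = INSTRUCTION_SECONDS + RESPONSE_SECONDS
    events: list[tuple[int, str]] = []
    for i, lab in enumerate(labels):
        onset = PRE_ROLL_SECONDS + i * spacing + INSTRUCTION_SECONDS
        events.append((int(round(onset * rate)), str(lab)))
    total = int(round(
        (PRE_ROLL_SECONDS + labels.size * spacing + POST_ROLL_SECONDS) * rate
    ))
    return events, total


def _window_mask(
    events: Iterable[tuple[int, str]], condition: str, n_samples: int, rate: float
) -> np.ndarray:
    """Boolean mask of the response windows of one condition."""
    mask = np.zeros(n_samples, dtype=bool)
    w = int(round(RESPONSE_SECONDS * rate))
    for s, cond in events:
        if cond == condition:
            mask[s:min(s + w, n_samples)] = True
    return mask


#: Correlation time (seconds) of the amplitude drift.  Kept well below
#: the 11.5 s inter-trial interval (Gaussian-kernel autocorrelation
#: exp(-dt^2/(4 sigma^2)) ~ 0.005 between adjacent trials) so per-trial
#: features stay exchangeable under the null — the independence the
#: chance-level z-test assumes — while still adding burst-like
#: trial-to-trial power variability.
DRIFT_TIMESCALE_S = 2.5


def _amplitude_drift(
    rng: np.random.Generator, sd: float, n_ch: int, n_samples: int,
    rate: float,
) -> np.ndarray:
    """Slow log-normal per-channel gain, mean ~1, log-SD ``sd``.

    Drawn at 1 Hz, Gaussian-smoothed over DRIFT_TIMESCALE_S, unit-
    normalized and linearly interpolated to the sampling grid; the drift
    is condition-independent, so it cannot break null exchangeability.
    """
    from scipy.ndimage import gaussian_filter1d

    n_sec = int(np.ceil(n_samples / rate)) + 2
    z = gaussian_filter1d(
        rng.standard_normal((n_ch, n_sec)), sigma=DRIFT_TIMESCALE_S,
        axis=1, mode="reflect",
    )
    # normalize by the theoretical SD of Gaussian-smoothed white noise
    # (sum of squared kernel weights); the realized per-row SD has too few
    # effective dof here to be a stable normalizer
    z = z * np.sqrt(2.0 * np.sqrt(np.pi) * DRIFT_TIMESCALE_S)
    z = np.clip(z, -2.0, 2.0)  # saturate: drift, not runaway gain
    t_coarse = np.arange(n_sec) * rate
    t_fine = np.arange(n_samples)
    gain = np.empty((n_ch, n_samples))
    for ch in range(n_ch):
        gain[ch] = np.interp(t_fine, t_coarse, z[ch])
    return np.exp(sd * gain - 0.5 * sd * sd)


def _baseline_band_msc(
    x: np.ndarray, band: tuple[float, float], rate: float
) -> float:
    """Mean in-band magnitude-squared coherence over all channel pairs."""
    f, spec = signal.welch(x, fs=rate, nperseg=1024, return_onesided=True)
    sel = (f >= band[0]) & (f < band[1])
    vals = []
    for i in range(x.shape[0]):
        for j in range(i + 1, x.shape[0]):
            f, cxy = signal.csd(x[i], x[j], fs=rate, nperseg=1024)
            msc = np.abs(cxy[sel]) ** 2 / (spec[i, sel] * spec[j, sel])
            vals.append(msc.mean())
    return float(np.mean(vals))


def _band_power(x: np.ndarray, band: tuple[float, float], rate: float) -> float:
    """Power of a 1-D signal within ``band`` from a periodogram."""
    f, p = signal.periodogram(x, fs=rate)
    sel = (f >= band[0]) & (f < band[1])
    return float(p[sel].sum() * (f[1] - f[0]))


def generate_subject(
    spec: EffectSpec,
    montage: Sequence[str] = DEFAULT_MONTAGE,
    seed: int = 0,
    subject_id: str = "S00",
    group_tag: str | None = None,
    keep_components: bool = False,
) -> Recording:
    """Generate one continuous synthetic recording.

    The recording contains ``spec.n_trials_per_condition`` pseudo-randomly
    interleaved events per condition, each followed by a 5 s response
    window.  During imagery windows the mu component on ``erd_channels`` is
    scaled by sqrt(1 - erd_depth) (power ratio 1 - erd_depth) and a shared
    band-limited source is added to both channels of each ``coh_pair``,
    calibrated so the in-band coherence gain is approximately ``coh_gain``.
    With ``erd_depth = 0`` and ``coh_gain = 0`` the two conditions are
    generated by an identical process.
    """
    if len(montage) < 21:
        raise MontageError(f"montage must have >= 21 channels, got {len(montage)}")
    spec.validate_montage(montage)
    rng = np.random.default_rng(seed)
    events, n_total = _event_schedule(spec, rng)
    n_ch = len(montage)
    rate = spec.rate

    background = one_over_f_noise(rng, spec.noise_exponent, n_total, n_ch, rate)
    background *= BACKGROUND_RMS_UV

    mixing = _common_mixing(montage)
    sources = one_over_f_noise(
        rng, spec.noise_exponent, n_total, mixing.shape[1], rate
    )
    common = (mixing @ sources) * (COMMON_RMS_FRACTION * BACKGROUND_RMS_UV)

    x = background + common

    imagery_mask = _window_mask(events, "imagery", n_total, rate)
    erd_gain = np.ones(n_total)
    erd_gain[imagery_mask] = np.sqrt(1.0 - spec.erd_depth)

    mu = np.zeros_like(x)
    if spec.snr > 0 and spec.erd_channels:
        mu_raw = _bandpass_noise(
            rng, spec.mu_band, n_total, len(spec.erd_channels), rate
        ) * (spec.snr * BACKGROUND_RMS_UV)
        for row, ch in enumerate(spec.erd_channels):
            mu[list(montage).index(ch)] = mu_raw[row] * erd_gain
    x = x + mu

    coupling = np.zeros_like(x)
    if spec.coh_gain > 0 and spec.coh_pairs:
        # Power-preserving synchronization: during imagery each coupled
        # channel's in-band content is cross-faded toward one shared
        # band-limited source, in-band power staying (in expectation)
        # unchanged.  A single shared source is essential — independent
        # per-pair sources inflate auto-power faster than cross-power and
        # *lower* the coherence — and power preservation keeps the
        # coupling invisible to single-channel power features, as
        # synchronization (not activation) of frontal cortex would be.
        # With cross-fade weight lam the in-band correlation becomes
        # lam + (1 - lam) r0 (r0 = sqrt of the baseline coherence c0), so
        # lam is solved from sqrt(c0 + coh_gain) = lam + (1 - lam) r0.
        coupled = sorted(
            {ch for pair in spec.coh_pairs for ch in pair},
            key=list(montage).index,
        )
        rows = [list(montage).index(ch) for ch in coupled]
        shared = _bandpass_noise(rng, COUPLING_BAND, n_total, 1, rate)[0]
        c0 = _baseline_band_msc(x[rows], COUPLING_BAND, rate)
        r0 = np.sqrt(c0)
        rt = np.sqrt(min(c0 + spec.coh_gain, 0.95))
        lam = float(np.clip((rt - r0) / max(1.0 - r0, 1e-6), 0.0, 0.95))
        sos_band = signal.butter(4, COUPLING_BAND, btype="bandpass",
                                 fs=rate, output="sos")
        for r in rows:
            in_band = signal.sosfiltfilt(sos_band, x[r])
            s_scaled = shared * in_band.std()
            delta = ((np.sqrt(1.0 - lam) - 1.0) * in_band
                     + np.sqrt(lam) * s_scaled)
            coupling[r] = delta * imagery_mask
    x = x + coupling

    gain = np.ones((1, 1))
    if spec.amplitude_drift_sd > 0:
        gain = _amplitude_drift(rng, spec.amplitude_drift_sd, n_ch, n_total,
                                rate)
        x = x * gain

    if group_tag is None:
        group_tag = "null" if spec.erd_depth == 0 and spec.coh_gain == 0 else "responsive"
    components = None
    if keep_components:
        # components are stored pre-drift so the injected condition
        # modulation stays directly measurable; the drift gain is stored
        # alongside (samples = gain * sum of signal components)
        components = {
            "background": background, "common": common, "mu": mu,
            "coupling": coupling, "erd_gain": erd_gain,
            "imagery_mask": imagery_mask, "drift_gain": gain,
        }
    return Recording(
        samples=x, rate=rate, channel_labels=list(montage), events=events,
        subject_id=subject_id, group_tag=group_tag, components=components,
    )


def generate_cohort(
    n_responsive: int,
    n_null: int,
    spec: EffectSpec,
    seed: int = 0,
    montage: Sequence[str] = DEFAULT_MONTAGE,
) -> list[Recording]:
    """Generate a cohort of responsive and null subjects.

    Responsive subjects carry the stated effect with per-subject ERD-depth
    jitter (truncated normal, SD ``ERD_JITTER_SD``, clipped to [0, 1]);
    null subjects have ``erd_depth = 0`` and ``coh_gain = 0``.  Subject
    seeds derive deterministically from the cohort seed, so permuting the
    order of generation cannot change any subject's data.
    """
    if n_responsive < 0 or n_null < 0:
        raise ValueError("cohort counts must be >= 0")
    recordings: list[Recording] = []
    for i in range(n_responsive + n_null):
        ss = np.random.SeedSequence([int(seed), i])
        jitter_seed, signal_seed = ss.spawn(2)
        if i < n_responsive:
            jit = np.random.default_rng(jitter_seed).normal(0.0, ERD_JITTER_SD)
            depth = float(np.clip(spec.erd_depth + jit, 0.0, 1.0))
            sub_spec = replace(spec, erd_depth=depth)
            tag = "responsive"
            sid = f"HC{i + 1:02d}"
        else:
            sub_spec = replace(spec, erd_depth=0.0, coh_gain=0.0)
            tag = "null"
            sid = f"NULL{i - n_responsive + 1:02d}"
        recordings.append(
            generate_subject(
                sub_spec, montage=montage,
                seed=int(signal_seed.generate_state(1)[0] % (2**31)),
                subject_id=sid, group_tag=tag,
            )
        )
    return recordings


def inject_artifacts(
    rec: Recording,
    artifacts: Sequence[tuple[int, str, float, float]],
    seed: int = 0,
    channels: Sequence[str] | None = None,
) -> Recording:
    """Inject voltage-step or flat-line artifacts into a copy of ``rec``.

    Each artifact is (sample_index, kind, magnitude_uV, duration_seconds).
    ``step`` adds an instantaneous offset over the window; ``flat``
    replaces the window with near-constant signal (range < 0.1 uV).
    By default artifacts hit every non-mastoid channel: an artifact
    common to the reference channels too would be cancelled exactly by
    mastoid re-referencing and could never be detected downstream.
    """
    out = rec.copy()
    rng = np.random.default_rng(seed)
    n = out.n_samples
    from .montage import MASTOID_CHANNELS

    if channels is None:
        channels = [ch for ch in rec.channel_labels
                    if ch not in MASTOID_CHANNELS]
    rows = [rec.channel_labels.index(ch) for ch in channels]
    for start, kind, magnitude, duration in artifacts:
        length = int(round(duration * out.rate))
        if start < 0 or start + length > n:
            raise IndexError(
                f"artifact window [{start}, {start + length}) outside recording"
            )
        sl = slice(start, start + length)
        if kind == "step":
            out.samples[np.ix_(rows, range(start, start + length))] += magnitude
        elif kind == "flat":
            level = out.samples[rows][:, sl].mean(axis=1, keepdims=True)
            wobble = rng.uniform(-0.02, 0.02, size=(len(rows), length))
            out.samples[np.ix_(rows, range(start, start + length))] = (
                level + wobble
            )
        else:
            raise ValueError(f"unknown artifact kind: {kind!r}")
    return out
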