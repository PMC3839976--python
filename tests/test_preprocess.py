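"""Preprocessing chain: filter response, downsampling, segmentation,
artifact rejection rules, and common average reference."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import signal

from mieeg.montage import ANALYSIS_CHANNELS, DEFAULT_MONTAGE
from mieeg.preprocess import (
    EmptyTrialError,
    ParameterError,
    bandpass_sos,
    common_average_reference,
    preprocess_recording,
    reject_artifacts,
    segment_trials,
)
from mieeg.synth import EffectSpec, Recording, generate_subject, inject_artifacts
from conftest import make_trialset


def make_recording(samples: np.ndarray, rate: float = 250.0,
                   events=None) -> Recording:
    labels = list(DEFAULT_MONTAGE[: samples.shape[0]])
    return Recording(samples=samples, rate=rate, channel_labels=labels,
                     events=events or [], subject_id="T")


class TestFilterResponse:
    def test_passband_sine_amplitude_and_phase_preserved(self):
        t = np.arange(5000) / 250.0
        x = np.tile(np.sin(2 * np.pi * 10.0 * t), (21, 1))
        rec = make_recording(x, events=[(2000, "imagery")])
        out = preprocess_recording(rec)
        mid = out.samples[0, 1000:4000]
        ref = np.sin(2 * np.pi * 10.0 * np.arange(1000, 4000) / 250.0)
        amp = mid.std() / ref.std()
        assert amp == pytest.approx(1.0, abs=0.01)
        # zero net phase: peak cross-correlation at zero lag
        lag = np.argmax(np.correlate(mid, ref, "full")) - (len(ref) - 1)
        assert lag == 0
        phase = np.angle(np.vdot(ref, signal.hilbert(mid))
                         / np.vdot(ref, signal.hilbert(ref)))
        assert abs(phase) < 0.01

    @pytest.mark.parametrize("freq", [0.2, 60.0])
    def test_stopband_attenuation_exceeds_40db(self, freq):
        sos = bandpass_sos((1.0, 48.0), 250.0)
        w, h = signal.sosfreqz(sos, worN=2**14, fs=250.0)
        idx = np.argmin(np.abs(w - freq))
        # forward-backward application squares the magnitude response
        att_db = 20 * np.log10(max(np.abs(h[idx]) ** 2, 1e-300))
        assert att_db <= -40.0

    def test_band_beyond_nyquist_rejected(self):
        rec = make_recording(np.zeros((21, 1000)))
        with pytest.raises(ParameterError):
            preprocess_recording(rec, band=(1.0, 130.0))

    def test_filtering_is_linear(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((21, 2000))
        y = rng.standard_normal((21, 2000))
        a, b = 2.5, -1.3
        out_sum = preprocess_recording(make_recording(a * x + b * y)).samples
        out_x = preprocess_recording(make_recording(x)).samples
        out_y = preprocess_recording(make_recording(y)).samples
        assert np.allclose(out_sum, a * out_x + b * out_y, atol=1e-8)


class TestDownsampling:
    def test_patient_mode_1000hz_decimated_by_four(self):
        rng = np.random.default_rng(1)
        rec = make_recording(rng.standard_normal((21, 8000)), rate=1000.0,
                             events=[(400, "imagery")])
        out = preprocess_recording(rec, target_rate=250.0)
        assert out.rate == 250.0
        assert out.samples.shape[1] == 8000 // 4
        assert out.events == [(100, "imagery")]

    def test_non_integer_factor_rejected(self):
        rec = make_recording(np.zeros((21, 1000)), rate=300.0)
        with pytest.raises(ParameterError):
            preprocess_recording(rec, target_rate=250.0)


class TestSegmentation:
    def test_one_epoch_per_event_with_exact_content(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((23, 250 * 240))
        events = [(250 + i * 1150, "imagery" if i % 2 else "rest")
                  for i in range(48)]
        rec = Recording(samples=x, rate=250.0,
                        channel_labels=list(DEFAULT_MONTAGE), events=events)
        trials = segment_trials(rec)
        assert trials.epochs.shape == (48, 21, 1000)
        assert trials.channel_labels == list(ANALYSIS_CHANNELS)
        row = list(DEFAULT_MONTAGE).index("C3")
        crow = trials.channel_labels.index("C3")
        assert np.array_equal(trials.epochs[0, crow],
                              x[row, 250:1250])

    def test_epoch_overrunning_recording_skipped_and_logged(self):
        x = np.zeros((21, 3000))
        rec = make_recording(x, events=[(100, "imagery"), (2500, "rest")])
        trials = segment_trials(rec)
        assert trials.n_trials == 1
        skipped = [e for e in trials.rejected_log if e["reason"]]
        assert len(skipped) == 1 and "overruns" in skipped[0]["reason"]

    def test_no_events_raises(self):
        rec = make_recording(np.zeros((21, 1000)))
        with pytest.raises(EmptyTrialError):
            segment_trials(rec)


class TestArtifactRejection:
    @staticmethod
    def build_epochs() -> tuple[np.ndarray, list[str]]:
        """10 clean noise epochs; violations are planted by the tests."""
        rng = np.random.default_rng(3)
        sos = signal.butter(4, (1, 48), btype="bandpass", fs=250, output="sos")
        epochs = signal.sosfiltfilt(
            sos, rng.standard_normal((10, 5, 1000)) * 20.0, axis=2)
        conditions = ["imagery", "rest"] * 5
        return epochs, conditions

    def test_planted_violations_rejected_with_named_rules(self):
        epochs, conditions = self.build_epochs()
        epochs[1, 2, 400:] += 60.0           # rule (a): 60 uV step
        ramp = np.concatenate([np.arange(60) * 4.5,
                               np.arange(60, 0, -1) * 4.5])
        epochs[4, 0, 300:420] += ramp         # rule (b): 225 uV per 200 ms
        epochs[7, 3, 500:538] = 42.0          # rule (c): flat 150 ms
        trials = make_trialset(epochs, conditions)
        out = reject_artifacts(trials)
        assert out.n_trials == 7
        reasons = {e["event"]: e["reason"] for e in out.rejected_log
                   if e["reason"]}
        assert "voltage-step" in reasons[1]
        assert "max-range" in reasons[4]
        assert "low-range" in reasons[7]

    def test_clean_noise_retained(self):
        epochs, conditions = self.build_epochs()
        out = reject_artifacts(make_trialset(epochs, conditions))
        assert out.n_trials == 10

    def test_rejection_is_order_independent(self):
        epochs, conditions = self.build_epochs()
        epochs[2, 1, 100] += 80.0
        perm = np.random.default_rng(4).permutation(10)
        direct = reject_artifacts(make_trialset(epochs, conditions))
        permuted = reject_artifacts(
            make_trialset(epochs[perm], [conditions[i] for i in perm]))
        assert permuted.n_trials == direct.n_trials == 9
        assert np.allclose(np.sort(permuted.epochs.sum(axis=(1, 2))),
                           np.sort(direct.epochs.sum(axis=(1, 2))))

    def test_injected_step_artifact_rejected_end_to_end(self):
        """A 60 uV step inside an epoch survives filtering and is caught."""
        spec = EffectSpec(n_trials_per_condition=4)
        rec = generate_subject(spec, seed=8)
        target = rec.events[2][0] + 500
        bad = inject_artifacts(rec, [(target, "step", 80.0, 0.4)])
        from mieeg.study import StudyConfig, prepare_subject

        clean = prepare_subject(rec, StudyConfig(seed=0))
        dirty = prepare_subject(bad, StudyConfig(seed=0))
        assert dirty.n_trials == clean.n_trials - 1

    def test_flat_stretch_rejected_by_low_range_rule(self):
        epochs, conditions = self.build_epochs()
        epochs[0, 0, 200:238] = epochs[0, 0, 200]
        out = reject_artifacts(make_trialset(epochs, conditions))
        assert out.n_trials == 9
        reason = next(e["reason"] for e in out.rejected_log if e["reason"])
        assert "low-range" in reason


class TestCommonAverageReference:
    def test_column_sums_zero(self, responsive_trials):
        out = common_average_reference(responsive_trials)
        sums = out.epochs.sum(axis=1)
        assert np.abs(sums).max() < 1e-9

    def test_identical_channels_become_zero(self):
        epochs = np.tile(np.random.default_rng(5).standard_normal(1000),
                         (2, 4, 1))
        trials = make_trialset(epochs, ["imagery", "rest"])
        out = common_average_reference(trials)
        assert np.abs(out.epochs).max() < 1e-12

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        trials = make_trialset(rng.standard_normal((3, 5, 200)),
                               ["imagery", "rest", "imagery"])
        once = common_average_reference(trials)
        twice = common_average_reference(once)
        assert np.allclose(once.epochs, twice.epochs, atol=1e-12)
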