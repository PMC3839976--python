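"""Shared fixtures: small synthetic subjects prepared once per session."""

from __future__ import annotations

import numpy as np
import pytest

from mieeg.montage import ANALYSIS_CHANNELS, MASTOID_CHANNELS
from mieeg.preprocess import TrialSet
from mieeg.study import StudyConfig, prepare_subject
from mieeg.synth import EffectSpec, generate_subject


@pytest.fixture(scope="session")
def responsive_trials() -> TrialSet:
    """One responsive subject (default effect) through the full preprocessing."""
    rec = generate_subject(EffectSpec(), seed=101, subject_id="RESP")
    return prepare_subject(rec, StudyConfig(seed=0))


@pytest.fixture(scope="session")
def null_trials() -> TrialSet:
    """One null subject (no ERD, no coupling) through the full preprocessing."""
    spec = EffectSpec(erd_depth=0.0, coh_gain=0.0)
    rec = generate_subject(spec, seed=202, subject_id="NULL")
    return prepare_subject(rec, StudyConfig(seed=0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def make_trialset(
    epochs: np.ndarray,
    conditions: list[str],
    rate: float = 250.0,
    channel_labels: list[str] | None = None,
) -> TrialSet:
    """Build a TrialSet around a raw epochs array for unit tests."""
    if channel_labels is None:
        channel_labels = list(ANALYSIS_CHANNELS[: epochs.shape[1]])
    return TrialSet(
        epochs=epochs, conditions=conditions,
        channel_labels=channel_labels, rate=rate, subject_id="TEST",
    )
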