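"""Shared fixtures.

The expensive synthetic-night pipeline (generation, artifact mask,
spectrogram, both detectors) is computed once per session and shared by
the module tests and the acceptance suite.
"""

from __future__ import annotations

import numpy as np
import pytest

import tfspindle as tf

NIGHT_SEED = 2
NIGHT_MINUTES = 30.0


@pytest.fixture(scope="session")
def night():
    """Synthetic night (recording + ground truth), default nested preset."""
    cfg = tf.SynthConfig(duration_min=NIGHT_MINUTES, seed=NIGHT_SEED)
    return tf.generate(cfg)


@pytest.fixture(scope="session")
def night_rec(night):
    return night[0]


@pytest.fixture(scope="session")
def night_truth(night):
    return night[1]


@pytest.fixture(scope="session")
def night_mask(night_rec):
    return tf.detect_artifacts(night_rec)


@pytest.fixture(scope="session")
def night_spec(night_rec):
    return tf.compute_spectrogram(night_rec)


@pytest.fixture(scope="session")
def night_tfsigma(night_rec, night_truth, night_mask, night_spec):
    """(event table, report) of the unsupervised detector on the night."""
    return tf.detect_tfsigma(
        night_rec, night_truth.hypnogram, night_mask, spec=night_spec
    )


@pytest.fixture(scope="session")
def night_wavelet_trace(night_rec):
    return tf.magnitude_trace(night_rec)


@pytest.fixture(scope="session")
def night_spindles(night_rec, night_truth, night_mask, night_wavelet_trace):
    """(event table, report) of the wavelet detector at the default threshold."""
    return tf.detect_spindles(
        night_rec, night_truth.hypnogram, night_mask, trace=night_wavelet_trace
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
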