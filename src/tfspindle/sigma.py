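"""Unsupervised sigma-band time-frequency event detection.

Candidate peaks come from the two-step prominence extraction run over the
whole artifact-free record, on a search band one Hz wider than the sigma
range on each side.  Candidates shorter than 0.3 s or narrower than half
the spectral resolution (2 Hz) are dropped, log prominences are split
into event/noise classes by exact two-class 1-D k-means, and events with
a central frequency outside 10-16 Hz are excluded.  Nothing is random:
the k-means objective is minimized exactly over contiguous splits of the
sorted values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tfspindle.artifact import ArtifactMask
from tfspindle.io import Hypnogram, Recording, events_to_table
from tfspindle.multitaper import SpectrogramParams, Spectrogram, compute_spectrogram
from tfspindle.peaks import TFPeak, frequency_step, time_step

__all__ = [
    "TfSigmaParams",
    "ClusterResult",
    "filter_candidates",
    "kmeans_two_class",
    "detect_tfsigma",
]


@dataclass
class TfSigmaParams:
    min_duration_s: float = 0.3
    min_bandwidth_hz: float = 2.0  # half of the 4 Hz spectral resolution
    freq_lo: float = 10.0
    freq_hi: float = 16.0
    search_pad_hz: float = 3.0  # widen the search band so band-edge peaks keep their flanks
    spectrogram: SpectrogramParams = field(default_factory=SpectrogramParams)

    def __post_init__(self) -> None:
        if not self.min_duration_s > 0:
            raise ValueError("min_duration_s must be > 0")
        if not self.freq_lo < self.freq_hi:
            raise ValueError("freq_lo must be < freq_hi")

    @property
    def search_band(self) -> tuple[float, float]:
        return (self.freq_lo - self.search_pad_hz, self.freq_hi + self.search_pad_hz)


@dataclass
class ClusterResult:
    """Outcome of the two-class split of log prominences."""

    threshold_logprom: float  # boundary between the classes
    labels: np.ndarray  # bool per input, True = event class
    means: tuple[float, float]  # (noise mean, event mean)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)


def filter_candidates(peaks: list[TFPeak], params: TfSigmaParams | None = None) -> list[TFPeak]:
    """Drop peaks too short or too narrow to be resolvable; order preserved."""
    params = params or TfSigmaParams()
    return [
        p
        for p in peaks
        if p.duration_s >= params.min_duration_s and p.bandwidth_hz >= params.min_bandwidth_hz
    ]


def kmeans_two_class(values) -> ClusterResult:
    """Exact two-class 1-D k-means.

    The optimal two-class partition in one dimension is a contiguous split
    of the sorted values; this enumerates all n-1 splits and minimizes the
    within-class sum of squares, so the result is deterministic (no
    random initialization).  The first minimal split is taken; the
    reported threshold is the midpoint of the two boundary values, which
    always lies between the class means.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be 1-D")
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct values to form two clusters")
    order = np.argsort(x, kind="stable")
    s = x[order]
    n = s.size
    csum = np.cumsum(s)
    csq = np.cumsum(s**2)
    k = np.arange(1, n)  # left class size
    left_ss = csq[k - 1] - csum[k - 1] ** 2 / k
    rsum = csum[-1] - csum[k - 1]
    rsq = csq[-1] - csq[k - 1]
    right_ss = rsq - rsum**2 / (n - k)
    wcss = left_ss + right_ss
    split = int(np.argmin(wcss)) + 1  # first minimum
    labels_sorted = np.zeros(n, dtype=bool)
    labels_sorted[split:] = True
    labels = np.empty(n, dtype=bool)
    labels[order] = labels_sorted
    noise_mean = float(s[:split].mean())
    event_mean = float(s[split:].mean())
    threshold = float((s[split - 1] + s[split]) / 2.0)
    return ClusterResult(threshold_logprom=threshold, labels=labels, means=(noise_mean, event_mean))


def detect_tfsigma(
    rec: Recording,
    hyp: Hypnogram | None = None,
    mask: ArtifactMask | None = None,
    params: TfSigmaParams | None = None,
    spec: Spectrogram | None = None,
    subject: str = "s0",
    night: int = 1,
) -> tuple[pd.DataFrame, dict]:
    """Full unsupervised detection pipeline on one recording.

    Returns the detected events as an event table (method tag
    ``"tfpeak_auto"``) plus a report dict with the candidate count,
    threshold and class means.  Candidates whose apex falls on an
    artifact sample are excluded before clustering; stage filtering is
    left to downstream event selection.  ``spec`` may pass in a
    precomputed spectrogram of the same recording.

    Bit-reproducible: contains no source of randomness.
    """
    params = params or TfSigmaParams()
    if spec is None:
        spec = compute_spectrogram(rec, params.spectrogram)
    trace = frequency_step(spec, params.search_band)
    peaks = time_step(trace)
    peaks = filter_candidates(peaks, params)
    if mask is not None:
        n = mask.mask.size
        peaks = [
            p
            for p in peaks
            if not mask.mask[min(n - 1, int(p.t_peak * rec.fs))]
        ]
    if len(peaks) < 2:
        raise ValueError(
            f"only {len(peaks)} candidate peaks; too few to cluster "
            "(provide a longer recording)"
        )
    logprom = np.log([p.prominence_db for p in peaks])
    clusters = kmeans_two_class(logprom)
    kept = [
        p
        for p, is_event in zip(peaks, clusters.labels)
        if is_event and params.freq_lo <= p.central_freq <= params.freq_hi
    ]
    table = events_to_table(
        starts=np.array([p.t_lo for p in kept]),
        ends=np.array([p.t_hi for p in kept]),
        method="tfpeak_auto",
        subject=subject,
        night=night,
        prominence_db=np.array([p.prominence_db for p in kept]),
        duration_s=np.array([p.duration_s for p in kept]),
        central_freq_hz=np.array([p.central_freq for p in kept]),
        bandwidth_hz=np.array([p.bandwidth_hz for p in kept]),
    )
    report = {
        "n_candidates": len(peaks),
        "n_events": len(kept),
        "threshold_logprom": clusters.threshold_logprom,
        "noise_mean_logprom": clusters.means[0],
        "event_mean_logprom": clusters.means[1],
    }
    return table, report
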