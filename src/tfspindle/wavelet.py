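"""Wavelet-threshold spindle detection and F1 threshold optimization.

The detector convolves the trace with a bank of complex Morlet wavelets
whose center frequencies span 10-16 Hz, forms the square of the real
component of the squared coefficient at each sample (averaged across the
bank), smooths with a 100-ms moving average, and thresholds at
``threshold_scalar`` times the mean of this statistic over artifact-free
N2 samples.  Supra-threshold runs of at least 0.3 s become events; runs
longer than 3 s are truncated and onsets closer than 1 s to the previous
onset are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import fftconvolve

from tfspindle.artifact import ArtifactMask
from tfspindle.io import Hypnogram, Recording, events_to_table

__all__ = [
    "WaveletParams",
    "MagnitudeTrace",
    "magnitude_trace",
    "detect_spindles",
    "optimize_threshold",
]


@dataclass
class WaveletParams:
    f_lo: float = 10.0
    f_hi: float = 16.0
    n_scales: int = 7  # center frequencies f_lo..f_hi inclusive
    n_cycles: float = 7.0
    smooth_ms: float = 100.0
    threshold_scalar: float = 4.5
    min_dur_s: float = 0.3
    max_dur_s: float = 3.0
    min_sep_s: float = 1.0

    def __post_init__(self) -> None:
        if not self.f_lo < self.f_hi:
            raise ValueError("f_lo must be < f_hi")
        if not 0 < self.min_dur_s < self.max_dur_s:
            raise ValueError("require 0 < min_dur_s < max_dur_s")
        if not self.threshold_scalar > 0:
            raise ValueError("threshold_scalar must be > 0")

    @property
    def center_freqs(self) -> np.ndarray:
        return np.linspace(self.f_lo, self.f_hi, self.n_scales)


@dataclass
class MagnitudeTrace:
    """Smoothed per-sample wavelet magnitude statistic (arbitrary units)."""

    times: np.ndarray
    value: np.ndarray
    fs: float


def _morlet_kernel(freq: float, n_cycles: float, fs: float) -> np.ndarray:
    """Complex Morlet wavelet, L1-normalized, truncated at +-4 sigma."""
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(4.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    kernel = np.exp(2j * np.pi * freq * t) * np.exp(-(t**2) / (2.0 * sigma_t**2))
    return kernel / np.sum(np.abs(kernel))


def magnitude_trace(rec: Recording, params: WaveletParams | None = None) -> MagnitudeTrace:
    """Smoothed wavelet magnitude statistic of a recording.

    Per scale the statistic is ``(Re(w^2))^2`` where ``w`` is the complex
    wavelet coefficient; scaling the signal by c therefore scales the
    trace by c^4.
    """
    params = params or WaveletParams()
    if params.f_hi >= rec.fs / 2:
        raise ValueError(
            f"wavelet passband upper edge {params.f_hi:g} Hz >= Nyquist {rec.fs / 2:g} Hz"
        )
    stat = np.zeros(rec.samples.size)
    for freq in params.center_freqs:
        w = fftconvolve(rec.samples, _morlet_kernel(freq, params.n_cycles, rec.fs), mode="same")
        stat += np.real(w**2) ** 2
    stat /= params.n_scales
    n_smooth = max(1, int(round(params.smooth_ms / 1000.0 * rec.fs)))
    value = uniform_filter1d(stat, size=n_smooth, mode="nearest")
    return MagnitudeTrace(times=rec.times, value=value, fs=rec.fs)


def _n2_mean(trace: MagnitudeTrace, hyp: Hypnogram, mask: ArtifactMask | None) -> float:
    n2 = hyp.sample_mask("N2", trace.fs, trace.value.size)
    if mask is not None:
        n2 &= ~mask.mask[: trace.value.size]
    if not n2.any():
        raise ValueError("no artifact-free N2 samples to set the detection threshold")
    return float(trace.value[n2].mean())


def _events_from_trace(
    trace: MagnitudeTrace, threshold: float, params: WaveletParams
) -> tuple[np.ndarray, np.ndarray]:
    """Supra-threshold runs -> event bounds (s), applying the duration rules."""
    fs = trace.fs
    supra = trace.value > threshold
    edges = np.flatnonzero(np.diff(np.r_[0, supra.astype(np.int8), 0]))
    runs = edges.reshape(-1, 2)  # [start, end) sample indices
    min_len = int(round(params.min_dur_s * fs))
    runs = runs[(runs[:, 1] - runs[:, 0]) >= min_len]
    starts = runs[:, 0] / fs
    ends = np.minimum(runs[:, 1] / fs, starts + params.max_dur_s)
    keep, last_onset = [], -np.inf
    for i, s in enumerate(starts):
        if s - last_onset >= params.min_sep_s:
            keep.append(i)
            last_onset = s
    return starts[keep], ends[keep]


def detect_spindles(
    rec: Recording,
    hyp: Hypnogram,
    mask: ArtifactMask | None = None,
    params: WaveletParams | None = None,
    trace: MagnitudeTrace | None = None,
    subject: str = "s0",
    night: int = 1,
) -> tuple[pd.DataFrame, dict]:
    """Threshold the magnitude statistic and report spindle events.

    Returns the event table (method tag ``"spindle_auto"``) and a report
    dict with the N2 mean statistic and the absolute threshold.  A
    precomputed ``trace`` for the same recording may be passed to avoid
    recomputing the wavelet transform.
    """
    params = params or WaveletParams()
    if trace is None:
        trace = magnitude_trace(rec, params)
    n2_mean = _n2_mean(trace, hyp, mask)
    threshold = params.threshold_scalar * n2_mean
    starts, ends = _events_from_trace(trace, threshold, params)
    table = events_to_table(starts, ends, "spindle_auto", subject, night)
    report = {
        "n2_mean_statistic": n2_mean,
        "threshold": threshold,
        "threshold_scalar": params.threshold_scalar,
        "n_events": len(table),
    }
    return table, report


def optimize_threshold(
    rec: Recording,
    hyp: Hypnogram,
    mask: ArtifactMask | None,
    reference: pd.DataFrame,
    grid: np.ndarray | None = None,
    params: WaveletParams | None = None,
    trace: MagnitudeTrace | None = None,
) -> tuple[float, float, pd.DataFrame]:
    """Scan the threshold scalar and maximize F1 against a reference event set.

    The default grid is 0.01, 0.02, ..., 4.5.  Returns
    ``(best_scalar, best_f1, curve)`` where ``curve`` is a DataFrame with
    one row per grid point (columns ``scalar``, ``f1``, ``n_events``).
    F1 ties resolve to the largest scalar.
    """
    from tfspindle.stats import match_events  # deferred: stats imports this module's tables

    params = params or WaveletParams()
    if reference is None or len(reference) == 0:
        raise ValueError("reference event table is empty")
    if grid is None:
        grid = np.round(np.arange(1, 451) * 0.01, 10)
    if trace is None:
        trace = magnitude_trace(rec, params)
    n2_mean = _n2_mean(trace, hyp, mask)

    scalars, f1s, counts = [], [], []
    best_scalar, best_f1 = float(grid[0]), -1.0
    for scalar in grid:
        starts, ends = _events_from_trace(trace, scalar * n2_mean, params)
        detected = events_to_table(starts, ends, "spindle_auto")
        f1 = match_events(reference, detected, fs=rec.fs).f1 if len(detected) else 0.0
        scalars.append(float(scalar))
        f1s.append(f1)
        counts.append(len(detected))
        if f1 >= best_f1:  # >= so ties go to the largest scalar
            best_f1, best_scalar = f1, float(scalar)
    curve = pd.DataFrame({"scalar": scalars, "f1": f1s, "n_events": counts})
    return best_scalar, best_f1, curve
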