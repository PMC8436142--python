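"""Iterative amplitude-z-score artifact detection.

Two passes over the raw trace -- a high-frequency pass (high-pass at
35 Hz) and a broadband pass (high-pass at 2 Hz).  Each pass computes the
analytic-signal amplitude, log-scales it, smooths with a 2-s running
average, removes slow drift with a 300-knot least-squares cubic spline,
and then iteratively flags samples whose |z| exceeds 4 SD, recomputing
mean/SD over the still-unflagged samples until convergence.  The final
mask is the union of both passes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import LSQUnivariateSpline
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, hilbert, sosfiltfilt

from tfspindle.io import Recording

__all__ = ["ArtifactParams", "ArtifactMask", "detect_artifacts", "mask_to_intervals"]


@dataclass
class ArtifactParams:
    hf_cutoff: float = 35.0  # Hz, high-frequency-noise pass
    bb_cutoff: float = 2.0  # Hz, broadband-noise pass
    filter_order: int = 8
    smooth_s: float = 2.0
    n_knots: int = 300
    z_thresh: float = 4.0
    max_iter: int = 50

    def __post_init__(self) -> None:
        if not self.z_thresh > 0:
            raise ValueError("z_thresh must be > 0")


@dataclass
class ArtifactMask:
    """Boolean per-sample artifact flags (True = artifact)."""

    mask: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def flagged_fraction(self) -> float:
        return float(self.mask.mean())

    def intervals(self) -> np.ndarray:
        return mask_to_intervals(self.mask, self.fs)


def _log_amplitude_envelope(x: np.ndarray, fs: float, cutoff: float, params: ArtifactParams) -> np.ndarray:
    """High-pass -> Hilbert amplitude -> log -> smooth -> spline detrend."""
    sos = butter(params.filter_order, cutoff, btype="highpass", fs=fs, output="sos")
    filt = sosfiltfilt(sos, x)
    amp = np.abs(hilbert(filt))
    log_amp = np.log(np.maximum(amp, np.finfo(float).tiny))
    n_smooth = max(1, int(round(params.smooth_s * fs)))
    smoothed = uniform_filter1d(log_amp, size=n_smooth, mode="nearest")
    # least-squares cubic spline with uniformly spaced interior knots
    t = np.arange(smoothed.size, dtype=float)
    n_knots = min(params.n_knots, max(1, smoothed.size // 8))
    knots = np.linspace(t[0], t[-1], n_knots + 2)[1:-1]
    trend = LSQUnivariateSpline(t, smoothed, knots, k=3)(t)
    return smoothed - trend


def _iterative_zscore_mask(x: np.ndarray, z_thresh: float, max_iter: int) -> np.ndarray:
    """Grow a mask of |z| > z_thresh outliers, re-estimating mean/SD on the
    unmasked samples each iteration, until no further sample exceeds the
    threshold (or the iteration cap)."""
    mask = np.zeros(x.size, dtype=bool)
    for _ in range(max_iter):
        kept = x[~mask]
        if kept.size < 2:
            break
        mu, sd = kept.mean(), kept.std()
        if sd == 0:
            break
        new = (np.abs(x - mu) / sd > z_thresh) & ~mask
        if not new.any():
            break
        mask |= new
    return mask


def detect_artifacts(rec: Recording, params: ArtifactParams | None = None) -> ArtifactMask:
    """Detect artifact samples in a recording.

    The high-frequency pass is skipped with a warning when the sampling
    rate cannot resolve the cutoff (fs/2 <= hf_cutoff), e.g. for 50 Hz
    material.
    """
    params = params or ArtifactParams()
    if not np.all(np.isfinite(rec.samples)):
        raise ValueError("recording contains non-finite samples")
    cutoffs = []
    if rec.fs / 2 > params.hf_cutoff:
        cutoffs.append(params.hf_cutoff)
    else:
        warnings.warn(
            f"fs/2 = {rec.fs / 2:g} Hz cannot resolve the {params.hf_cutoff:g} Hz "
            "high-frequency pass; skipping it",
            stacklevel=2,
        )
    if rec.fs / 2 > params.bb_cutoff:
        cutoffs.append(params.bb_cutoff)
    else:
        raise ValueError("sampling rate too low for the broadband pass")

    mask = np.zeros(rec.samples.size, dtype=bool)
    for cutoff in cutoffs:
        env = _log_amplitude_envelope(rec.samples, rec.fs, cutoff, params)
        mask |= _iterative_zscore_mask(env, params.z_thresh, params.max_iter)
    return ArtifactMask(mask=mask, fs=rec.fs)


def mask_to_intervals(mask: np.ndarray, fs: float) -> np.ndarray:
    """Maximal runs of True samples as an (n, 2) array of [start_s, end_s)."""
    padded = np.r_[0, mask.astype(np.int8), 0]
    edges = np.flatnonzero(np.diff(padded))
    return edges.reshape(-1, 2) / fs
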