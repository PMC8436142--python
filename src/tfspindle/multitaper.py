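"""Multitaper spectrogram estimation with Slepian (DPSS) tapers.

Defaults follow the sleep-EEG analysis convention: 1-s windows, 0.05-s
step, time-half-bandwidth product 2 with 3 tapers, NFFT >= 1024, and
constant detrending within each window.  Power is a one-sided PSD in
linear units (signal units squared per Hz); timestamps are window
centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import rfft, rfftfreq
from scipy.signal.windows import dpss

from tfspindle.io import Recording

__all__ = ["SpectrogramParams", "Spectrogram", "compute_spectrogram"]

_CHUNK = 4096  # windows processed per FFT batch (memory cap)


@dataclass
class SpectrogramParams:
    """Parameters of the multitaper spectrogram.

    The spectral resolution of the estimate is ``2 * tw / window_s``
    (4 Hz with the defaults); downstream bandwidth rules use half of it.
    """

    window_s: float = 1.0
    step_s: float = 0.05
    tw: float = 2.0
    n_tapers: int = 3
    min_nfft: int = 1024
    detrend: str = "constant"

    def __post_init__(self) -> None:
        if self.n_tapers > 2 * self.tw - 1:
            raise ValueError(
                f"n_tapers={self.n_tapers} exceeds 2*tw-1={2 * self.tw - 1:g}"
            )
        if self.step_s > self.window_s:
            raise ValueError("step_s must not exceed window_s")
        if self.detrend not in ("constant", "off"):
            raise ValueError("detrend must be 'constant' or 'off'")

    def n_window_samples(self, fs: float) -> int:
        n = self.window_s * fs
        if abs(n - round(n)) > 1e-6:
            raise ValueError(
                f"window_s*fs = {n} is not an integer number of samples"
            )
        return int(round(n))

    def nfft(self, fs: float) -> int:
        n_win = self.n_window_samples(fs)
        return max(int(self.min_nfft), 1 << (n_win - 1).bit_length())

    @property
    def resolution_hz(self) -> float:
        return 2.0 * self.tw / self.window_s


@dataclass
class Spectrogram:
    """Time x frequency power array plus the grids and parameters that made it."""

    times: np.ndarray  # window-center timestamps, s
    freqs: np.ndarray  # Hz
    power: np.ndarray  # (n_times, n_freqs), linear PSD
    params: SpectrogramParams
    fs: float

    @property
    def step_s(self) -> float:
        return self.params.step_s

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def mean_spectrum(self) -> np.ndarray:
        """Time-averaged PSD."""
        return self.power.mean(axis=0)


def compute_spectrogram(rec: Recording, params: SpectrogramParams | None = None) -> Spectrogram:
    """Compute the multitaper spectrogram of a recording.

    Each window is constant-detrended (unless disabled), multiplied by each
    of the ``n_tapers`` unit-norm DPSS sequences, and the taper
    periodograms are averaged.  One-sided PSD scaling doubles all bins
    except DC and Nyquist.  Windows start at offsets ``k * step_s`` from
    ``t0``; a final partial window is dropped.
    """
    params = params or SpectrogramParams()
    fs = rec.fs
    n_win = params.n_window_samples(fs)
    if rec.samples.size < n_win:
        raise ValueError(
            f"recording ({rec.samples.size} samples) shorter than one "
            f"window ({n_win} samples)"
        )
    nfft = params.nfft(fs)
    if nfft < n_win:
        raise ValueError("min_nfft smaller than the window length")

    step = params.step_s * fs
    n_steps = int(np.floor((rec.samples.size - n_win) / step)) + 1
    starts = np.round(np.arange(n_steps) * step).astype(np.int64)
    # guard against rounding pushing the last window past the end
    starts = starts[starts + n_win <= rec.samples.size]

    # symmetric DPSS are the exact eigenvectors: unit norm, orthogonal to ~1e-15
    tapers = dpss(n_win, params.tw, params.n_tapers, sym=True)
    freqs = rfftfreq(nfft, 1.0 / fs)
    one_sided = np.full(freqs.size, 2.0)
    one_sided[0] = 1.0
    if nfft % 2 == 0:
        one_sided[-1] = 1.0

    power = np.empty((starts.size, freqs.size))
    offsets = np.arange(n_win)
    for lo in range(0, starts.size, _CHUNK):
        idx = starts[lo : lo + _CHUNK, None] + offsets[None, :]
        seg = rec.samples[idx]
        if params.detrend == "constant":
            seg = seg - seg.mean(axis=1, keepdims=True)
        spec = rfft(seg[None, :, :] * tapers[:, None, :], n=nfft, axis=-1)
        psd = (spec.real**2 + spec.imag**2).mean(axis=0) / fs
        power[lo : lo + _CHUNK] = psd * one_sided

    times = rec.t0 + starts / fs + params.window_s / 2.0
    return Spectrogram(times=times, freqs=freqs, power=power, params=params, fs=fs)
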