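"""Two-step prominence extraction of time-frequency peaks.

Step 1 ("frequency step"): in every spectrogram time column, find local
maxima of the dB power spectrum inside the search band and keep the one
with the largest topographic prominence, recording its prominence,
frequency, and spectral half-prominence width.

Step 2 ("time step"): find local maxima of the resulting prominence time
trace; each becomes a :class:`TFPeak` whose temporal bounds are the
half-prominence crossings of the temporal peak and whose frequency
properties are read off the trace at the apex.

Prominence is computed on dB-scaled power, so it is invariant to overall
power scaling.  Ties are broken toward earlier time, then lower
frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, peak_widths

from tfspindle.multitaper import Spectrogram

__all__ = [
    "TFPeak",
    "ProminenceTrace",
    "frequency_step",
    "time_step",
    "most_prominent_in_interval",
]

_DB_FLOOR = 1e-30  # linear power floor before log scaling


@dataclass
class TFPeak:
    """One well-formed time-frequency local maximum."""

    t_peak: float  # apex time, s
    t_lo: float  # temporal bounds, s (half-prominence crossings)
    t_hi: float
    central_freq: float  # Hz
    f_lo: float  # spectral half-prominence bounds, Hz
    f_hi: float
    prominence_db: float  # dB

    def __post_init__(self) -> None:
        if not (self.t_lo < self.t_peak < self.t_hi):
            raise ValueError("require t_lo < t_peak < t_hi")
        if not (self.f_lo < self.central_freq < self.f_hi):
            raise ValueError("require f_lo < central_freq < f_hi")
        if not self.prominence_db > 0:
            raise ValueError("prominence must be positive")

    @property
    def duration_s(self) -> float:
        return self.t_hi - self.t_lo

    @property
    def bandwidth_hz(self) -> float:
        return self.f_hi - self.f_lo


@dataclass
class ProminenceTrace:
    """Largest-peak prominence per spectrogram time column (0 where none)."""

    times: np.ndarray  # s, the spectrogram time grid
    value: np.ndarray  # prominence in dB, >= 0
    freq_at: np.ndarray  # central frequency of that peak, Hz (nan where none)
    band_at: np.ndarray  # spectral half-prominence width, Hz (nan where none)

    @property
    def step_s(self) -> float:
        return float(self.times[1] - self.times[0])


def _column_winner(col_db: np.ndarray) -> tuple[float, int, float] | None:
    """Largest-prominence interior local maximum of one dB spectrum column.

    Returns (prominence, index, half-prominence width in bins) or None.
    With equal prominences the lowest-frequency peak wins (np.argmax
    returns the first).
    """
    idx, props = find_peaks(col_db, prominence=0)
    if idx.size == 0:
        return None
    best = int(np.argmax(props["prominences"]))
    widths = peak_widths(
        col_db,
        idx[best : best + 1],
        rel_height=0.5,
        prominence_data=(
            props["prominences"][best : best + 1],
            props["left_bases"][best : best + 1],
            props["right_bases"][best : best + 1],
        ),
    )
    return float(props["prominences"][best]), int(idx[best]), float(widths[0][0])


def frequency_step(spec: Spectrogram, f_range: tuple[float, float]) -> ProminenceTrace:
    """Per-column largest-prominence spectral peak inside ``f_range``.

    Power is converted to dB (10 log10) and peaks are searched only within
    the band, so the flanking minima that define prominence are also
    band-restricted.
    """
    f_lo, f_hi = f_range
    if not (0 < f_lo < f_hi):
        raise ValueError(f"invalid f_range {f_range}")
    if f_hi > spec.freqs[-1] or f_lo < spec.freqs[0]:
        raise ValueError(
            f"f_range {f_range} outside the frequency grid "
            f"[{spec.freqs[0]:g}, {spec.freqs[-1]:g}] Hz"
        )
    band = (spec.freqs >= f_lo) & (spec.freqs <= f_hi)
    i0 = int(np.argmax(band))
    db = 10.0 * np.log10(np.maximum(spec.power[:, band], _DB_FLOOR))
    df = spec.df

    n_t = db.shape[0]
    value = np.zeros(n_t)
    freq_at = np.full(n_t, np.nan)
    band_at = np.full(n_t, np.nan)
    for t in range(n_t):
        winner = _column_winner(db[t])
        if winner is None:
            continue
        prom, j, width_bins = winner
        value[t] = prom
        freq_at[t] = spec.freqs[i0 + j]
        band_at[t] = width_bins * df
    return ProminenceTrace(times=spec.times.copy(), value=value, freq_at=freq_at, band_at=band_at)


def time_step(trace: ProminenceTrace) -> list[TFPeak]:
    """Temporal local maxima of the prominence trace as TFPeak objects.

    The temporal bounds of each peak are the half-prominence crossings of
    the *temporal* peak (linearly interpolated); its reported prominence,
    central frequency and spectral bounds come from the trace at the apex.
    """
    if trace.value.size < 3:
        return []
    idx, props = find_peaks(trace.value, prominence=0)
    if idx.size == 0:
        return []
    widths = peak_widths(
        trace.value,
        idx,
        rel_height=0.5,
        prominence_data=(props["prominences"], props["left_bases"], props["right_bases"]),
    )
    dt = trace.step_s
    t0 = trace.times[0]
    peaks: list[TFPeak] = []
    for k, i in enumerate(idx):
        prom_db = float(trace.value[i])
        cf = float(trace.freq_at[i])
        bw = float(trace.band_at[i])
        if not (np.isfinite(cf) and np.isfinite(bw)) or prom_db <= 0:
            continue
        peaks.append(
            TFPeak(
                t_peak=float(t0 + i * dt),
                t_lo=float(t0 + widths[2][k] * dt),
                t_hi=float(t0 + widths[3][k] * dt),
                central_freq=cf,
                f_lo=cf - bw / 2.0,
                f_hi=cf + bw / 2.0,
                prominence_db=prom_db,
            )
        )
    peaks.sort(key=lambda p: (p.t_peak, p.central_freq))
    return peaks


def most_prominent_in_interval(
    start_s: float, end_s: float, peaks: list[TFPeak]
) -> TFPeak | None:
    """The most prominent peak whose apex lies in ``[start_s, end_s)``.

    Ties go to the earliest apex.  Returns None when no apex falls inside
    the interval.
    """
    best: TFPeak | None = None
    for p in peaks:
        if start_s <= p.t_peak < end_s:
            if best is None or p.prominence_db > best.prominence_db:
                best = p
    return best
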