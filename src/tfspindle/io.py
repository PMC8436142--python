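"""I/O for the formats the pipeline touches.

Signals are read/written as EDF (European Data Format) with a minimal
pure-numpy codec (16-bit, one data record per second).  Sleep stages are
plain text (one token per 30-s epoch, or comma separated).  Event lists
are CSV tables handled through pandas.

Time convention: all event intervals are half-open ``[start_s, end_s)``
in seconds from the recording start; sample ``i`` covers
``[i/fs, (i+1)/fs)``.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Recording",
    "Hypnogram",
    "STAGE_CODES",
    "STAGE_ALIASES",
    "read_edf",
    "write_edf",
    "read_hypnogram",
    "write_hypnogram",
    "read_event_table",
    "write_event_table",
    "validate_event_table",
    "events_to_table",
    "load_config",
]

#: canonical stage vocabulary
STAGE_CODES = ("W", "N1", "N2", "N3", "REM", "UNKNOWN")

#: recognized spellings -> canonical code (includes the Rechtschaffen-Kales
#: aliases S1-S4 still used by older scoring archives)
STAGE_ALIASES = {
    "W": "W",
    "WAKE": "W",
    "0": "W",
    "N1": "N1",
    "S1": "N1",
    "1": "N1",
    "N2": "N2",
    "S2": "N2",
    "2": "N2",
    "N3": "N3",
    "S3": "N3",
    "S4": "N3",
    "3": "N3",
    "4": "N3",
    "REM": "REM",
    "R": "REM",
    "5": "REM",
    "UNKNOWN": "UNKNOWN",
    "?": "UNKNOWN",
}

#: required columns of an event table
EVENT_COLUMNS = ("start_s", "end_s", "method", "subject", "night")

#: optional linked peak-property columns
PROPERTY_COLUMNS = ("prominence_db", "duration_s", "central_freq_hz", "bandwidth_hz")


@dataclass
class Recording:
    """A single-channel EEG trace.

    Parameters
    ----------
    samples : ndarray
        Signal samples in microvolts.
    fs : float
        Sampling rate in Hz, > 0.
    channel : str
        Channel label.
    t0 : float
        Time origin in seconds (default 0).
    """

    samples: np.ndarray
    fs: float
    channel: str = "EEG"
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not self.fs > 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass
class Hypnogram:
    """Per-epoch sleep stages (30-s epochs by default)."""

    stages: np.ndarray
    epoch_s: float = 30.0

    def __post_init__(self) -> None:
        if not self.epoch_s > 0:
            raise ValueError("epoch_s must be > 0")
        stages = np.asarray(self.stages, dtype=object)
        bad = [s for s in stages if s not in STAGE_CODES]
        if bad:
            raise ValueError(f"unrecognized stage codes: {sorted(set(bad))}")
        self.stages = stages

    @property
    def duration_s(self) -> float:
        return len(self.stages) * self.epoch_s

    def stage_at(self, t: float | np.ndarray) -> np.ndarray:
        """Stage code(s) at time(s) ``t`` (seconds from recording start)."""
        idx = np.floor(np.atleast_1d(t) / self.epoch_s).astype(int)
        out = np.where(
            (idx >= 0) & (idx < len(self.stages)),
            self.stages[np.clip(idx, 0, len(self.stages) - 1)],
            "UNKNOWN",
        )
        return out if np.ndim(t) else out[0]

    def sample_mask(self, stage: str, fs: float, n_samples: int) -> np.ndarray:
        """Boolean per-sample mask of samples whose epoch has the given stage."""
        epoch_idx = (np.arange(n_samples) / (fs * self.epoch_s)).astype(int)
        epoch_idx = np.clip(epoch_idx, 0, len(self.stages) - 1)
        return np.asarray(self.stages[epoch_idx] == stage)

    def check_covers(self, rec: Recording) -> bool:
        """Warn (and return False) if the stage sequence does not cover the recording."""
        needed = int(np.ceil(rec.duration_s / self.epoch_s))
        if len(self.stages) != needed:
            warnings.warn(
                f"hypnogram has {len(self.stages)} epochs but the recording "
                f"needs {needed} ({rec.duration_s:.0f} s / {self.epoch_s:.0f} s epochs)",
                stacklevel=2,
            )
            return False
        return True


# ---------------------------------------------------------------------------
# EDF codec
# ---------------------------------------------------------------------------

_EDF_HDR = 256  # bytes, fixed part
_EDF_SIG = 256  # bytes per signal header


def _pad(text: str, width: int) -> bytes:
    b = str(text)[:width].encode("ascii", errors="replace")
    return b + b" " * (width - len(b))


def write_edf(path: str | os.PathLike, rec: Recording, *, extra: dict | None = None) -> None:
    """Write a single-channel recording as a 16-bit EDF file.

    Uses one data record per second, so ``rec.fs`` must be an integer and
    any trailing partial second is dropped (with a warning).
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError(f"EDF writer requires an integer sampling rate, got fs={fs}")
    fs = int(round(fs))
    n_rec = rec.samples.size // fs
    if n_rec < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    if n_rec * fs != rec.samples.size:
        warnings.warn(
            f"dropping {rec.samples.size - n_rec * fs} trailing samples "
            "(partial EDF data record)",
            stacklevel=2,
        )
    x = rec.samples[: n_rec * fs]

    pmax = float(np.max(np.abs(x)))
    if pmax == 0:
        pmax = 1.0
    dmin, dmax = -32768, 32767
    gain = 2 * pmax / (dmax - dmin)
    digital = np.clip(np.round((x + pmax) / gain) + dmin, dmin, dmax).astype("<i2")

    header = b"".join(
        [
            _pad("0", 8),
            _pad((extra or {}).get("patient", "X X X X"), 80),
            _pad((extra or {}).get("recording", "Startdate X X X X"), 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(_EDF_HDR + _EDF_SIG), 8),
            _pad("", 44),
            _pad(str(n_rec), 8),
            _pad("1", 8),
            _pad("1", 4),
            # per-signal fields
            _pad(rec.channel, 16),
            _pad("", 80),
            _pad("uV", 8),
            _pad(f"{-pmax:.6g}"[:8], 8),
            _pad(f"{pmax:.6g}"[:8], 8),
            _pad(str(dmin), 8),
            _pad(str(dmax), 8),
            _pad("", 80),
            _pad(str(fs), 8),
            _pad("", 32),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())


def read_edf(path: str | os.PathLike, channel: str | None = None) -> Recording:
    """Read one channel from an EDF file.

    Parameters
    ----------
    path : path
        EDF file.
    channel : str, optional
        Channel label (whitespace-insensitive).  Defaults to the first
        signal.  A missing channel raises ``KeyError`` naming the
        available channels.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such EDF file: {path}")
    with open(path, "rb") as fh:
        hdr = fh.read(_EDF_HDR)
        if len(hdr) < _EDF_HDR:
            raise ValueError(f"{path}: truncated EDF header")
        try:
            n_rec = int(hdr[236:244].decode("ascii").strip())
            rec_dur = float(hdr[244:252].decode("ascii").strip())
            ns = int(hdr[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise ValueError(f"{path}: malformed EDF header") from exc
        sig = fh.read(_EDF_SIG * ns)

        def fields(offset: int, width: int) -> list[str]:
            base = offset * ns
            return [
                sig[base + i * width : base + (i + 1) * width].decode("ascii").strip()
                for i in range(ns)
            ]

        labels = fields(0, 16)
        pmins = [float(v) for v in fields(16 + 80 + 8, 8)]
        pmaxs = [float(v) for v in fields(16 + 80 + 8 + 8, 8)]
        dmins = [int(v) for v in fields(16 + 80 + 8 + 8 + 8, 8)]
        dmaxs = [int(v) for v in fields(16 + 80 + 8 + 8 + 8 + 8, 8)]
        sprs = [int(v) for v in fields(16 + 80 + 8 * 5 + 80, 8)]

        if channel is None:
            ch_idx = 0
        else:
            norm = [lb.replace(" ", "") for lb in labels]
            want = channel.replace(" ", "")
            if want not in norm:
                raise KeyError(
                    f"channel {channel!r} not in {path}; available: {labels}"
                )
            ch_idx = norm.index(want)

        rec_len = sum(sprs)
        raw = np.frombuffer(fh.read(n_rec * rec_len * 2), dtype="<i2")
    if raw.size < n_rec * rec_len:
        raise ValueError(f"{path}: truncated EDF data section")
    raw = raw.reshape(n_rec, rec_len)
    off = sum(sprs[:ch_idx])
    digital = raw[:, off : off + sprs[ch_idx]].reshape(-1).astype(float)
    gain = (pmaxs[ch_idx] - pmins[ch_idx]) / (dmaxs[ch_idx] - dmins[ch_idx])
    physical = (digital - dmins[ch_idx]) * gain + pmins[ch_idx]
    fs = sprs[ch_idx] / rec_dur
    return Recording(samples=physical, fs=fs, channel=labels[ch_idx])


# ---------------------------------------------------------------------------
# Hypnograms
# ---------------------------------------------------------------------------


def read_hypnogram(
    path: str | os.PathLike,
    epoch_s: float = 30.0,
    aliases: dict | None = None,
) -> Hypnogram:
    """Read a plain-text hypnogram (one stage token per line, or comma separated).

    Tokens are mapped through :data:`STAGE_ALIASES` (optionally overridden);
    unrecognized tokens become ``UNKNOWN`` with a warning.
    """
    alias = dict(STAGE_ALIASES)
    if aliases:
        alias.update({k.upper(): v for k, v in aliases.items()})
    with open(path) as fh:
        tokens = [tok.strip() for line in fh for tok in line.replace(",", " ").split()]
    if not tokens:
        raise ValueError(f"{path}: empty hypnogram file")
    stages = []
    unknown: set[str] = set()
    for tok in tokens:
        code = alias.get(tok.upper())
        if code is None:
            unknown.add(tok)
            code = "UNKNOWN"
        stages.append(code)
    if unknown:
        warnings.warn(
            f"{path}: unrecognized stage tokens mapped to UNKNOWN: {sorted(unknown)}",
            stacklevel=2,
        )
    return Hypnogram(stages=np.array(stages, dtype=object), epoch_s=epoch_s)


def write_hypnogram(path: str | os.PathLike, hyp: Hypnogram) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(str(s) for s in hyp.stages) + "\n")


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------


def validate_event_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check schema and interval validity of an event table; returns it unchanged."""
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"event table missing required columns: {missing}")
    if len(table):
        req = table[list(EVENT_COLUMNS)]
        if req.isna().any().any():
            rows = table.index[req.isna().any(axis=1)].tolist()
            raise ValueError(f"NaN in required event-table columns at rows {rows[:5]}")
        bad = table.index[~(table["start_s"] < table["end_s"])].tolist()
        if bad:
            raise ValueError(f"start_s >= end_s at rows {bad[:5]}")
        neg = table.index[table["start_s"] < 0].tolist()
        if neg:
            raise ValueError(f"negative start_s at rows {neg[:5]}")
    return table


def read_event_table(path: str | os.PathLike) -> pd.DataFrame:
    table = pd.read_csv(path, float_precision="round_trip")
    return validate_event_table(table)


def write_event_table(path: str | os.PathLike, table: pd.DataFrame) -> None:
    validate_event_table(table)
    table.to_csv(path, index=False)


def events_to_table(
    starts: np.ndarray,
    ends: np.ndarray,
    method: str,
    subject: str = "s0",
    night: int = 1,
    **extra_columns,
) -> pd.DataFrame:
    """Assemble parallel arrays of event bounds into a validated event table."""
    table = pd.DataFrame(
        {
            "start_s": np.asarray(starts, dtype=float),
            "end_s": np.asarray(ends, dtype=float),
            "method": method,
            "subject": subject,
            "night": night,
            **extra_columns,
        }
    )
    return validate_event_table(table)


def load_config(path: str | os.PathLike) -> dict:
    """Load a YAML pipeline-parameter file (empty file -> empty dict)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
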