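"""Synthetic sleep-EEG generator with ground truth.

Produces a single-channel recording of pink-noise background with
stage-dependent slow activity, transient sigma-range (10-16 Hz) bursts
placed by a Poisson process during N2, occasional high-amplitude
broadband artifacts, a stage schedule, and an exact ground-truth event
table.  Burst envelope amplitudes follow a two-component (nested) model:
a high-amplitude subset (one third by default) mimics traditional
spindles while the remainder only stands out in the time-frequency
domain.  A continuous lognormal envelope mode is available for
distribution-shape tests.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal.windows import tukey

from tfspindle.io import (
    Hypnogram,
    Recording,
    events_to_table,
    write_edf,
    write_event_table,
    write_hypnogram,
)

__all__ = ["SynthConfig", "GroundTruth", "generate", "write_fixture", "stage_schedule"]


@dataclass
class SynthConfig:
    fs: float = 100.0
    duration_min: float = 30.0
    burst_rate_per_min: float = 10.0  # during N2
    frac_high_amp: float = 1.0 / 3.0
    freq_mean: float = 13.0
    freq_sd: float = 1.0  # truncated to [10, 16]
    dur_lognorm_mu: float = float(np.log(1.2))  # log-seconds
    dur_lognorm_sigma: float = 0.4  # truncated to [0.3, 3]
    burst_taper: float = 0.8  # tapered-cosine envelope shape parameter
    amp_low: float = 36.0  # uV envelope peak, low-amplitude component
    amp_high: float = 108.0  # uV envelope peak, high-amplitude component
    background: float = 15.0  # pink-noise SD, uV
    so_amp: float = 40.0  # 0.8 Hz slow-oscillation amplitude in N2/N3, uV
    artifact_rate_per_hour: float = 2.0
    artifact_amp: float = 500.0  # uV
    artifact_dur_s: float = 0.5
    min_gap_s: float = 0.5  # minimum gap between bursts
    amp_mode: str = "nested"  # "nested" (two-component) or "continuum" (lognormal)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.frac_high_amp <= 1:
            raise ValueError("frac_high_amp must be in [0, 1]")
        for name in ("burst_rate_per_min", "amp_low", "amp_high", "background", "artifact_rate_per_hour"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.amp_mode not in ("nested", "continuum"):
            raise ValueError("amp_mode must be 'nested' or 'continuum'")


@dataclass
class GroundTruth:
    events: pd.DataFrame  # true bursts, with frequency/amplitude columns
    artifacts: np.ndarray  # (n, 2) [start_s, end_s)
    hypnogram: Hypnogram


def stage_schedule(duration_min: float, epoch_s: float = 30.0) -> Hypnogram:
    """Default mostly-N2 schedule: 2 min W, 1 min N1, then cycles of
    10 min N2 / 4 min N3, trimmed to the requested duration."""
    epochs_per_min = 60.0 / epoch_s
    stages: list[str] = []
    stages += ["W"] * int(2 * epochs_per_min)
    stages += ["N1"] * int(1 * epochs_per_min)
    while len(stages) < duration_min * epochs_per_min:
        stages += ["N2"] * int(10 * epochs_per_min)
        stages += ["N3"] * int(4 * epochs_per_min)
    n_epochs = int(np.ceil(duration_min * epochs_per_min))
    return Hypnogram(stages=np.array(stages[:n_epochs], dtype=object), epoch_s=epoch_s)


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f (power) noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shaping = np.ones_like(f)
    shaping[1:] = 1.0 / np.sqrt(f[1:])
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n)
    return x / x.std()


def _n2_runs(hyp: Hypnogram) -> np.ndarray:
    """Maximal N2 runs as (n, 2) [start_s, end_s)."""
    flags = np.r_[0, (hyp.stages == "N2").astype(np.int8), 0]
    edges = np.flatnonzero(np.diff(flags))
    return edges.reshape(-1, 2) * hyp.epoch_s


def _place_bursts(
    runs: np.ndarray, cfg: SynthConfig, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Poisson placement within N2 runs, rejecting overlaps/gaps < min_gap_s."""
    n2_minutes = float(np.sum(runs[:, 1] - runs[:, 0])) / 60.0
    n_target = rng.poisson(cfg.burst_rate_per_min * n2_minutes)
    placed: list[tuple[float, float]] = []
    run_lens = runs[:, 1] - runs[:, 0]
    weights = run_lens / run_lens.sum()
    attempts = 0
    while len(placed) < n_target and attempts < 50 * max(n_target, 1):
        attempts += 1
        dur = float(
            np.clip(rng.lognormal(cfg.dur_lognorm_mu, cfg.dur_lognorm_sigma), 0.3, 3.0)
        )
        r = runs[rng.choice(len(runs), p=weights)]
        if r[1] - r[0] <= dur + 1.0:
            continue
        start = float(rng.uniform(r[0] + 0.5, r[1] - dur - 0.5))
        if all(
            start - (s + d) >= cfg.min_gap_s or s - (start + dur) >= cfg.min_gap_s
            for s, d in ((a, b - a) for a, b in placed)
        ):
            placed.append((start, start + dur))
    if len(placed) < n_target and n_target > 0 and len(placed) < 0.5 * n_target:
        raise ValueError(
            f"could only place {len(placed)}/{n_target} bursts; "
            "burst density too high for the N2 time available"
        )
    placed.sort()
    return placed


def generate(config: SynthConfig | None = None) -> tuple[Recording, GroundTruth]:
    """Generate a synthetic recording and its ground truth."""
    cfg = config or SynthConfig()
    if cfg.duration_min < 5:
        raise ValueError("duration must be at least 5 minutes")
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs
    n = int(round(cfg.duration_min * 60 * fs))
    t = np.arange(n) / fs
    hyp = stage_schedule(cfg.duration_min)

    x = cfg.background * _pink_noise(n, rng)
    nrem = hyp.sample_mask("N2", fs, n) | hyp.sample_mask("N3", fs, n)
    x += cfg.so_amp * np.sin(2 * np.pi * 0.8 * t + rng.uniform(0, 2 * np.pi)) * nrem

    runs = _n2_runs(hyp)
    bursts = _place_bursts(runs, cfg, rng) if runs.size else []
    rows = []
    for start, end in bursts:
        dur = end - start
        freq = float(np.clip(rng.normal(cfg.freq_mean, cfg.freq_sd), 10.0, 16.0))
        if cfg.amp_mode == "nested":
            is_high = rng.random() < cfg.frac_high_amp
            amp = cfg.amp_high if is_high else cfg.amp_low
            component = "high" if is_high else "low"
        else:  # continuous lognormal envelope spread
            amp = float(
                cfg.amp_low * np.exp(rng.normal(0.0, np.log(cfg.amp_high / cfg.amp_low) / 2))
            )
            component = "high" if amp >= np.sqrt(cfg.amp_low * cfg.amp_high) else "low"
        i0, i1 = int(round(start * fs)), int(round(end * fs))
        seg_t = t[i0:i1] - start
        envelope = tukey(i1 - i0, alpha=cfg.burst_taper)
        phase = rng.uniform(0, 2 * np.pi)
        x[i0:i1] += amp * envelope * np.sin(2 * np.pi * freq * seg_t + phase)
        rows.append(
            {
                "start_s": start,
                "end_s": end,
                "method": "truth",
                "subject": f"synth{cfg.seed}",
                "night": 1,
                "central_freq_hz": freq,
                "duration_s": dur,
                "amplitude_uv": amp,
                "component": component,
            }
        )
    events = (
        pd.DataFrame(rows)
        if rows
        else events_to_table(np.array([]), np.array([]), "truth", f"synth{cfg.seed}", 1)
    )

    # broadband artifact transients, kept clear of the bursts
    hours = cfg.duration_min / 60.0
    n_art = rng.poisson(cfg.artifact_rate_per_hour * hours)
    art_list: list[tuple[float, float]] = []
    guard = 0
    while len(art_list) < n_art and guard < 100 * max(n_art, 1):
        guard += 1
        start = float(rng.uniform(1.0, cfg.duration_min * 60 - cfg.artifact_dur_s - 1.0))
        end = start + cfg.artifact_dur_s
        if any(s < end + 1.0 and start < e + 1.0 for s, e in bursts):
            continue
        if any(s < end + 1.0 and start < e + 1.0 for s, e in art_list):
            continue
        i0, i1 = int(round(start * fs)), int(round(end * fs))
        x[i0:i1] += cfg.artifact_amp * rng.standard_normal(i1 - i0)
        art_list.append((start, end))
    artifacts = np.array(sorted(art_list)).reshape(-1, 2)

    rec = Recording(samples=x, fs=fs, channel="SYNTH")
    return rec, GroundTruth(events=events, artifacts=artifacts, hypnogram=hyp)


def write_fixture(rec: Recording, truth: GroundTruth, out_dir: str | os.PathLike) -> dict:
    """Write the fixture files (EDF signal, hypnogram text, truth CSV).

    Returns the mapping of roles to paths.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "edf": os.path.join(out_dir, "synthetic.edf"),
        "hypnogram": os.path.join(out_dir, "hypnogram.txt"),
        "events": os.path.join(out_dir, "ground_truth.csv"),
        "artifacts": os.path.join(out_dir, "artifacts.csv"),
    }
    write_edf(paths["edf"], rec)
    write_hypnogram(paths["hypnogram"], truth.hypnogram)
    write_event_table(paths["events"], truth.events)
    pd.DataFrame(truth.artifacts, columns=["start_s", "end_s"]).to_csv(
        paths["artifacts"], index=False
    )
    return paths
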