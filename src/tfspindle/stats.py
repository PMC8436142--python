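"""Comparison statistics for detected event sets.

Implements the event-based confusion-matrix semantics (asymmetric TP
counting: detector-side for precision, reference-side for recall, no
minimal overlap requirement), intersection-over-union overlap
percentages on the sample grid, paired t-tests on per-subject property
medians, bin-wise signed-rank tests on modified-z-scored properties,
trough-aligned aggregate event spectrograms, and night-to-night rate
stability with robust regression and a permutation test on the
difference of Pearson correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

from tfspindle.artifact import ArtifactMask
from tfspindle.io import Hypnogram, PROPERTY_COLUMNS, Recording, validate_event_table
from tfspindle.multitaper import Spectrogram

__all__ = [
    "ConfusionStats",
    "BinwiseResult",
    "StabilityResult",
    "select_events",
    "match_events",
    "f1_score",
    "median_property_tests",
    "binwise_rate_tests",
    "aggregate_event_spectrogram",
    "night_stability",
    "BIN_EDGES",
]

#: modified-z bin edges: width-1 bins centered at -2..2 with open-ended extremes
BIN_EDGES = np.array([-np.inf, -2.5, -1.5, -0.5, 0.5, 1.5, 2.5, np.inf])


@dataclass
class ConfusionStats:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    mean_overlap_pct: float


@dataclass
class BinwiseResult:
    bin_edges: np.ndarray
    rates_a: pd.DataFrame  # subject x bin, events/min
    rates_b: pd.DataFrame
    p_values: np.ndarray  # per bin, two-sided signed-rank across subjects


@dataclass
class StabilityResult:
    rates: pd.DataFrame  # subject x night x method
    rho: dict  # method -> cross-night Pearson correlation
    slope: dict  # method -> robust regression slope
    slope_ci95: dict  # method -> (lo, hi)
    observed_delta_rho: float
    perm_p: float
    n_perm: int


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when degenerate."""
    if not (np.isfinite(precision) and np.isfinite(recall)) or precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


# ---------------------------------------------------------------------------
# Event selection
# ---------------------------------------------------------------------------


def select_events(
    events: pd.DataFrame,
    hyp: Hypnogram,
    mask: ArtifactMask | None = None,
    f_range: tuple[float, float] = (10.0, 16.0),
    buffer_s: float = 3.0,
    fs: float | None = None,
) -> pd.DataFrame:
    """Keep events inside clean N2, away from artifacts/stage boundaries.

    An event survives when every sample within ``buffer_s`` of
    ``[start_s, end_s)`` is N2 and artifact free (samples beyond the
    recording edges count as bad, to avoid clipped events), and -- when a
    ``central_freq_hz`` column is present -- its central frequency lies
    inside ``f_range``.
    """
    validate_event_table(events)
    if fs is None:
        if mask is None:
            raise ValueError("pass fs explicitly when no artifact mask is given")
        fs = mask.fs
    n = mask.mask.size if mask is not None else int(round(hyp.duration_s * fs))
    good = hyp.sample_mask("N2", fs, n)
    if mask is not None:
        good &= ~mask.mask
    keep = []
    for idx, row in events.iterrows():
        lo = int(np.floor((row["start_s"] - buffer_s) * fs))
        hi = int(np.ceil((row["end_s"] + buffer_s) * fs))
        if lo < 0 or hi > n:
            keep.append(False)
            continue
        ok = bool(good[lo:hi].all())
        if ok and "central_freq_hz" in events.columns and np.isfinite(row.get("central_freq_hz", np.nan)):
            ok = f_range[0] <= row["central_freq_hz"] <= f_range[1]
        keep.append(ok)
    return events.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Confusion statistics
# ---------------------------------------------------------------------------


def _overlap_matrix(ref: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Boolean (n_other, n_ref) half-open interval overlap, chunked."""
    out = np.zeros((len(other), len(ref)), dtype=bool)
    chunk = max(1, 10_000_000 // max(1, len(ref)))
    for lo in range(0, len(other), chunk):
        o = other[lo : lo + chunk]
        out[lo : lo + chunk] = (o[:, None, 0] < ref[None, :, 1]) & (
            o[:, None, 1] > ref[None, :, 0]
        )
    return out


def _iou_pct(event: np.ndarray, refs: np.ndarray, fs: float | None) -> float:
    """Intersection-over-union (%) of one event against the union of the
    reference intervals it overlaps, counted on the sample grid when fs
    is given."""

    def to_samples(iv: np.ndarray) -> np.ndarray:
        if fs is None:
            return iv
        return np.round(iv * fs)

    e = to_samples(event)
    r = to_samples(refs)
    r = r[np.argsort(r[:, 0])]
    inter = sum(max(0.0, min(e[1], b) - max(e[0], a)) for a, b in r)
    # union length: event plus non-overlapping parts of the refs
    merged = [list(e)]
    for a, b in r:
        placed = False
        for seg in merged:
            if a <= seg[1] and b >= seg[0]:
                seg[0], seg[1] = min(seg[0], a), max(seg[1], b)
                placed = True
                break
        if not placed:
            merged.append([a, b])
    # merge any segments that became adjacent
    merged.sort()
    union = 0.0
    cur_lo, cur_hi = merged[0]
    for a, b in merged[1:]:
        if a <= cur_hi:
            cur_hi = max(cur_hi, b)
        else:
            union += cur_hi - cur_lo
            cur_lo, cur_hi = a, b
    union += cur_hi - cur_lo
    return 100.0 * inter / union if union > 0 else 0.0


def match_events(
    reference: pd.DataFrame, other: pd.DataFrame, fs: float | None = None
) -> ConfusionStats:
    """Event-based confusion statistics of ``other`` against ``reference``.

    TP counting is asymmetric, with no minimal overlap requirement:

    * detector side -- every ``other`` event overlapping at least one
      reference event is one TP (several detections on one reference each
      count; one detection spanning several references counts once);
      FP = detections with no overlap; precision = TP / (TP + FP).
    * reference side -- FN = reference events with no overlapping
      detection; recall = (overlapped references) / (all references).

    ``mean_overlap_pct`` averages, over TP detections, the
    intersection-over-union with the overlapped reference intervals,
    counted in samples at ``fs`` when given (else in continuous time).
    With no detections precision is NaN and F1 is 0.
    """
    if reference is None or len(reference) == 0:
        raise ValueError("reference event table is empty")
    ref = reference[["start_s", "end_s"]].to_numpy(dtype=float)
    oth = other[["start_s", "end_s"]].to_numpy(dtype=float) if len(other) else np.empty((0, 2))
    n_ref = len(ref)
    if len(oth) == 0:
        return ConfusionStats(
            tp=0, fp=0, fn=n_ref, precision=np.nan, recall=0.0, f1=0.0,
            mean_overlap_pct=np.nan,
        )
    ov = _overlap_matrix(ref, oth)
    det_hit = ov.any(axis=1)
    ref_hit = ov.any(axis=0)
    tp = int(det_hit.sum())
    fp = int((~det_hit).sum())
    fn = int((~ref_hit).sum())
    precision = tp / (tp + fp) if tp + fp > 0 else np.nan
    recall = float(ref_hit.sum()) / n_ref
    overlaps = [
        _iou_pct(oth[i], ref[ov[i]], fs) for i in np.flatnonzero(det_hit)
    ]
    return ConfusionStats(
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        f1=f1_score(precision, recall),
        mean_overlap_pct=float(np.mean(overlaps)) if overlaps else np.nan,
    )


# ---------------------------------------------------------------------------
# Property tests
# ---------------------------------------------------------------------------


def median_property_tests(
    events_a: pd.DataFrame,
    events_b: pd.DataFrame,
    properties: tuple[str, ...] = PROPERTY_COLUMNS,
) -> pd.DataFrame:
    """Paired t-tests across subjects on per-subject property medians.

    Effect size is the mean of the paired median differences (b minus a).
    Returns a DataFrame indexed by property with columns ``t``, ``p``,
    ``effect`` and ``n_subjects``.
    """
    subjects = sorted(set(events_a["subject"]) | set(events_b["subject"]))
    only_a = set(events_a["subject"]) - set(events_b["subject"])
    only_b = set(events_b["subject"]) - set(events_a["subject"])
    if only_a or only_b:
        raise ValueError(
            f"subjects present in only one table: {sorted(only_a | only_b)}"
        )
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects for a paired t-test")
    if len(subjects) == 2:
        import warnings

        warnings.warn("only 2 subjects: paired t-test has 1 degree of freedom", stacklevel=2)
    rows = {}
    med_a = events_a.groupby("subject")[list(properties)].median()
    med_b = events_b.groupby("subject")[list(properties)].median()
    for prop in properties:
        diffs = (med_b[prop] - med_a[prop]).loc[subjects].to_numpy(dtype=float)
        if np.allclose(diffs, 0):
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_rel(med_b[prop].loc[subjects], med_a[prop].loc[subjects])
        rows[prop] = {"t": float(t), "p": float(p), "effect": float(diffs.mean()), "n_subjects": len(subjects)}
    return pd.DataFrame(rows).T


def binwise_rate_tests(
    events_a: pd.DataFrame,
    events_b: pd.DataFrame,
    anchor: str,
    n2_minutes: dict,
    prop: str = "prominence_db",
) -> BinwiseResult:
    """Bin-wise rate comparison on modified-z-scored property values.

    Per subject the anchoring center/scale are the median and SD of the
    ``anchor`` method's events (``anchor`` must be the method tag of
    ``events_a`` or ``events_b``).  Both methods' property values are
    z-scored as (x - median)/SD, binned into the seven fixed bins, and
    counts are divided by that subject's N2 minutes.  A two-sided
    Wilcoxon signed-rank test across subjects compares the two methods'
    rates per bin (p = 1 for all-zero differences).
    """
    anchor_tab = events_a if (events_a["method"] == anchor).all() else events_b
    if not (anchor_tab["method"] == anchor).all():
        raise ValueError(f"anchor method {anchor!r} does not match either table")
    subjects = sorted(set(events_a["subject"]) | set(events_b["subject"]))
    rates_a = np.zeros((len(subjects), 7))
    rates_b = np.zeros((len(subjects), 7))
    for i, subj in enumerate(subjects):
        anchor_vals = anchor_tab.loc[anchor_tab["subject"] == subj, prop].to_numpy(dtype=float)
        if anchor_vals.size == 0:
            raise ValueError(f"anchor method has no events for subject {subj!r}")
        center = np.median(anchor_vals)
        scale = anchor_vals.std()
        if scale == 0:
            raise ValueError(f"zero SD for subject {subj!r} anchor events")
        minutes = float(n2_minutes[subj])
        for rates, tab in ((rates_a, events_a), (rates_b, events_b)):
            vals = tab.loc[tab["subject"] == subj, prop].to_numpy(dtype=float)
            z = (vals - center) / scale
            counts, _ = np.histogram(z, bins=BIN_EDGES)
            rates[i] = counts / minutes
    p_values = np.ones(7)
    for b in range(7):
        diff = rates_a[:, b] - rates_b[:, b]
        if np.allclose(diff, 0):
            p_values[b] = 1.0
        else:
            p_values[b] = sps.wilcoxon(diff, alternative="two-sided").pvalue
    return BinwiseResult(
        bin_edges=BIN_EDGES.copy(),
        rates_a=pd.DataFrame(rates_a, index=subjects),
        rates_b=pd.DataFrame(rates_b, index=subjects),
        p_values=p_values,
    )


# ---------------------------------------------------------------------------
# Aggregate event spectrograms
# ---------------------------------------------------------------------------


def aggregate_event_spectrogram(
    rec: Recording,
    events: pd.DataFrame,
    spec: Spectrogram,
    half_window_s: float = 1.5,
    f_range: tuple[float, float] = (10.0, 16.0),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Trough-aligned element-wise median spectrogram of events, in dB.

    Each event is aligned on the minimum of the band-passed (10-16 Hz)
    time-domain signal within its interval; the spectrogram columns
    within ``+-half_window_s`` of the trough are collected and the
    element-wise median across events is converted to dB.  Events whose
    window falls outside the spectrogram are dropped with a warning.

    Returns (rel_times, freqs, median_db).
    """
    import warnings

    from scipy.signal import butter, sosfiltfilt

    if len(events) == 0:
        raise ValueError("no events to aggregate")
    sos = butter(4, f_range, btype="bandpass", fs=rec.fs, output="sos")
    filtered = sosfiltfilt(sos, rec.samples)
    k = int(round(half_window_s / spec.step_s))
    windows = []
    for _, row in events.iterrows():
        lo = int(np.floor((row["start_s"] - rec.t0) * rec.fs))
        hi = int(np.ceil((row["end_s"] - rec.t0) * rec.fs))
        lo, hi = max(lo, 0), min(hi, rec.samples.size)
        trough_t = rec.t0 + (lo + int(np.argmin(filtered[lo:hi]))) / rec.fs
        c = int(np.argmin(np.abs(spec.times - trough_t)))
        if c - k < 0 or c + k >= len(spec.times):
            warnings.warn(
                f"event at {row['start_s']:.1f} s too close to the record edge; dropped",
                stacklevel=2,
            )
            continue
        windows.append(spec.power[c - k : c + k + 1])
    if not windows:
        raise ValueError("all events fell too close to the record edges")
    median = np.median(np.stack(windows), axis=0)
    rel_times = np.arange(-k, k + 1) * spec.step_s
    return rel_times, spec.freqs.copy(), 10.0 * np.log10(np.maximum(median, 1e-30))


# ---------------------------------------------------------------------------
# Night-to-night stability
# ---------------------------------------------------------------------------


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of two (m, n) arrays."""
    xc = x - x.mean(axis=-1, keepdims=True)
    yc = y - y.mean(axis=-1, keepdims=True)
    num = (xc * yc).sum(axis=-1)
    den = np.sqrt((xc**2).sum(axis=-1) * (yc**2).sum(axis=-1))
    return num / den


def _robust_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, tuple[float, float]]:
    """IRLS line fit with bisquare weights (tuning constant 4.685)."""
    model = sm.RLM(y, sm.add_constant(x), M=sm.robust.norms.TukeyBiweight(c=4.685))
    fit = model.fit()
    slope = float(fit.params[1])
    ci = fit.conf_int(alpha=0.05)
    return slope, (float(ci[1][0]), float(ci[1][1]))


def night_stability(
    rates: pd.DataFrame,
    method_a: str,
    method_b: str,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> StabilityResult:
    """Cross-night rate stability of two methods with a permutation test.

    ``rates`` must have columns ``subject``, ``night`` (two values) and
    one rate column per comparison, in long form with columns
    ``subject``, ``night``, ``method``, ``rate``.  Per method the Pearson
    correlation between night-1 and night-2 rates and a robust (bisquare)
    regression slope with 95% CI are computed.  The permutation test
    z-scores the rates within each method, takes the observed
    ``rho_a - rho_b``, and ``n_perm`` times swaps each subject's pair of
    z-scored rates between the methods; ``perm_p`` is the one-sided
    fraction of null differences >= the observed one.
    """
    for col in ("subject", "night", "method", "rate"):
        if col not in rates.columns:
            raise ValueError(f"rates table missing column {col!r}")
    nights = sorted(rates["night"].unique())
    if len(nights) != 2:
        raise ValueError(f"need exactly 2 nights, got {nights}")
    wide = rates.pivot_table(index="subject", columns=["method", "night"], values="rate")
    for m in (method_a, method_b):
        for nt in nights:
            if (m, nt) not in wide.columns or wide[(m, nt)].isna().any():
                raise ValueError(f"missing rates for method {m!r}, night {nt!r}")
    subjects = wide.index.to_numpy()
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects to correlate")

    rho, slope, slope_ci = {}, {}, {}
    pairs = {}
    for m in (method_a, method_b):
        x = wide[(m, nights[0])].to_numpy(dtype=float)
        y = wide[(m, nights[1])].to_numpy(dtype=float)
        rho[m] = float(_pearson_rows(x[None], y[None])[0])
        slope[m], slope_ci[m] = _robust_slope(x, y)
        pooled = np.r_[x, y]
        mu, sd = pooled.mean(), pooled.std()
        if sd == 0:
            raise ValueError(f"zero rate variance for method {m!r}")
        pairs[m] = np.c_[(x - mu) / sd, (y - mu) / sd]  # (n_subj, 2), z-scored

    observed = rho[method_a] - rho[method_b]
    rng = np.random.default_rng(seed)
    a, b = pairs[method_a], pairs[method_b]
    swap = rng.random((n_perm, len(subjects))) < 0.5
    a1 = np.where(swap, b[:, 0], a[:, 0])
    a2 = np.where(swap, b[:, 1], a[:, 1])
    b1 = np.where(swap, a[:, 0], b[:, 0])
    b2 = np.where(swap, a[:, 1], b[:, 1])
    null = _pearson_rows(a1, a2) - _pearson_rows(b1, b2)
    perm_p = float(np.mean(null >= observed))
    return StabilityResult(
        rates=wide,
        rho=rho,
        slope=slope,
        slope_ci95=slope_ci,
        observed_delta_rho=observed,
        perm_p=perm_p,
        n_perm=n_perm,
    )
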