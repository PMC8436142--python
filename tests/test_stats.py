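import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tfspindle as tf
import tfspindle.stats as sts
from tfspindle.io import Hypnogram, Recording, events_to_table


def table(intervals, method="m", subject="s0", night=1, **extra):
    iv = np.asarray(intervals, dtype=float).reshape(-1, 2)
    return events_to_table(iv[:, 0], iv[:, 1], method, subject, night, **extra)


# ---------------------------------------------------------------------------
# f1
# ---------------------------------------------------------------------------


class TestF1:
    def test_worked_example_1(self):
        assert round(sts.f1_score(0.89, 0.43), 2) == 0.58

    def test_perfect(self):
        assert sts.f1_score(1.0, 1.0) == 1.0

    def test_worked_example_2(self):
        assert round(sts.f1_score(0.91, 0.90), 2) == 0.90

    def test_degenerate(self):
        assert sts.f1_score(0.0, 0.0) == 0.0
        assert sts.f1_score(np.nan, 0.5) == 0.0

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_bounds(self, p, r):
        f1 = sts.f1_score(p, r)
        assert f1 <= 2 * min(p, r) + 1e-12
        assert f1 <= max(p, r) + 1e-12


# ---------------------------------------------------------------------------
# match_events
# ---------------------------------------------------------------------------


def brute_match(ref, oth):
    """All-pairs overlap enumeration oracle."""
    ref, oth = np.asarray(ref, float), np.asarray(oth, float)
    ov = [[(o[0] < r[1] and o[1] > r[0]) for r in ref] for o in oth]
    tp = sum(any(row) for row in ov)
    fp = len(oth) - tp
    ref_hit = sum(any(ov[i][j] for i in range(len(oth))) for j in range(len(ref)))
    fn = len(ref) - ref_hit
    precision = tp / (tp + fp) if oth.size else np.nan
    recall = ref_hit / len(ref)
    return tp, fp, fn, precision, recall


class TestMatchEvents:
    def test_identical_lists(self):
        a = table([[0, 1], [2, 3], [5, 6]])
        cm = sts.match_events(a, a, fs=100.0)
        assert (cm.precision, cm.recall, cm.f1) == (1.0, 1.0, 1.0)
        assert cm.mean_overlap_pct == pytest.approx(100.0)

    def test_one_spanning_two_references(self):
        ref = table([[0, 1], [2, 3]])
        oth = table([[0.5, 2.5]])
        cm = sts.match_events(ref, oth, fs=100.0)
        assert (cm.tp, cm.fp, cm.fn) == (1, 0, 0)
        assert cm.precision == 1.0 and cm.recall == 1.0

    def test_two_on_one_reference(self):
        ref = table([[0, 1]])
        oth = table([[0.2, 0.6], [0.7, 1.4]])
        cm = sts.match_events(ref, oth, fs=100.0)
        assert (cm.tp, cm.fp) == (2, 0)
        assert cm.precision == 1.0 and cm.recall == 1.0

    def test_empty_other(self):
        cm = sts.match_events(table([[0, 1]]), table(np.empty((0, 2))))
        assert np.isnan(cm.precision)
        assert cm.f1 == 0.0 and cm.fn == 1

    def test_empty_reference_errors(self):
        with pytest.raises(ValueError, match="reference"):
            sts.match_events(table(np.empty((0, 2))), table([[0, 1]]))

    def test_overlap_pct_symmetric_one_to_one(self):
        a = table([[0.0, 1.0]])
        b = table([[0.25, 1.25]])
        ab = sts.match_events(a, b, fs=100.0).mean_overlap_pct
        ba = sts.match_events(b, a, fs=100.0).mean_overlap_pct
        assert ab == pytest.approx(ba)
        assert ab == pytest.approx(100 * 75 / 125, abs=1.5)

    @settings(max_examples=100, deadline=None)
    @given(st.data())
    def test_matches_brute_force(self, data):
        def intervals(n):
            starts = data.draw(
                st.lists(st.floats(0, 50), min_size=1, max_size=n)
            )
            return [[s, s + data.draw(st.floats(0.1, 5))] for s in starts]

        ref = table(intervals(30))
        oth = table(intervals(30))
        cm = sts.match_events(ref, oth)
        tp, fp, fn, precision, recall = brute_match(
            ref[["start_s", "end_s"]].to_numpy(), oth[["start_s", "end_s"]].to_numpy()
        )
        assert (cm.tp, cm.fp, cm.fn) == (tp, fp, fn)
        assert cm.precision == pytest.approx(precision)
        assert cm.recall == pytest.approx(recall)


# ---------------------------------------------------------------------------
# select_events
# ---------------------------------------------------------------------------


class TestSelectEvents:
    @pytest.fixture()
    def n2_hyp(self):
        return Hypnogram(stages=np.array(["N2"] * 10, dtype=object))  # 300 s

    def test_event_near_artifact_removed(self, n2_hyp):
        from tfspindle.artifact import ArtifactMask

        mask = np.zeros(300 * 100, dtype=bool)
        mask[100 * 100 : 101 * 100] = True  # artifact at 100-101 s
        am = ArtifactMask(mask=mask, fs=100.0)
        events = table([[96.0, 98.0], [110.0, 111.0]])
        kept = sts.select_events(events, n2_hyp, am)
        assert kept["start_s"].tolist() == [110.0]

    def test_low_central_freq_removed(self, n2_hyp):
        events = table([[100, 101], [110, 111]], central_freq_hz=[9.5, 13.0])
        kept = sts.select_events(events, n2_hyp, None, fs=100.0)
        assert kept["central_freq_hz"].tolist() == [13.0]

    def test_clean_n2_event_kept(self, n2_hyp):
        events = table([[100, 101]], central_freq_hz=[13.0])
        assert len(sts.select_events(events, n2_hyp, None, fs=100.0)) == 1

    def test_non_n2_removed(self):
        hyp = Hypnogram(stages=np.array(["N2"] * 5 + ["REM"] + ["N2"] * 4, dtype=object))
        events = table([[100, 101], [149, 150.5]])  # second is within 3 s of REM epoch
        kept = sts.select_events(events, hyp, None, fs=100.0)
        assert kept["start_s"].tolist() == [100.0]


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------


def property_table(rng, subjects, method, prom_shift=0.0):
    rows = []
    for s in subjects:
        n = 40
        starts = np.sort(rng.uniform(0, 1000, n))
        rows.append(
            events_to_table(
                starts, starts + 1.0, method, s, 1,
                prominence_db=rng.lognormal(2.0, 0.3, n) + prom_shift,
                duration_s=rng.uniform(0.3, 2.0, n),
                central_freq_hz=rng.uniform(10, 16, n),
                bandwidth_hz=rng.uniform(2, 5, n),
            )
        )
    return pd.concat(rows, ignore_index=True)


class TestMedianTests:
    def test_identical_tables(self, rng):
        a = property_table(rng, [f"s{i}" for i in range(4)], "a")
        res = sts.median_property_tests(a, a.assign(method="b"))
        assert (res["effect"] == 0).all()
        assert (res["p"] == 1).all()
        assert (res["t"] == 0).all()

    def test_constructed_shift(self, rng):
        subjects = [f"s{i}" for i in range(6)]
        a = property_table(rng, subjects, "a")
        b = a.assign(method="b", prominence_db=a["prominence_db"] + 3.0)
        res = sts.median_property_tests(a, b)
        assert res.loc["prominence_db", "effect"] == pytest.approx(3.0)
        assert res.loc["prominence_db", "p"] < 0.01
        assert res.loc["duration_s", "effect"] == 0.0

    def test_two_subjects_warns(self, rng):
        a = property_table(rng, ["s0", "s1"], "a")
        b = property_table(rng, ["s0", "s1"], "b")
        with pytest.warns(UserWarning, match="degree"):
            sts.median_property_tests(a, b)

    def test_unpaired_subject_errors(self, rng):
        a = property_table(rng, ["s0", "s1"], "a")
        b = property_table(rng, ["s0", "s2"], "b")
        with pytest.raises(ValueError, match="only one table"):
            sts.median_property_tests(a, b)


class TestBinwise:
    def test_identical_tables(self, rng):
        subjects = [f"s{i}" for i in range(5)]
        a = property_table(rng, subjects, "a")
        b = a.assign(method="b")
        res = sts.binwise_rate_tests(a, b, "a", {s: 60.0 for s in subjects})
        assert np.allclose(res.rates_a.values, res.rates_b.values)
        assert (res.p_values == 1.0).all()

    def test_enrichment_at_low_z(self, rng):
        subjects = [f"s{i}" for i in range(8)]
        a = property_table(rng, subjects, "a")
        extra = a.copy()
        extra["prominence_db"] = 0.1  # far below every subject's median
        b = pd.concat([a, extra], ignore_index=True).assign(method="b")
        res = sts.binwise_rate_tests(a, b, "a", {s: 60.0 for s in subjects})
        # significant difference only where the injected low-z events landed
        low_bins = res.p_values[:2]
        high_bins = res.p_values[4:]
        assert (res.rates_b.values.sum(axis=0) >= res.rates_a.values.sum(axis=0)).all()
        assert low_bins.min() < 0.05
        assert (high_bins > 0.05).all()

    def test_outer_bins_open_ended(self):
        z = np.array([-3.0, -2.6, 2.6, 9.0])
        counts, _ = np.histogram(z, bins=sts.BIN_EDGES)
        assert counts[0] == 2 and counts[-1] == 2

    def test_conservation(self, rng):
        subjects = ["s0", "s1", "s2"]
        a = property_table(rng, subjects, "a")
        b = property_table(rng, subjects, "b")
        res = sts.binwise_rate_tests(a, b, "a", {s: 60.0 for s in subjects})
        for s in subjects:
            n_events = (a["subject"] == s).sum()
            assert res.rates_a.loc[s].sum() * 60.0 == pytest.approx(n_events)

    def test_zero_scale_errors(self):
        a = table([[0, 1], [2, 3]], method="a", prominence_db=[5.0, 5.0],
                  duration_s=[1, 1], central_freq_hz=[13, 13], bandwidth_hz=[3, 3])
        b = a.assign(method="b")
        with pytest.raises(ValueError, match="zero SD"):
            sts.binwise_rate_tests(a, b, "a", {"s0": 60.0})


# ---------------------------------------------------------------------------
# aggregate event spectrograms
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def burst_record():
    fs = 100.0
    rng = np.random.default_rng(21)
    n = int(200 * fs)
    x = 1.0 * rng.standard_normal(n)
    t_burst = np.arange(int(1.0 * fs)) / fs
    starts = [20.0, 50.0, 80.0, 110.0, 140.0]
    for s in starts:
        i0 = int(s * fs)
        x[i0 : i0 + t_burst.size] += 20 * np.hanning(t_burst.size) * np.sin(
            2 * np.pi * 13 * t_burst
        )
    rec = Recording(samples=x, fs=fs)
    spec = tf.compute_spectrogram(rec)
    events = table([[s, s + 1.0] for s in starts])
    return rec, spec, events


class TestAggregate:
    def test_median_of_one(self, burst_record):
        rec, spec, events = burst_record
        rel, freqs, db = sts.aggregate_event_spectrogram(rec, events.iloc[:1], spec)
        assert db.shape == (len(rel), len(freqs))
        assert rel[0] == pytest.approx(-1.5) and rel[-1] == pytest.approx(1.5)

    def test_identical_bursts_peak_at_13(self, burst_record):
        rec, spec, events = burst_record
        rel, freqs, db = sts.aggregate_event_spectrogram(rec, events, spec)
        center = db[len(rel) // 2]
        band = (freqs >= 5) & (freqs <= 25)
        assert freqs[band][np.argmax(center[band])] == pytest.approx(13.0, abs=spec.df + 0.2)

    def test_median_robust_to_outlier_window(self, burst_record):
        rec, spec, events = burst_record
        _, _, db9 = sts.aggregate_event_spectrogram(rec, pd.concat([events] * 2, ignore_index=True).iloc[:9], spec)
        noisy = rec.samples.copy()
        noisy[int(170 * rec.fs) : int(172 * rec.fs)] = 500.0 * np.random.default_rng(0).standard_normal(int(2 * rec.fs))
        rec2 = Recording(samples=noisy, fs=rec.fs)
        spec2 = tf.compute_spectrogram(rec2)
        ev10 = pd.concat([events] * 2, ignore_index=True).iloc[:10].copy()
        ev10.iloc[-1, ev10.columns.get_loc("start_s")] = 170.5
        ev10.iloc[-1, ev10.columns.get_loc("end_s")] = 171.5
        _, _, db10 = sts.aggregate_event_spectrogram(rec2, ev10, spec2)
        sigma_band = (spec.freqs >= 10) & (spec.freqs <= 16)
        assert np.median(np.abs(db10[:, sigma_band] - db9[:, sigma_band])) < 0.5

    def test_edge_event_dropped(self, burst_record):
        rec, spec, events = burst_record
        edgy = pd.concat(
            [events, table([[0.2, 1.0]])], ignore_index=True
        )
        with pytest.warns(UserWarning, match="edge"):
            sts.aggregate_event_spectrogram(rec, edgy, spec)


# ---------------------------------------------------------------------------
# night-to-night stability
# ---------------------------------------------------------------------------


def rates_frame(rng, rho_a, rho_b, n=17):
    rows = []
    for m, rho in (("a", rho_a), ("b", rho_b)):
        xy = rng.multivariate_normal([10, 10], [[1, rho], [rho, 1]], size=n)
        for i in range(n):
            rows.append(dict(subject=f"s{i}", night=1, method=m, rate=xy[i, 0]))
            rows.append(dict(subject=f"s{i}", night=2, method=m, rate=xy[i, 1]))
    return pd.DataFrame(rows)


class TestStability:
    def test_identical_nights(self, rng):
        rows = []
        for m in ("a", "b"):
            vals = rng.uniform(5, 15, 10)
            for i, v in enumerate(vals):
                rows.append(dict(subject=f"s{i}", night=1, method=m, rate=v))
                rows.append(dict(subject=f"s{i}", night=2, method=m, rate=v))
        res = sts.night_stability(pd.DataFrame(rows), "a", "b", n_perm=200, seed=0)
        assert res.rho["a"] == pytest.approx(1.0)
        assert res.rho["b"] == pytest.approx(1.0)
        assert res.observed_delta_rho == pytest.approx(0.0, abs=1e-12)
        assert res.perm_p == pytest.approx(1.0)

    def test_perm_p_resolution(self, rng):
        res = sts.night_stability(rates_frame(rng, 0.9, 0.5), "a", "b", n_perm=10, seed=1)
        assert res.perm_p in np.round(np.arange(11) / 10, 10)

    def test_detects_strong_difference(self, rng):
        res = sts.night_stability(rates_frame(rng, 0.98, 0.3), "a", "b", n_perm=500, seed=2)
        assert res.rho["a"] > res.rho["b"]
        assert res.perm_p < 0.05

    def test_slope_recovers_identity(self, rng):
        rows = []
        x = rng.uniform(5, 15, 17)
        for m in ("a", "b"):
            for i, v in enumerate(x):
                rows.append(dict(subject=f"s{i}", night=1, method=m, rate=v))
                rows.append(dict(subject=f"s{i}", night=2, method=m, rate=v + rng.normal(0, 0.2)))
        res = sts.night_stability(pd.DataFrame(rows), "a", "b", n_perm=100, seed=0)
        for m in ("a", "b"):
            lo, hi = res.slope_ci95[m]
            assert res.slope[m] == pytest.approx(1.0, abs=0.1)
            assert lo < res.slope[m] < hi

    def test_too_few_subjects(self):
        rows = []
        for m in ("a", "b"):
            for i in range(2):
                rows.append(dict(subject=f"s{i}", night=1, method=m, rate=1.0 + i))
                rows.append(dict(subject=f"s{i}", night=2, method=m, rate=2.0 + i))
        with pytest.raises(ValueError, match="subjects"):
            sts.night_stability(pd.DataFrame(rows), "a", "b")

    def test_missing_night_errors(self, rng):
        frame = rates_frame(rng, 0.9, 0.9)
        frame = frame[~((frame.subject == "s0") & (frame.method == "a") & (frame.night == 2))]
        with pytest.raises(ValueError, match="missing"):
            sts.night_stability(frame, "a", "b")
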