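"""Catalog model, temporal analytics and their brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from rumblekit import catalog as cat
from rumblekit import sigproc, synth
from rumblekit.catalog import (
    Catalog,
    EventPick,
    IntervalHistogram,
    Rumble,
    activity_series,
    estimate_event_features,
    group_events_to_rumbles,
    histogram_similarity,
    hourly_activity_profile,
    interval_histogram,
    label_motion,
    match_cross_domain,
    noise_profile,
)
from rumblekit.trace import Trace


def _catalog(starts, freqs=None, durs=None, domain="seismic"):
    starts = list(starts)
    freqs = freqs or [15.0] * len(starts)
    durs = durs or [4.0] * len(starts)
    return Catalog(
        [
            Rumble([EventPick(t, f, d, domain=domain)])
            for t, f, d in zip(starts, freqs, durs)
        ],
        domain=domain,
    )


# ----------------------------------------------------------------------
# brute-force oracles (kept deliberately naive and independent)


def oracle_interval_hist(starts):
    edges = [0, 5, 10, 30, 60, 120]
    counts = [0] * 6
    starts = sorted(starts)
    for i, t in enumerate(starts):
        if i == len(starts) - 1:
            counts[5] += 1
            continue
        gap = starts[i + 1] - t
        b = 5
        for j in range(6):
            hi = edges[j + 1] if j < 5 else float("inf")
            if edges[j] <= gap < hi:
                b = j
                break
        counts[b] += 1
    return counts


def oracle_motion(starts, durs, feet, half=50.0):
    out = []
    for t, d in zip(starts, durs):
        hit = any(t - half <= f <= t + d + half for f in feet)
        out.append("yes" if hit else "no")
    return out


def oracle_max_matching(ts, fs_, ti, fi, t_tol, f_tol):
    """Exhaustive maximum bipartite matching by recursion (tiny n only)."""
    edges = [
        [j for j in range(len(ti))
         if abs(ts[i] - ti[j]) <= t_tol and abs(fs_[i] - fi[j]) <= f_tol]
        for i in range(len(ts))
    ]

    def best(i, used):
        if i == len(edges):
            return 0
        top = best(i + 1, used)
        for j in edges[i]:
            if not used & (1 << j):
                top = max(top, 1 + best(i + 1, used | (1 << j)))
        return top

    return best(0, 0)


# ----------------------------------------------------------------------


class TestGrouping:
    def test_fundamental_and_two_harmonics_merge(self):
        events = [
            EventPick(0.0, 15.0, 4.0),
            EventPick(0.0, 30.0, 4.0),
            EventPick(0.0, 45.0, 4.0),
        ]
        out = group_events_to_rumbles(events)
        assert len(out) == 1
        assert len(out.rumbles[0].events) == 3
        assert out.rumbles[0].fundamental_frequency == 15.0

    def test_single_event_is_singleton(self):
        out = group_events_to_rumbles([EventPick(10.0, 18.0, 3.0)])
        assert len(out) == 1
        assert out.rumbles[0].fundamental_frequency == 18.0

    def test_disjoint_times_stay_separate(self):
        events = [EventPick(0.0, 15.0, 4.0), EventPick(300.0, 15.0, 4.0)]
        assert len(group_events_to_rumbles(events)) == 2

    def test_non_harmonic_overlap_stays_separate(self):
        events = [EventPick(0.0, 15.0, 4.0), EventPick(1.0, 22.0, 4.0)]
        assert len(group_events_to_rumbles(events)) == 2


class TestIntervalHistogram:
    def test_two_close_starts(self):
        h = interval_histogram(_catalog([0.0, 3.0]))
        assert h.counts.tolist() == [1, 0, 0, 0, 0, 1]

    def test_gap_in_second_bin(self):
        h = interval_histogram(_catalog([0.0, 7.0]))
        assert h.counts.tolist() == [0, 1, 0, 0, 0, 1]

    def test_empty_catalog(self):
        h = interval_histogram(Catalog([]))
        assert h.counts.sum() == 0

    def test_matches_oracle_on_random_catalogs(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            starts = np.sort(rng.uniform(0, 600, size=rng.integers(1, 30)))
            got = interval_histogram(_catalog(starts)).counts.tolist()
            assert got == oracle_interval_hist(starts)
            assert sum(got) == len(starts)


class TestMotionLabels:
    def test_footfall_inside_window(self):
        c = label_motion(_catalog([100.0], durs=[4.0]), [130.0])
        assert c.rumbles[0].motion_label == "yes"

    def test_footfall_outside_window(self):
        c = label_motion(_catalog([100.0], durs=[4.0]), [160.0])
        assert c.rumbles[0].motion_label == "no"

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = rng.integers(1, 20)
            starts = np.sort(rng.uniform(0, 2000, n))
            durs = rng.uniform(1, 8, n)
            feet = rng.uniform(0, 2000, rng.integers(0, 15))
            c = Catalog([Rumble([EventPick(t, 15.0, d)]) for t, d in zip(starts, durs)])
            got = [r.motion_label for r in label_motion(c, feet).rumbles]
            assert got == oracle_motion(starts, durs, feet)

    def test_invariant_to_footfall_permutation(self):
        starts = [10.0, 200.0, 900.0]
        feet = [5.0, 260.0, 1100.0]
        a = [r.motion_label for r in label_motion(_catalog(starts), feet).rumbles]
        b = [r.motion_label for r in label_motion(_catalog(starts), feet[::-1]).rumbles]
        assert a == b


class TestActivity:
    def test_counts_per_bin_and_conservation(self):
        c = _catalog([100.0, 200.0, 300.0, 8000.0])
        df = activity_series(c, 7200.0, duration=14400.0)
        assert df["count"].tolist() == [3, 1]
        assert df["count"].sum() == len(c)

    def test_empty_catalog_zeros(self):
        df = activity_series(Catalog([]), 3600.0, duration=7200.0)
        assert df["count"].sum() == 0

    def test_hourly_profile_places_counts_at_clock_hour(self):
        c = Catalog(
            [Rumble([EventPick(3 * 3600.0 + 60.0 * k, 15.0, 4.0)]) for k in range(4)],
            epoch=pd.Timestamp("2024-08-02 00:00:00"),
        )
        prof = hourly_activity_profile(c, n_days=1)
        assert prof.loc[prof.hour == 3, "mean_count"].iloc[0] == 4
        assert prof["mean_count"].sum() == 4


class TestNoiseProfile:
    def test_sine_rms_closed_form(self):
        fs = 200.0
        t = np.arange(int(7200 * fs)) / fs
        tr = Trace(np.sin(2 * np.pi * 30.0 * t), fs)
        prof = noise_profile(tr, window=3600.0)
        assert len(prof) == 2
        assert prof["rms"].iloc[0] == pytest.approx(1 / np.sqrt(2), rel=0.01)

    def test_zero_trace(self):
        tr = Trace(np.zeros(int(3600 * 200)) + 0.0, 200.0)
        assert noise_profile(tr)["rms"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            noise_profile(Trace(np.ones(100), 200.0))


class TestCrossDomainMatching:
    def test_identical_catalogs_fully_matched(self):
        a = _catalog([10.0, 50.0, 90.0], domain="seismic")
        b = _catalog([10.0, 50.0, 90.0], domain="infrasound")
        res = match_cross_domain(a, b)
        assert res.n_matched == 3
        assert res.n_seismic_only == res.n_infrasound_only == 0

    def test_disjoint_supports_unmatched(self):
        a = _catalog([10.0, 20.0])
        b = _catalog([500.0, 600.0], domain="infrasound")
        assert match_cross_domain(a, b).n_matched == 0

    def test_greedy_trap_resolved_optimally(self):
        """Configuration where nearest-first greedy matching would find one
        pair; the optimal assignment finds two."""
        a = _catalog([1.0, 2.0])
        b = _catalog([0.0, 1.1], domain="infrasound")
        assert match_cross_domain(a, b, t_tol=1.0).n_matched == 2

    def test_matched_count_agrees_with_exhaustive_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            n, m = rng.integers(0, 9), rng.integers(0, 9)
            ts = np.sort(rng.uniform(0, 60, n))
            ti = np.sort(rng.uniform(0, 60, m))
            fs_ = rng.uniform(10, 25, n)
            fi = rng.uniform(10, 25, m)
            a = Catalog([Rumble([EventPick(t, f, 4.0)]) for t, f in zip(ts, fs_)])
            b = Catalog([Rumble([EventPick(t, f, 4.0)]) for t, f in zip(ti, fi)])
            got = match_cross_domain(a, b).n_matched
            assert got == oracle_max_matching(ts, fs_, ti, fi, 2.0, 2.0)

    def test_matched_count_symmetric(self):
        rng = np.random.default_rng(3)
        ts = np.sort(rng.uniform(0, 100, 12))
        ti = np.sort(rng.uniform(0, 100, 9))
        a = _catalog(ts)
        b = _catalog(ti, domain="infrasound")
        assert (
            match_cross_domain(a, b).n_matched == match_cross_domain(b, a).n_matched
        )


class TestCollapseTimes:
    def test_nearby_times_merge_to_cluster_mean(self):
        out = cat.collapse_times([0.0, 1.5, 20.0], resolution=6.0)
        np.testing.assert_allclose(out, [0.75, 20.0])

    def test_chain_merging_and_empty(self):
        out = cat.collapse_times([0.0, 5.0, 9.0, 30.0], resolution=6.0)
        np.testing.assert_allclose(out, [14.0 / 3.0, 30.0])
        assert cat.collapse_times([], 6.0).size == 0


class TestHistogramSimilarity:
    def test_identical_histograms(self):
        h = IntervalHistogram([5, 3, 2, 1, 0, 9])
        assert histogram_similarity(h, h) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        a = IntervalHistogram([5, 0, 0, 0, 0, 0])
        b = IntervalHistogram([0, 3, 0, 0, 0, 0])
        assert histogram_similarity(a, b) == pytest.approx(0.0)

    def test_hand_computed_overlap(self):
        assert histogram_similarity(
            np.array([0.5, 0.5, 0.0]), np.array([0.5, 0.0, 0.5])
        ) == pytest.approx(0.5)

    def test_bin_mismatch_rejected(self):
        with pytest.raises(ValueError):
            histogram_similarity(np.ones(3), np.ones(4))


class TestFeatureEstimation:
    def _scene_map(self, spec, seed=0, night=True):
        noise = synth.NoiseModel()
        cfg = synth.SceneConfig(
            duration=60.0, seed=seed, rumble_specs=[spec], footfall_specs=[],
            start_time=pd.Timestamp("2024-08-02 00:00:00" if night
                                    else "2024-08-02 12:00:00"),
        )
        bundle = synth.render_scene(cfg)
        maps = [
            sigproc.compute_spectrogram(sigproc.bandpass_filter(tr))
            for tr in bundle.seismic
        ]
        return sigproc.average_component_maps(maps)

    def test_apex_and_duration_recovered(self):
        spec = synth.RumbleSpec(20.0, 18.0, 4.0, peak_ground_velocity=5.0)
        m = self._scene_map(spec)
        ev = estimate_event_features(m, (10.0, 40.0))
        assert ev is not None
        assert abs(ev.apex_frequency - 18.0) <= 1.0
        assert abs(ev.duration - 4.0) <= 0.75
        assert abs(ev.timestamp - 22.0) <= 1.5  # centroid near call centre

    def test_pure_noise_yields_no_event(self):
        cfg = synth.SceneConfig(duration=60.0, seed=5, rumble_specs=[],
                                footfall_specs=[])
        bundle = synth.render_scene(cfg)
        m = sigproc.compute_spectrogram(sigproc.bandpass_filter(bundle.seismic_Z))
        assert estimate_event_features(m, (10.0, 40.0)) is None


class TestCatalogIO:
    def test_csv_roundtrip(self, tmp_path):
        events = [
            EventPick(100.0, 15.0, 4.0, source="manual"),
            EventPick(100.5, 30.0, 3.5, source="manual"),
            EventPick(400.0, 20.0, 2.0, source="manual"),
        ]
        c = group_events_to_rumbles(events)
        c = label_motion(c, [120.0])
        p = tmp_path / "catalog.csv"
        c.to_csv(p)
        back = Catalog.from_csv(p, epoch=c.epoch)
        assert len(back) == len(c)
        np.testing.assert_allclose(back.start_times(), c.start_times(), atol=1e-6)
        assert [r.motion_label for r in back.rumbles] == [
            r.motion_label for r in c.rumbles
        ]
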