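import numpy as np
import pytest

from fabas import ctg
from fabas.core import FabasError
from fabas.ctg import (
    BaselineSeries,
    EpochSeries,
    EventList,
    detect_events,
    detect_events_sampled,
    epoch_series,
    episodes_of_high_variation,
    estimate_baseline,
    ltv,
    mark_analyzable,
    stv,
)

from conftest import series_from_nn

E = ctg.EPOCH_S  # 3.75 s


def epochs_from_values(values, artifact=None):
    values = np.asarray(values, dtype=float)
    art = np.zeros(len(values)) if artifact is None else np.asarray(artifact, float)
    return EpochSeries(values=values, artifact_fraction=art)


def flat_baseline(epochs, bpm):
    return BaselineSeries(values=np.full(epochs.n_epochs, float(bpm)))


def epochs_from_bpm(bpm):
    return epochs_from_values(60000.0 / np.asarray(bpm, dtype=float))


class TestEpoching:
    def test_thirty_minutes_gives_480_epochs(self):
        s = series_from_nn(np.full(4500, 400.0))  # exactly 1800 s
        assert epoch_series(s).n_epochs == 480

    def test_constant_intervals(self):
        s = series_from_nn(np.full(100, 400.0))
        ep = epoch_series(s)
        np.testing.assert_allclose(ep.values, 400.0)
        np.testing.assert_allclose(ep.artifact_fraction, 0.0, atol=1e-9)

    def test_time_weighted_mean_oracle(self):
        # one epoch: first half covered by 400 ms beats, second by 600 ms
        nn = np.concatenate([np.full(5, 375.0), np.full(3, 625.0)])  # 1.875 s each
        s = series_from_nn(nn)
        ep = epoch_series(s)
        # brute-force oracle on a fine grid
        grid = np.linspace(0, E, 20000, endpoint=False)
        onsets = s.beat_times
        ends = s.end_times
        val = np.zeros_like(grid)
        for t0, t1, v in zip(onsets, ends, nn):
            val[(grid >= t0) & (grid < t1)] = v
        assert ep.values[0] == pytest.approx(val[val > 0].mean(), rel=1e-3)

    def test_invalid_time_counts_as_artifact(self):
        nn = np.full(16, 500.0)
        valid = np.ones(16, bool)
        valid[:8] = False  # first 4 s invalid
        s = series_from_nn(nn, valid=valid)
        ep = epoch_series(s)
        assert ep.artifact_fraction[0] == pytest.approx(1.0, abs=0.01)

    def test_too_short_errors(self):
        with pytest.raises(FabasError):
            epoch_series(series_from_nn([500.0, 500.0]))


class TestStv:
    def test_constant_epochs_zero(self):
        ep = epochs_from_values(np.full(32, 500.0))
        minutes = mark_analyzable(ep, EventList([], "ctg_dawes"))
        assert stv(ep, minutes) == pytest.approx(0.0)

    def test_alternating_495_505_gives_10ms(self):
        ep = epochs_from_values(np.tile([495.0, 505.0], 16))
        minutes = mark_analyzable(ep, EventList([], "ctg_dawes"))
        assert stv(ep, minutes) == pytest.approx(10.0)

    def test_mean_across_minutes(self):
        # minute 1: |diffs| all 4 ms; minute 2: all 6 ms
        m1 = 500.0 + 2.0 * np.arange(16)
        m2 = 600.0 + 3.0 * np.arange(16)
        ep = epochs_from_values(np.concatenate([m1, m2]))
        minutes = mark_analyzable(ep, EventList([], "ctg_dawes"))
        per = [2.0, 3.0]  # ramp steps
        assert stv(ep, minutes) == pytest.approx(np.mean(per))

    def test_no_analyzable_minutes_missing(self):
        ep = epochs_from_values(np.full(32, 500.0), artifact=np.full(32, 0.9))
        minutes = mark_analyzable(ep, EventList([], "ctg_dawes"))
        assert stv(ep, minutes) is None

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        vals = 500.0 + rng.normal(0, 5, 64)
        ep1 = epochs_from_values(vals)
        ep2 = epochs_from_values(vals + 40.0)
        ev = EventList([], "ctg_dawes")
        assert stv(ep1, mark_analyzable(ep1, ev)) == pytest.approx(
            stv(ep2, mark_analyzable(ep2, ev))
        )


class TestLtv:
    def test_equal_to_baseline_zero(self):
        ep = epochs_from_values(np.full(16, 60000.0 / 140))
        minutes = mark_analyzable(ep, EventList([], "ctg_dawes"))
        assert ltv(ep, minutes, flat_baseline(ep, 140.0)) == pytest.approx(0.0, abs=1e-9)

    def test_above_plus_below(self):
        vals = np.full(16, 400.0)
        vals[3], vals[9] = 412.0, 394.0
        ep = epochs_from_values(vals)
        minutes = mark_analyzable(ep, EventList([], "ctg_dawes"))
        base = flat_baseline(ep, 150.0)  # 150 bpm = 400 ms
        assert ltv(ep, minutes, base) == pytest.approx(12.0 + 6.0)
        assert minutes[0].minute_range_ms == pytest.approx(18.0)

    def test_one_sided_deviation_clamps(self):
        vals = np.full(16, 400.0)
        vals[5] = 410.0
        ep = epochs_from_values(vals)
        minutes = mark_analyzable(ep, EventList([], "ctg_dawes"))
        assert ltv(ep, minutes, flat_baseline(ep, 150.0)) == pytest.approx(10.0)


class TestBaseline:
    def test_constant_trace(self):
        ep = epochs_from_bpm(np.full(480, 140.0))
        base = estimate_baseline(ep)
        np.testing.assert_allclose(base.values, 140.0, atol=1e-9)

    def test_robust_to_acceleration(self):
        bpm = np.full(480, 140.0)
        bpm[100:108] = 160.0  # 20 bpm for 30 s
        base = estimate_baseline(epochs_from_bpm(bpm))
        assert np.all(np.abs(base.values - 140.0) < 1.0)

    def test_tracks_linear_drift(self):
        bpm = np.linspace(140.0, 150.0, 160)  # 10 min drift
        base = estimate_baseline(epochs_from_bpm(bpm))
        inner = slice(30, 130)  # away from edges
        assert np.all(np.abs(base.values[inner] - bpm[inner]) < 1.0)


class TestDetectEvents:
    def make(self, dev_profile):
        """Epoch trace at 140 bpm plus a per-epoch deviation array."""
        n = len(dev_profile)
        ep = epochs_from_bpm(140.0 + np.asarray(dev_profile, float))
        return ep, flat_baseline(ep, 140.0)

    def run(self, dev_profile, rule="ctg_dawes"):
        ep, base = self.make(dev_profile)
        return detect_events(ep, base, rule)

    def test_ac_12bpm_20s(self):
        dev = np.zeros(32)
        dev[8:14] = 12.0  # 6 epochs = 22.5 s
        ev = self.run(dev)
        kinds = [e.kind for e in ev.events]
        assert kinds == ["AC"]

    def test_ac_below_duration_gate_not_detected(self):
        dev = np.zeros(32)
        dev[8:12] = 12.0  # 15 s exactly, not > 15 s
        assert self.run(dev).events == []

    def test_dc_15bpm_40s_is_not_dc(self):
        dev = np.zeros(48)
        dev[10:21] = -15.0  # 41.25 s, deviation < 20 bpm
        assert self.run(dev).of_kind("DC") == []

    def test_dc_12bpm_70s_is_dc(self):
        dev = np.zeros(48)
        dev[10:29] = -12.0  # 71.25 s
        assert [e.kind for e in self.run(dev).events] == ["DC"]

    def test_dc_22bpm_40s_is_dc(self):
        dev = np.zeros(48)
        dev[10:21] = -22.0  # 41.25 s deep
        assert [e.kind for e in self.run(dev).events] == ["DC"]

    def test_lost_beats_riemann_oracle(self):
        rng = np.random.default_rng(3)
        dev = np.zeros(64)
        dev[10:30] = -(15.0 + 10.0 * rng.random(20))  # irregular deep DC
        ep, base = self.make(dev)
        ev = detect_events(ep, base, "ctg_dawes")
        (dc,) = ev.of_kind("DC")
        oracle = np.sum(-dev[10:30] * ctg.EPOCH_S) / 60.0
        assert dc.lost_beats == pytest.approx(oracle, rel=0.01)

    def test_lost_beats_20bpm_arithmetic(self):
        dev = np.zeros(48)
        dev[10:27] = -22.0  # 17 epochs = 63.75 s at 22 bpm deficit
        (dc,) = self.run(dev).of_kind("DC")
        assert dc.lost_beats == pytest.approx(22.0 * 17 * ctg.EPOCH_S / 60.0)

    def test_pattern_rule_superset_of_ctg(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            dev = rng.normal(0, 8, 200)
            ctg_dc = self.run(dev, "ctg_dawes").of_kind("DC")
            pat_dc = self.run(dev, "pattern_10bpm").of_kind("DC")
            pat_spans = [(e.onset_s, e.end_s) for e in pat_dc]
            for e in ctg_dc:
                assert any(a <= e.onset_s and e.end_s <= b for a, b in pat_spans)

    def test_state_rule_needs_15bpm(self):
        dev = np.zeros(32)
        dev[8:14] = 12.0
        assert self.run(dev, "state_classification").events == []
        dev[8:14] = 16.0
        assert [e.kind for e in self.run(dev, "state_classification").events] == ["AC"]


class TestMarkAnalyzable:
    def test_clean_minute_analyzable(self):
        ep = epochs_from_values(np.full(16, 430.0))
        minutes = mark_analyzable(ep, EventList([], "ctg_dawes"))
        assert minutes[0].analyzable

    def test_over_half_artifact_not_analyzable(self):
        art = np.zeros(16)
        art[:9] = 1.0  # 56%
        ep = epochs_from_values(np.full(16, 430.0), artifact=art)
        minutes = mark_analyzable(ep, EventList([], "ctg_dawes"))
        assert not minutes[0].analyzable

    def test_large_dc_overlap_not_analyzable(self):
        ep = epochs_from_values(np.full(32, 430.0))
        dc = ctg.Event("DC", onset_s=30.0, duration_s=40.0,
                       peak_deviation_bpm=25.0, lost_beats=30.0)
        minutes = mark_analyzable(ep, EventList([dc], "ctg_dawes"))
        assert not minutes[0].analyzable and not minutes[1].analyzable

    def test_small_dc_does_not_exclude(self):
        ep = epochs_from_values(np.full(16, 430.0))
        dc = ctg.Event("DC", 10.0, 30.0, 12.0, lost_beats=8.0)
        minutes = mark_analyzable(ep, EventList([dc], "ctg_dawes"))
        assert minutes[0].analyzable


class TestEpisodes:
    def minutes_with_ranges(self, ranges):
        out = []
        for i, r in enumerate(ranges):
            m = ctg.MinuteSection(index=i, epoch_start=16 * i, analyzable=True)
            m.minute_range_ms = r
            out.append(m)
        return out

    def test_all_high_single_episode(self):
        eps = episodes_of_high_variation(self.minutes_with_ranges([50.0] * 30))
        assert eps == [(0, 480)]

    def test_all_low_no_episode(self):
        assert episodes_of_high_variation(self.minutes_with_ranges([10.0] * 30)) == []

    def test_five_of_six_rule_bridges_gap(self):
        ranges = [50] * 5 + [10] + [50] * 5
        eps = episodes_of_high_variation(self.minutes_with_ranges(ranges))
        assert eps == [(0, 11 * 16)]

    def test_alternating_never_qualifies(self):
        ranges = [50, 10] * 15
        assert episodes_of_high_variation(self.minutes_with_ranges(ranges)) == []
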