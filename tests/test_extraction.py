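import numpy as np
import pandas as pd
import pytest

from vswim.extraction import (
    ExtractionConfig,
    compute_speed,
    extract_bouts,
    extract_ibis,
    filter_daytime,
    select_epochs,
)
from vswim.records import SessionMetadata


def _bump(n, peak, fps=100.0, width=0.2, center=None):
    """Raised-cosine speed bump sampled on an n-frame grid."""
    t = np.arange(n) / fps
    c = center if center is not None else t[n // 2]
    s = np.zeros(n)
    in_b = np.abs(t - c) <= width / 2
    s[in_b] = peak * np.cos(np.pi * (t[in_b] - c) / width) ** 2
    return s


class TestComputeSpeed:
    def test_stationary_fish_has_zero_speed(self, make_speed_records):
        rec = make_speed_records(np.zeros(300))
        out = compute_speed(rec, ExtractionConfig(speed_smoothing=1))
        assert np.allclose(out["speed"], 0.0)

    def test_constant_displacement_hand_arithmetic(self, make_speed_records):
        # 0.03 mm per frame at 166 Hz -> 4.98 mm/s, just below threshold
        n = 300
        rec = make_speed_records(np.full(n, 0.03 * 166.0), fps=166.0)
        out = compute_speed(rec, ExtractionConfig(speed_smoothing=1), frame_rate=166.0)
        assert np.allclose(out["speed"], 4.98)
        assert (out["speed"] < 5.0).all()

    def test_speed_never_bridges_epoch_boundary(self, make_speed_records, stack_records):
        a = make_speed_records(np.zeros(300), epoch_id=0)
        b = make_speed_records(np.zeros(300), epoch_id=1, t0=5.0)
        b[["body_x"]] += 50.0  # far away; a bridge would imply a huge speed
        rec = stack_records(a, b)
        out = compute_speed(rec, ExtractionConfig(speed_smoothing=1))
        assert np.allclose(out["speed"], 0.0)

    def test_single_frame_epoch_dropped_with_warning(self, make_speed_records, stack_records):
        good = make_speed_records(np.zeros(300), epoch_id=0)
        lone = make_speed_records(np.zeros(1), epoch_id=1, t0=9.0)
        with pytest.warns(UserWarning, match="single frame"):
            out = compute_speed(stack_records(good, lone), ExtractionConfig(speed_smoothing=1))
        assert set(out["epoch_id"]) == {0}

    def test_first_frame_inherits_successor_speed(self, make_speed_records):
        speed = np.full(100, 2.0)
        out = compute_speed(make_speed_records(speed), ExtractionConfig(speed_smoothing=1))
        assert out["speed"].iloc[0] == pytest.approx(2.0)


class TestSelectEpochs:
    def _with_speed(self, rec, fps=100.0):
        return compute_speed(rec, ExtractionConfig(speed_smoothing=1), frame_rate=fps)

    def test_two_second_epoch_excluded(self, make_speed_records):
        rec = self._with_speed(make_speed_records(_bump(200, 10.0)))
        kept, excl = select_epochs(rec, frame_rate=100.0)
        assert len(kept) == 0
        assert excl == [(0, "too_short")]

    def test_slow_epoch_excluded(self, make_speed_records):
        rec = self._with_speed(make_speed_records(_bump(300, 4.0)))
        kept, excl = select_epochs(rec, frame_rate=100.0)
        assert excl == [(0, "no_swimming")]

    def test_qualifying_epoch_kept(self, make_speed_records):
        rec = self._with_speed(make_speed_records(_bump(300, 10.0)))
        kept, excl = select_epochs(rec, frame_rate=100.0)
        assert len(kept) == 300 and excl == []

    def test_teleport_artifact_excluded(self, make_speed_records):
        raw = make_speed_records(_bump(300, 10.0))
        raw.loc[200:, "body_x"] += 5.0  # 5 mm jump in one frame
        rec = self._with_speed(raw)
        kept, excl = select_epochs(rec, frame_rate=100.0)
        assert excl == [(0, "jump_artifact")]

    def test_length_outlier_epoch_excluded(self, make_speed_records, stack_records):
        eps = [make_speed_records(_bump(300, 10.0), epoch_id=i, t0=4.0 * i, length=l)
               for i, l in enumerate([4.0, 4.0, 8.0])]
        rec = self._with_speed(stack_records(*eps))
        kept, excl = select_epochs(rec, frame_rate=100.0)
        assert excl == [(2, "length_outlier")]
        assert set(kept["epoch_id"]) == {0, 1}

    def test_missing_frames_excluded(self, make_speed_records):
        raw = make_speed_records(_bump(300, 10.0))
        raw = raw.drop(index=range(150, 160)).reset_index(drop=True)
        rec = self._with_speed(raw)
        kept, excl = select_epochs(rec, frame_rate=100.0)
        assert excl == [(0, "missing_frames")]


class TestExtractBouts:
    def test_single_bump_yields_one_aligned_bout(self, make_speed_records):
        rec = compute_speed(make_speed_records(_bump(300, 10.0)),
                            ExtractionConfig(speed_smoothing=1), frame_rate=100.0)
        cfg = ExtractionConfig(speed_smoothing=1)
        bouts = extract_bouts(rec, cfg, frame_rate=100.0)
        assert len(bouts) == 1
        b = bouts[0]
        # window spans exactly -500..+300 ms: round(0.5*fps)+round(0.3*fps)+1 samples
        assert len(b.times_ms) == 81
        assert b.times_ms[0] == -500.0 and b.times_ms[-1] == 300.0
        i0 = np.argmin(np.abs(b.times_ms))
        assert b.speed[i0] == b.speed.max()
        assert b.peak_speed == pytest.approx(10.0)

    def test_peak_too_close_to_epoch_start_is_dropped(self, make_speed_records):
        # peak 200 ms after epoch start: the 500 ms pre-window cannot fit
        rec = compute_speed(make_speed_records(_bump(300, 10.0, center=0.2)),
                            ExtractionConfig(speed_smoothing=1), frame_rate=100.0)
        assert extract_bouts(rec, ExtractionConfig(speed_smoothing=1), frame_rate=100.0) == []

    def test_lower_threshold_never_reduces_candidate_spans(self):
        from vswim.extraction import _threshold_runs

        rng = np.random.default_rng(0)
        speed = np.abs(rng.normal(4.0, 3.0, size=2000))
        counts = [len(_threshold_runs(speed, thr)) for thr in (8.0, 6.0, 4.0, 2.0, 1.0)]
        spans = [sum(b - a for a, b in _threshold_runs(speed, thr)) for thr in (8.0, 6.0, 4.0, 2.0)]
        assert all(s2 >= s1 for s1, s2 in zip(spans, spans[1:]))
        assert min(counts) >= 1


class TestExtractIbis:
    def _epoch_with_two_bouts(self, make_speed_records, gap_frames, pitch=12.0):
        speed = np.concatenate([
            np.ones(110), np.full(30, 8.0), np.ones(gap_frames),
            np.full(30, 8.0), np.ones(110),
        ])
        return compute_speed(make_speed_records(speed, pitch=pitch),
                             ExtractionConfig(speed_smoothing=1), frame_rate=100.0)

    def test_buffer_deduction_and_frequency(self, make_speed_records):
        # 1.0 s sub-threshold span -> 0.8 s after the two 100 ms buffers
        rec = self._epoch_with_two_bouts(make_speed_records, gap_frames=100)
        (ibi,) = extract_ibis(rec, frame_rate=100.0)
        assert ibi.duration == pytest.approx(0.8)
        assert ibi.bout_frequency == pytest.approx(1.25)

    def test_short_span_discarded(self, make_speed_records):
        rec = self._epoch_with_two_bouts(make_speed_records, gap_frames=20)
        assert extract_ibis(rec, frame_rate=100.0) == []

    def test_mean_pitch_over_buffered_interval(self, make_speed_records):
        rec = self._epoch_with_two_bouts(make_speed_records, gap_frames=100, pitch=12.0)
        (ibi,) = extract_ibis(rec, frame_rate=100.0)
        assert ibi.mean_pitch == pytest.approx(12.0)

    def test_ibi_count_bounded_by_bout_count(self, quiet_session, quiet_profile):
        from vswim.synth import trace_to_records

        fr = quiet_profile.frame_rate
        rec = compute_speed(trace_to_records(quiet_session), frame_rate=fr)
        kept, _ = select_epochs(rec, frame_rate=fr)
        bouts = extract_bouts(kept, frame_rate=fr)
        ibis = extract_ibis(kept, frame_rate=fr)
        for eid in {b.epoch_id for b in bouts}:
            nb = sum(b.epoch_id == eid for b in bouts)
            ni = sum(r.epoch_id == eid for r in ibis)
            assert ni <= nb - 1 if nb else ni == 0


class TestDaytimeFilter:
    def _day_meta(self):
        return SessionMetadata(frame_rate=100.0, light_on="08:00", light_off="22:00",
                               session_start="08:00")

    def test_full_day_retains_fourteen_hours(self):
        times = np.arange(0, 24 * 3600, 60.0)
        df = pd.DataFrame({"time": times})
        kept = filter_daytime(df, self._day_meta())
        assert len(kept) == pytest.approx(14 * 60, abs=1)

    def test_night_only_data_is_empty(self):
        meta = self._day_meta()
        df = pd.DataFrame({"time": np.arange(15 * 3600, 20 * 3600, 60.0)})  # 23:00-04:00
        assert len(filter_daytime(df, meta)) == 0

    def test_missing_schedule_passes_through_with_warning(self):
        df = pd.DataFrame({"time": [0.0, 1.0]})
        with pytest.warns(UserWarning, match="day filter skipped"):
            out = filter_daytime(df, None)
        assert out is df
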