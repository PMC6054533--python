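import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from behavrc import behavior_core as bc
from behavrc.behavior_core import (
    IN_TRANSITION,
    TransitionEvent,
    classify_dwells,
    extract_transitions,
    fraction_to_rate,
    rate_change,
    rate_timeseries,
    rate_to_fraction,
)

from .conftest import make_track

DT = 1 / 14


class TestDwellRule:
    def test_exact_half_second_run_is_kept(self):
        # 7 frames at 14 Hz is exactly 0.5 s: kept as a behavior
        tr = make_track([("A", 10), ("B", 7), ("A", 10)])
        out = classify_dwells(tr)
        assert list(out.labels[10:17]) == ["B"] * 7

    def test_short_run_relabeled(self):
        tr = make_track([("A", 10), ("B", 3), ("A", 10)])
        out = classify_dwells(tr)
        assert list(out.labels[10:13]) == [IN_TRANSITION] * 3

    def test_constant_track_unchanged(self):
        tr = make_track([("A", 20)])
        assert list(classify_dwells(tr).labels) == ["A"] * 20

    def test_empty_track(self):
        tr = make_track([])
        assert len(classify_dwells(tr)) == 0

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.tuples(st.sampled_from("ABC"), st.integers(1, 12)),
                    min_size=0, max_size=10))
    def test_idempotent(self, runs):
        tr = make_track(runs)
        once = classify_dwells(tr)
        twice = classify_dwells(once)
        assert list(once.labels) == list(twice.labels)


class TestTransitionExtraction:
    def test_direct_transition(self):
        tr = make_track([("W", 10), ("X", 10)])
        evs = extract_transitions(tr)
        assert len(evs) == 1
        assert evs[0].from_state == "W" and evs[0].to_state == "X"
        assert evs[0].frame == 10
        assert evs[0].time == pytest.approx(10 * DT)

    def test_bridged_transition_keeps_origin(self):
        tr = classify_dwells(make_track([("W", 10), ("X", 3), ("Y", 10)]))
        evs = extract_transitions(tr)
        assert len(evs) == 1
        assert evs[0].from_state == "W" and evs[0].to_state == "Y"

    def test_return_to_same_state_ignored(self):
        tr = classify_dwells(make_track([("X", 10), ("Y", 3), ("X", 10)]))
        assert extract_transitions(tr) == []

    def test_single_state_track(self):
        assert extract_transitions(make_track([("X", 30)])) == []

    def test_unknown_origin_after_leading_sentinel(self):
        tr = classify_dwells(make_track([("A", 3), ("X", 10)]))
        evs = extract_transitions(tr)
        assert len(evs) == 1
        assert evs[0].from_state is None and evs[0].to_state == "X"

    def test_track_start_in_state_is_not_an_event(self):
        evs = extract_transitions(make_track([("X", 10), ("Y", 10)]))
        assert [e.to_state for e in evs] == ["Y"]

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.tuples(st.sampled_from("ABC"), st.integers(7, 12)),
                    min_size=1, max_size=12))
    def test_conservation_and_reversal_symmetry(self, runs):
        tr = classify_dwells(make_track(runs))
        evs = extract_transitions(tr)
        # conservation: per-to-state counts sum to the total
        per_state = {}
        for ev in evs:
            per_state[ev.to_state] = per_state.get(ev.to_state, 0) + 1
        assert sum(per_state.values()) == len(evs)
        # known-origin event count is invariant under time reversal
        rev = make_track(list(tr.labels)[::-1])
        evs_rev = extract_transitions(rev)
        n_known = sum(1 for e in evs if e.from_state is not None)
        n_known_rev = sum(1 for e in evs_rev if e.from_state is not None)
        assert n_known == n_known_rev


class TestRates:
    def test_unit_conversion_round_trip(self):
        f = 0.0123
        assert rate_to_fraction(fraction_to_rate(f, DT), DT) == pytest.approx(f, rel=1e-15)

    def test_single_transition_among_ten_animals(self):
        # 1 of 10 animals transitioning in one frame → 0.1*14*60 = 84 /animal/min
        tracks = [make_track([("A", 28)], track_id=f"t{i}") for i in range(10)]
        evs = [TransitionEvent(track_id="t0", time=14 * DT, to_state="B",
                               from_state="A", frame=14)]
        rs = rate_timeseries(tracks, evs, [14 * DT], window=(0.0, 0.0))
        assert rs.rate[0] == pytest.approx(84.0)

    def test_no_events_all_zero(self):
        tracks = [make_track([("A", 140)], track_id=f"t{i}") for i in range(3)]
        rs = rate_timeseries(tracks, [], [2.0], window=(-1.0, 1.0))
        assert np.all(rs.rate[np.isfinite(rs.rate)] == 0.0)

    def test_untracked_bins_flagged_missing(self):
        tracks = [make_track([("A", 14)])]  # 1 s long track
        rs = rate_timeseries(tracks, [], [0.5], window=(-2.0, 2.0))
        assert np.isnan(rs.rate[0])  # before the track exists
        assert np.isfinite(rs.rate[len(rs.rate) // 2])

    def test_poisson_agent_rate_recovered(self):
        # homogeneous hazard r: time-averaged rate ≈ r (per minute)
        rng = np.random.default_rng(42)
        r = 0.2  # per second
        n_frames = 14 * 600
        tracks, evs = [], []
        for i in range(20):
            tid = f"t{i}"
            tracks.append(make_track([("A", n_frames)], track_id=tid))
            hits = np.flatnonzero(rng.random(n_frames) < r * DT)
            evs += [TransitionEvent(track_id=tid, time=f * DT, to_state="B",
                                    from_state="A", frame=int(f)) for f in hits]
        rs = rate_timeseries(tracks, evs, [300.0], window=(-200.0, 200.0))
        assert np.nanmean(rs.rate) == pytest.approx(r * 60.0, rel=0.05)

    def test_stationary_process_change_near_zero(self):
        rng = np.random.default_rng(1)
        n_frames = 14 * 600
        tracks, evs = [], []
        for i in range(10):
            tid = f"t{i}"
            tracks.append(make_track([("A", n_frames)], track_id=tid))
            hits = np.flatnonzero(rng.random(n_frames) < 0.3 * DT)
            evs += [TransitionEvent(track_id=tid, time=f * DT, to_state="B",
                                    from_state="A", frame=int(f)) for f in hits]
        onsets = list(np.arange(60.0, 570.0, 60.0))
        rc = rate_change(tracks, evs, onsets, response_window=(0.0, 2.0),
                         baseline_mode="pre_window")
        assert abs(rc.change) < 4.0  # ≪ the 18 /animal/min baseline
        assert rc.p_value > 0.01

    def test_step_hazard_doubling_detected(self):
        rng = np.random.default_rng(2)
        r = 0.3
        n_frames = 14 * 600
        onsets = list(np.arange(60.0, 570.0, 60.0))
        on_frames = {int(round(t / DT)) for t in onsets}
        tracks, evs = [], []
        for i in range(30):
            tid = f"t{i}"
            tracks.append(make_track([("A", n_frames)], track_id=tid))
            p = np.full(n_frames, r * DT)
            for f0 in on_frames:  # doubled hazard for 2 s post-onset
                p[f0: f0 + 28] = 2 * r * DT
            hits = np.flatnonzero(rng.random(n_frames) < p)
            evs += [TransitionEvent(track_id=tid, time=f * DT, to_state="B",
                                    from_state="A", frame=int(f)) for f in hits]
        rc = rate_change(tracks, evs, onsets, response_window=(0.0, 2.0),
                         baseline_mode="pre_window", baseline_window=20.0)
        assert rc.change == pytest.approx(r * 60.0, rel=0.35)
        assert rc.p_value < 0.01

    def test_overlapping_windows_rejected(self):
        tracks = [make_track([("A", 140)])]
        with pytest.raises(ValueError, match="overlap"):
            rate_change(tracks, [], [5.0], response_window=(-1.0, 1.0),
                        baseline_mode="pre_window")

    def test_smooth_rate_preserves_mean(self):
        tracks = [make_track([("A", 1400)], track_id=f"t{i}") for i in range(5)]
        rng = np.random.default_rng(3)
        evs = []
        for i in range(5):
            hits = np.flatnonzero(rng.random(1400) < 0.01)
            evs += [TransitionEvent(track_id=f"t{i}", time=f * DT, to_state="B",
                                    from_state="A", frame=int(f)) for f in hits]
        rs = rate_timeseries(tracks, evs, [50.0], window=(-40.0, 40.0))
        sm = bc.smooth_rate(rs, width=1.0)
        assert np.nanmean(sm.rate) == pytest.approx(np.nanmean(rs.rate), rel=0.05)
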