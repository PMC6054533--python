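"""Labeled behavior tracks, transition extraction and transition rates.

A *track* is one animal's contiguous run of per-frame discrete behavior
labels (tracks are split upstream wherever frames were dropped).  Runs of
a label shorter than a minimum dwell (default 0.5 s) are relabeled with
the ``IN_TRANSITION`` sentinel before transitions are extracted: a
transition into state X occurs on the first frame classified as X, with
the origin taken as the most recent non-sentinel state.  X → 'in
transition' → X excursions produce no event.

Rates are reported in transitions · animal⁻¹ · min⁻¹, computed from the
fraction of tracked animals transitioning per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Iterable, Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "IN_TRANSITION",
    "DEFAULT_STATES",
    "BehaviorTrack",
    "TransitionEvent",
    "RateSeries",
    "RateChange",
    "run_lengths",
    "classify_dwells",
    "extract_transitions",
    "rate_timeseries",
    "per_presentation_rates",
    "rate_change",
    "smooth_rate",
    "fraction_to_rate",
    "rate_to_fraction",
]

#: reserved label for sub-dwell occupancies
IN_TRANSITION = "in transition"

#: the nine-state alphabet used throughout (six forward speeds, turning,
#: and two reversal states)
DEFAULT_STATES = (
    "Forward 1", "Forward 2", "Forward 3", "Forward 4", "Forward 5",
    "Forward 6", "Turn", "Slow Reverse", "Fast Reverse",
)


@dataclass
class BehaviorTrack:
    """One animal's contiguous per-frame behavior labels."""

    track_id: str
    t_start: float
    dt: float
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_frames(self) -> int:
        return len(self.labels)

    @property
    def t_end(self) -> float:
        """Time just past the last frame."""
        return self.t_start + self.n_frames * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.n_frames) * self.dt

    def frame_of(self, t: float) -> int:
        return int(round((t - self.t_start) / self.dt))

    def covers(self, t_lo: float, t_hi: float) -> bool:
        """True if the track is tracked throughout [t_lo, t_hi]."""
        eps = 0.5 * self.dt
        return self.t_start - eps <= t_lo and self.t_end - self.dt + eps >= t_hi


@dataclass(frozen=True)
class TransitionEvent:
    """Entry into a behavior state.

    ``from_state`` is None (unknown origin) when the track begins in the
    sentinel or the origin could not be determined.
    """

    track_id: str
    time: float
    to_state: str
    from_state: str | None = None
    frame: int = 0  # frame index within the parent track


@dataclass
class RateSeries:
    """Stimulus-aligned transition-rate timeseries.

    ``rate`` is NaN in bins where no animals were tracked (missing, not
    zero).  ``times`` are bin times relative to stimulus onset.
    """

    times: np.ndarray
    rate: np.ndarray
    n_transitions: np.ndarray
    n_tracked: np.ndarray
    n_presentations: int
    dt: float


@dataclass
class RateChange:
    """Windowed transition-rate change relative to baseline."""

    change: float
    per_presentation: np.ndarray
    baseline: float
    sem: float
    t_stat: float
    p_value: float


def run_lengths(labels: np.ndarray) -> list[tuple[int, int, object]]:
    """Maximal runs of identical labels as (start, length, label)."""
    labels = np.asarray(labels, dtype=object)
    n = len(labels)
    if n == 0:
        return []
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    return [(int(s), int(e - s), labels[s]) for s, e in zip(starts, ends)]


def classify_dwells(track: BehaviorTrack, min_dwell: float = 0.5) -> BehaviorTrack:
    """Relabel sub-dwell runs as 'in transition'.

    Every maximal run of identical labels whose duration is strictly less
    than ``min_dwell`` seconds becomes ``IN_TRANSITION``; runs of at least
    ``min_dwell`` (e.g. exactly 7 frames at 14 Hz for 0.5 s) are kept.
    """
    labels = track.labels.copy()
    for start, length, label in run_lengths(labels):
        if label == IN_TRANSITION:
            continue
        if length * track.dt < min_dwell - 1e-9:
            labels[start: start + length] = IN_TRANSITION
    return BehaviorTrack(track.track_id, track.t_start, track.dt, labels)


def extract_transitions(track: BehaviorTrack) -> list[TransitionEvent]:
    """Extract one event per entry into a state from a dwell-classified track.

    The event time is the first frame classified as the new state.  The
    origin is the most recent non-sentinel state; if there is none but the
    track did not begin in this state, the origin is unknown (None).  The
    first run of a track that starts the track produces no event (the entry
    was not observed), and X → sentinel → X excursions are ignored.
    """
    events: list[TransitionEvent] = []
    last_state: str | None = None
    for i, (start, _length, label) in enumerate(run_lengths(track.labels)):
        if label == IN_TRANSITION:
            continue
        if i == 0:
            # track begins already inside this state: entry unobserved
            last_state = label
            continue
        if label == last_state:
            continue
        events.append(
            TransitionEvent(
                track_id=track.track_id,
                time=track.t_start + start * track.dt,
                to_state=label,
                from_state=last_state,
                frame=start,
            )
        )
        last_state = label
    return events


def fraction_to_rate(fraction: float | np.ndarray, dt: float) -> float | np.ndarray:
    """Convert fraction-of-animals-transitioning-per-frame to
    transitions · animal⁻¹ · min⁻¹."""
    return fraction * (60.0 / dt)


def rate_to_fraction(rate: float | np.ndarray, dt: float) -> float | np.ndarray:
    return rate * (dt / 60.0)


def _occupancy_ok(track: BehaviorTrack, frame: int, from_state: str | None) -> bool:
    if from_state is None:
        return True
    return track.labels[frame] == from_state


def rate_timeseries(
    tracks: Sequence[BehaviorTrack],
    events: Iterable[TransitionEvent],
    stimulus_onsets: Sequence[float],
    window: tuple[float, float] = (-10.0, 10.0),
    to_state: str | None = None,
    from_state: str | None = None,
) -> RateSeries:
    """Stimulus-aligned transition-rate timeseries.

    Behavior timeseries from all tracks are cropped in ``window`` around
    each onset, commingled and time aligned; the per-bin rate is the
    fraction of tracked animals transitioning, converted to
    transitions · animal⁻¹ · min⁻¹.  When ``from_state`` is given the
    denominator counts only animals occupying that state in the bin and
    only matching-origin events are counted.
    """
    if not tracks:
        raise ValueError("rate_timeseries needs at least one track")
    dt = tracks[0].dt
    lo = int(round(window[0] / dt))
    hi = int(round(window[1] / dt))
    nbins = hi - lo + 1
    n_trans = np.zeros(nbins)
    n_tracked = np.zeros(nbins)

    by_id = {tr.track_id: tr for tr in tracks}

    for onset in stimulus_onsets:
        for tr in tracks:
            onset_frame = tr.frame_of(onset)
            f_lo = max(onset_frame + lo, 0)
            f_hi = min(onset_frame + hi, tr.n_frames - 1)
            if f_lo > f_hi:
                continue
            b_lo = f_lo - onset_frame - lo
            if from_state is None:
                n_tracked[b_lo: b_lo + (f_hi - f_lo + 1)] += 1
            else:
                occ = (tr.labels[f_lo: f_hi + 1] == from_state).astype(float)
                n_tracked[b_lo: b_lo + (f_hi - f_lo + 1)] += occ

    onsets = np.asarray(stimulus_onsets, dtype=float)
    for ev in events:
        if to_state is not None and ev.to_state != to_state:
            continue
        if from_state is not None and ev.from_state != from_state:
            continue
        tr = by_id.get(ev.track_id)
        if tr is None:
            continue
        rel = ev.time - onsets
        for r in rel[(rel >= window[0] - dt / 2) & (rel <= window[1] + dt / 2)]:
            b = int(round(r / dt)) - lo
            if 0 <= b < nbins:
                n_trans[b] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(n_tracked > 0, n_trans / np.maximum(n_tracked, 1e-300), np.nan)
    rate = fraction_to_rate(rate, dt)
    times = (np.arange(lo, hi + 1)) * dt
    return RateSeries(times=times, rate=rate, n_transitions=n_trans,
                      n_tracked=n_tracked, n_presentations=len(stimulus_onsets), dt=dt)


def per_presentation_rates(
    tracks: Sequence[BehaviorTrack],
    events: Iterable[TransitionEvent],
    stimulus_onsets: Sequence[float],
    window: tuple[float, float],
    to_state: str | None = None,
    from_state: str | None = None,
) -> np.ndarray:
    """Mean transition rate within ``window`` of each onset, one value per
    presentation (NaN where nothing was tracked)."""
    events = list(events)
    out = np.empty(len(stimulus_onsets))
    for i, onset in enumerate(stimulus_onsets):
        rs = rate_timeseries(tracks, events, [onset], window,
                             to_state=to_state, from_state=from_state)
        tot_tracked = rs.n_tracked.sum()
        if tot_tracked == 0:
            out[i] = np.nan
        else:
            out[i] = fraction_to_rate(rs.n_transitions.sum() / tot_tracked, rs.dt)
    return out


def mean_rate(
    tracks: Sequence[BehaviorTrack],
    events: Iterable[TransitionEvent],
    to_state: str | None = None,
    from_state: str | None = None,
) -> float:
    """Overall mean transition rate throughout the recording,
    transitions · animal⁻¹ · min⁻¹."""
    n_frames = 0.0
    for tr in tracks:
        if from_state is None:
            n_frames += tr.n_frames
        else:
            n_frames += float(np.sum(tr.labels == from_state))
    n_ev = 0
    for ev in events:
        if to_state is not None and ev.to_state != to_state:
            continue
        if from_state is not None and ev.from_state != from_state:
            continue
        n_ev += 1
    if n_frames == 0:
        return float("nan")
    return fraction_to_rate(n_ev / n_frames, tracks[0].dt)


def rate_change(
    tracks: Sequence[BehaviorTrack],
    events: Iterable[TransitionEvent],
    stimulus_onsets: Sequence[float],
    response_window: tuple[float, float] = (0.0, 2.0),
    baseline_mode: str = "pre_window",
    baseline_window: float = 20.0,
    to_state: str | None = None,
    from_state: str | None = None,
) -> RateChange:
    """Windowed transition-rate change relative to baseline.

    ``baseline_mode='pre_window'`` uses the mean rate in a window of
    ``baseline_window`` seconds immediately before each onset;
    ``'recording_mean'`` uses the overall mean rate of the recording.
    Per-presentation (response − baseline) samples feed a two-sided
    one-sample t-test.
    """
    events = list(events)
    if baseline_mode not in ("pre_window", "recording_mean"):
        raise ValueError(f"unknown baseline_mode {baseline_mode!r}")
    if baseline_mode == "pre_window" and response_window[0] < 0:
        raise ValueError("response window overlaps the pre-stimulus baseline window")

    resp = per_presentation_rates(tracks, events, stimulus_onsets, response_window,
                                  to_state=to_state, from_state=from_state)
    if baseline_mode == "pre_window":
        base = per_presentation_rates(
            tracks, events, stimulus_onsets, (-baseline_window, 0.0),
            to_state=to_state, from_state=from_state)
    else:
        base = np.full_like(resp, mean_rate(tracks, events, to_state=to_state,
                                            from_state=from_state))
    diff = resp - base
    diff = diff[np.isfinite(diff)]
    if len(diff) == 0:
        raise ValueError("no presentation had tracked animals in both windows")
    change = float(diff.mean())
    sem = float(diff.std(ddof=1) / np.sqrt(len(diff))) if len(diff) > 1 else float("nan")
    if len(diff) > 1 and np.ptp(diff) > 0:
        t_stat, p = _sps.ttest_1samp(diff, 0.0)
    else:
        t_stat, p = float("nan"), float("nan")
    return RateChange(change=change, per_presentation=diff,
                      baseline=float(np.nanmean(base)), sem=sem,
                      t_stat=float(t_stat), p_value=float(p))


def smooth_rate(series: RateSeries, width: float = 1.0) -> RateSeries:
    """Centered moving average of a rate timeseries (NaN-aware), default
    1 s window, for display and model-prediction comparison."""
    w = max(int(round(width / series.dt)), 1)
    if w % 2 == 0:
        w += 1
    half = w // 2
    rate = series.rate
    out = np.full_like(rate, np.nan)
    for i in range(len(rate)):
        seg = rate[max(i - half, 0): i + half + 1]
        good = np.isfinite(seg)
        if good.any():
            out[i] = seg[good].mean()
    return RateSeries(times=series.times, rate=out,
                      n_transitions=series.n_transitions,
                      n_tracked=series.n_tracked,
                      n_presentations=series.n_presentations, dt=series.dt)
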