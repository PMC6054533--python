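"""Behavior-triggered averages (kernels), circle-shift significance,
context-dependent pairwise kernels, and kernel clustering.

The kernel of the linear-nonlinear model is estimated as the
mean-subtracted, time-reversed behavior-triggered average (BTA): the mean
stimulus in a 20 s window centered on the times of entry into a behavior
state.  In kernel coordinates, lag τ > 0 refers to stimulus τ seconds
*before* the transition (the causal half).

Significance is assessed against a permutation null built by
circle-shifting transition times within each track, which preserves the
temporal statistics of the transition train while decorrelating it from
the stimulus.  A kernel is significant when its L2 norm exceeds the 99th
percentile of the null norms.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from collections.abc import Iterable, Sequence

import numpy as np

from .behavior_core import BehaviorTrack, TransitionEvent
from .stimgen import StimulusSeries

__all__ = [
    "Kernel",
    "behavior_triggered_average",
    "shuffle_null",
    "estimate_kernel",
    "pairwise_kernels",
    "cluster_kernels",
]


@dataclass
class Kernel:
    """Estimated LN-model kernel for one (optionally origin-conditioned)
    behavior transition.

    ``values`` hold the mean-subtracted, time-reversed BTA; ``lags`` run
    from −window_half to +window_half seconds, positive lags being
    pre-transition (causal) stimulus.  ``bta`` is the same waveform in
    forward (stimulus playback) time order.
    """

    values: np.ndarray
    dt: float
    window_half: float
    n_events: int
    to_state: str | None = None
    from_state: str | None = None
    n_dropped: int = 0
    shuffle_norms: np.ndarray | None = field(default=None, repr=False)
    percentile_99: float | None = None
    significant: bool | None = None

    @property
    def lags(self) -> np.ndarray:
        n_half = (len(self.values) - 1) // 2
        return (np.arange(len(self.values)) - n_half) * self.dt

    @property
    def bta(self) -> np.ndarray:
        """Mean-subtracted BTA in forward time order (for playback)."""
        return self.values[::-1]

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.values))

    @property
    def is_empty(self) -> bool:
        return self.n_events == 0

    def causal(self) -> tuple[np.ndarray, np.ndarray]:
        """(lags, values) of the causal half (lag ≥ 0)."""
        m = self.lags >= -1e-12
        return self.lags[m], self.values[m]


def _window_half_frames(window_half: float, dt: float) -> int:
    return int(round(window_half / dt))


def _event_frames(
    stimulus: StimulusSeries,
    events: Sequence[TransitionEvent],
    n_half: int,
    tracks: dict[str, BehaviorTrack] | None,
) -> tuple[np.ndarray, int]:
    """Stimulus frame index of each usable event; events whose full window
    exits the stimulus record (or their track, when tracks are supplied)
    are dropped and counted."""
    idx = []
    dropped = 0
    n = len(stimulus)
    for ev in events:
        i = stimulus.index_of(ev.time)
        if i - n_half < 0 or i + n_half >= n:
            dropped += 1
            continue
        if tracks is not None:
            tr = tracks.get(ev.track_id)
            if tr is None or ev.frame - n_half < 0 or ev.frame + n_half >= tr.n_frames:
                dropped += 1
                continue
        idx.append(i)
    return np.asarray(idx, dtype=np.intp), dropped


def _bta_from_frames(values: np.ndarray, frames: np.ndarray, n_half: int) -> np.ndarray:
    offsets = np.arange(-n_half, n_half + 1)
    windows = values[frames[:, None] + offsets[None, :]]
    return windows.mean(axis=0)


def behavior_triggered_average(
    stimulus: StimulusSeries,
    events: Sequence[TransitionEvent],
    window_half: float = 10.0,
    tracks: Sequence[BehaviorTrack] | None = None,
    to_state: str | None = None,
    from_state: str | None = None,
) -> Kernel:
    """Estimate a kernel as the mean-subtracted, time-reversed BTA.

    Events whose centered window of ±``window_half`` s exits the stimulus
    record (or their parent track, when ``tracks`` are given) are dropped
    and counted in ``n_dropped``.  Zero usable events yield an explicit
    empty kernel (all-zero values), never NaN.
    """
    n_half = _window_half_frames(window_half, stimulus.dt)
    track_map = {tr.track_id: tr for tr in tracks} if tracks is not None else None
    frames, dropped = _event_frames(stimulus, list(events), n_half, track_map)
    nbins = 2 * n_half + 1
    if len(frames) == 0:
        return Kernel(values=np.zeros(nbins), dt=stimulus.dt, window_half=window_half,
                      n_events=0, to_state=to_state, from_state=from_state,
                      n_dropped=dropped, significant=False)
    bta = _bta_from_frames(stimulus.values, frames, n_half)
    kernel = (bta - bta.mean())[::-1]
    return Kernel(values=kernel, dt=stimulus.dt, window_half=window_half,
                  n_events=len(frames), to_state=to_state, from_state=from_state,
                  n_dropped=dropped)


def shuffle_null(
    stimulus: StimulusSeries,
    tracks: Sequence[BehaviorTrack],
    events: Sequence[TransitionEvent],
    window_half: float = 10.0,
    n_shuffles: int = 100,
    rng: np.random.Generator | int | None = 0,
) -> np.ndarray:
    """Null distribution of kernel L2 norms from circle-shifted event times.

    Within every track, event frame offsets are rotated by a random integer
    in 1..n_frames−1 (never the identity), preserving the track's
    inter-event structure while decorrelating it from the stimulus; the BTA
    is then recomputed.  Returns the ``n_shuffles`` null norms.  Tracks
    shorter than the full window contribute no usable events and are left
    out of the shifting.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n_half = _window_half_frames(window_half, stimulus.dt)
    nbins = 2 * n_half + 1
    track_map = {tr.track_id: tr for tr in tracks}

    # flatten events into per-event arrays grouped by track
    groups: dict[str, int] = {}
    offs, g_idx = [], []
    g_len, g_t0 = [], []
    for ev in events:
        tr = track_map.get(ev.track_id)
        if tr is None or tr.n_frames < nbins:
            continue  # tracks shorter than the window cannot host any event
        gi = groups.get(ev.track_id)
        if gi is None:
            gi = groups[ev.track_id] = len(g_len)
            g_len.append(tr.n_frames)
            g_t0.append(stimulus.index_of(tr.t_start))
        offs.append(ev.frame)
        g_idx.append(gi)
    norms = np.zeros(n_shuffles)
    if not offs:
        return norms
    offs = np.asarray(offs, dtype=np.int64)
    g_idx = np.asarray(g_idx, dtype=np.intp)
    g_len = np.asarray(g_len, dtype=np.int64)
    g_t0 = np.asarray(g_t0, dtype=np.int64)
    n_stim = len(stimulus)

    for s in range(n_shuffles):
        shifts = np.array([rng.integers(1, n) if n > 1 else 0 for n in g_len])
        f = (offs + shifts[g_idx]) % g_len[g_idx]
        i = g_t0[g_idx] + f
        ok = (f >= n_half) & (f + n_half < g_len[g_idx]) \
            & (i >= n_half) & (i + n_half < n_stim)
        if not ok.any():
            continue
        bta = _bta_from_frames(stimulus.values, i[ok].astype(np.intp), n_half)
        norms[s] = np.linalg.norm(bta - bta.mean())
    return norms


def estimate_kernel(
    stimulus: StimulusSeries,
    tracks: Sequence[BehaviorTrack],
    events: Sequence[TransitionEvent],
    window_half: float = 10.0,
    n_shuffles: int = 100,
    rng: np.random.Generator | int | None = 0,
    to_state: str | None = None,
    from_state: str | None = None,
) -> Kernel:
    """BTA kernel plus circle-shift significance (norm above the 99th
    percentile of 100 shuffled-kernel norms by default)."""
    kern = behavior_triggered_average(stimulus, events, window_half, tracks,
                                      to_state=to_state, from_state=from_state)
    if kern.is_empty:
        return kern
    norms = shuffle_null(stimulus, tracks, events, window_half, n_shuffles, rng)
    kern.shuffle_norms = norms
    kern.percentile_99 = float(np.percentile(norms, 99))
    kern.significant = bool(kern.norm > kern.percentile_99)
    return kern


def pairwise_kernels(
    stimulus: StimulusSeries,
    tracks: Sequence[BehaviorTrack],
    events: Sequence[TransitionEvent],
    states: Sequence[str],
    window_half: float = 10.0,
    n_shuffles: int = 100,
    rng: np.random.Generator | int | None = 0,
) -> dict[tuple[str, str], Kernel]:
    """Context-dependent kernels, one per ordered (from, to) state pair.

    Unknown-origin events are excluded; the diagonal is excluded; a
    9-state alphabet yields 72 pairs.  Pairs with no usable events get an
    explicit empty-kernel placeholder.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out: dict[tuple[str, str], Kernel] = {}
    events = [ev for ev in events if ev.from_state is not None]
    for w, x in itertools.permutations(states, 2):
        evs = [ev for ev in events if ev.from_state == w and ev.to_state == x]
        out[(w, x)] = estimate_kernel(stimulus, tracks, evs, window_half,
                                      n_shuffles, rng, to_state=x, from_state=w)
    return out


def cluster_kernels(
    kernels: Sequence[Kernel],
    method: str = "average",
    scale: str = "unit_norm",
):
    """Agglomerative hierarchy over Euclidean distances of scaled kernels.

    Kernels are scaled to unit L2 norm (``scale='unit_norm'``, default) or
    left as-is (``scale='none'``) before hierarchical clustering; returns
    the scipy linkage matrix.
    """
    from scipy.cluster.hierarchy import linkage

    if len(kernels) < 2:
        raise ValueError("clustering requires at least two kernels")
    lengths = {len(k.values) for k in kernels}
    if len(lengths) != 1:
        raise ValueError("kernels must have equal length")
    X = np.stack([k.values for k in kernels]).astype(float)
    if scale == "unit_norm":
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("cannot scale a zero-norm kernel")
        X = X / norms
    elif scale != "none":
        raise ValueError(f"unknown scale {scale!r}")
    return linkage(X, method=method, metric="euclidean")
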