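"""Context-dependent response statistics.

For context-dependent pulse/tap experiments, a single transition rate is
computed for a short window (default 2 s) after each stimulus: tracks
uninterrupted through the window and occupying the origin state at onset
qualify; the first matching transition (if any) within the window is
counted, the count is divided by the total number of tracked time-points,
and the value is converted to transitions · animal⁻¹ · min⁻¹.  Mock
controls are placed at the midpoints between consecutive stimuli.

Stimulus and mock rates are compared with the two-sample Poisson E-test
(Krishnamoorthy & Thomson), and pairwise transition matrices are corrected
by Bonferroni (α = 0.05 / 72 for the 9-state alphabet).
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Iterable, Sequence

import numpy as np
from scipy import stats as _sps

from .behavior_core import BehaviorTrack, TransitionEvent, fraction_to_rate

__all__ = [
    "WindowedCount",
    "ETestResult",
    "windowed_first_transitions",
    "mock_onsets",
    "e_test",
    "e_test_counts",
    "bonferroni",
    "pairwise_response_pvalues",
]


@dataclass
class WindowedCount:
    """First-transition count and exposure for a windowed rate."""

    n_transitions: int
    exposure: float  # tracked time-points (frames) in qualifying windows
    n_presentations: int
    window: float
    dt: float

    @property
    def rate_per_frame(self) -> float:
        if self.exposure == 0:
            return float("nan")
        return self.n_transitions / self.exposure

    @property
    def rate(self) -> float:
        """Transitions · animal⁻¹ · min⁻¹."""
        return float(fraction_to_rate(self.rate_per_frame, self.dt))


@dataclass
class ETestResult:
    rate_stim: float
    rate_mock: float
    statistic: float
    p_value: float
    alpha_corrected: float | None = None

    @property
    def significant(self) -> bool | None:
        if self.alpha_corrected is None:
            return None
        return self.p_value < self.alpha_corrected


def windowed_first_transitions(
    tracks: Sequence[BehaviorTrack],
    events: Iterable[TransitionEvent],
    onsets: Sequence[float],
    from_state: str,
    to_state: str,
    window: float = 2.0,
) -> WindowedCount:
    """Count first W→X transitions in a post-onset window.

    A presentation qualifies for a track when the track is tracked through
    the full ``[onset, onset+window]`` and the animal occupies
    ``from_state`` at onset.  At most one transition is counted per
    qualifying (track, presentation); exposure sums the tracked frames of
    all qualifying windows.
    """
    if not tracks:
        return WindowedCount(0, 0.0, 0, window, float("nan"))
    dt = tracks[0].dt
    wframes = int(round(window / dt))
    ev_by_track: dict[str, list[TransitionEvent]] = {}
    for ev in events:
        if ev.to_state == to_state and ev.from_state == from_state:
            ev_by_track.setdefault(ev.track_id, []).append(ev)

    n_trans = 0
    exposure = 0.0
    n_pres = 0
    for onset in onsets:
        for tr in tracks:
            if not tr.covers(onset, onset + window):
                continue
            f0 = tr.frame_of(onset)
            if f0 < 0 or f0 >= tr.n_frames or tr.labels[f0] != from_state:
                continue
            n_pres += 1
            exposure += wframes
            hits = [ev for ev in ev_by_track.get(tr.track_id, ())
                    if onset < ev.time <= onset + window + 1e-9]
            if hits:
                n_trans += 1  # first transition only
    return WindowedCount(n_trans, exposure, n_pres, window, dt)


def mock_onsets(stim_onsets: Sequence[float]) -> np.ndarray:
    """Mock-control times at the midpoints between consecutive stimuli."""
    onsets = np.asarray(sorted(stim_onsets), dtype=float)
    if len(onsets) < 2:
        raise ValueError("mock controls need at least two stimulus onsets")
    return 0.5 * (onsets[:-1] + onsets[1:])


def _etest_pvalue(k1: int, n1: float, k2: int, n2: float,
                  exact_max: int = 100) -> tuple[float, float]:
    """Two-sided p-value of the two-sample Poisson E-test for H0: λ1 = λ2
    with counts k1, k2 over exposures n1, n2.

    The test statistic is T = (λ̂1 − λ̂2)/sqrt(λ̂1/n1 + λ̂2/n2); its null
    distribution is evaluated by enumerating Poisson outcomes at the
    pooled rate estimate (exact enumeration when both counts are below
    ``exact_max``, a normal approximation otherwise).
    """
    lam1, lam2 = k1 / n1, k2 / n2
    var = lam1 / n1 + lam2 / n2
    if var == 0:
        return 0.0, 1.0
    t_obs = abs(lam1 - lam2) / np.sqrt(var)
    lam_pool = (k1 + k2) / (n1 + n2)

    if max(k1, k2) >= exact_max:
        # normal-based E-statistic for large counts
        p = 2.0 * _sps.norm.sf(t_obs)
        return float(t_obs), float(min(p, 1.0))

    m1 = int(_sps.poisson.ppf(1 - 1e-12, n1 * lam_pool)) + 1
    m2 = int(_sps.poisson.ppf(1 - 1e-12, n2 * lam_pool)) + 1
    x1 = np.arange(m1 + 1)
    x2 = np.arange(m2 + 1)
    p1 = _sps.poisson.pmf(x1, n1 * lam_pool)
    p2 = _sps.poisson.pmf(x2, n2 * lam_pool)
    L1 = x1[:, None] / n1
    L2 = x2[None, :] / n2
    V = L1 / n1 + L2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        T = np.abs(L1 - L2) / np.sqrt(V)
    T[~np.isfinite(T)] = 0.0
    mask = T >= t_obs - 1e-12
    p = float((p1[:, None] * p2[None, :])[mask].sum())
    return float(t_obs), min(p, 1.0)


def e_test_counts(k1: int, n1: float, k2: int, n2: float) -> tuple[float, float]:
    """(statistic, p-value) of the E-test for raw counts and exposures."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("E-test requires positive exposures")
    return _etest_pvalue(int(k1), float(n1), int(k2), float(n2))


def e_test(
    count_stim: WindowedCount,
    count_mock: WindowedCount,
    alpha_corrected: float | None = None,
) -> ETestResult:
    """Two-sided E-test comparing stimulus and mock windowed rates."""
    if count_stim.exposure <= 0 or count_mock.exposure <= 0:
        raise ValueError("E-test requires positive exposures in both conditions")
    stat, p = _etest_pvalue(count_stim.n_transitions, count_stim.exposure,
                            count_mock.n_transitions, count_mock.exposure)
    return ETestResult(rate_stim=count_stim.rate, rate_mock=count_mock.rate,
                       statistic=stat, p_value=p, alpha_corrected=alpha_corrected)


def bonferroni(
    p_values: Sequence[float] | np.ndarray,
    m: int = 72,
    alpha: float = 0.05,
) -> tuple[np.ndarray, float]:
    """Bonferroni correction: flags p < alpha/m; returns (flags, threshold).

    For the 9-state pairwise transition matrix m = 72, giving the
    threshold 0.05/72 ≈ 7·10⁻⁴.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    threshold = alpha / m
    p = np.asarray(p_values, dtype=float)
    return p < threshold, threshold


def pairwise_response_pvalues(
    tracks: Sequence[BehaviorTrack],
    events: Sequence[TransitionEvent],
    onsets: Sequence[float],
    states: Sequence[str],
    window: float = 2.0,
    mock: Sequence[float] | None = None,
    alpha: float = 0.05,
):
    """E-test p-value table over all ordered state pairs (rows = from,
    columns = to), with mock controls at inter-stimulus midpoints unless
    supplied.  Returns a pandas DataFrame; pairs with zero exposure are
    NaN."""
    import pandas as pd

    if mock is None:
        mock = mock_onsets(onsets)
    events = list(events)
    table = pd.DataFrame(np.nan, index=list(states), columns=list(states))
    m = len(states) * (len(states) - 1)
    for w in states:
        for x in states:
            if w == x:
                continue
            cs = windowed_first_transitions(tracks, events, onsets, w, x, window)
            cm = windowed_first_transitions(tracks, events, mock, w, x, window)
            if cs.exposure <= 0 or cm.exposure <= 0:
                continue
            table.loc[w, x] = e_test(cs, cm, alpha_corrected=alpha / m).p_value
    return table
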