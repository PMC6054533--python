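"""Linear-nonlinear model: causal filtering, static nonlinearity, and
transition-rate prediction.

The LN model treats a behavioral transition as a stochastic point process:
the stimulus s(t) is convolved with a kernel A (linear stage), and the
filtered signal is mapped through a static nonlinearity f to a per-frame
transition probability, P(t) = f[(A∗s)(t)].  The convolution integrates
over past stimulus only (lag τ ∈ [0, ∞)); here the causal half of the
estimated ±10 s kernel is used for prediction, the acausal half being kept
for display and significance testing.

The nonlinearity is estimated as the ratio of two histograms over the
filtered signal — time-points at which a transition occurred versus all
time-points — in 10 equally spaced bins, with a propagated Poisson error
per bin, and summarized by a weighted two-parameter exponential fit
f(x) = a·exp(b·x).
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Callable, Sequence

import numpy as np

from .behavior_core import BehaviorTrack, TransitionEvent, fraction_to_rate
from .revcorr import Kernel
from .stimgen import StimulusSeries

__all__ = [
    "Nonlinearity",
    "LNModel",
    "filter_stimulus",
    "poisson_ratio_error",
    "estimate_nonlinearity",
    "fit_ln_model",
]


def poisson_ratio_error(T: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Propagated error of the per-bin probability T/F assuming Poisson
    counting statistics in both the transition count T and the
    filtered-signal time-point count F (with T ⊆ F):

        E = sqrt( T/F² + T²·(F−1)/F⁴ ).
    """
    T = np.asarray(T, dtype=float)
    F = np.asarray(F, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.sqrt(T / F**2 + T**2 * (F - 1.0) / F**4)


@dataclass
class Nonlinearity:
    """Static nonlinearity estimated from the two-histogram ratio.

    ``probs`` are per-frame transition probabilities per bin; ``errors``
    the propagated Poisson errors; (a, b) the weighted exponential fit
    f(x) = a·exp(b·x) with standard errors (a_err, b_err).
    """

    bin_centers: np.ndarray
    probs: np.ndarray
    errors: np.ndarray
    T: np.ndarray
    F: np.ndarray
    a: float
    b: float
    a_err: float
    b_err: float

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        return self.a * np.exp(self.b * np.asarray(x, dtype=float))


def filter_stimulus(kernel: Kernel | np.ndarray, stimulus: StimulusSeries) -> np.ndarray:
    """Causal convolution of the stimulus with the kernel's causal half.

    filtered(t) = Σ_{τ≥0} A(τ)·s(t−τ)·dt.  The leading samples without
    full kernel support are NaN.
    """
    if isinstance(kernel, Kernel):
        _, causal = kernel.causal()
        dt = kernel.dt
    else:
        causal = np.asarray(kernel, dtype=float)
        dt = stimulus.dt
    if abs(dt - stimulus.dt) > 1e-9:
        raise ValueError("kernel and stimulus frame periods differ")
    n_k = len(causal)
    s = stimulus.values
    if len(s) < n_k:
        raise ValueError("stimulus shorter than the kernel's causal support")
    filt = np.convolve(s, causal)[: len(s)] * dt
    filt[: n_k - 1] = np.nan
    return filt


def estimate_nonlinearity(
    filtered: np.ndarray,
    event_frames: Sequence[int] | np.ndarray,
    n_bins: int = 10,
    exposure: np.ndarray | None = None,
    error_form: Callable[[np.ndarray, np.ndarray], np.ndarray] = poisson_ratio_error,
) -> Nonlinearity:
    """Estimate the static nonlinearity from the ratio of two histograms.

    Parameters
    ----------
    filtered : ndarray
        Filtered-signal timeseries (NaN marks invalid samples).
    event_frames : array of int
        Frame indices at which transitions occurred (may repeat when
        several animals transition in the same frame).
    n_bins : int
        Number of equally spaced bins spanning the filtered-signal range.
    exposure : ndarray, optional
        Per-frame count of animals at risk; defaults to 1 per frame.  The
        all-time-points histogram F is exposure-weighted.
    error_form : callable
        Per-bin error E(T, F); defaults to the propagated Poisson form.

    The fit minimizes Σ ((a·exp(b·x) − p)/E)²; bins with F = 0 are
    dropped, and empty-transition bins (T = 0) use the error evaluated at
    T = 1 so they retain finite weight.
    """
    from scipy.optimize import curve_fit

    filtered = np.asarray(filtered, dtype=float)
    valid = np.isfinite(filtered)
    if not valid.any():
        raise ValueError("no valid samples in the filtered signal")
    event_frames = np.asarray(event_frames, dtype=np.intp)
    if len(event_frames) and not valid[event_frames].all():
        event_frames = event_frames[valid[event_frames]]

    lo, hi = filtered[valid].min(), filtered[valid].max()
    if hi <= lo:
        raise ValueError("filtered signal has zero range; cannot bin")
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    w = None if exposure is None else np.asarray(exposure, dtype=float)[valid]
    F, _ = np.histogram(filtered[valid], bins=edges, weights=w)
    T, _ = np.histogram(filtered[event_frames], bins=edges)
    F = F.astype(float)
    T = T.astype(float)
    # evaluate each bin at its (exposure-weighted) mean filtered value,
    # not the geometric midpoint: with curved nonlinearities the midpoint
    # introduces a systematic binning bias
    sx, _ = np.histogram(filtered[valid], bins=edges,
                         weights=filtered[valid] if w is None else w * filtered[valid])
    centers = np.where(F > 0, sx / np.maximum(F, 1e-300), centers)

    occupied = F > 0
    if not occupied.any():
        raise ValueError("all nonlinearity bins are empty")
    with np.errstate(divide="ignore", invalid="ignore"):
        probs = np.where(occupied, T / np.maximum(F, 1e-300), np.nan)
    E = error_form(np.maximum(T, 1.0), F)  # T=0 bins keep finite weight

    x = centers[occupied]
    p = probs[occupied]
    sig = E[occupied]

    # initialize from a log-linear regression on positive bins
    pos = p > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(x[pos], np.log(p[pos]), 1)
        p0 = [float(np.exp(intercept)), float(slope)]
    else:
        p0 = [max(p.mean(), 1e-12), 0.0]

    def model(xx, a, b):
        return a * np.exp(b * xx)

    popt, pcov = curve_fit(model, x, p, p0=p0, sigma=sig,
                           absolute_sigma=True, maxfev=20000)
    perr = np.sqrt(np.diag(pcov))
    return Nonlinearity(bin_centers=centers, probs=probs, errors=E, T=T, F=F,
                        a=float(popt[0]), b=float(popt[1]),
                        a_err=float(perr[0]), b_err=float(perr[1]))


@dataclass
class LNModel:
    """Kernel plus fitted nonlinearity; predicts transition rates."""

    kernel: Kernel
    nonlinearity: Nonlinearity
    dt: float

    def filter(self, stimulus: StimulusSeries) -> np.ndarray:
        return filter_stimulus(self.kernel, stimulus)

    def predict_prob(self, stimulus: StimulusSeries) -> np.ndarray:
        """Per-frame transition probability P(t) = f[(A∗s)(t)]; NaN where
        the convolution lacks support."""
        return self.nonlinearity(self.filter(stimulus))

    def predict_rate(self, stimulus: StimulusSeries) -> np.ndarray:
        """Predicted rate in transitions · animal⁻¹ · min⁻¹."""
        return fraction_to_rate(self.predict_prob(stimulus), self.dt)

    def predict_rate_change(
        self,
        stimulus: StimulusSeries,
        baseline_mode: str = "recording_mean",
        onsets: Sequence[float] | None = None,
        baseline_window: float = 20.0,
    ) -> np.ndarray:
        """Baseline-subtracted predicted rate timeseries.

        ``recording_mean`` subtracts the mean predicted rate over the
        whole record; ``pre_window`` subtracts, per presentation, the mean
        predicted rate in ``baseline_window`` s before each onset and is
        meaningful when ``onsets`` are supplied.
        """
        rate = self.predict_rate(stimulus)
        if baseline_mode == "recording_mean":
            return rate - np.nanmean(rate)
        if baseline_mode != "pre_window":
            raise ValueError(f"unknown baseline_mode {baseline_mode!r}")
        if not onsets:
            raise ValueError("pre_window baseline requires stimulus onsets")
        out = rate.copy()
        nb = int(round(baseline_window / stimulus.dt))
        bounds = [stimulus.index_of(t) for t in onsets] + [len(rate)]
        for k, onset in enumerate(onsets):
            i = bounds[k]
            seg = rate[max(i - nb, 0): i]
            base = np.nanmean(seg) if len(seg) else np.nan
            out[i: bounds[k + 1]] = rate[i: bounds[k + 1]] - base
        return out


def fit_ln_model(
    stimulus: StimulusSeries,
    tracks: Sequence[BehaviorTrack],
    events: Sequence[TransitionEvent],
    kernel: Kernel,
    n_bins: int = 10,
) -> LNModel:
    """Fit the nonlinearity for a given kernel from observed transitions.

    The filtered signal is computed on the shared (plate-wide) stimulus;
    the exposure per frame counts how many animals were tracked, so the
    per-bin probability is transitions per tracked animal-frame.
    """
    filt = filter_stimulus(kernel, stimulus)
    exposure = np.zeros(len(stimulus))
    for tr in tracks:
        i0 = stimulus.index_of(tr.t_start)
        i1 = min(i0 + tr.n_frames, len(stimulus))
        exposure[max(i0, 0): i1] += 1
    frames = [stimulus.index_of(ev.time) for ev in events]
    frames = [f for f in frames if 0 <= f < len(stimulus)]
    nl = estimate_nonlinearity(filt, frames, n_bins=n_bins, exposure=exposure)
    return LNModel(kernel=kernel, nonlinearity=nl, dt=stimulus.dt)
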