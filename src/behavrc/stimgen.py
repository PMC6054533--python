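"""Stimulus generation on a fixed frame clock.

Four stimulus classes are supported, all sampled at the acquisition frame
rate (default 14 Hz):

* exponentially correlated (AR(1) / Ornstein-Uhlenbeck-like) broad-spectrum
  noise, the workhorse stimulus for reverse correlation;
* triangle waves (linear up/down ramps);
* rectangular pulses at a fixed inter-stimulus interval;
* playback waveforms shaped like an estimated kernel, offset onto a
  baseline intensity and scaled to fill the allowed intensity range.

Intensities are in μW mm⁻² throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "NoiseParams",
    "StimulusSeries",
    "generate_noise",
    "generate_triangle",
    "generate_pulse",
    "pulse_onset_times",
    "kernel_to_stimulus",
    "autocorrelation",
    "fit_correlation_time",
]

#: default acquisition frame period, seconds (14 Hz camera clock)
DEFAULT_DT = 1.0 / 14.0


@dataclass(frozen=True)
class NoiseParams:
    """Parameters of the exponentially correlated noise stimulus.

    The discrete recursion is ``s[t+1] = A*s[t] + B*n[t] + (1-A)*C`` with
    ``A = exp(-tau_period/tau_c)`` and ``B = sigma_rms*sqrt(1-A**2)``, where
    ``n`` is unit-variance Gaussian noise.  This gives a stationary process
    with mean ``C = mean_intensity`` and standard deviation ``sigma_rms``
    before clipping.
    """

    tau_c: float = 0.5
    tau_period: float = DEFAULT_DT
    sigma_rms: float = 25.0
    mean_intensity: float = 25.0
    clip_min: float = 0.0
    clip_max: float = 50.0
    seed: int = 0
    duration: float = 1800.0

    def __post_init__(self) -> None:
        for name in ("tau_c", "tau_period", "sigma_rms", "mean_intensity",
                     "clip_min", "clip_max", "duration"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"NoiseParams.{name} must be finite, got {v!r}")
        if self.tau_c <= 0:
            raise ValueError("NoiseParams.tau_c must be > 0")
        if self.tau_period <= 0:
            raise ValueError("NoiseParams.tau_period must be > 0")
        if self.sigma_rms < 0:
            raise ValueError("NoiseParams.sigma_rms must be >= 0")
        if not self.clip_min < self.clip_max:
            raise ValueError("NoiseParams requires clip_min < clip_max")

    @property
    def ar_weight(self) -> float:
        """AR(1) weighting of the previous sample, exp(-tau_period/tau_c)."""
        return math.exp(-self.tau_period / self.tau_c)

    @property
    def noise_weight(self) -> float:
        return self.sigma_rms * math.sqrt(1.0 - self.ar_weight ** 2)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class StimulusSeries:
    """Uniformly sampled intensity timeseries.

    Attributes
    ----------
    values : ndarray
        Intensity per frame, μW mm⁻².
    dt : float
        Frame period, seconds.
    t0 : float
        Time of the first sample, seconds.
    clip_min, clip_max : float or None
        Bounds the series was clipped to, if any.
    unclipped : ndarray or None
        The series before clipping (same noise draws), retained for
        autocorrelation diagnostics.
    """

    values: np.ndarray
    dt: float
    t0: float = 0.0
    clip_min: float | None = None
    clip_max: float | None = None
    unclipped: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) * self.dt

    @property
    def duration(self) -> float:
        return len(self.values) * self.dt

    @property
    def clipped(self) -> bool:
        return self.clip_min is not None or self.clip_max is not None

    def index_of(self, t: float) -> int:
        """Frame index of time ``t`` (nearest sample)."""
        return int(round((t - self.t0) / self.dt))

    def value_at(self, t: float) -> float:
        return float(self.values[self.index_of(t)])


def _n_samples(duration: float, dt: float) -> int:
    return int(round(duration / dt))


def generate_noise(
    params: NoiseParams,
    *,
    clip_in_loop: bool = True,
    literal_offset: bool = False,
) -> StimulusSeries:
    """Generate the exponentially correlated noise stimulus.

    Parameters
    ----------
    params : NoiseParams
    clip_in_loop : bool
        If True (default), each updated sample is clipped before being fed
        back into the recursion, matching an online per-frame hardware
        implementation.  If False, the full unclipped recursion is run and
        clipping is applied afterwards.
    literal_offset : bool
        If True use the constant offset ``C`` verbatim in the recursion
        (stationary mean C/(1-A)); by default the offset is ``(1-A)*C`` so
        that the stationary mean equals ``mean_intensity``.

    Returns
    -------
    StimulusSeries
        Clipped series; the pre-clipping series (same noise draws) is in
        ``.unclipped``.
    """
    n = _n_samples(params.duration, params.tau_period)
    A = params.ar_weight
    B = params.noise_weight
    C = params.mean_intensity
    offset = C if literal_offset else (1.0 - A) * C
    rng = np.random.default_rng(params.seed)
    noise = rng.standard_normal(max(n - 1, 0))

    lo, hi = params.clip_min, params.clip_max
    clipped = np.empty(n)
    unclipped = np.empty(n)
    s0 = C  # initialize at the stationary mean: no burn-in transient
    clipped[0] = min(max(s0, lo), hi)
    unclipped[0] = s0
    c_prev = clipped[0]
    u_prev = s0
    for t in range(n - 1):
        drive = B * noise[t] + offset
        u_prev = A * u_prev + drive
        unclipped[t + 1] = u_prev
        c = A * c_prev + drive if clip_in_loop else u_prev
        c_prev = min(max(c, lo), hi)
        clipped[t + 1] = c_prev

    return StimulusSeries(
        values=clipped, dt=params.tau_period, t0=0.0,
        clip_min=lo, clip_max=hi, unclipped=unclipped,
    )


def generate_triangle(
    period_up: float = 10.0,
    period_down: float = 10.0,
    lo: float = 0.0,
    hi: float = 50.0,
    duration: float = 1800.0,
    dt: float = DEFAULT_DT,
) -> StimulusSeries:
    """Triangle wave: linear ramp lo→hi over ``period_up`` s then hi→lo
    over ``period_down`` s, repeated for the full duration."""
    if not lo < hi:
        raise ValueError("generate_triangle requires lo < hi")
    if period_up <= 0 or period_down <= 0:
        raise ValueError("ramp periods must be > 0")
    cycle = period_up + period_down
    if duration < cycle:
        import warnings

        warnings.warn(
            f"duration {duration} s shorter than one full cycle ({cycle} s); "
            "emitting a partial cycle", stacklevel=2,
        )
    t = np.arange(_n_samples(duration, dt)) * dt
    phase = np.mod(t, cycle)
    rising = phase < period_up
    vals = np.where(
        rising,
        lo + (hi - lo) * phase / period_up,
        hi - (hi - lo) * (phase - period_up) / period_down,
    )
    return StimulusSeries(values=vals, dt=dt, t0=0.0)


def generate_pulse(
    amplitude: float = 20.0,
    width: float = 1.0,
    isi: float = 60.0,
    duration: float = 1800.0,
    dt: float = DEFAULT_DT,
    baseline: float = 0.0,
) -> StimulusSeries:
    """Rectangular pulses of ``amplitude`` above ``baseline``, ``width``
    seconds long, delivered every ``isi`` seconds starting at t = 0."""
    if width >= isi:
        raise ValueError("pulse width must be shorter than the inter-stimulus interval")
    t = np.arange(_n_samples(duration, dt)) * dt
    in_pulse = np.mod(np.round(t / dt).astype(int), int(round(isi / dt))) < int(round(width / dt))
    vals = np.where(in_pulse, baseline + amplitude, baseline)
    return StimulusSeries(values=vals, dt=dt, t0=0.0)


def pulse_onset_times(isi: float, duration: float) -> np.ndarray:
    """Onset times of pulses delivered every ``isi`` s starting at t=0."""
    return np.arange(0.0, duration, isi)


def kernel_to_stimulus(
    kernel,
    baseline: float = 25.0,
    clip_min: float = 0.0,
    clip_max: float = 50.0,
) -> StimulusSeries:
    """Playback stimulus shaped like a kernel's behavior-triggered average.

    The (mean-zero) BTA waveform is offset onto ``baseline`` and scaled by
    the largest factor keeping the series within ``[clip_min, clip_max]`` —
    i.e. until either the minimum touches ``clip_min`` or the maximum
    touches ``clip_max``.  Duration equals the kernel window.

    ``kernel`` may be a :class:`behavrc.revcorr.Kernel` or a plain array in
    BTA (forward-time) orientation together with ``dt`` via a tuple
    ``(values, dt)``.
    """
    if hasattr(kernel, "bta"):
        waveform = np.asarray(kernel.bta, dtype=float)
        dt = kernel.dt
    else:
        waveform, dt = kernel
        waveform = np.asarray(waveform, dtype=float)
    waveform = waveform - waveform.mean()
    norm = float(np.linalg.norm(waveform))
    if norm == 0.0:
        raise ValueError("cannot build a playback stimulus from a zero-norm kernel")
    wmax = waveform.max()
    wmin = waveform.min()
    scales = []
    if wmax > 0:
        scales.append((clip_max - baseline) / wmax)
    if wmin < 0:
        scales.append((baseline - clip_min) / (-wmin))
    scale = min(scales)
    vals = baseline + scale * waveform
    return StimulusSeries(values=vals, dt=dt, t0=0.0, clip_min=clip_min, clip_max=clip_max)


def autocorrelation(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Empirical autocorrelation of ``x`` at lags ``0..max_lag``."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    var = float(np.dot(x, x)) / len(x)
    if var == 0:
        raise ValueError("autocorrelation undefined for a constant series")
    acf = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        acf[k] = np.dot(x[: len(x) - k], x[k:]) / len(x) / var
    return acf


def fit_correlation_time(
    series: StimulusSeries | np.ndarray,
    dt: float | None = None,
    max_lag_s: float = 2.0,
    use_unclipped: bool = True,
) -> float:
    """Fit a single exponential to the empirical ACF; return its time
    constant in seconds.

    For a :class:`StimulusSeries` produced by :func:`generate_noise` the
    pre-clipping series is used by default (clipping distorts the ACF).
    """
    from scipy.optimize import curve_fit

    if isinstance(series, StimulusSeries):
        x = series.unclipped if (use_unclipped and series.unclipped is not None) else series.values
        dt = series.dt
    else:
        x = np.asarray(series, dtype=float)
        if dt is None:
            raise ValueError("dt required when passing a plain array")
    max_lag = int(round(max_lag_s / dt))
    acf = autocorrelation(x, max_lag)
    lags = np.arange(max_lag + 1) * dt

    def model(t, tau):
        return np.exp(-t / tau)

    popt, _ = curve_fit(model, lags, acf, p0=[0.5], maxfev=10000)
    return float(popt[0])
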