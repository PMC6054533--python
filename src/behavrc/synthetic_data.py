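"""Simulated behaving populations with ground-truth LN couplings.

Each animal is a discrete-state Markov chain on the nine-state behavior
alphabet, stepped on the acquisition frame clock.  For an uncoupled
ordered pair W→X the per-frame transition probability is a constant
baseline hazard q·dt; for a stimulus-coupled pair it is
a·exp(b·(g∗s)(t))·dt, the generative assumption behind the LN model.
Hazards are per second; the discrete-time Bernoulli approximation is valid
while the per-frame total transition probability stays well below one
(enforced).

Tracking artifacts are emulated: tracks fragment at a per-frame break
probability (the broken frame is dropped, as when a tracker rejects a
frame), and brief mislabeling "flickers" are injected into the observed
labels to exercise the 0.5 s dwell rule.  Ground-truth transition events
are returned alongside the observed tracks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .behavior_core import (
    DEFAULT_STATES,
    BehaviorTrack,
    TransitionEvent,
)
from .stimgen import DEFAULT_DT, NoiseParams, StimulusSeries, generate_noise

__all__ = [
    "Coupling",
    "AgentModel",
    "PopulationConfig",
    "simulate_population",
    "simulate_point_process",
    "make_plate_scenario",
    "expected_bta_kernel",
    "gaussian_kernel",
    "derivative_kernel",
]


@dataclass
class Coupling:
    """Stimulus coupling of one ordered transition pair.

    The hazard (per second) is ``a * exp(b * (x - offset))`` where
    ``x = (g∗s)(t)`` is the causal convolution of the stimulus with the
    ground-truth kernel ``g`` (kernel coordinates, lag 0 first, spacing
    dt) times dt.  ``offset`` recenters the filtered signal (typically its
    stationary mean) so that ``a`` is the hazard at the mean stimulus.
    """

    kernel: np.ndarray
    a: float
    b: float
    offset: float = 0.0


@dataclass
class AgentModel:
    """Ground-truth generative model of one behaving animal."""

    states: tuple[str, ...] = DEFAULT_STATES
    baseline_hazard: np.ndarray | None = None  # (S, S) per second, diag 0
    couplings: dict[tuple[str, str], Coupling] = field(default_factory=dict)
    dwell_floor: float = 0.0  # refractory after a transition, seconds
    dt: float = DEFAULT_DT

    def __post_init__(self) -> None:
        S = len(self.states)
        if self.baseline_hazard is None:
            self.baseline_hazard = np.full((S, S), 0.04)
        self.baseline_hazard = np.asarray(self.baseline_hazard, dtype=float)
        np.fill_diagonal(self.baseline_hazard, 0.0)
        if (self.baseline_hazard < 0).any():
            raise ValueError("hazards must be >= 0")
        for (w, x) in self.couplings:
            if w == x:
                raise ValueError("self-transitions cannot be coupled")
            if w not in self.states or x not in self.states:
                raise ValueError(f"unknown state in coupling ({w}, {x})")

    def state_index(self, name: str) -> int:
        return self.states.index(name)


@dataclass
class PopulationConfig:
    """Population and tracking-artifact settings.

    Defaults emulate a plate of ~60 simultaneously tracked animals
    recorded for 30 minutes, with tracks breaking about once per 2,000
    frames and occasional 2–4 frame label flickers.
    """

    seed: int
    n_animals: int = 60
    duration: float = 1800.0
    frag_rate: float = 1.0 / 2000.0  # per frame
    flicker_rate: float = 5e-4  # per frame
    initial_state: str | None = None

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")


def _filtered_signal(coupling: Coupling, stimulus: StimulusSeries) -> np.ndarray:
    g = np.asarray(coupling.kernel, dtype=float)
    s = stimulus.values
    x = np.convolve(s, g)[: len(s)] * stimulus.dt
    # leading samples lack full support: hold at the offset (mean drive)
    x[: len(g) - 1] = coupling.offset
    return x


def _hazard_tensor(model: AgentModel, stimulus: StimulusSeries, n_frames: int) -> np.ndarray:
    S = len(model.states)
    H = np.broadcast_to(model.baseline_hazard, (n_frames, S, S)).copy()
    for (w, x), cpl in model.couplings.items():
        xi = _filtered_signal(cpl, stimulus)[:n_frames]
        H[:, model.state_index(w), model.state_index(x)] = (
            cpl.a * np.exp(cpl.b * (xi - cpl.offset))
        )
    return H


def simulate_population(
    model: AgentModel,
    stimulus: StimulusSeries,
    config: PopulationConfig,
) -> tuple[list[BehaviorTrack], list[TransitionEvent]]:
    """Simulate a tracked population; returns (tracks, ground-truth events).

    Ground-truth events are the true state changes, attributed to the
    observed track containing them (events falling on dropped frames are
    omitted, as they would be unobservable).  Observed track labels may
    additionally contain injected sub-dwell flickers that the dwell rule
    is expected to remove.
    """
    dt = model.dt
    n_frames = int(round(config.duration / dt))
    if stimulus.duration < config.duration - 1e-9:
        raise ValueError("stimulus does not cover the requested duration")
    if abs(stimulus.dt - dt) > 1e-9:
        raise ValueError("stimulus and model frame periods differ")

    H = _hazard_tensor(model, stimulus, n_frames)
    P = H * dt
    worst = P.sum(axis=2).max()
    if worst > 1.0:
        raise ValueError(
            f"per-frame total transition probability reaches {worst:.3f} > 1; "
            "time step too coarse for these hazards"
        )

    rng = np.random.default_rng(config.seed)
    S = len(model.states)
    n = config.n_animals
    floor_frames = int(round(model.dwell_floor / dt))

    if config.initial_state is None:
        states = rng.integers(0, S, size=n)
    else:
        states = np.full(n, model.state_index(config.initial_state))
    since = np.full(n, floor_frames)  # frames since last transition

    codes = np.empty((n_frames, n), dtype=np.int8)
    truth: list[list[tuple[int, int, int]]] = [[] for _ in range(n)]  # (frame, from, to)

    for t in range(n_frames):
        codes[t] = states
        probs = P[t][states]  # (n, S)
        c = np.cumsum(probs, axis=1)
        u = rng.random(n)
        moved = (u < c[:, -1]) & (since >= floor_frames)
        if moved.any():
            targets = (u[moved, None] < c[moved]).argmax(axis=1)
            for ai, tgt in zip(np.flatnonzero(moved), targets):
                truth[ai].append((t + 1, int(states[ai]), int(tgt)))
            states = states.copy()
            states[moved] = targets
            since[moved] = 0
        since += 1
    # note: transitions recorded at t+1 take effect on the next frame's labels

    # observed labels: inject brief flickers (observation noise only)
    obs = codes.copy()
    n_flick = rng.poisson(config.flicker_rate * n_frames * n)
    for _ in range(n_flick):
        ai = int(rng.integers(0, n))
        t0 = int(rng.integers(0, n_frames))
        length = int(rng.integers(2, 5))
        wrong = int(rng.integers(0, S - 1))
        if wrong >= obs[t0, ai]:
            wrong += 1
        obs[t0: t0 + length, ai] = wrong

    # fragmentation: dropped frames split each animal's series into tracks
    breaks = rng.random((n_frames, n)) < config.frag_rate

    state_names = np.asarray(model.states, dtype=object)
    tracks: list[BehaviorTrack] = []
    events: list[TransitionEvent] = []
    for ai in range(n):
        drop = np.flatnonzero(breaks[:, ai])
        bounds = np.concatenate(([-1], drop, [n_frames]))
        truth_ai = truth[ai]
        for seg, (b0, b1) in enumerate(zip(bounds[:-1], bounds[1:])):
            start, stop = b0 + 1, b1
            if stop - start < 1:
                continue
            tid = f"a{ai:03d}.{seg}"
            tracks.append(
                BehaviorTrack(
                    track_id=tid,
                    t_start=stimulus.t0 + start * dt,
                    dt=dt,
                    labels=state_names[obs[start:stop, ai]],
                )
            )
            for (tf, frm, to) in truth_ai:
                if start <= tf < stop:
                    events.append(
                        TransitionEvent(
                            track_id=tid,
                            time=stimulus.t0 + tf * dt,
                            to_state=str(state_names[to]),
                            from_state=str(state_names[frm]),
                            frame=tf - start,
                        )
                    )
    return tracks, events


def simulate_plates(
    model: AgentModel,
    stimulus: StimulusSeries,
    config: PopulationConfig,
    n_plates: int,
) -> tuple[list[BehaviorTrack], list[TransitionEvent]]:
    """Pool several independently seeded plates sharing one stimulus.

    Emulates the study design of pooling recordings from many plates;
    track ids are made unique across plates.
    """
    from dataclasses import replace as _replace

    tracks: list[BehaviorTrack] = []
    events: list[TransitionEvent] = []
    for p in range(n_plates):
        cfg = _replace(config, seed=config.seed + 1009 * p)
        trs, evs = simulate_population(model, stimulus, cfg)
        remap = {tr.track_id: f"p{p:02d}.{tr.track_id}" for tr in trs}
        for tr in trs:
            tr.track_id = remap[tr.track_id]
        tracks.extend(trs)
        events.extend(
            TransitionEvent(track_id=remap[ev.track_id], time=ev.time,
                            to_state=ev.to_state, from_state=ev.from_state,
                            frame=ev.frame)
            for ev in evs
        )
    return tracks, events


def simulate_point_process(
    a: float,
    b: float,
    kernel: np.ndarray,
    stimulus: StimulusSeries,
    n_animals: int = 1,
    seed: int = 0,
    offset: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact LN point process: per frame and animal, an event occurs with
    probability a·exp(b·(x(t)−offset))·dt.

    Returns ``(event_frames, x)`` where ``event_frames`` repeats a frame
    index once per animal that fired in it (suitable for
    :func:`behavrc.lnmodel.estimate_nonlinearity` with exposure
    ``n_animals`` per frame).
    """
    cpl = Coupling(kernel=np.asarray(kernel, dtype=float), a=a, b=b, offset=offset)
    x = _filtered_signal(cpl, stimulus)
    p = a * np.exp(b * (x - offset)) * stimulus.dt
    if p.max() > 1.0:
        raise ValueError("per-frame event probability exceeds 1; reduce the hazard")
    rng = np.random.default_rng(seed)
    hits = rng.random((n_animals, len(p))) < p[None, :]
    frames = np.repeat(np.arange(len(p)), hits.sum(axis=0))
    return frames, x


def gaussian_kernel(center: float = 1.5, width: float = 0.75,
                    support: float = 6.0, dt: float = DEFAULT_DT) -> np.ndarray:
    """Causal Gaussian-bump kernel (integrator-like tuning), peak at
    ``center`` seconds in the past; unit peak before normalization."""
    tau = np.arange(0.0, support, dt)
    return np.exp(-0.5 * ((tau - center) / width) ** 2)


def derivative_kernel(center: float = 1.5, width: float = 0.75,
                      support: float = 6.0, dt: float = DEFAULT_DT,
                      sign: float = 1.0) -> np.ndarray:
    """Causal derivative-of-Gaussian kernel.

    With ``sign=+1`` (default) the weight is negative at recent lags and
    positive at older lags, so the filtered signal is large when the
    stimulus has been *decreasing*; ``sign=-1`` flips the tuning to
    increases.
    """
    tau = np.arange(0.0, support, dt)
    g = (tau - center) / width * np.exp(-0.5 * ((tau - center) / width) ** 2)
    return sign * g


def _normalize_coupling(
    g: np.ndarray, params: NoiseParams
) -> tuple[np.ndarray, float]:
    """Scale ``g`` so the filtered signal of the (unclipped) noise process
    has unit standard deviation; return (scaled kernel, mean offset).

    For the AR(1) stimulus, Var[(g∗s)·dt] = σ² Σ_jk g_j g_k ρ(|j−k|) dt²
    with ρ(m) = A^m; the mean is C · Σ g · dt.
    """
    g = np.asarray(g, dtype=float)
    A = params.ar_weight
    dt = params.tau_period
    j = np.arange(len(g))
    rho = A ** np.abs(j[:, None] - j[None, :])
    var = params.sigma_rms ** 2 * float(g @ rho @ g) * dt ** 2
    scale = 1.0 / math.sqrt(var)
    g_scaled = g * scale
    offset = params.mean_intensity * float(g_scaled.sum()) * dt
    return g_scaled, offset


def expected_bta_kernel(
    g: np.ndarray,
    params: NoiseParams,
    window_half: float = 10.0,
) -> np.ndarray:
    """Shape the BTA pipeline is expected to recover for coupling kernel
    ``g`` under the exponentially correlated stimulus.

    For a weakly nonlinear LN agent on a correlated stimulus the BTA is
    proportional to the coupling kernel convolved with the stimulus
    autocorrelation, Cov(s(t−τ), x(t)) ∝ Σ_j g_j ρ(τ − j·dt), evaluated on
    the centered ±window lag grid, mean-subtracted (unit-normalized; the
    BTA determines the kernel only up to scale).
    """
    g = np.asarray(g, dtype=float)
    dt = params.tau_period
    A = params.ar_weight
    n_half = int(round(window_half / dt))
    lags = np.arange(-n_half, n_half + 1)
    j = np.arange(len(g))
    rho = A ** np.abs(lags[:, None] - j[None, :])
    k = rho @ g
    k = k - k.mean()
    return k / np.linalg.norm(k)


def make_plate_scenario(
    seed: int,
    n_animals: int = 60,
    duration: float = 1800.0,
) -> tuple[AgentModel, StimulusSeries, PopulationConfig]:
    """Nine-state scenario mimicking the study's qualitative structure.

    Animals in the four slower forward states respond to the stimulus:
    transitions into the two reversal states are coupled through
    Gaussian-shaped (integrator-like) kernels, and transitions into the
    two fastest forward states through derivative-shaped kernels tuned to
    stimulus decreases.  Every transition out of 'Turn' is uncoupled
    (stimulus-ignoring), as are all remaining pairs.  Coupled origins are
    restricted to states whose own entries are uncoupled, and hazards are
    kept low (dwells of several seconds), so that stimulus-driven
    occupancy fluctuations of the origin state — a real confound of
    context-dependent reverse correlation — stay small compared with the
    direct coupling.  The stimulus is the default exponentially correlated
    noise (0.5 s correlation time, mean 25, clipped to 0–50 μW mm⁻²).

    Coupling strengths are set against the unit-variance normalized
    filtered signal: hazard = a·exp(b·x̃) with b = 1 and a chosen so the
    mean hazard is ≈ 0.025 s⁻¹ (E[e^{bx̃}] = e^{b²/2} for Gaussian x̃);
    uncoupled pairs have a constant 0.012 s⁻¹ hazard.
    """
    params = NoiseParams(seed=seed, duration=duration)
    stimulus = generate_noise(params)

    states = DEFAULT_STATES
    S = len(states)
    q = np.full((S, S), 0.012)
    np.fill_diagonal(q, 0.0)

    b = 1.0
    a = 0.025 * math.exp(-0.5 * b * b)

    shapes = {
        "Slow Reverse": gaussian_kernel(),
        "Fast Reverse": gaussian_kernel(center=2.0, width=1.0),
        "Forward 5": derivative_kernel(),
        "Forward 6": derivative_kernel(center=2.0, width=1.0),
    }
    origins = ("Forward 1", "Forward 2", "Forward 3", "Forward 4")
    couplings: dict[tuple[str, str], Coupling] = {}
    for target, g in shapes.items():
        g_scaled, offset = _normalize_coupling(g, params)
        for origin in origins:
            couplings[(origin, target)] = Coupling(
                kernel=g_scaled, a=a, b=b, offset=offset
            )

    model = AgentModel(states=states, baseline_hazard=q, couplings=couplings,
                       dt=params.tau_period)
    config = PopulationConfig(seed=seed + 1, n_animals=n_animals, duration=duration)
    return model, stimulus, config
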