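# Methods

This note documents the models, estimators and numerical choices behind
`behavrc`, and what the bundled simulator does and does not emulate.

## The LN model of behavioral transitions

A behavioral transition into state X is modeled as an inhomogeneous
point process on the camera frame clock (period dt = 1/14 s). The
per-frame transition probability is

  P(t) = f[(A ∗ s)(t)],  (A ∗ s)(t) = Σ_{τ≥0} A(τ)·s(t−τ)·dt,

where s(t) is the shared (plate-wide) stimulus intensity in μW mm⁻²,
A is a linear kernel, and f a static nonlinearity. The convolution is
causal: only past stimulus can drive a transition. Rates are reported in
transitions·animal⁻¹·min⁻¹ via rate = P·(60/dt).

Assumptions worth keeping in mind: the model is memoryless beyond the
kernel support (no habituation or adaptation terms), assumes a single
linear filter per transition, and treats animals as exchangeable and
independent given the stimulus.

## Stimulus generation

The correlated-noise stimulus follows the AR(1) recursion
s(t+1) = A·s(t) + B·n(t) + (1−A)·C with A = exp(−τ_period/τ_c),
B = σ_rms·√(1−A²), n ~ N(0,1). Defaults: τ_c = 0.5 s, τ_period = 1/14 s,
C = σ_rms = 25 μW mm⁻², clipped to [0, 50] μW mm⁻², 30 min duration.
With the offset written as (1−A)·C the stationary mean is exactly C and
the stationary standard deviation σ_rms; a `literal_offset` flag
reproduces the variant with a bare constant C, whose stationary mean is
C/(1−A). The recursion is initialized at the stationary mean, so there
is no burn-in transient.

Clipping is applied per sample *inside* the recursion by default (the
clipped value propagates), matching an online implementation that
computes each frame's intensity from the last delivered frame; an
outside-the-loop variant is available. The pre-clipping series is
retained on the returned object because clipping biases the ACF; the
correlation-time diagnostic (`fit_correlation_time`) fits exp(−t/τ) to
the empirical ACF of the unclipped series over lags 0–2 s.

Triangle waves default to 10 s up / 10 s down between 0 and
50 μW mm⁻²; pulses to 1 s width at a 60 s inter-stimulus interval.
Kernel-shaped playback offsets the (mean-zero) BTA waveform onto a 25
μW mm⁻² baseline and scales it by the largest factor keeping it inside
[0, 50] — one extreme always touches a bound.

## Dwell rule and transition events

Runs of a single label shorter than 0.5 s are relabeled 'in transition'.
The boundary is inclusive: exactly 7 frames at 14 Hz (0.5 s) counts as a
behavior. A transition into X is stamped on the first frame classified
as X; the origin is the most recent non-sentinel state, including across
an 'in transition' bridge. X → 'in transition' → X excursions produce no
event. A track that simply begins inside a state produces no entry event
(the entry was not observed); a track that begins in the sentinel
produces an unknown-origin event at the first real state. Unknown-origin
events are used for unconditional (into-state) kernels but excluded from
pairwise W→X analyses, which need a defined origin.

Aligned rate timeseries normalize per bin by the number of tracked
animals in that bin (occupancy of the origin state, for pairwise rates);
bins with zero tracked animals are NaN (missing), not zero. Windowed
rate changes subtract either a per-presentation 20 s pre-stimulus
baseline or the whole-recording mean rate; per-presentation
(response − baseline) samples feed a two-sided one-sample t-test,
matching per-presentation standard errors.

## Kernel estimation and significance

The BTA averages the stimulus in a centered ±10 s window (281 samples at
14 Hz) around event times; events whose window leaves the stimulus
record or their parent track are dropped and counted. The kernel is the
BTA minus its own within-window mean, time-reversed, so that positive
lags are pre-transition stimulus; prediction uses only the causal half
(lags ≥ 0), while the acausal half is retained for display and for the
norm-based significance test.

The null distribution circle-shifts event frame offsets within each
track by an integer drawn uniformly from 1..n−1 (n = track frames); the
upper end excludes n because a full rotation would replicate the true
alignment. This preserves the inter-event interval structure of each
train while decorrelating it from the stimulus. One hundred shuffled
BTAs are computed and a kernel is significant when its L2 norm exceeds
the 99th percentile (linear interpolation) of the null norms. On
stimulus-independent event trains the procedure flags ≈1% of kernels, as
calibrated in the test suite over 500 replicates.

Two practical caveats, both visible in the simulator: (i) for a
temporally correlated stimulus the BTA estimates the coupling kernel
*convolved with the stimulus autocorrelation* (helper
`expected_bta_kernel` computes this analytically for the AR(1)
stimulus); no whitening is applied, mirroring raw-BTA practice.
(ii) In pairwise analyses the origin state's occupancy is itself
stimulus-modulated whenever flows in or out of that state are coupled,
which leaks stimulus correlation into otherwise uncoupled exits and
contaminates pairwise kernels for origins with strongly coupled entries.
This is a property of the experiment design, not of the estimator.

Clustering scales kernels to unit L2 norm and applies average-linkage
agglomeration on Euclidean distances; both the scaling and linkage are
configurable since neither is canonical.

## Nonlinearity estimation

f is estimated as the ratio of two histograms over the filtered signal:
T (time-points with a transition) over F (all valid time-points,
exposure-weighted by the number of tracked animals), in 10 equally
spaced bins spanning the filtered-signal range. The per-bin error
assumes Poisson counting in both numerator and denominator:
E = √(T/F² + T²(F−1)/F⁴); the exact algebraic form is swappable via
`error_form`. Bins with F = 0 are dropped; bins with T = 0 use the error
evaluated at T = 1 so they keep finite weight instead of an infinite
one. Each bin is evaluated at its exposure-weighted mean filtered value
rather than the geometric midpoint — with a curved f the midpoint
introduces a systematic (Jensen-type) bias that is visible at ~5·10⁴
events. A two-parameter exponential f(x) = a·e^(bx) is fitted by
weighted least squares (weights 1/E), initialized from a log-linear
regression on positive bins; the fit is deterministic.

Note that a = f(0) is an extrapolation when the filtered signal does not
straddle zero; flat-profile checks therefore evaluate the fitted curve
at the mean filtered value, where the data live.

## E-test and multiple comparisons

Context-dependent responses compare the rate of first transitions in a
2 s post-stimulus window against mock controls placed at inter-stimulus
midpoints. Qualifying presentations require the track to be contiguous
through the window and the animal to occupy the origin state at onset;
at most one transition is counted per presentation and the exposure is
the summed tracked frames of qualifying windows.

Rates are compared with the two-sample Poisson E-test (Krishnamoorthy &
Thomson): the statistic T = (λ̂₁−λ̂₂)/√(λ̂₁/n₁+λ̂₂/n₂) is referred to
its null distribution obtained by enumerating Poisson outcomes at the
pooled rate estimate. Enumeration is exact for counts below 100 and
switches to the normal-based evaluation above, where the two agree
closely. The E-test is uniformly more powerful than the exact
conditional binomial (C-) test; consequently their rejection decisions
cannot coincide on every small-count configuration — the extra
rejections near the α boundary are precisely the E-test's documented
advantage, and the type-I error remains at or below the nominal level
(calibrated at 10⁴ equal-rate replicates in the test suite). Pairwise
transition matrices use Bonferroni correction, α = 0.05/72 ≈ 7·10⁻⁴ for
nine states.

## The synthetic population simulator

Each simulated animal is a discrete-state Markov chain on the nine-state
alphabet, stepped at dt = 1/14 s. Uncoupled ordered pairs W→X transition
with constant probability q·dt; coupled pairs with a·exp(b·(g∗s−μ))·dt,
the generative counterpart of the LN model. Hazards are per second; the
Bernoulli-per-frame approximation is enforced by rejecting
configurations whose per-frame total transition probability exceeds one.
Coupling kernels are normalized so the filtered signal has unit variance
under the nominal (unclipped) stimulus statistics, making b directly
interpretable as log-hazard modulation per standard deviation.

Tracking artifacts are emulated minimally: tracks break with per-frame
probability 1/2000 (the broken frame is dropped, splitting the track),
and brief 2–4-frame label flickers are injected at ~5·10⁻⁴ per frame to
exercise the dwell rule. Ground-truth transition events are returned
alongside the observed tracks.

The 'mechanosensory-plate' scenario couples transitions out of the four slower
forward states into the two reversal states (Gaussian-shaped,
integrator-like kernels, centers 1.5–2 s, widths 0.75–1 s) and into the
two fastest forward states (derivative-of-Gaussian kernels tuned to
stimulus decreases); every exit from 'Turn' is uncoupled. Coupled
origins are restricted to states whose own entries are uncoupled and
hazards are kept low (q = 0.012 s⁻¹ uncoupled, mean 0.025 s⁻¹ coupled;
dwells of several seconds) so that stimulus-driven occupancy
fluctuations — the contamination described above — stay small relative
to the direct coupling. Defaults are 60 animals per plate and 30 min
recordings; analyses that need more events pool several independently
seeded plates sharing one stimulus, mirroring the multi-plate design of
high-throughput assays.

What the simulator does *not* emulate: posture dynamics and the
classification step that produces labels from video (label noise is
reduced to flickers), habituation and other long-timescale
nonstationarities, spatial light-field inhomogeneity, and real dwell-time
distributions (dwells are geometric, possibly with a refractory floor).
Passing tests therefore demonstrate correctness of the estimators under
the LN generative assumptions, not robustness to violations of them.

## Problem sizes and numerical choices

The test suite runs everything at desk scale, chosen once as realistic
reductions of a multi-plate experiment: kernel-recovery checks pool 10
plates × 60 animals × 30 min (~10⁵ transitions, >5,000 events per
coupled target); null calibration uses 500 replicate stimulus-
independent trains of ~240 events on a 10 min stimulus; nonlinearity
recovery uses an exact-LN agent with ~5·10⁴ events; the LN round trip
fits on 30 min of noise and predicts a held-out 10 min triangle wave.
Degenerate inputs are handled explicitly: zero usable events yield an
explicit empty kernel (never NaN), zero-exposure windows are flagged,
zero-norm kernels are rejected for playback and clustering, and
convolution samples without full kernel support propagate as NaN.
All stochastic components take explicit seeds (numpy Generator); fixed
seeds give bit-identical stimuli, populations and shuffle nulls.
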