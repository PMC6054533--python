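import numpy as np
import pytest

from behavrc import lnmodel
from behavrc.lnmodel import (
    LNModel,
    estimate_nonlinearity,
    filter_stimulus,
    poisson_ratio_error,
)
from behavrc.revcorr import Kernel, behavior_triggered_average
from behavrc.behavior_core import TransitionEvent
from behavrc.stimgen import DEFAULT_DT, StimulusSeries, generate_triangle
from behavrc.synthetic_data import (
    _normalize_coupling,
    gaussian_kernel,
    simulate_point_process,
)

DT = DEFAULT_DT


def _kernel_from_causal(causal, dt=DT):
    """Embed a causal filter into a centered-window Kernel."""
    n = len(causal)
    values = np.zeros(2 * (n - 1) + 1)
    values[n - 1:] = causal
    return Kernel(values=values, dt=dt, window_half=(n - 1) * dt, n_events=1)


class TestFiltering:
    def test_delta_kernel_is_identity(self, noise_stim):
        causal = np.zeros(29)
        causal[0] = 1.0 / DT
        k = _kernel_from_causal(causal)
        filt = filter_stimulus(k, noise_stim)
        valid = np.isfinite(filt)
        assert np.allclose(filt[valid], noise_stim.values[valid])

    def test_constant_stimulus(self):
        causal = np.linspace(1.0, 0.0, 20)
        s = StimulusSeries(values=np.full(500, 4.0), dt=DT)
        filt = filter_stimulus(causal, s)
        expected = 4.0 * causal.sum() * DT
        assert np.allclose(filt[np.isfinite(filt)], expected)

    def test_leading_samples_invalid(self, noise_stim):
        causal = np.ones(30)
        filt = filter_stimulus(causal, noise_stim)
        assert np.isnan(filt[:29]).all() and np.isfinite(filt[29:]).all()

    def test_boxcar_matches_brute_force(self):
        tri = generate_triangle(duration=60.0)
        n_box = int(round(3.0 / DT))
        causal = np.full(n_box, 1.0 / (n_box * DT))  # 3 s trailing mean
        filt = filter_stimulus(causal, tri)
        s = tri.values
        for t in [50, 123, 400, 800]:
            brute = sum(causal[j] * s[t - j] * DT for j in range(n_box))
            assert filt[t] == pytest.approx(brute, rel=1e-12)

    def test_convolution_matches_double_loop_exactly(self, noise_stim):
        rng = np.random.default_rng(0)
        causal = rng.standard_normal(12)
        short = StimulusSeries(values=noise_stim.values[:60].copy(), dt=DT)
        filt = filter_stimulus(causal, short)
        for t in range(11, 60):
            brute = sum(causal[j] * short.values[t - j] for j in range(12)) * DT
            assert filt[t] == pytest.approx(brute, rel=1e-12)


class TestNonlinearity:
    def test_stimulus_independent_events_fit_flat(self, noise_stim, noise_params):
        g, off = _normalize_coupling(gaussian_kernel(), noise_params)
        frames, _ = simulate_point_process(0.05, 0.0, g, noise_stim,
                                           n_animals=300, seed=2, offset=off)
        filt = filter_stimulus(g, noise_stim)
        nl = estimate_nonlinearity(filt, frames,
                                   exposure=np.full(len(noise_stim), 300.0))
        # flat profile: slope consistent with zero, and the fitted curve
        # evaluated where the data live equals the event rate per frame
        assert abs(nl.b) < 3 * nl.b_err
        assert nl(off) == pytest.approx(0.05 * DT, rel=0.05)

    def test_exact_ln_agent_recovery(self, noise_stim, noise_params):
        g, off = _normalize_coupling(gaussian_kernel(), noise_params)
        a, b = 0.05, 0.9
        frames, _ = simulate_point_process(a, b, g, noise_stim,
                                           n_animals=300, seed=5, offset=off)
        filt = filter_stimulus(g, noise_stim)
        nl = estimate_nonlinearity(filt, frames,
                                   exposure=np.full(len(noise_stim), 300.0))
        assert nl.b == pytest.approx(b, abs=3 * nl.b_err)

    def test_default_ten_bins(self, noise_stim, noise_params):
        g, off = _normalize_coupling(gaussian_kernel(), noise_params)
        frames, _ = simulate_point_process(0.05, 0.5, g, noise_stim,
                                           n_animals=50, seed=1, offset=off)
        filt = filter_stimulus(g, noise_stim)
        nl = estimate_nonlinearity(filt, frames)
        assert len(nl.bin_centers) == 10 and len(nl.probs) == 10

    def test_uniform_weights_match_any_scale(self, noise_stim, noise_params):
        g, off = _normalize_coupling(gaussian_kernel(), noise_params)
        frames, _ = simulate_point_process(0.05, 0.5, g, noise_stim,
                                           n_animals=50, seed=4, offset=off)
        filt = filter_stimulus(g, noise_stim)
        nl1 = estimate_nonlinearity(filt, frames,
                                    error_form=lambda T, F: np.ones_like(T))
        nl2 = estimate_nonlinearity(filt, frames,
                                    error_form=lambda T, F: 2.0 * np.ones_like(T))
        assert nl1.a == pytest.approx(nl2.a, rel=1e-7)
        assert nl1.b == pytest.approx(nl2.b, rel=1e-7)

    def test_error_formula(self):
        T = np.array([4.0])
        F = np.array([100.0])
        expected = np.sqrt(4 / 100**2 + 16 * 99 / 100**4)
        assert poisson_ratio_error(T, F) == pytest.approx(expected)

    def test_all_invalid_rejected(self):
        with pytest.raises(ValueError):
            estimate_nonlinearity(np.full(100, np.nan), [])


class TestPrediction:
    def _model(self, noise_stim, a=0.05, b=0.9):
        from behavrc.stimgen import NoiseParams

        g, off = _normalize_coupling(gaussian_kernel(),
                                     NoiseParams(seed=3, duration=300.0))
        frames, _ = simulate_point_process(a, b, g, noise_stim,
                                           n_animals=300, seed=6, offset=off)
        events = [TransitionEvent(track_id="t", time=f * DT, to_state="X",
                                  frame=int(f)) for f in frames]
        k = behavior_triggered_average(noise_stim, events)
        filt = filter_stimulus(k, noise_stim)
        nl = estimate_nonlinearity(filt, frames,
                                   exposure=np.full(len(noise_stim), 300.0))
        return LNModel(kernel=k, nonlinearity=nl, dt=DT)

    def test_flat_stimulus_zero_change(self, noise_stim):
        model = self._model(noise_stim)
        flat = StimulusSeries(values=np.full(2000, 25.0), dt=DT)
        change = model.predict_rate_change(flat, "recording_mean")
        assert np.nanmax(np.abs(change)) < 1e-9

    def test_own_kernel_stimulus_evokes_positive_response(self, noise_stim):
        from behavrc.stimgen import kernel_to_stimulus

        model = self._model(noise_stim)
        playback = kernel_to_stimulus(model.kernel, baseline=25.0)
        padded = StimulusSeries(
            values=np.concatenate([np.full(600, 25.0), playback.values,
                                   np.full(600, 25.0)]), dt=DT)
        change = model.predict_rate_change(padded, "recording_mean")
        assert np.nanmax(change) > 0
        # the peak response comes after playback onset, near its end
        peak = np.nanargmax(change)
        assert 600 < peak < 600 + 281 + 140

    def test_invalid_leading_samples_propagate(self, noise_stim):
        model = self._model(noise_stim)
        rate = model.predict_rate(noise_stim)
        n_causal = int(round(10.0 / DT))
        assert np.isnan(rate[: n_causal - 1]).all()
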