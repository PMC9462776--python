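import numpy as np
import pytest

from ablink import (
    NoiseParams,
    ParameterError,
    SensoryTrace,
    analysis_window,
    attentional_load,
    build_impulse_train,
    deterministic_excess,
    deterministic_load,
    make_params,
    sensory_trace,
    simulate_trial,
)
from ablink.blinkprob import exact_noblink_from_excess


def full_excess(spec, params, n_targets):
    """Full-trial deterministic load minus baseline (no window crop)."""
    u = build_impulse_train(spec, n_targets=n_targets)
    return deterministic_load(sensory_trace(u, params), params) - params.mu


class TestSensoryTrace:
    def test_single_target_stays_below_clipping_threshold(self, time1):
        trace = sensory_trace(
            build_impulse_train(time1.stimulus_spec(3), n_targets=1), time1
        )
        assert 0.8 < trace.values.max() < 1.0

    def test_lag1_pair_engages_clipping(self, time1):
        spec = time1.stimulus_spec(1)
        u = build_impulse_train(spec, n_targets=2)
        unclipped = np.convolve(u.values, time1.h1().coefficients)[: u.values.size]
        trace = sensory_trace(u, time1)
        assert unclipped.max() > 1.0
        assert trace.values.max() == 1.0

    def test_lag1_trace_is_sublinear_in_targets(self, time1):
        # combined trace <= sum of single-target traces, strictly somewhere
        spec = time1.stimulus_spec(1)
        pair = sensory_trace(build_impulse_train(spec, n_targets=2), time1).values
        t1_alone = sensory_trace(build_impulse_train(spec, n_targets=1), time1).values
        t2_alone = np.zeros_like(t1_alone)
        shift = spec.lag * spec.target_duration_samples
        t2_alone[shift:] = t1_alone[: t1_alone.size - shift]
        assert np.all(pair <= t1_alone + t2_alone + 1e-12)
        assert np.any(pair < t1_alone + t2_alone - 1e-6)

    def test_clipping_loss_maximal_at_lag1_and_decreasing(self, time1):
        losses = []
        for lag in (1, 2, 3, 4):
            spec = time1.stimulus_spec(lag)
            u = build_impulse_train(spec, n_targets=2)
            unclipped = np.convolve(u.values, time1.h1().coefficients)[: u.values.size]
            losses.append((unclipped - sensory_trace(u, time1).values).sum())
        assert losses[0] > 0
        assert all(a >= b for a, b in zip(losses, losses[1:]))

    def test_two_target_peak_subadditive(self, time1):
        for lag in (1, 2, 3, 5):
            spec = time1.stimulus_spec(lag)
            single_peak = full_excess(spec, time1, 1).max()
            assert full_excess(spec, time1, 2).max() <= 2 * single_peak + 1e-9


class TestLinearRegime:
    def test_superposition_without_clipping(self):
        # low stage-1 gain: no clipping anywhere, so the response to the
        # pair is exactly the sum of the shifted single-target responses
        params = make_params(mu=17.4, sigma=3.2, g1=0.5)
        for lag in (1, 3, 5):
            spec = params.stimulus_spec(lag)
            two = full_excess(spec, params, 2)
            one = full_excess(spec, params, 1)
            shifted = np.zeros_like(one)
            shift = lag * spec.target_duration_samples
            shifted[shift:] = one[: one.size - shift]
            assert np.allclose(two, one + shifted, atol=1e-10)


class TestAttentionalLoad:
    def test_zero_trace_small_sigma_rests_at_mu(self, time1):
        spec = time1.stimulus_spec(3)
        trace = SensoryTrace(values=np.zeros(spec.trial_length_samples), spec=spec)
        params = make_params(mu=17.4, sigma=1e-9)
        load = attentional_load(trace, params, seed=0)
        assert np.allclose(load.values, 17.4, atol=1e-6)

    def test_load_decomposition_invariant(self, time1):
        spec = time1.stimulus_spec(3)
        u = build_impulse_train(spec)
        load = attentional_load(sensory_trace(u, time1), time1, seed=11)
        recomposed = load.deterministic - time1.mu + load.noise_realization
        assert np.allclose(load.values, recomposed)

    def test_mean_load_matches_deterministic_path(self, time1):
        spec = time1.stimulus_spec(3)
        trace = sensory_trace(build_impulse_train(spec), time1)
        det = deterministic_load(trace, time1)
        rng = np.random.default_rng(2024)
        idx = [100, 150, 200, 300]
        n = 600
        sums = np.zeros(len(idx))
        for _ in range(n):
            load = attentional_load(trace, time1, seed=rng)
            sums += load.values[idx]
        se = time1.sigma / np.sqrt(n)
        assert np.all(np.abs(sums / n - det[idx]) < 4 * se)

    def test_distant_targets_make_two_load_peaks(self, time1):
        spec = time1.stimulus_spec(15)
        excess = deterministic_excess(spec, time1)
        interior = excess[1:-1]
        local_max = (interior > excess[:-2]) & (interior >= excess[2:])
        peaks = np.flatnonzero(local_max) + 1
        tall = peaks[excess[peaks] > 0.5 * excess.max()]
        assert tall.size == 2

    def test_rest_state_blink_probability_negligible(self, time1):
        # baseline load is ~11 sigma below threshold: the system does not
        # blink spontaneously
        noblink = exact_noblink_from_excess(
            np.zeros(500), time1.mu, time1.sigma, time1.y_b
        )
        assert 1.0 - noblink < 1e-6


class TestSimulateTrial:
    def test_same_seed_is_bit_identical(self, time1):
        spec = time1.stimulus_spec(3)
        assert simulate_trial(spec, time1, seed=42) == simulate_trial(spec, time1, seed=42)

    def test_blink_flag_consistent_with_max(self, time1):
        spec = time1.stimulus_spec(2)
        for seed in range(20):
            result = simulate_trial(spec, time1, seed=seed)
            assert result.blinked == (result.max_load >= time1.y_b)

    def test_single_target_never_blinks_noise_free(self, time1):
        # deterministic single-target peak sits well below threshold
        spec = time1.stimulus_spec(3)
        peak = deterministic_excess(spec, time1, n_targets=1).max()
        assert time1.mu + peak < time1.y_b

    def test_window_covers_response(self, time1):
        spec = time1.stimulus_spec(3)
        window = analysis_window(spec)
        excess = full_excess(spec, time1, 2)
        assert excess[window].max() == excess.max()


class TestParamInvariants:
    def test_threshold_must_exceed_noise_mean(self):
        with pytest.raises(ParameterError):
            make_params(mu=60.0, sigma=3.0, y_b=53.3)

    def test_clip_threshold_fixed_at_one(self, time1):
        from dataclasses import replace

        with pytest.raises(ParameterError):
            replace(time1, clip_threshold=2.0)

    def test_noise_sd_positive(self):
        with pytest.raises(ParameterError):
            NoiseParams(mean=10.0, sd=0.0)

    def test_mismatched_sample_period_rejected(self, time1):
        spec = time1.stimulus_spec(3)
        bad = type(spec)(lag=3, sample_period_ms=5.0, kernel_lengths=(90, 263))
        with pytest.raises(ParameterError):
            sensory_trace(build_impulse_train(bad), time1)
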