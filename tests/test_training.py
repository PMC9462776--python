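import numpy as np
import pytest

from ablink import (
    ConsistencyConditions,
    CriterionError,
    NoiseParams,
    TrainingScenario,
    check_consistency,
    load_traces_before_after,
    make_params,
    sweep_noise_grid,
    training_interaction,
    ushape_product,
)
from ablink.training import _ushape_from_blink_probs


class TestUshapeProduct:
    def test_degenerate_products(self):
        lags = np.arange(1, 12)
        zero = {lag: 0.0 for lag in lags}
        assert _ushape_from_blink_probs(zero, lags) == 0.0  # never blinks at lag 2
        ideal = {**zero, 2: 1.0}
        assert _ushape_from_blink_probs(ideal, lags) == 1.0

    def test_requires_lags_1_2_and_5plus(self, time1):
        for lags in ([2, 3, 5], [1, 3, 5], [1, 2, 3, 4]):
            with pytest.raises(CriterionError):
                ushape_product(time1, reps=10, lags=lags, seed=0)

    def test_reference_preset_shows_lag1_sparing(self, time1):
        value = ushape_product(time1, reps=500, lags=range(1, 12), seed=0)
        assert 0.2 <= value <= 1.0

    def test_exact_and_mc_agree(self, time1):
        exact = ushape_product(time1, lags=range(1, 12), method="exact_product")
        mc = ushape_product(time1, reps=4000, lags=range(1, 12), seed=1)
        assert abs(exact - mc) < 0.05

    def test_bounded_in_unit_interval(self, time1):
        for mu in (12.0, 16.0, 20.0):
            for sigma in (2.5, 4.5):
                value = ushape_product(
                    time1.with_noise(mu, sigma), lags=range(1, 12),
                    method="exact_product",
                )
                assert 0.0 <= value <= 1.0


class TestCheckConsistency:
    def test_reference_pair_is_consistent(self, time1):
        report = check_consistency(
            (NoiseParams(17.4, 3.2), NoiseParams(13.2, 3.8)), time1
        )
        assert report.condition1 and report.condition2 and report.condition3
        assert report.consistent

    def test_reference_pair_fails_strict_time2_ushape(self, time1):
        # the post-training optimum nearly abolishes the blink, so its own
        # lag-2 blink probability is too low to clear the U-shape bound
        cond = ConsistencyConditions(require_ushape_at_time2=True)
        report = check_consistency(
            (NoiseParams(17.4, 3.2), NoiseParams(13.2, 3.8)), time1, cond=cond
        )
        assert report.ushape_t2 < 0.2
        assert not report.consistent

    def test_unchanged_noise_fails_detection_improvement(self, time1):
        report = check_consistency(
            (NoiseParams(17.4, 3.2), NoiseParams(17.4, 3.2)), time1
        )
        assert not report.condition1
        assert report.detection_t2 < 0.8

    def test_stable_under_reseeding_with_mc(self, time1):
        pair = (NoiseParams(17.4, 3.2), NoiseParams(13.2, 3.8))
        r1 = check_consistency(pair, time1, seed=1, method="monte_carlo")
        r2 = check_consistency(pair, time1, seed=2, method="monte_carlo")
        assert r1.consistent == r2.consistent


@pytest.fixture(scope="module")
def small_grid(time1):
    return sweep_noise_grid(
        np.arange(13.0, 18.5, 0.5), np.arange(3.0, 4.2, 0.4), time1
    )


class TestSweep:
    def test_detection_monotone_in_mu(self, small_grid):
        det = small_grid.detection
        assert np.all(np.diff(det, axis=0) <= 1e-12)

    def test_probabilities_bounded(self, small_grid):
        for arr in (small_grid.detection, small_grid.ushape):
            assert arr.min() >= 0.0 and arr.max() <= 1.0

    def test_consistent_pairs_satisfy_conditions(self, time1, small_grid):
        for (m1, s1), (m2, s2) in small_grid.pair_params()[:5]:
            report = check_consistency(
                (NoiseParams(m1, s1), NoiseParams(m2, s2)), time1
            )
            assert report.consistent

    def test_sigma_increases_on_average(self, small_grid):
        _, mean_dsigma, _ = small_grid.mu_ratio_stats()
        assert mean_dsigma > 0

    def test_grid_containing_reference_presets_pairs_them(self, time1):
        grid = sweep_noise_grid([17.4, 13.2], [3.2, 3.8], time1)
        assert ((0, 0), (1, 1)) in grid.consistent_pairs

    def test_empty_grid_rejected(self, time1):
        from ablink import ParameterError

        with pytest.raises(ParameterError):
            sweep_noise_grid([], [3.0], time1)


class TestInteraction:
    def test_identical_scenarios_give_null_interaction(self, time1, novices):
        same = TrainingScenario(
            group="practitioners",
            time1_noise=novices.time1_noise,
            time2_noise=novices.time2_noise,
        )
        report = training_interaction(same, novices, time1, lag=2, n_reps=4000, seed=3)
        assert abs(report.interaction_percent) < 2.0

    def test_novices_change_little_between_times(self, time1, practitioners, novices):
        report = training_interaction(
            practitioners, novices, time1, lag=2, n_reps=4000, seed=3
        )
        for condition in ("noblink", "blink"):
            d = report.cell_mean("novices", "time1", condition) - report.cell_mean(
                "novices", "time2", condition
            )
            assert abs(d) < 0.01

    def test_practitioner_reduction_is_selective_to_noblink(
        self, time1, practitioners, novices
    ):
        report = training_interaction(
            practitioners, novices, time1, lag=2, n_reps=20000, seed=6
        )
        d_noblink = report.cell_mean("practitioners", "time1", "noblink") - report.cell_mean(
            "practitioners", "time2", "noblink"
        )
        d_blink = report.cell_mean("practitioners", "time1", "blink") - report.cell_mean(
            "practitioners", "time2", "blink"
        )
        assert d_noblink > d_blink > 0


class TestLoadTraces:
    def test_baseline_shift_and_sd_change(self, time1, practitioners):
        before, after = load_traces_before_after(practitioners, time1, lag=2, seed=0)
        # resting deterministic baseline drops by mu1 - mu2 = 3.0 load units
        assert before.deterministic[0] - after.deterministic[0] == pytest.approx(3.0)
        assert practitioners.time2_noise.sd > practitioners.time1_noise.sd

    def test_shared_noise_z_scores(self, time1, practitioners):
        before, after = load_traces_before_after(practitioners, time1, lag=2, seed=8)
        z1 = (before.noise_realization - 17.5) / 3.15
        z2 = (after.noise_realization - 14.5) / 3.8
        assert np.allclose(z1, z2)
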