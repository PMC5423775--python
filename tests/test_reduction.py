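"""Assay reduction: slopes, normalization, model selection, rate recovery."""

import numpy as np
import pytest

from ringmotor import (
    CouplingModel,
    FluorescenceTrace,
    MotorParams,
    fit_escape_model,
    fit_threshold_model,
    gen_band_timecourse,
    gen_doping_dataset,
    gen_fluorescence_trace,
    initial_slope,
    normalize_and_aggregate,
    quantify_degradation,
)

R_GRID = np.arange(0.0, 1.0, 0.1)


class TestInitialSlope:
    def test_exactly_linear_trace(self):
        t = np.arange(20.0)
        tr = FluorescenceTrace(times=t, fluorescence=100.0 - 2.0 * t)
        assert initial_slope(tr) == pytest.approx(-2.0, abs=1e-12)

    def test_short_window_limits_to_derivative(self):
        k, F0 = 0.1, 50.0
        tr = gen_fluorescence_trace(k, F0=F0, dt=1e-4, t_end=0.01)
        assert initial_slope(tr, window=3) == pytest.approx(-F0 * k, rel=1e-3)

    def test_window_validation(self):
        t = np.arange(10.0)
        tr = FluorescenceTrace(times=t, fluorescence=np.ones(10))
        with pytest.raises(ValueError):
            initial_slope(tr, window=2)
        with pytest.raises(ValueError):
            initial_slope(tr, window=20)

    def test_mean_recovery_on_noisy_traces_within_five_percent(self):
        # noise 1% of F0; window covers k * t_window = 0.05
        k, F0 = 0.01, 100.0
        slopes = [
            initial_slope(
                gen_fluorescence_trace(k, F0=F0, noise_sd=1.0, dt=0.1,
                                       t_end=50.0, seed=s)
            )
            for s in range(100)
        ]
        assert abs(np.mean(slopes) - (-F0 * k)) < 0.05 * F0 * k


class TestNormalizeAndAggregate:
    def test_reference_group_normalizes_to_one(self):
        curve = normalize_and_aggregate({0.0: [2.0, 2.2, 1.8], 0.2: [1.0, 1.1]})
        assert curve.activity[0] == pytest.approx(1.0)
        assert curve.activity[1] == pytest.approx(1.05 / 2.0)

    def test_identical_replicates_have_zero_sd(self):
        curve = normalize_and_aggregate({0.0: [2.0, 2.0], 0.5: [1.0, 1.0]})
        assert np.allclose(curve.stderr, 0.0)

    def test_missing_reference_group_rejected(self):
        with pytest.raises(ValueError, match="r = 0"):
            normalize_and_aggregate({0.1: [1.0], 0.2: [0.5]})

    def test_sd_estimate_has_correct_sampling_distribution(self):
        # sample variance of Gaussian triplicates: 2 s^2 / sigma^2 ~ chi2(2)
        rng = np.random.default_rng(0)
        sigma = 0.05
        stats = []
        for _ in range(500):
            reps = 1.0 + rng.normal(0, sigma, size=3)
            curve = normalize_and_aggregate({0.0: [1.0], 0.3: reps})
            stats.append(2 * curve.stderr[1] ** 2 / sigma**2)
        from scipy.stats import chi2, kstest

        assert kstest(stats, chi2(2).cdf).pvalue > 0.01


class TestThresholdModelFit:
    def test_noiseless_single_poison_data_fit_exactly(self):
        ds = gen_doping_dataset(CouplingModel(1), R_GRID, noise_sd=0.0, seed=1)
        fit = fit_threshold_model(ds)
        assert fit.best_m == 1
        assert fit.rss_by_m[1] == pytest.approx(0.0, abs=1e-20)
        assert fit.rss_by_m[2] > 0

    def test_recovers_single_poison_from_noisy_triplicates(self):
        hits = sum(
            fit_threshold_model(
                gen_doping_dataset(CouplingModel(1), R_GRID, reps=3,
                                   noise_sd=0.02, seed=s)
            ).best_m == 1
            for s in range(100)
        )
        assert hits >= 95

    def test_discriminates_two_hit_model(self):
        hits = sum(
            fit_threshold_model(
                gen_doping_dataset(CouplingModel(2), R_GRID, reps=3,
                                   noise_sd=0.02, seed=s)
            ).best_m == 2
            for s in range(100)
        )
        assert hits >= 95

    def test_bootstrap_frequencies_concentrate_on_truth(self):
        ds = gen_doping_dataset(CouplingModel(1), R_GRID, reps=3,
                                noise_sd=0.02, seed=5)
        fit = fit_threshold_model(ds, n_bootstrap=100, seed=6)
        assert fit.bootstrap_ci_m[1] >= 0.9
        assert abs(sum(fit.bootstrap_ci_m.values()) - 1.0) < 1e-12

    def test_simulator_generated_data_select_single_poison(self):
        # closes the loop: mechanistic simulator -> closed-form inference
        ds = gen_doping_dataset(
            MotorParams(k_escape=0.0),
            [0.0, 0.1, 0.2, 0.3, 0.5],
            reps=2, noise_sd=0.0, seed=7, n_assembled=300, t_end=200.0,
        )
        assert fit_threshold_model(ds).best_m == 1

    def test_escape_leaves_positive_residuals_on_poison_curve(self):
        # moderate escape elevates intermediate-r activity above (1-r)^6
        ds = gen_doping_dataset(
            MotorParams(k_escape=0.5, k_reengage=1.0),
            [0.0, 0.2, 0.3, 0.4],
            reps=2, noise_sd=0.0, seed=8, n_assembled=300, t_end=150.0,
        )
        resid = [
            np.mean(ds.replicates_at(r)) - (1 - r) ** 6
            for r in (0.2, 0.3, 0.4)
        ]
        assert all(x > 0 for x in resid)

    def test_degenerate_data_rejected(self):
        ds = gen_doping_dataset(CouplingModel(1), [0.0, 0.1], noise_sd=0.0,
                                seed=9)
        with pytest.raises(ValueError):
            fit_threshold_model(ds)


class TestEscapeFit:
    def test_no_escape_data_estimates_lower_boundary(self):
        ds = gen_doping_dataset(
            MotorParams(k_escape=0.0), [0.0, 0.2, 0.4], reps=2, noise_sd=0.0,
            seed=10, n_assembled=200, t_end=100.0,
        )
        fit = fit_escape_model(ds, MotorParams(), [0.0, 0.2, 0.5, 1.0],
                               seed=11, n_complexes=200, t_end=100.0)
        assert fit.k_escape_hat == 0.0
        assert len(fit.profile) == 4

    def test_fitted_curves_shift_up_with_escape_rate(self):
        # the simulated objective's model curves rise monotonically at r=0.3
        from dataclasses import replace

        from ringmotor import ensemble_activity

        acts = [
            ensemble_activity(
                replace(MotorParams(k_reengage=1.0), k_escape=k),
                0.3, 300, 100.0, seed=12,
            ).atpase_activity
            for k in (0.0, 0.3, 1.0)
        ]
        assert acts[0] < acts[1] < acts[2]


class TestDegradation:
    def test_exact_exponential_recovered_exactly(self):
        table = gen_band_timecourse(0.25, np.arange(8.0))
        fit = quantify_degradation(table[table["condition"] == "complete"])
        assert fit.rate == pytest.approx(0.25, abs=1e-12)
        assert np.allclose(fit.fraction_remaining["fraction"].iloc[0], 1.0)

    def test_control_rate_consistent_with_zero(self):
        table = gen_band_timecourse(0.25, np.arange(8.0), noise_sd=0.01,
                                    seed=13)
        fit = quantify_degradation(table[table["condition"] == "control"])
        assert abs(fit.rate) < 3 * fit.rate_se

    def test_noisy_recovery_within_ten_percent(self):
        k = 0.2
        rates = []
        for s in range(100):
            table = gen_band_timecourse(k, np.arange(8.0), noise_sd=0.02,
                                        seed=s)
            rates.append(
                quantify_degradation(
                    table[table["condition"] == "complete"]
                ).rate
            )
        assert abs(np.mean(rates) - k) < 0.1 * k
        assert np.mean(np.abs(np.array(rates) - k) < 0.1 * k) >= 0.9

    def test_non_positive_intensities_rejected(self):
        import pandas as pd

        bad = pd.DataFrame({"time": [0, 1, 2], "intensity": [1.0, 0.5, -0.1]})
        with pytest.raises(ValueError):
            quantify_degradation(bad)
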