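import numpy as np
import pandas as pd
import pytest

from pigwater.armax import acf
from pigwater.synthetic import (
    TABLE2_ETA,
    BatchConfig,
    CorruptionRates,
    EnvironmentConfig,
    daily_total_curve,
    diurnal_shape,
    mean_consumption_profile,
    simulate_batch,
    simulate_environment,
    simulate_pig_counts,
    truth_parameters,
)


class TestEnvironment:
    def test_degenerate_config_is_pure_annual_sinusoid(self):
        cfg = EnvironmentConfig(diurnal_amplitude=0.0, noise_sd=0.0)
        env = simulate_environment(48, "2021-03-01", cfg, seed=5)
        t = env["temperature"].to_numpy()
        assert np.ptp(t[:24]) == 0.0  # within-day temperatures identical
        doy = pd.Timestamp("2021-03-01").dayofyear
        expected = cfg.annual_mean + cfg.annual_amplitude * np.cos(
            2 * np.pi * (doy - 196) / 365.0)
        assert t[0] == pytest.approx(expected)

    def test_determinism(self):
        env1 = simulate_environment(200, "2021-03-01", seed=11)
        env2 = simulate_environment(200, "2021-03-01", seed=11)
        pd.testing.assert_frame_equal(env1, env2)

    def test_noise_autocorrelation_matches_config(self):
        cfg = EnvironmentConfig(noise_ar=0.8)
        det = simulate_environment(10_000, "2021-01-01",
                                   EnvironmentConfig(noise_ar=0.8, noise_sd=0.0), seed=3)
        env = simulate_environment(10_000, "2021-01-01", cfg, seed=3)
        # deterministic parts coincide, so the difference isolates the noise
        noise = env["temperature"].to_numpy() - det["temperature"].to_numpy()
        assert acf(noise, 1)[1] == pytest.approx(0.8, abs=0.05)

    def test_ammonia_cooler_in_summer(self):
        env = simulate_environment(24 * 365, "2021-01-01", seed=1)
        hot = env[env.index.month.isin([6, 7, 8])]["ammonia"].mean()
        cold = env[env.index.month.isin([12, 1, 2])]["ammonia"].mean()
        assert hot < cold
        assert (env["ammonia"] >= 0).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            simulate_environment(10, "2021-01-01", EnvironmentConfig(noise_ar=1.0))
        with pytest.raises(ValueError):
            simulate_environment(10, "2021-01-01", EnvironmentConfig(noise_sd=-1.0))
        with pytest.raises(ValueError):
            simulate_environment(10, "2021-01-01", EnvironmentConfig(annual_mean=np.nan))


class TestPigCounts:
    def test_zero_mortality_constant(self):
        counts = simulate_pig_counts(700, 0.0, 100, seed=1)
        assert (counts == 700).all()

    def test_non_increasing(self):
        for seed in range(5):
            counts = simulate_pig_counts(690, 0.0339, 2520, seed=seed)
            assert (np.diff(counts) <= 0).all()
            assert counts[0] == 690

    def test_monte_carlo_mean_final_count(self):
        finals = [simulate_pig_counts(690, 0.0339, 2520, seed=s)[-1] for s in range(200)]
        assert np.mean(finals) == pytest.approx(690 * (1 - 0.0339), abs=2.0)


class TestMeanProfile:
    def test_model_truth_constant_when_no_terms(self):
        params = truth_parameters(mu=7.0)
        params.eta = {}
        out = mean_consumption_profile(np.arange(48), np.repeat([1, 2], 24),
                                       mode="model-truth", params=params)
        assert np.allclose(out, 7.0)

    def test_model_truth_harmonics_match_direct_evaluation(self):
        """The harmonic part equals an independently coded sum of sines/cosines
        with the published amplitudes."""
        hours = np.arange(24)
        params = truth_parameters(mu=0.0)
        params.eta = {k: v for k, v in TABLE2_ETA.items() if k[0] in "SC"}
        got = mean_consumption_profile(hours, np.ones(24), mode="model-truth", params=params)
        expected = np.zeros(24, dtype=float)
        for k in range(1, 5):
            expected += TABLE2_ETA[f"S{k}"] * np.sin(2 * np.pi * k * hours / 24)
            expected += TABLE2_ETA[f"C{k}"] * np.cos(2 * np.pi * k * hours / 24)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_farm_first_week_calibration(self):
        hours = np.arange(7 * 24)
        days = 1 + hours // 24
        prof = mean_consumption_profile(hours % 24, days, mode="farm-realistic")
        daily_totals = prof.reshape(7, 24).sum(axis=1) / 1000.0  # L/pig/day
        assert daily_totals.mean() == pytest.approx(2.35, rel=0.01)

    def test_farm_plateau_calibration(self):
        assert daily_total_curve(300.0) == pytest.approx(8.05, rel=0.01)

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            mean_consumption_profile([0], [1], mode="bogus")

    def test_diurnal_shape_peaks(self):
        g = diurnal_shape()
        assert g.sum() == pytest.approx(1.0)
        assert 16 <= np.argmax(g) <= 17  # late-afternoon peak
        morning = g[6:15]
        assert 8 <= 6 + np.argmax(morning) <= 12  # morning bump inside 8-12
        assert g[:5].sum() < 0.02  # near-zero overnight


class TestSimulateBatch:
    def test_noise_free_reproduces_profile(self):
        cfg = BatchConfig(seed=1, duration_weeks=4, corruption=CorruptionRates.none(),
                          non_drinking_rate=0.0, noise_log_sd=0.0)
        batch = simulate_batch(cfg)
        hourly = batch.raw.groupby(batch.raw["timestamp"].dt.floor("h"))["volume_l"].sum()
        per_pig = 1000 * hourly.to_numpy() / batch.clean.data["pig_count"].to_numpy()
        np.testing.assert_allclose(per_pig, batch.clean.data["consumption"].to_numpy(),
                                   rtol=1e-9, atol=1e-9)
        hours = np.arange(cfg.n_hours)
        profile = mean_consumption_profile(hours % 24, 1 + hours // 24, mode="farm-realistic")
        ramp_h = 3 * 24
        np.testing.assert_allclose(batch.clean.data["consumption"].to_numpy()[:-ramp_h],
                                   profile[:-ramp_h], rtol=1e-9)

    def test_farm_clean_non_negative(self):
        cfg = BatchConfig(seed=8, corruption=CorruptionRates.none())
        batch = simulate_batch(cfg)
        assert (batch.clean.data["consumption"] >= 0).all()

    def test_determinism(self):
        b1 = simulate_batch(BatchConfig(seed=77, duration_weeks=2))
        b2 = simulate_batch(BatchConfig(seed=77, duration_weeks=2))
        pd.testing.assert_frame_equal(b1.raw, b2.raw)
        pd.testing.assert_frame_equal(b1.clean.data, b2.clean.data)
        pd.testing.assert_frame_equal(b1.faults, b2.faults)

    def test_model_truth_ar1_noise_autocorrelation(self):
        """With phi = {1: 0.5} and no regressors, the clean series has lag-1
        autocorrelation ~0.5 (AR(1) closed form)."""
        from pigwater.armax import ModelSpec, ParameterSet

        spec = ModelSpec(ar_lags=(1,), regressors=(), intercept=True)
        params = ParameterSet(mu=0.0, phi={1: 0.5}, sigma2=1.0)
        cfg = BatchConfig(mode="model-truth", seed=10, duration_weeks=15,
                          corruption=CorruptionRates.none(), non_drinking_rate=0.0)
        batch = simulate_batch(cfg, model=(spec, params))
        y = batch.clean.data["consumption"].to_numpy()
        assert acf(y, 1)[1] == pytest.approx(0.5, abs=0.04)

    def test_nonstationary_truth_rejected(self):
        from pigwater.armax import ModelSpec, ParameterSet

        spec = ModelSpec(ar_lags=(1,))
        params = ParameterSet(phi={1: 1.01})
        cfg = BatchConfig(mode="model-truth", seed=1, duration_weeks=2)
        with pytest.raises(ValueError, match="root modulus"):
            simulate_batch(cfg, model=(spec, params))


class TestCorruption:
    def test_zero_rates_identity(self):
        cfg = BatchConfig(seed=2, duration_weeks=2, corruption=CorruptionRates.none())
        batch = simulate_batch(cfg)
        from pigwater.synthetic import corrupt_readings

        out, ledger = corrupt_readings(batch.raw, CorruptionRates.none(), seed=3)
        pd.testing.assert_frame_equal(out, batch.raw)
        assert ledger.empty

    def test_extreme_values_exceed_threshold_by_construction(self):
        cfg = BatchConfig(seed=4, duration_weeks=4,
                          corruption=CorruptionRates(0.0, 0.08, 0.0, 0.0))
        batch = simulate_batch(cfg)
        hour = batch.raw["timestamp"].dt.floor("h")
        per_pig = 1000 * batch.raw.groupby(hour)["volume_l"].sum() / \
            batch.raw.groupby(hour)["pig_count"].first()
        extreme_hours = pd.to_datetime(batch.faults.loc[batch.faults["kind"] == "extreme",
                                                        "timestamp"])
        assert len(extreme_hours) > 0
        assert (per_pig.loc[extreme_hours] > 10_000).all()

    def test_injected_count_mean_matches_rate(self):
        """Per-kind injection counts are Binomial(n_hours, rate)."""
        n_hours = BatchConfig(duration_weeks=4).n_hours
        rate = 0.05
        counts = []
        for seed in range(30):
            cfg = BatchConfig(seed=seed, duration_weeks=4,
                              corruption=CorruptionRates(rate, 0.0, 0.0, 0.0))
            counts.append(len(simulate_batch(cfg).faults))
        expect = rate * n_hours
        sd = np.sqrt(n_hours * rate * (1 - rate) / 30)
        assert np.mean(counts) == pytest.approx(expect, abs=4 * sd)

    def test_outlier_fraction_near_paper_rate(self):
        """Default split of the 7.48% outlier rate injects ~7.48% faulted hours."""
        total = 0
        hours = 0
        for seed in range(3):
            cfg = BatchConfig(seed=seed, corruption=CorruptionRates.from_outlier_rate(
                0.0748, consecutive=0.0, missing=0.0))
            b = simulate_batch(cfg)
            total += len(b.faults)
            hours += cfg.n_hours
        assert total / hours == pytest.approx(0.0748, abs=0.005)

    def test_ledger_matches_raw_vs_clean_difference(self):
        """The set of faulted hours equals exactly the hours where raw hourly
        aggregation differs from the clean ground truth."""
        cfg = BatchConfig(seed=12, duration_weeks=4, non_drinking_rate=0.0)
        batch = simulate_batch(cfg)
        hour = batch.raw["timestamp"].dt.floor("h")
        agg = batch.raw.groupby(hour).agg(volume_l=("volume_l", "sum"),
                                          n=("volume_l", "size"))
        clean_total = (batch.clean.data["consumption"] *
                       batch.clean.data["pig_count"] / 1000.0)
        agg = agg.reindex(clean_total.index, fill_value=0)
        differs = (~np.isclose(agg["volume_l"], clean_total, rtol=1e-9, atol=1e-9)) | \
                  (agg["n"] != 3)
        ledgered = set(pd.to_datetime(batch.faults["timestamp"]))
        assert set(clean_total.index[differs]) == ledgered
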