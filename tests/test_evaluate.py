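"""Evaluation methods: correlation machinery, significance thresholds,
conduction-loss metrics and the disposable-ECG compliance rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import seeplab as sl
from seeplab.circuit import band_grid
from seeplab.errors import (
    CoverageError,
    InputError,
    UndefinedCorrelationError,
    UndefinedMetricError,
)
from seeplab.evaluate import clas_metrics, critical_r, method2_correlate, pearson
from seeplab.features import ELECTROCHEMICAL_COLUMNS, SECP_COLUMNS
from seeplab.platforms import SignalPair


def brute_force_pearson(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    cx = x - x.mean()
    cy = y - y.mean()
    return float((cx * cy).sum() / np.sqrt((cx ** 2).sum() * (cy ** 2).sum()))


class TestPearson:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3], [2, 4, 6], 1.0),
            ([1, 2, 3], [6, 4, 2], -1.0),
            ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),
        ],
    )
    def test_known_values(self, x, y, expected):
        assert pearson(x, y) == pytest.approx(expected)
        assert pearson(x, y) == pytest.approx(brute_force_pearson(x, y))

    def test_random_draws_match_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.normal(size=15)
            y = rng.normal(size=15)
            assert pearson(x, y) == pytest.approx(brute_force_pearson(x, y))

    def test_error_conditions(self):
        with pytest.raises(InputError):
            pearson([1, 2], [1, 2, 3])
        with pytest.raises(InputError):
            pearson([1, 2], [3, 4])
        with pytest.raises(UndefinedCorrelationError):
            pearson([1, 1, 1], [1, 2, 3])


class TestCriticalR:
    def test_alpha_001_df8(self):
        # t_crit(0.005, 8) mapped through r = t/sqrt(t^2 + df)
        assert critical_r(0.01, 8) == pytest.approx(0.7646, abs=5e-4)

    def test_matches_t_distribution_oracle(self):
        for alpha, df in [(0.05, 8), (0.01, 18), (0.001, 5)]:
            t = stats.t.ppf(1 - alpha / 2, df)
            r = critical_r(alpha, df)
            # mapping back: the t statistic of r at n = df + 2 equals t_crit
            assert r * np.sqrt(df) / np.sqrt(1 - r * r) == pytest.approx(t)


def _linear_table(n_samples=3, n_levels=10, slope=-1.0, rng=None):
    """Feature table whose electrochemical columns are exact linear
    functions of USECP (plus optional noise)."""
    rows = []
    for s in range(n_samples):
        usecp = np.linspace(30, 300, n_levels)
        lsecp = np.full(n_levels, 123.0)
        for i in range(n_levels):
            row = {"sample": f"S{s}", "pressure_n": usecp[i] / 100}
            for col in ELECTROCHEMICAL_COLUMNS:
                val = 1000.0 + slope * usecp[i]
                if rng is not None:
                    val += rng.normal(0, 1e-9)
                row[col] = val
            row.update(
                {
                    "USECP": usecp[i],
                    "LSECP": lsecp[i],
                    "SECP_D": usecp[i] - lsecp[i],
                    "SECP_S": usecp[i] + lsecp[i],
                    "speed_mm_s": 0.0,
                    "path_mm": 0.0,
                }
            )
            rows.append(row)
    return pd.DataFrame(rows)


class TestMethod1:
    def test_exact_linearity_is_flagged_significant(self):
        report = sl.method1_correlate(_linear_table())
        assert report.critical == pytest.approx(0.7646, abs=5e-4)
        for col in ELECTROCHEMICAL_COLUMNS:
            assert report.mean.loc[col, "USECP"] == pytest.approx(-1.0)
            assert bool(report.significant.loc[col, "USECP"])

    def test_grid_dimensions(self):
        report = sl.method1_correlate(_linear_table())
        assert report.mean.shape == (14, 4)
        assert list(report.mean.columns) == SECP_COLUMNS

    def test_constant_conditioner_reported_as_missing(self):
        table = _linear_table()
        report = sl.method1_correlate(table)
        # LSECP is constant -> undefined, excluded from flags
        assert report.mean["LSECP"].isna().all()
        assert not report.significant["LSECP"].any()

    def test_coefficients_bounded(self, catalog, coarse_levels):
        sessions = [
            sl.simulate_peep_session(s, coarse_levels, seed=i)
            for i, s in enumerate(catalog[:4])
        ]
        report = sl.method1_correlate(sl.feature_table(sessions))
        vals = report.per_sample.to_numpy()
        finite = vals[np.isfinite(vals)]
        assert np.all(finite <= 1.0) and np.all(finite >= -1.0)

    def test_noise_off_low_bands_negative_vs_usecp(self, catalog, coarse_levels):
        import dataclasses

        quiet = [
            dataclasses.replace(s, noise=sl.NoiseSpec.off()) for s in catalog[:3]
        ]
        sessions = [
            sl.simulate_peep_session(s, coarse_levels, seed=i)
            for i, s in enumerate(quiet)
        ]
        report = sl.method1_correlate(sl.feature_table(sessions))
        for k in range(1, 7):
            assert report.mean.loc[f"ACI_{k}", "USECP"] < 0


class TestMethod2:
    def test_zero_motion_is_undefined_not_zero(self):
        table = _linear_table()
        report = method2_correlate(table)
        assert report.mean["speed_mm_s"].isna().all()
        assert not report.significant["speed_mm_s"].any()

    def test_constructed_speed_artifact_flagged(self):
        rng = np.random.default_rng(0)
        rows = []
        for s in range(3):
            speeds = np.linspace(0, 40, 10)
            for v in speeds:
                row = {"sample": f"S{s}", "pressure_n": 1.0}
                for col in ELECTROCHEMICAL_COLUMNS:
                    row[col] = 100.0 + 2.0 * v  # exact linear artifact
                row.update(
                    {
                        "USECP": 100.0 + rng.normal(),
                        "LSECP": 123.0,
                        "SECP_D": 0.0,
                        "SECP_S": 0.0,
                        "speed_mm_s": v,
                        "path_mm": v * 10,
                    }
                )
                rows.append(row)
        report = method2_correlate(pd.DataFrame(rows))
        assert report.mean.loc["ACI_3", "speed_mm_s"] == pytest.approx(1.0)
        assert bool(report.significant.loc["ACI_3", "speed_mm_s"])

    def test_shuffled_labels_rarely_reach_significance(self):
        """Permutation oracle: with the linear link broken by shuffling,
        |r| stays below the critical value in >= 99% of permutations."""
        rng = np.random.default_rng(17)
        n = 10
        y = rng.normal(size=n)
        speeds = rng.normal(size=n)
        crit = critical_r(0.01, n - 2)
        hits = 0
        n_perm = 10_000
        for _ in range(n_perm):
            r = brute_force_pearson(rng.permutation(speeds), y)
            if abs(r) >= crit:
                hits += 1
        assert hits / n_perm < 0.01


@pytest.fixture(scope="module")
def ecg():
    _, x = sl.synth_source_signal("ecg", 60.0, 1.0, 10.0, 500.0)
    return x


class TestClas:
    def test_identity_transfer_is_exactly_lossless(self, ecg):
        report = clas_metrics(SignalPair(500.0, ecg, ecg.copy(), 10.0))
        assert report.attenuation == 0.0
        assert report.rmse_mv == 0.0
        assert report.lag_s == 0.0
        assert report.snr_difference_db == 0.0
        assert np.nanmax(report.band_loss) == 0.0

    def test_half_amplitude_power_ratios(self, ecg):
        report = clas_metrics(SignalPair(500.0, ecg, 0.5 * ecg, 10.0))
        assert report.attenuation == pytest.approx(0.5)
        # power ratio (0.5)^2 -> loss 1 - 0.25 = 0.75 in every band
        np.testing.assert_allclose(report.band_loss, 0.75, rtol=1e-9)
        assert report.rmse_mv > 0

    def test_added_noise_raises_snr_difference(self, ecg):
        rng = np.random.default_rng(3)
        noisy = ecg + rng.normal(0, 0.05, ecg.size)
        report = clas_metrics(SignalPair(500.0, ecg, noisy, 10.0))
        assert report.snr_difference_db > 0

    def test_common_shift_invariance(self, ecg):
        shifted_sg = np.roll(ecg, 40)
        shifted_me = np.roll(0.5 * ecg, 40)
        a = clas_metrics(SignalPair(500.0, ecg, 0.5 * ecg, 10.0))
        b = clas_metrics(SignalPair(500.0, shifted_sg, shifted_me, 10.0))
        assert b.attenuation == pytest.approx(a.attenuation)
        np.testing.assert_allclose(b.band_loss, a.band_loss, rtol=1e-9)
        assert b.snr_difference_db == pytest.approx(a.snr_difference_db)

    def test_lag_detected(self, ecg):
        lagged = np.roll(ecg, 25)  # 50 ms at 500 Hz
        report = clas_metrics(SignalPair(500.0, ecg, lagged, 10.0))
        assert report.lag_s == pytest.approx(0.05)

    def test_zero_power_source_rejected(self):
        zeros = np.zeros(100)
        with pytest.raises(UndefinedMetricError):
            clas_metrics(SignalPair(500.0, zeros, zeros, 0.2))


def _flat_pair_spectra(values_ohm):
    grid = band_grid()
    return [
        sl.ImpedanceSpectrum(grid, np.full(grid.size, v), np.zeros(grid.size))
        for v in values_ohm
    ]


class TestCompliance:
    def test_uniform_1k_passes_both_impedance_rules(self):
        record = sl.yyt_compliance(_flat_pair_spectra([1000.0] * 12))
        assert record.mean_rule_pass and record.pair_rule_pass
        assert record.mean_z10_ohm == pytest.approx(1000.0)

    def test_single_outlier_fails_pair_rule_despite_mean(self):
        record = sl.yyt_compliance(_flat_pair_spectra([1000.0] * 11 + [3500.0]))
        assert record.mean_rule_pass  # mean ~1208 ohm still passes
        assert not record.pair_rule_pass

    def test_mean_rule_boundary(self):
        record = sl.yyt_compliance(_flat_pair_spectra([2100.0] * 12))
        assert not record.mean_rule_pass  # mean 2.1 kOhm > 2 kOhm
        assert record.pair_rule_pass

    def test_current_rule_from_low_frequency_impedance(self):
        # 100 mV over 900 ohm -> 111 uA exceeds the 100 uA limit
        record = sl.yyt_compliance(_flat_pair_spectra([900.0] * 12), drive=100.0)
        assert not record.current_rule_pass
        ok = sl.yyt_compliance(_flat_pair_spectra([1100.0] * 12), drive=100.0)
        assert ok.current_rule_pass

    def test_wrong_pair_count_rejected(self):
        with pytest.raises(InputError):
            sl.yyt_compliance(_flat_pair_spectra([1000.0] * 11))

    def test_missing_10hz_coverage_rejected(self):
        grid = np.linspace(20.0, 100.0, 100)
        spectra = [
            sl.ImpedanceSpectrum(grid, np.ones(100), np.zeros(100))
            for _ in range(12)
        ]
        with pytest.raises(CoverageError):
            sl.yyt_compliance(spectra)
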