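"""Periodogram estimators, peak detection, and population rhythmicity statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ethokit as ek
from ethokit.periodogram import resample_series
from ethokit.time_utils import days, hours, mins


def brute_force_chi_sq(x: np.ndarray, r: int) -> float:
    """Independent O(N*P) Sokolove-Bushell statistic via explicit loops."""
    n = len(x)
    grand = sum(x) / n
    s2 = sum((v - grand) ** 2 for v in x) / n
    total = 0.0
    for h in range(r):
        phase = [x[i] for i in range(n) if i % r == h]
        if phase:
            m_h = sum(phase) / len(phase)
            total += (m_h - grand) ** 2
    return (n / r) * total / s2


class TestResample:
    def test_bin_means(self):
        t = 60.0 * np.arange(20)
        v = np.array([1, 1, 1, 1, 1, 1, 0, 0, 0, 0] * 2, dtype=float)
        t0, grid = resample_series(t, v, 600.0)
        assert t0 == 0.0
        np.testing.assert_allclose(grid, [0.6, 0.6])

    def test_empty_bins_are_missing(self):
        t = np.array([0.0, 1800.0])
        _, grid = resample_series(t, np.array([1.0, 2.0]), 600.0)
        assert np.isnan(grid[1]) and np.isnan(grid[2])
        np.testing.assert_allclose(grid[[0, 3]], [1.0, 2.0])


class TestChiSquare:
    def test_hand_computed_values(self):
        x = np.array([1.0, 0, 0, 0, 1, 0, 0, 0])
        pg = ek.chi_sq_periodogram(x, delta=1.0, period_range=(2, 4), correction="none")
        by_period = pg.set_index("period")
        assert by_period.loc[4.0, "power"] == pytest.approx(8.0, abs=1e-12)
        assert by_period.loc[2.0, "power"] == pytest.approx(8 / 3, abs=1e-12)
        # chi-square quantile threshold at P=4 bins: df=3
        assert by_period.loc[4.0, "signif_threshold"] == pytest.approx(
            stats.chi2.ppf(0.95, 3)
        )
        assert by_period.loc[4.0, "power"] > by_period.loc[4.0, "signif_threshold"]

    def test_matches_brute_force_on_random_series(self):
        rng = np.random.default_rng(2024)
        for _ in range(20):
            n = int(rng.integers(60, 200))
            x = rng.poisson(2, size=n).astype(float)
            if x.var() == 0:
                continue
            pg = ek.chi_sq_periodogram(x, 1.0, period_range=(5, n // 2))
            for period, power in zip(pg["period"], pg["power"]):
                assert power == pytest.approx(
                    brute_force_chi_sq(x, int(period)), abs=1e-10
                )

    def test_affine_invariance(self):
        rng = np.random.default_rng(9)
        x = rng.poisson(3, size=300).astype(float)
        base = ek.chi_sq_periodogram(x, 1.0, (5, 50))["power"]
        shifted = ek.chi_sq_periodogram(x + 7.5, 1.0, (5, 50))["power"]
        scaled = ek.chi_sq_periodogram(3.2 * x, 1.0, (5, 50))["power"]
        np.testing.assert_allclose(base, shifted, atol=1e-9)
        np.testing.assert_allclose(base, scaled, atol=1e-9)

    def test_zero_within_phase_variance_gives_n(self):
        # perfectly periodic series: Q at the true period equals N exactly
        x = np.tile([3.0, 1.0, 0.0, 0.0, 2.0], 40)
        pg = ek.chi_sq_periodogram(x, 1.0, (3, 8))
        q5 = pg.set_index("period").loc[5.0, "power"]
        assert q5 == pytest.approx(len(x), rel=1e-12)

    def test_missing_bins_dropped(self):
        x = np.tile([1.0, 0.0, 0.0, 0.0], 30)
        x_missing = x.copy()
        x_missing[5:9] = np.nan
        pg = ek.chi_sq_periodogram(x_missing, 1.0, (3, 6))
        assert np.isfinite(pg["power"]).all()
        # still strongly periodic at 4 bins
        assert pg.loc[pg["power"].idxmax(), "period"] == 4.0

    def test_constant_series_errors(self):
        with pytest.raises(ValueError, match="constant"):
            ek.chi_sq_periodogram(np.ones(100), 1.0, (3, 10))


class TestLombScargle:
    def test_constant_series_zero_power(self):
        t = 600.0 * np.arange(900)
        pg = ek.ls_periodogram(t, np.full(900, 2.0))
        assert (pg["power"] == 0).all()

    def test_m_frequency_threshold_closed_form(self):
        # with M evaluated frequencies, z* = -ln(1 - 0.95^(1/M)); M=100 -> 7.576
        z = -math.log(1 - 0.95 ** (1 / 100))
        assert z == pytest.approx(7.5766, abs=1e-3)

    def test_sinusoid_period_recovery(self):
        t = np.arange(0, days(6), mins(10))
        y = np.sin(2 * np.pi * t / hours(25))
        pg = ek.ls_periodogram(t, y, (hours(16), hours(32)))
        best = pg.loc[pg["power"].idxmax(), "period"]
        grid_step = np.diff(np.sort(pg["period"])).max()
        assert abs(best - hours(25)) <= grid_step

    def test_white_noise_unit_mean_power(self):
        rng = np.random.default_rng(77)
        t = np.arange(0, days(6), mins(10))
        powers = [
            ek.ls_periodogram(t, rng.normal(size=t.size), (hours(2), hours(32)))[
                "power"
            ].mean()
            for _ in range(20)
        ]
        assert np.mean(powers) == pytest.approx(1.0, abs=0.1)


class TestAutocorrelation:
    def test_threshold_closed_form(self):
        x = np.random.default_rng(1).normal(size=1000)
        pg = ek.ac_periodogram(x, 1.0, (10, 100), alpha=0.05)
        assert pg["signif_threshold"].iloc[0] == pytest.approx(1.96 / math.sqrt(1000), abs=1e-4)

    def test_periodic_series_acf_one(self):
        x = np.tile([1.0, 0.0, 0.0, 2.0, 0.5], 100)
        pg = ek.ac_periodogram(x, 1.0, (3, 20))
        acf5 = pg.set_index("period").loc[5.0, "power"]
        # circular repetition: ACF at the true lag is (N-L)/N of unity
        assert acf5 == pytest.approx((500 - 5) / 500, abs=1e-6)

    def test_white_noise_exceedance_near_alpha(self):
        rng = np.random.default_rng(42)
        exceed, total = 0, 0
        for _ in range(200):
            x = rng.normal(size=400)
            pg = ek.ac_periodogram(x, 1.0, (10, 60), alpha=0.05)
            exceed += int((np.abs(pg["power"]) > pg["signif_threshold"]).sum())
            total += len(pg)
        assert abs(exceed / total - 0.05) < 0.02


class TestFourier:
    def test_sinusoid_at_fourier_frequency(self):
        n, delta = 600, 1.0
        t = delta * np.arange(n)
        y = np.sin(2 * np.pi * 10 * t / n)  # exact Fourier frequency, period 60
        pg = ek.fourier_periodogram(y, delta, (30, 100))
        top = pg.loc[pg["power"].idxmax()]
        assert top["period"] == pytest.approx(60.0)
        # all signal power concentrates in that one bin: N/2 normalized
        assert top["power"] == pytest.approx(n / 2, rel=1e-6)

    def test_white_noise_unit_mean(self):
        rng = np.random.default_rng(3)
        means = [
            ek.fourier_periodogram(rng.normal(size=512), 1.0, (4, 128))["power"].mean()
            for _ in range(30)
        ]
        assert np.mean(means) == pytest.approx(1.0, abs=0.1)

    def test_amplitude_scaling_of_peak(self):
        n = 512
        t = np.arange(n)
        noise = np.random.default_rng(8).normal(0, 0.1, n)
        base = ek.fourier_periodogram(np.sin(2 * np.pi * 16 * t / n) + noise, 1.0, (8, 128))
        # doubling the amplitude quadruples the (un-normalised) peak power; the
        # ratio shows up against the constant noise floor
        double = ek.fourier_periodogram(2 * np.sin(2 * np.pi * 16 * t / n) + noise, 1.0, (8, 128))
        p1 = base.loc[base["power"].idxmax(), "power"] * np.var(np.sin(2 * np.pi * 16 * t / n) + noise)
        p2 = double.loc[double["power"].idxmax(), "power"] * np.var(2 * np.sin(2 * np.pi * 16 * t / n) + noise)
        assert p2 / p1 == pytest.approx(4.0, rel=0.05)


class TestFindPeaks:
    def _pg(self, power, thresh=5.0):
        periods = np.linspace(hours(16), hours(32), len(power))
        return pd.DataFrame(
            {"period": periods, "power": power, "signif_threshold": thresh}
        )

    def test_no_significant_power_no_peaks(self):
        pg = ek.find_peaks(self._pg(np.full(50, 1.0)))
        assert (pg["peak"] == 0).all()

    def test_single_peak_rank_one(self):
        power = np.full(50, 1.0)
        power[25] = 10.0
        pg = ek.find_peaks(self._pg(power))
        assert pg.loc[pg["peak"] == 1, "power"].item() == 10.0

    def test_two_peaks_ranked_by_relative_power(self):
        power = np.full(80, 1.0)
        power[20] = 8.0  # rel power 3
        power[60] = 10.0  # rel power 5
        pg = ek.find_peaks(self._pg(power))
        assert pg.loc[pg["peak"] == 1, "power"].item() == 10.0
        assert pg.loc[pg["peak"] == 2, "power"].item() == 8.0

    def test_dominance_window_suppresses_shoulder(self):
        power = np.full(200, 1.0)
        power[100] = 10.0
        power[102] = 9.0  # local max but within 5% of the bigger peak
        pg = ek.find_peaks(self._pg(power))
        peaks = pg[pg["peak"] > 0]
        assert len(peaks) == 1 and peaks["power"].item() == 10.0


class TestSummaries:
    def test_summarize_rhythmicity_fields(self):
        pg = pd.DataFrame(
            {
                "id": ["A"] * 3 + ["B"] * 3,
                "period": [hours(24), hours(25), hours(26)] * 2,
                "power": [10.0, 40.0, 12.0, 1.0, 2.0, 1.5],
                "signif_threshold": 30.0,
            }
        )
        pg = ek.find_peaks(pg)
        out = ek.summarize_rhythmicity(pg).set_index("id")
        assert out.loc["A", "is_rhythmic"] and not out.loc["B", "is_rhythmic"]
        assert out.loc["A", "first_peak_period"] == hours(25)
        assert out.loc["A", "first_peak_rel_power"] == pytest.approx(10.0)
        assert np.isnan(out.loc["B", "first_peak_period"])

    def test_group_summary_percentages(self):
        # the canonical two-genotype table: 4/22 and 29/31 rhythmic
        summary = pd.DataFrame(
            {
                "genotype": ["a"] * 22 + ["b"] * 31,
                "is_rhythmic": [True] * 4 + [False] * 18 + [True] * 29 + [False] * 2,
                "first_peak_period": [hours(25)] * 22 + [hours(26)] * 31,
            }
        )
        out = ek.group_summary(summary, "genotype").set_index("genotype")
        assert out.loc["a", "percent_rhythmic"] == 18.18
        assert out.loc["b", "percent_rhythmic"] == 93.55
        assert out.loc["a", "n_rhythmic"] == 4 and out.loc["a", "n"] == 22

    def test_group_summary_no_rhythmic(self):
        summary = pd.DataFrame(
            {
                "genotype": ["a"] * 5,
                "is_rhythmic": [False] * 5,
                "first_peak_period": [np.nan] * 5,
            }
        )
        out = ek.group_summary(summary, "genotype")
        assert out["percent_rhythmic"].item() == 0.0
        assert np.isnan(out["mean_period"].item())


class TestTwoGroupLogit:
    def test_symmetry_equal_proportions(self):
        fit = ek.two_group_logit_fit(5, 20, 10, 40)
        assert fit.beta1 == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_irls_library_fit(self):
        """Closed form matches statsmodels' IRLS logistic fit on random tables."""
        import statsmodels.api as sm

        rng = np.random.default_rng(55)
        for _ in range(50):
            n1, n2 = rng.integers(5, 60, size=2)
            k1 = int(rng.integers(1, n1))
            k2 = int(rng.integers(1, n2))
            fit = ek.two_group_logit_fit(k1, n1, k2, n2)
            y = np.concatenate([np.ones(k1), np.zeros(n1 - k1), np.ones(k2), np.zeros(n2 - k2)])
            g = np.concatenate([np.zeros(n1), np.ones(n2)])
            X = sm.add_constant(g)
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            assert fit.beta0 == pytest.approx(res.params[0], abs=1e-6)
            assert fit.beta1 == pytest.approx(res.params[1], abs=1e-6)
            assert fit.se1 == pytest.approx(res.bse[1], rel=1e-4)

    def test_separation_errors(self):
        with pytest.raises(ValueError, match="separation"):
            ek.two_group_logit_fit(0, 10, 5, 10)
        with pytest.raises(ValueError, match="separation"):
            ek.two_group_logit_fit(3, 10, 10, 10)

    def test_fit_rhythmicity_glm_from_summary(self):
        summary = pd.DataFrame(
            {
                "genotype": ["a"] * 22 + ["b"] * 31,
                "is_rhythmic": [True] * 4 + [False] * 18 + [True] * 29 + [False] * 2,
            }
        )
        fit = ek.fit_rhythmicity_glm(summary, "genotype")
        assert fit.beta0 == pytest.approx(math.log(4 / 18))
        assert fit.beta1 == pytest.approx(math.log(29 / 2) - math.log(4 / 18))


class TestEndToEnd:
    def test_rhythmic_population_median_period(self, tmp_path):
        """Simulated 25 h rhythms are recovered at the population median."""
        periods = []
        for seed in range(5):
            spec = ek.ActivitySimSpec(amplitude=1.0, period=hours(25), duration=days(6), seed=seed)
            df = ek.simulate_activity(spec)
            moving = (df["activity"] > 0).to_numpy().astype(float)
            _, grid = resample_series(df["t"].to_numpy(), moving, mins(10))
            pg = ek.find_peaks(ek.chi_sq_periodogram(grid, mins(10)))
            top = pg[pg["peak"] == 1]
            if len(top):
                periods.append(top["period"].item())
        assert len(periods) >= 4
        assert abs(np.median(periods) - hours(25)) <= mins(10)
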