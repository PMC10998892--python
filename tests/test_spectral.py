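"""Spectral analysis: power conservation, binning, cumulative power, DAS."""

import math

import numpy as np
import pytest

from tumorconn.spectral import (
    BoldSeries,
    DegenerateSpectrumError,
    aggregate_das,
    autocorrelation,
    binned_power_distribution,
    compute_power_spectrum,
    cumulative_power,
    das,
    harmonize_pair,
)


def naive_power(values: np.ndarray, tr: float, exclude_dc: bool = True):
    """O(N^2) direct discrete-transform oracle for the one-sided spectrum."""
    n = len(values)
    t = np.arange(n)
    freqs, power = [], []
    for k in range(n // 2 + 1):
        amp = np.sum(values * np.exp(-2j * math.pi * k * t / n))
        freqs.append(k / (n * tr))
        power.append(abs(amp) ** 2)
    freqs, power = np.array(freqs), np.array(power)
    if exclude_dc:
        freqs, power = freqs[1:], power[1:]
    return freqs, power


def sinusoid(k: int, n: int, tr: float, amplitude: float = 1.0) -> BoldSeries:
    t = np.arange(n)
    return BoldSeries(values=amplitude * np.cos(2 * math.pi * k * t / n), tr_seconds=tr)


class TestPowerSpectrum:
    def test_total_power_matches_naive_transform_oracle(self, rng):
        for _ in range(20):
            values = rng.standard_normal(48)
            series = BoldSeries(values=values, tr_seconds=2.1)
            spec = compute_power_spectrum(series)
            _, oracle = naive_power(values, 2.1)
            assert spec.total_power == pytest.approx(oracle.sum(), rel=1e-9)
            np.testing.assert_allclose(spec.squared_amplitudes, oracle, rtol=1e-8, atol=1e-8)

    def test_single_on_grid_sinusoid_concentrates_at_its_frequency(self):
        n, k, tr = 64, 5, 2.0
        spec = compute_power_spectrum(sinusoid(k, n, tr))
        nonzero = spec.squared_amplitudes > 1e-9 * spec.total_power
        assert nonzero.sum() == 1
        assert spec.frequencies[nonzero][0] == pytest.approx(k / (n * tr))

    def test_constant_series_is_degenerate_without_dc(self):
        spec = compute_power_spectrum(BoldSeries(values=np.ones(32), tr_seconds=2.1))
        assert spec.is_degenerate
        with pytest.raises(DegenerateSpectrumError):
            binned_power_distribution(spec)
        with pytest.raises(DegenerateSpectrumError):
            cumulative_power(spec)

    def test_dc_included_when_requested(self):
        spec = compute_power_spectrum(
            BoldSeries(values=np.ones(32), tr_seconds=2.1), exclude_dc=False
        )
        assert not spec.is_degenerate
        assert spec.frequencies[0] == 0.0


class TestBinnedPower:
    def test_two_equal_components_in_same_bin_give_hundred(self):
        n, tr = 64, 2.0
        series = BoldSeries(
            values=sinusoid(3, n, tr).values + sinusoid(4, n, tr).values, tr_seconds=tr
        )
        spec = compute_power_spectrum(series)
        binned = binned_power_distribution(spec, delta_omega=spec.nyquist_hz)
        assert binned.percentages[0] == pytest.approx(100.0)

    def test_two_equal_components_in_different_bins_split_evenly(self):
        n, tr = 64, 2.0
        series = BoldSeries(
            values=sinusoid(3, n, tr).values + sinusoid(20, n, tr).values, tr_seconds=tr
        )
        spec = compute_power_spectrum(series)
        binned = binned_power_distribution(spec, delta_omega=10 / (n * tr))
        occupied = binned.percentages[binned.percentages > 1e-9]  # ignore FFT round-off dust
        np.testing.assert_allclose(occupied, [50.0, 50.0])

    def test_matches_direct_binning_oracle(self, rng):
        series = BoldSeries(values=rng.standard_normal(80), tr_seconds=2.4)
        spec = compute_power_spectrum(series)
        delta = 0.013
        binned = binned_power_distribution(spec, delta_omega=delta)
        # oracle: sum power whose frequency falls in (edge - delta, edge]
        expected = np.zeros_like(binned.percentages)
        for f, p in zip(spec.frequencies, spec.squared_amplitudes):
            idx = min(int(np.ceil(f / delta - 1e-12)) - 1, len(expected) - 1)
            expected[max(idx, 0)] += p
        expected = 100.0 * expected / spec.total_power
        np.testing.assert_allclose(binned.percentages, expected, atol=1e-9)
        assert binned.percentages.sum() == pytest.approx(100.0, abs=1e-6)

    def test_equal_power_bins_carry_near_equal_power(self, rng):
        from tumorconn.spectral import equal_power_bins

        values = rng.standard_normal(183)
        spec = compute_power_spectrum(BoldSeries(values=values, tr_seconds=2.1))
        binned = equal_power_bins(spec, n_bins=10)
        assert binned.percentages.sum() == pytest.approx(100.0, abs=1e-6)
        assert len(binned.percentages) == 10
        # equal up to the discreteness of the 91-component spectrum
        assert np.all(np.abs(binned.percentages - 10.0) < 5.0)

    def test_first_occupied_bin_hits_target_fraction(self, rng):
        values = rng.standard_normal(183)
        spec = compute_power_spectrum(BoldSeries(values=values, tr_seconds=2.1))
        binned = binned_power_distribution(spec, target_first_bin_pct=10.0)
        first_occupied = binned.percentages[binned.percentages > 0][0]
        assert first_occupied == pytest.approx(10.0, abs=2.0)


class TestCumulativePower:
    def test_threshold_at_nyquist_reaches_hundred(self, rng):
        spec = compute_power_spectrum(BoldSeries(values=rng.standard_normal(60), tr_seconds=2.1))
        cp = cumulative_power(spec, thresholds=[spec.nyquist_hz / 2, spec.nyquist_hz])
        assert cp.cumulative_pct[-1] == pytest.approx(100.0)

    def test_single_sinusoid_is_a_step_function(self):
        n, k, tr = 64, 8, 2.0
        spec = compute_power_spectrum(sinusoid(k, n, tr))
        f = k / (n * tr)
        cp = cumulative_power(spec, thresholds=[f / 2, f, 2 * f])
        np.testing.assert_allclose(cp.cumulative_pct, [0.0, 100.0, 100.0], atol=1e-9)

    def test_matches_prefix_sum_oracle(self, rng):
        spec = compute_power_spectrum(BoldSeries(values=rng.standard_normal(90), tr_seconds=2.4))
        thresholds = np.sort(rng.uniform(0, spec.nyquist_hz, 12))
        thresholds = np.unique(thresholds)
        cp = cumulative_power(spec, thresholds=thresholds)
        for thr, got in zip(thresholds, cp.cumulative_pct):
            expected = 100.0 * spec.squared_amplitudes[spec.frequencies <= thr + 1e-12].sum() / spec.total_power
            assert got == pytest.approx(expected, abs=1e-9)

    def test_decile_mode_is_monotone_and_complete(self, rng):
        spec = compute_power_spectrum(BoldSeries(values=rng.standard_normal(90), tr_seconds=2.1))
        cp = cumulative_power(spec, thresholds="deciles")
        assert len(cp.thresholds) == 10
        assert np.all(np.diff(cp.cumulative_pct) >= 0)
        assert cp.cumulative_pct[-1] == pytest.approx(100.0)

    def test_unsorted_thresholds_rejected(self, rng):
        spec = compute_power_spectrum(BoldSeries(values=rng.standard_normal(60), tr_seconds=2.1))
        with pytest.raises(ValueError):
            cumulative_power(spec, thresholds=[0.2, 0.1])


class TestHarmonizePair:
    def test_equal_tr_pads_shorter_with_zeros(self, rng):
        a = BoldSeries(values=rng.standard_normal(100), tr_seconds=2.1)
        b = BoldSeries(values=rng.standard_normal(120), tr_seconds=2.1)
        ha, hb = harmonize_pair(a, b)
        assert ha.n_volumes == hb.n_volumes == 120
        np.testing.assert_array_equal(ha.values[:100], a.values)
        assert np.all(ha.values[100:] == 0)

    def test_equal_inputs_unchanged(self, rng):
        a = BoldSeries(values=rng.standard_normal(64), tr_seconds=2.4)
        ha, hb = harmonize_pair(a, a)
        np.testing.assert_array_equal(ha.values, a.values)
        np.testing.assert_array_equal(hb.values, a.values)

    def test_mixed_tr_dialects_match_durations(self, rng):
        a = BoldSeries(values=rng.standard_normal(183), tr_seconds=2.1)
        b = BoldSeries(values=rng.standard_normal(160), tr_seconds=2.4)
        ha, hb = harmonize_pair(a, b)
        assert abs(ha.duration_seconds - hb.duration_seconds) <= 2.4


class TestDas:
    def test_zero_on_identical_curves(self, rng):
        spec = compute_power_spectrum(BoldSeries(values=rng.standard_normal(64), tr_seconds=2.1))
        cp = cumulative_power(spec, "full")
        assert das(cp, cp).value == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetry(self, rng):
        for _ in range(50):
            s1 = compute_power_spectrum(BoldSeries(values=rng.standard_normal(64), tr_seconds=2.1))
            s2 = compute_power_spectrum(BoldSeries(values=rng.standard_normal(64), tr_seconds=2.1))
            cp1, cp2 = cumulative_power(s1, "full"), cumulative_power(s2, "full")
            assert das(cp1, cp2).value == pytest.approx(-das(cp2, cp1).value, abs=1e-10)

    def test_two_sinusoid_closed_form(self):
        n, tr = 128, 2.0
        k1, k2 = 10, 40
        cp1 = cumulative_power(compute_power_spectrum(sinusoid(k1, n, tr)), "full")
        cp2 = cumulative_power(compute_power_spectrum(sinusoid(k2, n, tr)), "full")
        f1, f2, f_ny = k1 / (n * tr), k2 / (n * tr), 0.5 / tr
        expected = 100.0 * (f2 - f1) / f_ny
        assert das(cp1, cp2).value == pytest.approx(expected, abs=1e-9)

    def test_triangle_additivity_on_common_grid(self, rng):
        cps = [
            cumulative_power(
                compute_power_spectrum(BoldSeries(values=rng.standard_normal(64), tr_seconds=2.1)),
                "full",
            )
            for _ in range(3)
        ]
        d_ik = das(cps[0], cps[2]).value
        d_ij = das(cps[0], cps[1]).value
        d_jk = das(cps[1], cps[2]).value
        assert d_ik == pytest.approx(d_ij + d_jk, abs=1e-9)

    def test_positive_das_means_slower_dynamics(self):
        n, tr = 128, 2.0
        slow = cumulative_power(compute_power_spectrum(sinusoid(5, n, tr)), "full")
        fast = cumulative_power(compute_power_spectrum(sinusoid(50, n, tr)), "full")
        assert das(slow, fast).value > 0

    def test_non_overlapping_ranges_rejected(self):
        from tumorconn.spectral import CumulativePower

        a = CumulativePower(thresholds=np.array([0.0, 0.1]), cumulative_pct=np.array([0.0, 100.0]))
        b = CumulativePower(thresholds=np.array([0.2, 0.3]), cumulative_pct=np.array([0.0, 100.0]))
        with pytest.raises(ValueError):
            das(a, b)


class TestAggregateDas:
    def test_signed_and_absolute_modes_differ(self):
        assert aggregate_das([1.0, -1.0], absolute=False)[0] == pytest.approx(0.0)
        assert aggregate_das([1.0, -1.0], absolute=True)[0] == pytest.approx(1.0)

    def test_hand_computed_mean_and_sem(self):
        mean, sem = aggregate_das([2.0, -4.0, 6.0], absolute=True)
        assert mean == pytest.approx(4.0)
        assert sem == pytest.approx(np.std([2.0, 4.0, 6.0], ddof=1) / math.sqrt(3))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate_das([])


class TestAutocorrelation:
    def test_lag_zero_is_one(self, rng):
        series = BoldSeries(values=rng.standard_normal(100), tr_seconds=2.1)
        acf = autocorrelation(series, max_lag=10)
        assert acf[0] == pytest.approx(1.0)

    def test_white_noise_within_sampling_bound(self, rng):
        n = 10_000
        series = BoldSeries(values=rng.standard_normal(n), tr_seconds=2.1)
        acf = autocorrelation(series, max_lag=10)
        assert np.all(np.abs(acf[1:]) < 4 / math.sqrt(n))

    def test_on_grid_sinusoid_recurs_at_its_period(self):
        n, period = 1000, 10
        t = np.arange(n)
        series = BoldSeries(values=np.cos(2 * math.pi * t / period), tr_seconds=2.1)
        acf = autocorrelation(series, max_lag=period)
        assert acf[period] == pytest.approx(1.0, abs=1e-6)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateSpectrumError):
            autocorrelation(BoldSeries(values=np.full(50, 3.0), tr_seconds=2.1), max_lag=5)
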