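"""Multitaper spectra, aperiodic fits, ALFF/fALFF, and feature tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hemospec import (
    VoxelTimeSeries,
    build_feature_table,
    compare_groups,
    compute_alff,
    compute_falff,
    fit_aperiodic,
    multitaper_psd,
    spectrum_slope,
)
from hemospec.spectral import SpectrumEstimate

TR = 0.227
N = 2185 + 62  # ~8.5 min run: 14 s baseline + analysis segment


def _ts(values, dt=TR):
    return VoxelTimeSeries(values, dt=dt, run_kind="rest")


def _white(seed, n=N, sd=1.0):
    return _ts(np.random.default_rng(seed).standard_normal(n) * sd)


def _flat_magnitude_series(seed, n=2048):
    """Real series whose FFT magnitude is identical at every non-DC bin."""
    rng = np.random.default_rng(seed)
    n_bins = n // 2 + 1
    phases = rng.uniform(0, 2 * np.pi, n_bins)
    spec = np.exp(1j * phases)
    spec[0] = 0.0
    spec[-1] = 1.0  # Nyquist bin must be real
    return _ts(np.fft.irfft(spec, n=n))


class TestMultitaper:
    def test_zero_signal_zero_power(self):
        spec = multitaper_psd(_ts(np.zeros(N)))
        assert np.all(spec.power == 0.0)

    def test_parseval_white_noise(self):
        """One-sided PSD integrates to the series variance (100-seed average)."""
        ratios = []
        for s in range(100):
            ts = _white(s)
            x = ts.values[62:]
            spec = multitaper_psd(ts)
            df = spec.freqs[1] - spec.freqs[0]
            ratios.append(np.sum(spec.power) * df / np.var(x - x.mean()))
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.05)

    def test_sinusoid_peak_location(self):
        t = np.arange(N) * TR
        spec = multitaper_psd(_ts(np.sin(2 * np.pi * 0.1 * t)))
        f_peak = spec.freqs[np.argmax(spec.power)]
        # resolution bandwidth = 2*NW/(N*dt)
        bw = 2 * 3.0 / (2185 * TR)
        assert abs(f_peak - 0.1) < bw

    def test_taper_count_validated(self):
        with pytest.raises(ValueError, match="tapers"):
            multitaper_psd(_white(0), n_tapers=6, nw=3.0)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="256"):
            multitaper_psd(_ts(np.ones(300)))  # 300 - 62 < 256


class TestSlope:
    def _spec(self, power, n=400, f_max=0.5):
        freqs = np.linspace(0.001, f_max, n)
        return SpectrumEstimate(freqs=freqs, power=power(freqs), n_tapers=5, time_bandwidth=3.0)

    def test_flat_power_zero_slope(self):
        spec = self._spec(lambda f: np.full_like(f, 2.5))
        assert spectrum_slope(spec) == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_recovery(self):
        spec = self._spec(lambda f: 10 ** (3.0 - 10.0 * f))
        assert spectrum_slope(spec) == pytest.approx(-10.0, abs=1e-9)

    def test_needs_enough_bins(self):
        spec = SpectrumEstimate(
            freqs=np.linspace(0.25, 0.5, 50), power=np.ones(50), n_tapers=5, time_bandwidth=3.0
        )
        with pytest.raises(ValueError):
            spectrum_slope(spec, f_max=0.2)


class TestAperiodicFit:
    def _spec(self, b, x, n=200):
        freqs = np.linspace(0.002, 0.5, n)
        return SpectrumEstimate(
            freqs=freqs, power=10 ** (b - x * np.log10(freqs)), n_tapers=5, time_bandwidth=3.0
        )

    def test_exact_model_recovery(self):
        b, x = fit_aperiodic(self._spec(2.0, 1.0))
        assert b == pytest.approx(2.0, abs=1e-6)
        assert x == pytest.approx(1.0, abs=1e-6)

    def test_equals_closed_form_regression_on_random_spectra(self):
        """The model is linear in (b, x): LM must match the OLS closed form."""
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = rng.integers(30, 300)
            freqs = np.sort(rng.uniform(0.003, 0.5, n))
            power = 10 ** rng.normal(0.0, 1.0, n)
            spec = SpectrumEstimate(freqs=freqs, power=power, n_tapers=5, time_bandwidth=3.0)
            b_fit, x_fit = fit_aperiodic(spec)
            res = stats.linregress(np.log10(freqs), np.log10(power))
            assert b_fit == pytest.approx(res.intercept, abs=1e-6)
            assert x_fit == pytest.approx(-res.slope, abs=1e-6)

    def test_power_scaling_shifts_offset_only(self):
        spec = self._spec(1.5, 0.8)
        scaled = SpectrumEstimate(
            freqs=spec.freqs, power=10.0 * spec.power, n_tapers=5, time_bandwidth=3.0
        )
        b0, x0 = fit_aperiodic(spec)
        b1, x1 = fit_aperiodic(scaled)
        assert b1 == pytest.approx(b0 + 1.0, abs=1e-9)
        assert x1 == pytest.approx(x0, abs=1e-9)


class TestALFF:
    def test_zero_signal(self):
        assert compute_alff(_ts(np.zeros(N))) == 0.0

    def test_homogeneity(self):
        ts = _white(5)
        a1 = compute_alff(ts)
        a3 = compute_alff(_ts(3.0 * ts.values))
        assert a3 == pytest.approx(3.0 * a1, rel=1e-12)

    def test_direct_dft_oracle_sinusoid(self):
        """ALFF of a 0.04 Hz sinusoid equals the from-scratch DFT computation."""
        n = 2185
        t = np.arange(n) * TR
        x = np.sin(2 * np.pi * 0.04 * t)
        ts = _ts(x)
        value = compute_alff(ts, baseline_discard=0.0)
        # independent oracle: explicit DFT sums, no FFT mask path
        xm = x - x.mean()
        freqs = np.fft.rfftfreq(n, d=TR)
        sel = (freqs >= 0.01) & (freqs <= 0.08)
        k_idx = np.nonzero(sel)[0]
        mags = np.array(
            [np.abs(np.sum(xm * np.exp(-2j * np.pi * k * np.arange(n) / n))) for k in k_idx]
        )
        oracle = np.mean(np.sqrt(mags**2 / n))
        assert value == pytest.approx(oracle, abs=1e-9)

    def test_band_validated(self):
        with pytest.raises(ValueError):
            compute_alff(_white(0), band=(0.01, 5.0))


class TestFALFF:
    def test_flat_magnitude_spectrum_gives_unity(self):
        ts = _flat_magnitude_series(0)
        assert compute_falff(ts, baseline_discard=0.0) == pytest.approx(1.0, abs=1e-12)

    def test_band_limited_series_gives_bin_count_ratio(self):
        n = 2048
        freqs = np.fft.rfftfreq(n, d=TR)
        low = (freqs >= 0.01) & (freqs <= 0.08)
        wide = (freqs >= 0.01) & (freqs <= 0.25)
        rng = np.random.default_rng(4)
        spec = np.where(low, np.exp(1j * rng.uniform(0, 2 * np.pi, freqs.size)), 0.0)
        spec[0] = 0.0
        x = np.fft.irfft(spec, n=n)
        falff = compute_falff(_ts(x), baseline_discard=0.0)
        assert falff == pytest.approx(wide.sum() / low.sum(), rel=1e-9)

    def test_scale_invariance(self):
        ts = _white(8)
        assert compute_falff(_ts(5.0 * ts.values)) == pytest.approx(
            compute_falff(ts), rel=1e-12
        )

    def test_sum_based_variant_below_one(self):
        ts = _white(9)
        assert compute_falff(ts, sum_based=True) < 1.0

    def test_zero_series_undefined(self):
        with pytest.raises(ValueError):
            compute_falff(_ts(np.zeros(N)))


class TestFeatureTable:
    def _runs(self, n_vox=8, seed=0):
        rng = np.random.default_rng(seed)
        return [
            [_ts(rng.standard_normal(N)) for _ in range(n_vox)],
            [_ts(rng.standard_normal(N)) for _ in range(n_vox)],
        ]

    def test_zscored_columns_standardized_per_run(self):
        runs = self._runs()
        with pytest.warns(UserWarning):
            table = build_feature_table(runs[:1])
        for col in ("slope_z", "alff_z", "falff_z", "aperiodic_exponent_z"):
            assert table[col].mean() == pytest.approx(0.0, abs=1e-12)
            assert table[col].std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_identical_runs_average_to_single_run(self):
        runs = self._runs()
        single = None
        with pytest.warns(UserWarning):
            single = build_feature_table([runs[0]])
        double = build_feature_table([runs[0], runs[0]])
        pd.testing.assert_frame_equal(single, double)

    def test_voxel_permutation_permutes_rows(self):
        runs = self._runs()
        table = build_feature_table(runs)
        perm = [3, 1, 0, 2, 7, 5, 6, 4]
        permuted_runs = [[run[i] for i in perm] for run in runs]
        table_p = build_feature_table(permuted_runs)
        for col in ("slope", "alff", "falff"):
            assert np.allclose(table_p[col].to_numpy(), table[col].to_numpy()[perm])


class TestCompareGroups:
    def _table(self, a, b):
        return (
            pd.DataFrame({"slope": np.concatenate([a, b])}),
            np.array(["fast"] * len(a) + ["slow"] * len(b)),
        )

    def test_identical_groups_not_significant(self):
        v = np.arange(20.0)
        df, labels = self._table(v, v)
        _, p = compare_groups(df, labels, "slope")
        assert p > 0.9

    def test_separated_groups_significant(self):
        df, labels = self._table(np.arange(20.0), np.arange(20.0) + 200.0)
        _, p = compare_groups(df, labels, "slope")
        assert p < 1e-6

    def test_small_group_rejected(self):
        df, labels = self._table(np.arange(3.0), np.arange(20.0))
        with pytest.raises(ValueError, match="fast=3"):
            compare_groups(df, labels, "slope")
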