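"""Synthetic subject generator: spectra, stimuli, forward model, ground truth."""

import numpy as np
import pytest
from scipy import stats

from hemospec import (
    HRFParams,
    SyntheticConfig,
    build_task_stimulus,
    generate_neural_signal,
    generate_subject,
    generate_voxel_run,
    hrf_fourier_response,
    lag_from_phase,
    make_double_gamma_hrf,
)
from hemospec.synth import BreathHoldSchedule, build_bh_waveform

from .conftest import impulse_kernel


def _loglog_slope(x: np.ndarray, dt: float) -> float:
    f = np.fft.rfftfreq(x.size, d=dt)[1:]
    p = np.abs(np.fft.rfft(x - x.mean())[1:]) ** 2
    res = stats.linregress(np.log10(f), np.log10(p))
    return res.slope


class TestNeuralSignal:
    def test_white_noise_has_flat_spectrum(self):
        slopes = [
            _loglog_slope(generate_neural_signal(8192, 0.227, alpha=0.0, seed=s).values, 0.227)
            for s in range(50)
        ]
        assert np.mean(slopes) == pytest.approx(0.0, abs=0.1)

    def test_one_over_f_exponent_recovered(self):
        slopes = [
            _loglog_slope(generate_neural_signal(8192, 0.227, alpha=1.0, seed=s).values, 0.227)
            for s in range(50)
        ]
        assert np.mean(slopes) == pytest.approx(-1.0, abs=0.1)

    def test_deterministic_per_seed(self):
        a = generate_neural_signal(256, 0.227, seed=7)
        b = generate_neural_signal(256, 0.227, seed=7)
        assert np.array_equal(a.values, b.values)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            generate_neural_signal(32, 0.227)
        with pytest.raises(ValueError):
            generate_neural_signal(256, 0.227, alpha=-1.0)


class TestTaskStimulus:
    def test_baseline_is_zero(self):
        s = build_task_stimulus(SyntheticConfig())
        n_baseline = int(14.0 / 0.227)  # 61 samples
        assert np.all(s.values[:n_baseline] == 0.0)
        assert s.n == int(round(254.0 / 0.227))

    def test_quarter_period_peak(self):
        cfg = SyntheticConfig()
        s = build_task_stimulus(cfg)
        # t = baseline + 5 s is a quarter of the 20 s cycle: sin = 1
        i = int(round((14.0 + 5.0) / cfg.tr))
        t = i * cfg.tr
        expected = np.sin(2 * np.pi * 0.05 * (t - 14.0))
        assert s.values[i] == pytest.approx(expected)
        assert expected == pytest.approx(1.0, abs=0.01)

    def test_fast_stimulus_variant_period(self):
        cfg = SyntheticConfig(f_stim=0.1)
        s = build_task_stimulus(cfg)
        t = s.times
        active = t >= 14.0
        # 0.1 Hz drive: 10 s period, so a 10 s shift reproduces the signal
        shift = int(round(10.0 / cfg.tr))
        v = s.values[active]
        assert np.allclose(v[shift:], v[:-shift], atol=0.02)


class TestVoxelRun:
    def test_noiseless_impulse_task_run_equals_stimulus(self):
        cfg = SyntheticConfig(thermal_sd=0.0)
        stim = build_task_stimulus(cfg)
        k = impulse_kernel(cfg.tr, duration=5.0)
        run = generate_voxel_run(k, "task", cfg, stim, seed=0)
        assert np.allclose(run.values, stim.values, atol=1e-9)

    def test_noiseless_lag_matches_fourier_ground_truth(self):
        cfg = SyntheticConfig(thermal_sd=0.0)
        stim = build_task_stimulus(cfg)
        k = make_double_gamma_hrf(HRFParams(5.0, 4.0, 1.0), dt=cfg.tr)
        run = generate_voxel_run(k, "task", cfg, stim, seed=0)
        _, phase = hrf_fourier_response(k, cfg.f_stim)
        lag_true = lag_from_phase(phase, cfg.f_stim)
        # demodulate the steady-state segment to measure the realized lag
        i0 = int((cfg.task_baseline + k.support) / cfg.tr)
        x = run.values[i0:]
        t = np.arange(run.n)[i0:] * cfg.tr - cfg.task_baseline
        c = np.mean(x * np.exp(-2j * np.pi * cfg.f_stim * t))
        lag_measured = (-np.angle(c) - np.pi / 2) % (2 * np.pi) / (2 * np.pi * cfg.f_stim)
        err = min(abs(lag_measured - lag_true), 20.0 - abs(lag_measured - lag_true))
        assert err <= cfg.tr

    def test_same_kernel_different_seeds_same_clean_component(self):
        cfg = SyntheticConfig(thermal_sd=0.0)
        stim = build_task_stimulus(cfg)
        k = make_double_gamma_hrf(HRFParams(5.0, 4.0, 1.0), dt=cfg.tr)
        a = generate_voxel_run(k, "task", cfg, stim, seed=1)
        b = generate_voxel_run(k, "task", cfg, stim, seed=2)
        assert np.array_equal(a.values, b.values)  # noiseless: seeds irrelevant

    def test_latency_shift_window_enforced(self):
        cfg = SyntheticConfig()
        wave = build_bh_waveform(cfg)
        k = impulse_kernel(cfg.tr, duration=5.0)
        with pytest.raises(ValueError, match="latency_shift"):
            generate_voxel_run(k, "bh", cfg, wave, latency_shift=20.0, seed=0)


class TestBreathHoldSchedule:
    def test_default_schedule_fits_run(self):
        s = BreathHoldSchedule()
        assert s.total == pytest.approx(510.0)
        holds = s.hold_intervals()
        assert len(holds) == 8
        assert all(end - start == pytest.approx(15.0) for start, end in holds)

    def test_bh_waveform_dips_during_holds(self):
        cfg = SyntheticConfig()
        wave = build_bh_waveform(cfg)
        assert wave.values.min() < 0
        assert np.abs(wave.values).max() == pytest.approx(1.0)


class TestGenerateSubject:
    def test_bookkeeping(self, small_subject, small_config):
        assert small_subject.n_voxels == 3 * small_config.n_per_class
        assert len(small_subject.rest_runs) == 2
        assert len(small_subject.task_runs) == 3
        assert len(small_subject.bh_runs) == 2
        assert small_subject.truth.voxel_id.tolist() == list(range(60))
        n_rest = int(round(510.0 / 0.227))
        assert all(ts.n == n_rest for ts in small_subject.rest_runs[0])

    def test_class_lag_ordering(self, small_subject):
        means = small_subject.truth.groupby("label").lag_true.mean()
        assert means["lgn"] < means["fast"] < means["slow"]

    def test_bitwise_reproducible(self, small_config, small_subject):
        again = generate_subject(small_config)
        for run_a, run_b in zip(small_subject.rest_runs, again.rest_runs):
            for a, b in zip(run_a, run_b):
                assert np.array_equal(a.values, b.values)
        assert small_subject.truth.equals(again.truth)

    def test_decoupled_latency_pools_classes(self):
        cfg = SyntheticConfig(n_per_class=40, seed=5, couple_latency_to_class=False)
        sub = generate_subject(cfg)
        means = sub.truth.groupby("label").vascular_latency_true.mean()
        assert means.max() - means.min() < 0.3  # common distribution

    def test_rest_spectra_slope_ordering_fast_vs_slow(self):
        """Fast-HRF voxels show shallower low-frequency log-power decay at rest."""
        cfg = SyntheticConfig(n_per_class=100, seed=21, n_task_runs=1, n_bh_runs=1)
        sub = generate_subject(cfg)
        from hemospec import multitaper_psd, spectrum_slope

        labels = sub.truth.label.to_numpy()
        slopes = np.array(
            [spectrum_slope(multitaper_psd(ts)) for ts in sub.rest_runs[0]]
        )
        assert slopes[labels == "fast"].mean() > slopes[labels == "slow"].mean()
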