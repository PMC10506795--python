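"""Synthetic fMRI subject generator with known hemodynamic ground truth.

Emulates the study geometry in time: fast-TR acquisitions (TR 0.227 s),
two 8.5-min resting runs, three 254-s visual-task runs driven by a 0.05 Hz
sinusoidal luminance oscillation after a 14-s baseline, and two breath-hold
runs of eight 60-s blocks. Voxels are drawn from three HRF families —
fast-cortical, slow-cortical, and LGN-like (fastest) — and each run is a
forward model: BOLD = HRF (*) drive + thermal noise. The generator records
per-voxel ground truth (HRF parameters, analytic phase lag at the stimulus
frequency, vascular latency), making the full analysis pipeline testable
against known answers.

No per-voxel cortical HRF distributions are published, so the class
parameter distributions are the package's own choice: Gaussians over
(TTP, FWHM) with means fast (4.25, 3.0), slow (5.5, 4.5), LGN (3.75, 2.5) s
and sd 0.5 s, truncated positive; slower classes carry larger peak
amplitudes. The 0.5 s timing spread makes the cortical (fast + slow) phase
lags form the broad overlapping continuum that real V1 voxels display —
narrow spreads would produce a multimodal lag histogram the Gaussian-window
grouping procedure is not designed for. Thermal noise sd defaults to 2.0
signal units per sample, the tSNR regime of 2-mm fast-TR 7T data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .core import VoxelTimeSeries
from .hrf import HRFKernel, HRFParams, hrf_fourier_response, lag_from_phase, make_double_gamma_hrf

__all__ = [
    "ClassDistribution",
    "SyntheticConfig",
    "SyntheticSubject",
    "generate_neural_signal",
    "build_task_stimulus",
    "build_bh_waveform",
    "generate_voxel_run",
    "generate_subject",
]

MAX_LATENCY_SHIFT = 15.0  # s; the breath-hold latency search window


@dataclass(frozen=True)
class ClassDistribution:
    """Gaussian distribution over HRF parameters for one voxel class."""

    ttp_mean: float
    fwhm_mean: float
    psc_mean: float
    ttp_sd: float = 0.5
    fwhm_sd: float = 0.5
    psc_sd: float = 0.1


DEFAULT_CLASS_HRFS: Dict[str, ClassDistribution] = {
    "fast": ClassDistribution(4.25, 3.0, 1.5),
    "slow": ClassDistribution(5.5, 4.5, 2.0),
    "lgn": ClassDistribution(3.75, 2.5, 1.0),
}

#: Vascular latency (mean_s, sd_s) per class when latency is coupled to
#: hemodynamic speed; the LGN dilates first, slow cortex last.
DEFAULT_LATENCY_MODEL: Dict[str, Tuple[float, float]] = {
    "lgn": (0.5, 0.3),
    "fast": (1.0, 0.3),
    "slow": (2.0, 0.3),
}


@dataclass(frozen=True)
class BreathHoldSchedule:
    """Breath-hold block structure in seconds."""

    free: float = 27.0
    paced: float = 18.0
    hold: float = 15.0
    repetitions: int = 8
    trailing_free: float = 30.0

    def __post_init__(self) -> None:
        if min(self.free, self.paced, self.hold, self.trailing_free) < 0:
            raise ValueError("schedule durations must be non-negative")
        if self.repetitions < 1:
            raise ValueError("need at least one block")

    @property
    def block(self) -> float:
        return self.free + self.paced + self.hold

    @property
    def total(self) -> float:
        return self.block * self.repetitions + self.trailing_free

    def hold_intervals(self) -> List[Tuple[float, float]]:
        """(start, end) of each breath hold in seconds."""
        return [
            (i * self.block + self.free + self.paced, (i + 1) * self.block)
            for i in range(self.repetitions)
        ]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic subject."""

    tr: float = 0.227
    rest_duration: float = 510.0
    task_duration: float = 254.0
    task_baseline: float = 14.0
    f_stim: float = 0.05
    bh_schedule: BreathHoldSchedule = field(default_factory=BreathHoldSchedule)
    n_per_class: int = 50
    class_hrf_params: Dict[str, ClassDistribution] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_HRFS)
    )
    neural_alpha: float = 1.0
    neural_sd: float = 1.0
    thermal_sd: float = 2.0
    bh_amplitude: float = 3.0
    vascular_latency_model: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LATENCY_MODEL)
    )
    couple_latency_to_class: bool = True
    n_rest_runs: int = 2
    n_task_runs: int = 3
    n_bh_runs: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if min(self.rest_duration, self.task_duration) <= 0:
            raise ValueError("durations must be positive")
        if not 0 < self.f_stim < 0.5 / self.tr:
            raise ValueError(f"f_stim={self.f_stim} must lie in (0, Nyquist)")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")


@dataclass
class SyntheticSubject:
    """All runs of one synthetic subject plus the ground-truth table.

    ``truth`` has one row per voxel: voxel_id, label, ttp, fwhm, peak_psc,
    lag_true (analytic phase lag at f_stim, s), vascular_latency_true (s),
    hemi (an arbitrary left/right tag for hemisphere-style splits).
    """

    config: SyntheticConfig
    rest_runs: List[List[VoxelTimeSeries]]
    task_runs: List[List[VoxelTimeSeries]]
    bh_runs: List[List[VoxelTimeSeries]]
    truth: pd.DataFrame

    @property
    def n_voxels(self) -> int:
        return len(self.truth)


def generate_neural_signal(
    n: int, dt: float, alpha: float = 1.0, seed: int | np.random.Generator = 0, sd: float = 1.0
) -> VoxelTimeSeries:
    """Zero-mean Gaussian process with power spectrum proportional to 1/f^alpha.

    White Gaussian noise is shaped in the frequency domain by f^(-alpha/2)
    (DC removed), then rescaled to standard deviation ``sd``. Deterministic
    per seed.
    """
    if n < 64:
        raise ValueError(f"need n >= 64 samples, got {n}")
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=dt)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-alpha / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    x = x - x.mean()
    s = x.std()
    if s > 0:
        x = x * (sd / s)
    return VoxelTimeSeries(x, dt=dt, run_kind="rest")


def build_task_stimulus(config: SyntheticConfig) -> VoxelTimeSeries:
    """The visual-task drive: zero baseline, then a unit sinusoid at f_stim."""
    n = int(round(config.task_duration / config.tr))
    t = np.arange(n) * config.tr
    s = np.where(
        t < config.task_baseline,
        0.0,
        np.sin(2 * np.pi * config.f_stim * (t - config.task_baseline)),
    )
    return VoxelTimeSeries(s, dt=config.tr, run_kind="task")


def build_bh_waveform(config: SyntheticConfig) -> VoxelTimeSeries:
    """Noise-free vasoactive response to the breath-hold schedule.

    Boxcar (1 during holds) convolved with the sign-reversed canonical
    double-gamma response and peak-normalized: holding the breath raises
    arterial CO2, so the BOLD signal dips during the hold and rebounds after.
    The per-voxel responses are latency-shifted copies of this waveform.
    """
    from .hrf import canonical_hrf

    sched = config.bh_schedule
    n = int(round(sched.total / config.tr))
    t = np.arange(n) * config.tr
    box = np.zeros(n)
    for start, end in sched.hold_intervals():
        box[(t >= start) & (t < end)] = 1.0
    k = canonical_hrf(config.tr)
    resp = np.convolve(box, -k.samples)[:n] * config.tr
    peak = np.abs(resp).max()
    if peak > 0:
        resp = resp / peak
    return VoxelTimeSeries(resp, dt=config.tr, run_kind="bh")


def _resample_kernel(kernel_params: HRFParams, tr: float) -> HRFKernel:
    return make_double_gamma_hrf(kernel_params, dt=tr, duration=32.0)


def _shift_series(values: np.ndarray, dt: float, shift: float) -> np.ndarray:
    """Delay a series by ``shift`` seconds via linear interpolation (edge-held)."""
    t = np.arange(values.size) * dt
    return np.interp(t - shift, t, values)


def generate_voxel_run(
    kernel: HRFKernel,
    run_kind: str,
    config: SyntheticConfig,
    drive: VoxelTimeSeries,
    latency_shift: float = 0.0,
    seed: int | np.random.Generator = 0,
    voxel_id: Optional[int] = None,
) -> VoxelTimeSeries:
    """Forward-model one voxel's run.

    rest/task: discrete convolution of the drive with the kernel (scaled by
    the sampling interval) plus thermal Gaussian noise. bh: the vasoactive
    waveform delayed by ``latency_shift`` seconds and scaled by the breath-hold
    response amplitude, plus noise. Deterministic per seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if drive.dt != config.tr:
        raise ValueError("drive must be sampled at the configured TR")
    n = drive.n
    if run_kind in ("rest", "task"):
        clean = np.convolve(drive.values, kernel.samples)[:n] * config.tr
    elif run_kind == "bh":
        if abs(latency_shift) > MAX_LATENCY_SHIFT:
            raise ValueError(
                f"latency_shift={latency_shift} s outside +/-{MAX_LATENCY_SHIFT} s window"
            )
        clean = config.bh_amplitude * _shift_series(drive.values, config.tr, latency_shift)
    else:
        raise ValueError(f"unknown run_kind {run_kind!r}")
    noise = rng.standard_normal(n) * config.thermal_sd
    return VoxelTimeSeries(clean + noise, dt=config.tr, run_kind=run_kind, voxel_id=voxel_id)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float) -> float:
    for _ in range(100):
        v = rng.normal(mean, sd)
        if v > lo:
            return float(v)
    return float(max(mean, lo + sd))


def generate_subject(config: SyntheticConfig) -> SyntheticSubject:
    """Generate all runs and the ground-truth table for one subject.

    Per voxel: draw HRF parameters from its class distribution, record the
    analytic phase lag at the stimulus frequency (Fourier oracle) and the
    vascular latency (class-coupled by default, pooled across classes when
    ``couple_latency_to_class`` is False), then emit resting, task and
    breath-hold runs. Bitwise reproducible for a fixed config seed.
    """
    rng = np.random.default_rng(config.seed)
    classes = list(config.class_hrf_params)
    rows = []
    kernels: List[HRFKernel] = []
    vid = 0
    if config.couple_latency_to_class:
        lat_model = config.vascular_latency_model
    else:
        means = [m for m, _ in config.vascular_latency_model.values()]
        sds = [s for _, s in config.vascular_latency_model.values()]
        pooled = (float(np.mean(means)), float(np.mean(sds)))
        lat_model = {c: pooled for c in classes}

    for label in classes:
        dist = config.class_hrf_params[label]
        lat_mean, lat_sd = lat_model[label]
        for _ in range(config.n_per_class):
            params = HRFParams(
                ttp=_truncated_normal(rng, dist.ttp_mean, dist.ttp_sd, 0.5),
                fwhm=_truncated_normal(rng, dist.fwhm_mean, dist.fwhm_sd, 0.5),
                peak_psc=_truncated_normal(rng, dist.psc_mean, dist.psc_sd, 0.05),
            )
            kernel = _resample_kernel(params, config.tr)
            _, phase = hrf_fourier_response(kernel, config.f_stim)
            lag_true = lag_from_phase(phase, config.f_stim)
            latency = rng.normal(lat_mean, lat_sd)
            rows.append(
                {
                    "voxel_id": vid,
                    "label": label,
                    "ttp": params.ttp,
                    "fwhm": params.fwhm,
                    "peak_psc": params.peak_psc,
                    "lag_true": lag_true,
                    "vascular_latency_true": latency,
                    "hemi": "left" if vid % 2 == 0 else "right",
                }
            )
            kernels.append(kernel)
            vid += 1

    truth = pd.DataFrame(rows)
    stim = build_task_stimulus(config)
    bh_wave = build_bh_waveform(config)
    n_rest = int(round(config.rest_duration / config.tr))

    rest_runs: List[List[VoxelTimeSeries]] = []
    for _run in range(config.n_rest_runs):
        run = []
        for i, kernel in enumerate(kernels):
            neural = generate_neural_signal(
                n_rest, config.tr, alpha=config.neural_alpha, seed=rng, sd=config.neural_sd
            )
            run.append(
                generate_voxel_run(kernel, "rest", config, neural, seed=rng, voxel_id=i)
            )
        rest_runs.append(run)

    task_runs = [
        [
            generate_voxel_run(kernels[i], "task", config, stim, seed=rng, voxel_id=i)
            for i in range(len(kernels))
        ]
        for _run in range(config.n_task_runs)
    ]

    bh_runs = [
        [
            generate_voxel_run(
                kernels[i],
                "bh",
                config,
                bh_wave,
                latency_shift=float(truth.vascular_latency_true.iloc[i]),
                seed=rng,
                voxel_id=i,
            )
            for i in range(len(kernels))
        ]
        for _run in range(config.n_bh_runs)
    ]

    return SyntheticSubject(
        config=config, rest_runs=rest_runs, task_runs=task_runs, bh_runs=bh_runs, truth=truth
    )
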