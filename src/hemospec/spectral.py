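"""Resting-state spectral features of voxel time series.

Four features summarize how quickly power falls off with frequency — the
signature that distinguishes fast from slow hemodynamics at rest:

1. slope — least-squares slope of log10(power) against frequency below 0.2 Hz
   (multitaper spectrum, five Slepian tapers);
2. aperiodic exponent x (with offset b) from the 1/f model
   ``y = b - log10(F^x)`` fit below 0.5 Hz by Levenberg-Marquardt;
3. ALFF — the mean square-root power in 0.01-0.08 Hz of the band-passed
   series, with power defined as ``P = |FFT|^2 / N``;
4. fALFF — the ratio of that band mean to the 0.01-0.25 Hz band mean.

Features are z-scored across voxels within each run and averaged across the
two resting runs, so classifiers see within-session relative values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit
from scipy.signal.windows import dpss

from .core import VoxelTimeSeries

__all__ = [
    "SpectrumEstimate",
    "periodogram_power",
    "multitaper_psd",
    "spectrum_slope",
    "fit_aperiodic",
    "compute_alff",
    "compute_falff",
    "voxel_features",
    "build_feature_table",
    "build_spectrum_matrix",
    "compare_groups",
    "FEATURE_NAMES",
]

FEATURE_NAMES = ["slope", "aperiodic_exponent", "alff", "falff"]

_POWER_FLOOR = 1e-300  # floor before log10 so zero-power bins never yield NaN


@dataclass(frozen=True)
class SpectrumEstimate:
    """One-sided multitaper PSD (first positive bin through Nyquist)."""

    freqs: np.ndarray
    power: np.ndarray
    n_tapers: int
    time_bandwidth: float

    @property
    def log_power(self) -> np.ndarray:
        return np.log10(np.maximum(self.power, _POWER_FLOOR))


def _discard(ts: VoxelTimeSeries, baseline_discard: float) -> np.ndarray:
    x = ts.values[int(np.ceil(baseline_discard / ts.dt)):]
    if x.size < 256:
        raise ValueError(f"need >= 256 post-discard samples, got {x.size}")
    return x - x.mean()


def multitaper_psd(
    ts: VoxelTimeSeries,
    n_tapers: int = 5,
    nw: float = 3.0,
    baseline_discard: float = 14.0,
) -> SpectrumEstimate:
    """Multitaper PSD: average of Slepian-tapered eigenspectra.

    The mean-removed post-discard series is zero-padded to the next power of
    two; each unit-norm DPSS taper yields one eigenspectrum and the estimate
    is their mean. One-sided density normalization: the spectrum integrated
    over (0, Nyquist] equals the series variance (in expectation).
    """
    if n_tapers > 2 * nw - 1:
        raise ValueError(f"n_tapers={n_tapers} exceeds 2*NW-1={2 * nw - 1:g}")
    x = _discard(ts, baseline_discard)
    n = x.size
    nfft = 1 << (n - 1).bit_length()
    tapers = dpss(n, nw, Kmax=n_tapers)
    X = np.fft.rfft(tapers * x[None, :], n=nfft, axis=1)
    # one-sided density: double interior bins; dt scales |FFT|^2 to per-Hz
    S = np.mean(np.abs(X) ** 2, axis=0) * ts.dt
    S[1:] *= 2.0
    if nfft % 2 == 0:
        S[-1] /= 2.0
    freqs = np.fft.rfftfreq(nfft, d=ts.dt)
    return SpectrumEstimate(freqs=freqs[1:], power=S[1:], n_tapers=n_tapers, time_bandwidth=nw)


def periodogram_power(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-sided bin index/power pair with the convention ``P = |FFT|^2 / N``.

    Returns (one-sided FFT magnitudes squared / N, full-length N). Summing P
    over the two-sided spectrum recovers ``N * variance`` for a mean-removed
    series (Parseval).
    """
    n = x.size
    P = np.abs(np.fft.rfft(x)) ** 2 / n
    return P, n


def spectrum_slope(spec: SpectrumEstimate, f_max: float = 0.2) -> float:
    """OLS slope of log10(power) against (linear) frequency over (0, f_max]."""
    sel = spec.freqs <= f_max
    if sel.sum() < 10:
        raise ValueError(f"need >= 10 bins below {f_max} Hz, got {int(sel.sum())}")
    res = stats.linregress(spec.freqs[sel], spec.log_power[sel])
    return float(res.slope)


def fit_aperiodic(spec: SpectrumEstimate, f_max: float = 0.5) -> tuple[float, float]:
    """Fit the aperiodic model ``y = b - x*log10(F)`` over (0, f_max].

    Solved by damped (Levenberg-Marquardt) nonlinear least squares on the
    log10 power; returns (offset b, exponent x). The DC bin is excluded by
    construction of the spectrum.
    """
    sel = spec.freqs <= f_max
    if sel.sum() < 20:
        raise ValueError(f"need >= 20 bins below {f_max} Hz, got {int(sel.sum())}")
    F = spec.freqs[sel]
    y = spec.log_power[sel]

    def model(f, b, x):
        return b - x * np.log10(f)

    p0 = (float(y.mean()), 1.0)
    try:
        popt, _ = curve_fit(model, F, y, p0=p0, method="lm", maxfev=10000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"aperiodic fit did not converge (initializer b={p0[0]:.3g}, x={p0[1]:.3g})"
        ) from exc
    return float(popt[0]), float(popt[1])


def _band_bins(n: int, dt: float, band: tuple[float, float]) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, d=dt)
    nyq = 0.5 / dt
    if not 0 < band[0] < band[1] <= nyq + 1e-12:
        raise ValueError(f"band {band} outside (0, Nyquist={nyq:.3g}] Hz")
    return (freqs >= band[0]) & (freqs <= band[1])


def compute_alff(
    ts: VoxelTimeSeries,
    band: tuple[float, float] = (0.01, 0.08),
    baseline_discard: float = 14.0,
) -> float:
    """Amplitude of low-frequency fluctuations.

    The mean-removed series is band-pass filtered with an ideal FFT-domain
    mask, transformed with ``P = |FFT|^2 / N``, and ALFF is the mean of
    ``sqrt(P)`` over the in-band bins.
    """
    x = _discard(ts, baseline_discard)
    sel = _band_bins(x.size, ts.dt, band)
    X = np.fft.rfft(x)
    filtered = np.fft.irfft(np.where(sel, X, 0.0), n=x.size)
    P, _ = periodogram_power(filtered)
    return float(np.mean(np.sqrt(P[sel])))


def compute_falff(
    ts: VoxelTimeSeries,
    low: tuple[float, float] = (0.01, 0.08),
    wide: tuple[float, float] = (0.01, 0.25),
    baseline_discard: float = 14.0,
    sum_based: bool = False,
) -> float:
    """Fractional ALFF: low-band root power relative to the wide band.

    Default follows the band-mean reading of the ALFF equations (the mean of
    ``sqrt(P)`` in each band); ``sum_based=True`` switches to the classical
    ratio of band sums.
    """
    x = _discard(ts, baseline_discard)
    P, _ = periodogram_power(x)
    agg = np.sum if sum_based else np.mean
    sel_low = _band_bins(x.size, ts.dt, low)
    sel_wide = _band_bins(x.size, ts.dt, wide)
    denom = agg(np.sqrt(P[sel_wide]))
    if denom == 0:
        raise ValueError("wide-band power is zero: fALFF undefined")
    return float(agg(np.sqrt(P[sel_low])) / denom)


def voxel_features(
    ts: VoxelTimeSeries,
    slope_fmax: float = 0.2,
    aperiodic_fmax: float = 0.5,
    n_tapers: int = 5,
    baseline_discard: float = 14.0,
    alff_band: tuple[float, float] = (0.01, 0.08),
) -> dict:
    """All four spectral features for one resting voxel."""
    spec = multitaper_psd(ts, n_tapers=n_tapers, baseline_discard=baseline_discard)
    b, x = fit_aperiodic(spec, f_max=aperiodic_fmax)
    return {
        "slope": spectrum_slope(spec, f_max=slope_fmax),
        "aperiodic_offset": b,
        "aperiodic_exponent": x,
        "alff": compute_alff(ts, band=alff_band, baseline_discard=baseline_discard),
        "falff": compute_falff(ts, low=alff_band, baseline_discard=baseline_discard),
    }


def _zscore_columns(df: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        v = df[c].to_numpy()
        out[c + "_z"] = (v - v.mean()) / v.std(ddof=0)
    return out

_RAW_COLS = ["slope", "aperiodic_offset", "aperiodic_exponent", "alff", "falff"]


def build_feature_table(
    rest_runs: List[List[VoxelTimeSeries]], **feature_kwargs
) -> pd.DataFrame:
    """Per-voxel feature table: z-score within each run, average across runs.

    ``rest_runs`` is a list of runs, each a list of VoxelTimeSeries in a
    consistent voxel order. Raw features are averaged across runs too, for
    inspection; classifiers use the ``*_z`` columns.
    """
    if len(rest_runs) == 1:
        warnings.warn("single resting run: features are not run-averaged", stacklevel=2)
    per_run = []
    for run in rest_runs:
        df = pd.DataFrame([voxel_features(ts, **feature_kwargs) for ts in run])
        per_run.append(_zscore_columns(df, _RAW_COLS))
    avg = sum(per_run[1:], per_run[0]) / len(per_run)
    avg.insert(0, "voxel_id", [ts.voxel_id if ts.voxel_id is not None else i
                               for i, ts in enumerate(rest_runs[0])])
    return avg


def build_spectrum_matrix(
    rest_runs: List[List[VoxelTimeSeries]],
    f_max: float = 0.5,
    n_tapers: int = 5,
    baseline_discard: float = 14.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel full-spectrum feature matrix: PSD bins up to ``f_max`` Hz.

    Bins are z-scored across voxels within each run and averaged across runs.
    Returns (matrix of voxels x bins, bin frequencies). The bin count depends
    on the padded spectral resolution.
    """
    mats = []
    freqs = None
    for run in rest_runs:
        specs = [
            multitaper_psd(ts, n_tapers=n_tapers, baseline_discard=baseline_discard)
            for ts in run
        ]
        sel = specs[0].freqs <= f_max
        freqs = specs[0].freqs[sel]
        M = np.vstack([s.power[sel] for s in specs])
        M = (M - M.mean(axis=0)) / M.std(axis=0, ddof=0)
        mats.append(M)
    return np.mean(mats, axis=0), freqs


def compare_groups(
    features: pd.DataFrame,
    labels: Sequence[str] | np.ndarray,
    feature_name: str,
    group_a: str = "fast",
    group_b: str = "slow",
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of a feature between two voxel groups."""
    labels = np.asarray(labels)
    a = features.loc[labels == group_a, feature_name].to_numpy()
    b = features.loc[labels == group_b, feature_name].to_numpy()
    if a.size < 5 or b.size < 5:
        raise ValueError(f"groups too small: {group_a}={a.size}, {group_b}={b.size} (need >= 5)")
    res = stats.ranksums(a, b)
    return float(res.statistic), float(res.pvalue)
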