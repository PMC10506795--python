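"""Breath-hold vascular latency mapping.

A breath hold raises arterial CO2 and drives a global vasodilatory BOLD
response; the per-voxel arrival time of that response probes local vascular
latency independent of neural activity. The task regressor is a boxcar over
the holds convolved with a sign-reversed canonical double-gamma response.
Voxels correlating with the regressor above r = 0.25 at zero lag are
averaged into a reference series, and each voxel's latency is the lag
maximizing its normalized cross-correlation with that reference, after both
are resampled to a 100 ms grid.
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np
import pandas as pd

from .core import VoxelTimeSeries
from .hrf import canonical_hrf
from .synth import BreathHoldSchedule

__all__ = [
    "BreathHoldSchedule",
    "make_bh_regressor",
    "build_reference",
    "bh_latency",
    "latency_map",
]

RESAMPLE_DT = 0.1  # s; the cross-correlation grid


def make_bh_regressor(schedule: BreathHoldSchedule, tr: float) -> VoxelTimeSeries:
    """Boxcar over the holds convolved with the negated canonical response."""
    n = int(round(schedule.total / tr))
    t = np.arange(n) * tr
    box = np.zeros(n)
    for start, end in schedule.hold_intervals():
        box[(t >= start) & (t < end)] = 1.0
    k = canonical_hrf(tr)
    reg = np.convolve(box, -k.samples)[:n] * tr
    return VoxelTimeSeries(reg, dt=tr, run_kind="bh")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return 0.0
    return float((a @ b) / denom)


def build_reference(
    runs: Sequence[VoxelTimeSeries], regressor: VoxelTimeSeries, r_min: float = 0.25
) -> VoxelTimeSeries:
    """Mean of the demeaned voxel series correlating with the regressor above r_min.

    Inclusion uses the zero-lag Pearson correlation. Raises if no voxel
    passes, reporting the maximum observed correlation.
    """
    rs = np.array([_pearson(ts.values, regressor.values) for ts in runs])
    keep = rs > r_min
    if not keep.any():
        raise ValueError(
            f"no voxel exceeds r_min={r_min}; max observed r={rs.max():.3f}"
        )
    stack = np.vstack([runs[i].values - runs[i].values.mean() for i in np.nonzero(keep)[0]])
    return VoxelTimeSeries(stack.mean(axis=0), dt=regressor.dt, run_kind="bh")


def _resample(values: np.ndarray, dt: float, new_dt: float) -> np.ndarray:
    t_old = np.arange(values.size) * dt
    t_new = np.arange(0.0, t_old[-1] + 1e-9, new_dt)
    return np.interp(t_new, t_old, values)


def bh_latency(
    voxel: VoxelTimeSeries,
    reference: VoxelTimeSeries,
    max_lag: float = 15.0,
) -> tuple[float, float]:
    """Latency (s) and peak correlation of a voxel against the reference.

    Both series are linearly interpolated to 100 ms sampling and mean-removed;
    the normalized cross-correlation is evaluated at every integer lag in
    [-max_lag, +max_lag], where positive latency means the voxel's response
    arrives *after* the reference. Ties break toward the smallest |lag|.
    """
    if voxel.n != reference.n:
        raise ValueError(f"length mismatch: voxel {voxel.n} vs reference {reference.n}")
    if np.ptp(voxel.values) == 0 or np.ptp(reference.values) == 0:
        raise ValueError("constant series: correlation undefined")
    x = _resample(voxel.values, voxel.dt, RESAMPLE_DT)
    y = _resample(reference.values, reference.dt, RESAMPLE_DT)
    x = x - x.mean()
    y = y - y.mean()
    max_shift = int(round(max_lag / RESAMPLE_DT))
    lags = np.arange(-max_shift, max_shift + 1)
    rs = np.empty(lags.size)
    for i, k in enumerate(lags):
        # positive k: voxel delayed, compare x[k:] against y[:-k]
        if k > 0:
            a, b = x[k:], y[:-k]
        elif k < 0:
            a, b = x[:k], y[-k:]
        else:
            a, b = x, y
        rs[i] = _pearson(a, b)
    best = rs.max()
    candidates = np.nonzero(rs >= best - 1e-12)[0]
    i_best = candidates[np.argmin(np.abs(lags[candidates]))]
    return float(lags[i_best] * RESAMPLE_DT), float(rs[i_best])


def latency_map(
    runs: Sequence[VoxelTimeSeries],
    regressor: VoxelTimeSeries,
    r_min: float = 0.25,
    max_lag: float = 15.0,
) -> pd.DataFrame:
    """Per-voxel latency table (voxel_id, latency_s, r) against the global reference."""
    reference = build_reference(runs, regressor, r_min=r_min)
    rows = []
    for i, ts in enumerate(runs):
        lat, r = bh_latency(ts, reference, max_lag=max_lag)
        rows.append(
            {"voxel_id": ts.voxel_id if ts.voxel_id is not None else i, "latency_s": lat, "r": r}
        )
    return pd.DataFrame(rows)
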