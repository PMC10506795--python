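"""Stimulus-driven voxel localization and phase-lag grouping.

A voxel driven by a sinusoidal stimulus responds at the stimulus frequency
with some delay set by its hemodynamic response. Regressing each voxel on
sine and cosine bases at the stimulus frequency gives (i) an F statistic for
the joint fit — thresholded as a functional localizer after conversion to a
Z score — and (ii) a phase lag from the arctangent of the two coefficients.
Fitting a Gaussian to the histogram of lags then defines symmetric "fast"
and "slow" lag windows, each one third of the histogram FWHM wide, on either
side of the centroid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

from .core import VoxelTimeSeries

__all__ = [
    "SinCosFit",
    "PhaseHistogramFit",
    "fit_sin_cos_glm",
    "phase_lag_from_betas",
    "localize_voxels",
    "fit_phase_histogram",
    "assign_speed_groups",
]

# Z score reported when the F test saturates (residual variance ~ 0); the
# upper-tail normal quantile of the smallest positive double.
_Z_SATURATED = float(stats.norm.isf(np.nextafter(0, 1)))


@dataclass(frozen=True)
class SinCosFit:
    """OLS fit of a series on sine/cosine bases at the stimulus frequency."""

    beta_sin: float
    beta_cos: float
    f_stat: float
    z_stat: float
    saturated: bool = False


def fit_sin_cos_glm(
    ts: VoxelTimeSeries, f_stim: float, baseline_discard: float = 14.0
) -> SinCosFit:
    """OLS of the post-baseline series on {1, sin, cos} at the stimulus frequency.

    The sine/cosine bases use time relative to the end of the discarded
    baseline, so the recovered phase is relative to the stimulus onset. The F
    statistic tests the sine and cosine coefficients jointly (2 numerator
    dof); z_stat is the upper-tail standard-normal quantile of the F survival
    probability. A perfect fit is flagged ``saturated`` with a large finite z.
    """
    i0 = int(np.ceil(baseline_discard / ts.dt))
    y = ts.values[i0:]
    n = y.size
    if n * ts.dt < 3.0 / f_stim:
        raise ValueError(
            f"post-discard duration {n * ts.dt:.1f} s is under 3 stimulus cycles"
        )
    # time measured from stimulus onset: the first retained sample sits at
    # i0*dt - baseline_discard (not zero) when the discard is not a multiple
    # of dt, and the phase estimate must account for that offset
    t = np.arange(i0, i0 + n) * ts.dt - baseline_discard
    X = np.column_stack(
        [np.ones(n), np.sin(2 * np.pi * f_stim * t), np.cos(2 * np.pi * f_stim * t)]
    )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss1 = float(resid @ resid)
    rss0 = float(np.sum((y - y.mean()) ** 2))
    dof = n - 3
    scale = max(rss0, 1.0)
    if rss1 <= 1e-12 * scale:
        return SinCosFit(float(beta[1]), float(beta[2]), np.inf, _Z_SATURATED, saturated=True)
    f_stat = ((rss0 - rss1) / 2.0) / (rss1 / dof)
    f_stat = max(f_stat, 0.0)
    p = stats.f.sf(f_stat, 2, dof)
    if p <= 0:
        return SinCosFit(float(beta[1]), float(beta[2]), float(f_stat), _Z_SATURATED, saturated=True)
    z = float(stats.norm.isf(p))
    return SinCosFit(float(beta[1]), float(beta[2]), float(f_stat), z)


def phase_lag_from_betas(fit: SinCosFit, f_stim: float) -> float:
    """Response delay in seconds from the sine/cosine coefficients.

    Modeling the response as ``A*sin(2*pi*f*(t) - phi)`` gives
    ``beta_sin = A*cos(phi)`` and ``beta_cos = -A*sin(phi)``, so
    ``phi = atan2(-beta_cos, beta_sin)``; the lag ``phi/(2*pi*f)`` is wrapped
    into [0, 1/f).
    """
    if fit.beta_sin == 0.0 and fit.beta_cos == 0.0:
        raise ValueError("zero-amplitude fit: phase undefined")
    phi = np.arctan2(-fit.beta_cos, fit.beta_sin)
    return float((phi % (2 * np.pi)) / (2 * np.pi * f_stim))


def localize_voxels(
    z_map: np.ndarray | Sequence[float],
    threshold: float = 2.5,
    anatomical_mask: Optional[np.ndarray] = None,
) -> Set[int]:
    """Voxel indices with z above threshold, intersected with the mask."""
    z_map = np.asarray(z_map, dtype=float)
    if anatomical_mask is None:
        anatomical_mask = np.ones(z_map.shape, dtype=bool)
    anatomical_mask = np.asarray(anatomical_mask, dtype=bool)
    if anatomical_mask.shape != z_map.shape:
        raise ValueError("z_map and anatomical_mask must be aligned")
    selected = set(np.nonzero((z_map > threshold) & anatomical_mask)[0].tolist())
    if not selected:
        warnings.warn("localizer selected no voxels", stacklevel=2)
    return selected


@dataclass(frozen=True)
class PhaseHistogramFit:
    """Gaussian fit to the histogram of phase lags."""

    centroid: float
    fwhm: float
    amplitude: float
    bin_edges: np.ndarray

    @property
    def sigma(self) -> float:
        return self.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def fit_phase_histogram(
    lags: Iterable[float], n_bins: int = 30, domain: Optional[tuple[float, float]] = None
) -> PhaseHistogramFit:
    """Least-squares Gaussian fit a*exp(-(x-b)^2/(2 s^2)) to the lag histogram.

    Bins span ``domain`` (default: the lag range) with ``n_bins`` equal-width
    bins; the fit is to counts at bin centers, initialized from the sample
    moments. FWHM = 2*sqrt(2 ln 2)*sigma.
    """
    lags = np.asarray(list(lags), dtype=float)
    if lags.size < 30:
        raise ValueError(f"need >= 30 lags to fit a histogram, got {lags.size}")
    if domain is None:
        domain = (float(lags.min()), float(lags.max()))
    counts, edges = np.histogram(lags, bins=n_bins, range=domain)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(x, a, b, s):
        return a * np.exp(-((x - b) ** 2) / (2.0 * s**2))

    span = domain[1] - domain[0]
    bin_w = span / n_bins
    a0 = float(counts.max())
    sd0 = float(np.clip(lags.std(), bin_w, span))
    # deterministic multi-start: broad or multimodal histograms have local
    # minima that can pin a single start against the parameter bounds
    starts = [
        (a0, float(np.clip(lags.mean(), *domain)), sd0),
        (a0, float(centers[np.argmax(counts)]), sd0),
        (a0, float(np.clip(np.median(lags), *domain)), max(sd0 / 2.0, bin_w)),
        (a0, float(np.clip(lags.mean(), *domain)), span / 4.0),
    ]
    bounds = ([0.0, domain[0], bin_w / 2.0], [10.0 * max(a0, 1.0), domain[1], span])
    best = None
    for p0 in starts:
        try:
            popt, _ = curve_fit(gauss, centers, counts, p0=p0, bounds=bounds, maxfev=20000)
        except RuntimeError:
            continue
        sse = float(np.sum((gauss(centers, *popt) - counts) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        raise RuntimeError(
            f"Gaussian histogram fit failed on {lags.size} lags "
            f"(initializers b={[f'{s[1]:.3g}' for s in starts]}, "
            f"sigma={[f'{s[2]:.3g}' for s in starts]})"
        )
    a, b, s = best[1]
    s = abs(float(s))
    return PhaseHistogramFit(
        centroid=float(b),
        fwhm=2.0 * np.sqrt(2.0 * np.log(2.0)) * s,
        amplitude=float(a),
        bin_edges=edges,
    )


def assign_speed_groups(
    lags: Sequence[float] | np.ndarray,
    fit: PhaseHistogramFit,
    voxel_ids: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Label voxels fast/slow/unassigned from their lag and the histogram fit.

    Fast voxels lie in the closed window [b - FWHM/2, b - FWHM/6]; slow
    voxels in [b + FWHM/6, b + FWHM/2]. Both windows are FWHM/3 wide,
    disjoint, and symmetric about the centroid b; everything else is
    unassigned.
    """
    lags = np.asarray(lags, dtype=float)
    b, w = fit.centroid, fit.fwhm
    labels = np.full(lags.shape, "unassigned", dtype=object)
    labels[(lags >= b - w / 2) & (lags <= b - w / 6)] = "fast"
    labels[(lags >= b + w / 6) & (lags <= b + w / 2)] = "slow"
    if voxel_ids is None:
        voxel_ids = np.arange(lags.size)
    return pd.DataFrame({"voxel_id": voxel_ids, "lag": lags, "label": labels})
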