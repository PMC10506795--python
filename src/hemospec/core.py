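"""Shared lightweight containers."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["VoxelTimeSeries"]


@dataclass(frozen=True)
class VoxelTimeSeries:
    """One voxel's sampled BOLD signal.

    Parameters
    ----------
    values : ndarray
        Signal samples (arbitrary units; percent signal change in synthetic
        runs). Must be finite.
    dt : float
        Sampling interval in seconds (the TR for scanner-resolution series).
    run_kind : {"rest", "task", "bh", "sim"}
        The kind of run the series belongs to.
    voxel_id : int or None
        Stable identifier within a subject, if any.
    """

    values: np.ndarray
    dt: float
    run_kind: str = "sim"
    voxel_id: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.n * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) * self.dt
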