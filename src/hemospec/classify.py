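"""SVM classification of voxel hemodynamic speed and latency regression.

Voxels are classified fast / slow / LGN from resting-state spectral features
(or breath-hold latency) with an RBF-kernel SVM (C = 10, gamma =
1/(n_features * feature-matrix variance) — scikit-learn's "scale" rule).
Validation follows the repeated-random-split scheme: each "bootstrap" draws a
fresh stratified 80/20 train/validate split, standardization is fit on the
training fold only, and the report is the mean validation accuracy with a
95% percentile interval. Continuous relative latency (clipped to +/-3 s
around the median) is regressed with epsilon-insensitive SVR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR

__all__ = [
    "ClassifierConfig",
    "BootstrapReport",
    "RegressionReport",
    "standardize_features",
    "train_classify_bootstrap",
    "train_regress_latency",
    "hemisphere_style_split",
]


@dataclass(frozen=True)
class ClassifierConfig:
    C: float = 10.0
    kernel: str = "rbf"
    gamma: str = "scale"  # 1/(n_features * X.var()), the stated rule
    epsilon: float = 0.1  # SVR only
    n_bootstraps: int = 1000
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class BootstrapReport:
    mean_accuracy: float
    ci95: tuple[float, float]
    accuracies: np.ndarray
    n_bootstraps: int
    feature_set: str = ""


@dataclass(frozen=True)
class RegressionReport:
    r2: float
    rmse: float
    r2_values: np.ndarray
    rmse_values: np.ndarray
    n_voxels: int


def standardize_features(X: np.ndarray) -> np.ndarray:
    """Z-score each feature column (constant columns dropped with a warning)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 voxels")
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant feature(s)", stacklevel=2)
    return (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]


def _percentile_ci(values: np.ndarray) -> tuple[float, float]:
    return (float(np.percentile(values, 2.5)), float(np.percentile(values, 97.5)))


def train_classify_bootstrap(
    X: np.ndarray,
    labels: Sequence[str] | np.ndarray,
    config: ClassifierConfig = ClassifierConfig(),
    feature_set: str = "four_features",
) -> BootstrapReport:
    """Repeated stratified 80/20 split validation of the RBF-kernel SVM.

    Standardization is fit on each training fold and applied to its
    validation fold, so validation rows never influence the transform.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 10:
        raise ValueError(
            f"need >= 10 voxels per class, got {dict(zip(classes.tolist(), counts.tolist()))}"
        )
    splitter = StratifiedShuffleSplit(
        n_splits=config.n_bootstraps,
        train_size=config.train_fraction,
        random_state=config.seed,
    )
    accs = np.empty(config.n_bootstraps)
    for i, (tr, va) in enumerate(splitter.split(X, labels)):
        model = make_pipeline(
            StandardScaler(), SVC(C=config.C, kernel=config.kernel, gamma=config.gamma)
        )
        model.fit(X[tr], labels[tr])
        accs[i] = model.score(X[va], labels[va])
    return BootstrapReport(
        mean_accuracy=float(accs.mean()),
        ci95=_percentile_ci(accs),
        accuracies=accs,
        n_bootstraps=config.n_bootstraps,
        feature_set=feature_set,
    )


def train_regress_latency(
    X: np.ndarray,
    lags: Sequence[float] | np.ndarray,
    config: ClassifierConfig = ClassifierConfig(),
    lag_window: float = 3.0,
) -> RegressionReport:
    """Epsilon-insensitive SVR of relative lag on the features.

    Lags are re-expressed relative to their median; voxels outside
    [-lag_window, +lag_window] s are excluded before fitting. Reports mean
    validation R^2 and RMSE over repeated 80/20 splits.
    """
    X = np.asarray(X, dtype=float)
    lags = np.asarray(lags, dtype=float)
    rel = lags - np.median(lags)
    keep = np.abs(rel) <= lag_window
    X, rel = X[keep], rel[keep]
    if X.shape[0] < 20:
        raise ValueError(f"only {X.shape[0]} voxels within +/-{lag_window} s; need >= 20")
    rng = np.random.default_rng(config.seed)
    n = X.shape[0]
    n_train = int(round(config.train_fraction * n))
    r2s = np.empty(config.n_bootstraps)
    rmses = np.empty(config.n_bootstraps)
    for i in range(config.n_bootstraps):
        perm = rng.permutation(n)
        tr, va = perm[:n_train], perm[n_train:]
        model = make_pipeline(
            StandardScaler(),
            SVR(C=config.C, kernel=config.kernel, gamma=config.gamma, epsilon=config.epsilon),
        )
        model.fit(X[tr], rel[tr])
        pred = model.predict(X[va])
        ss_res = float(np.sum((rel[va] - pred) ** 2))
        ss_tot = float(np.sum((rel[va] - rel[va].mean()) ** 2))
        r2s[i] = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        rmses[i] = float(np.sqrt(np.mean((rel[va] - pred) ** 2)))
    return RegressionReport(
        r2=float(r2s.mean()),
        rmse=float(rmses.mean()),
        r2_values=r2s,
        rmse_values=rmses,
        n_voxels=n,
    )


def hemisphere_style_split(
    X: np.ndarray,
    labels: Sequence[str] | np.ndarray,
    grouping: Sequence[str] | np.ndarray,
    config: ClassifierConfig = ClassifierConfig(),
) -> dict:
    """Train on one spatial group, validate on the other, in both directions.

    Guards against spatial leakage between neighboring voxels: the split is
    by the provided group tag (e.g. hemisphere) rather than random. Returns
    {direction: accuracy}.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    grouping = np.asarray(grouping)
    tags = np.unique(grouping)
    if tags.size != 2:
        raise ValueError(f"need exactly two group tags, got {tags.tolist()}")
    all_classes = set(np.unique(labels))
    out = {}
    for train_tag, test_tag in ((tags[0], tags[1]), (tags[1], tags[0])):
        tr = grouping == train_tag
        va = grouping == test_tag
        for side, sel in (("training", tr), ("validation", va)):
            missing = all_classes - set(np.unique(labels[sel]))
            if missing:
                raise ValueError(f"class(es) {sorted(missing)} missing from {side} group")
        model = make_pipeline(
            StandardScaler(), SVC(C=config.C, kernel=config.kernel, gamma=config.gamma)
        )
        model.fit(X[tr], labels[tr])
        out[f"{train_tag}->{test_tag}"] = float(model.score(X[va], labels[va]))
    return out
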