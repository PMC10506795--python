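"""End-to-end orchestration: synthetic or real-data runs, NIfTI I/O, manifest.

The full pipeline follows the study's analysis order: localize stimulus-driven
voxels on the first task run, estimate phase lags from the average of the
remaining task runs and assign fast/slow groups, extract resting-state
spectral features, map breath-hold vascular latency, train the speed
classifiers and the latency regression, and run group comparisons. In
synthetic mode the ground-truth table additionally yields recovery metrics.
"""

from __future__ import annotations

import json
import platform
import warnings
from dataclasses import asdict, dataclass, field, is_dataclass
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .breathhold import latency_map, make_bh_regressor
from .classify import ClassifierConfig, train_classify_bootstrap, train_regress_latency
from .core import VoxelTimeSeries
from .spectral import build_feature_table, compare_groups
from .synth import SyntheticConfig, SyntheticSubject, generate_subject
from .task_phase import (
    assign_speed_groups,
    fit_phase_histogram,
    fit_sin_cos_glm,
    localize_voxels,
    phase_lag_from_betas,
)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "load_bold_run",
    "save_subject_nifti",
    "run_full_pipeline",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for one full pipeline run."""

    mode: str = "synthetic"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    z_threshold: float = 2.5
    output_dir: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ValueError(f"mode must be 'synthetic' or 'real', got {self.mode!r}")


@dataclass
class PipelineResult:
    labels: pd.DataFrame
    features: pd.DataFrame
    latencies: pd.DataFrame
    classification: dict
    regression: dict
    comparisons: pd.DataFrame
    recovery: dict
    manifest: dict


def load_bold_run(path, mask_path) -> List[VoxelTimeSeries]:
    """Load a 4D NIfTI run masked by a 3D binary volume.

    Returns one VoxelTimeSeries per in-mask voxel, ordered by ascending
    linear (C-order) voxel index; dt is taken from the header's repetition
    time (4th zoom).
    """
    import nibabel as nib

    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"{path}: expected a 4D BOLD image, got {img.ndim}D")
    mask_img = nib.load(str(mask_path))
    if mask_img.shape != img.shape[:3]:
        raise ValueError(
            f"{mask_path}: mask grid {mask_img.shape} does not match run grid {img.shape[:3]}"
        )
    tr = float(img.header.get_zooms()[3])
    if tr <= 0:
        raise ValueError(f"{path}: header repetition time must be positive, got {tr}")
    data = np.asarray(img.dataobj)
    mask = np.asarray(mask_img.dataobj).astype(bool)
    idx = np.nonzero(mask.ravel(order="C"))[0]
    flat = data.reshape(-1, data.shape[3])
    return [
        VoxelTimeSeries(flat[i], dt=tr, run_kind="rest", voxel_id=int(i)) for i in idx
    ]


def save_subject_nifti(subject: SyntheticSubject, out_dir) -> dict:
    """Write a synthetic subject as 4D NIfTI runs + mask + truth TSV.

    Voxels are arranged on a near-square 2D grid (z = 1); the affine is
    identity with the TR in the 4th pixdim. Returns the written paths.
    """
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_vox = subject.n_voxels
    nx = int(np.ceil(np.sqrt(n_vox)))
    ny = int(np.ceil(n_vox / nx))
    paths = {}

    mask = np.zeros(nx * ny, dtype=np.uint8)
    mask[:n_vox] = 1
    mask_img = nib.Nifti1Image(mask.reshape(nx, ny, 1), np.eye(4))
    mask_path = out_dir / "mask.nii.gz"
    mask_img.to_filename(mask_path)
    paths["mask"] = str(mask_path)

    for kind, runs in (
        ("rest", subject.rest_runs),
        ("task", subject.task_runs),
        ("bh", subject.bh_runs),
    ):
        for r, run in enumerate(runs):
            n_t = run[0].n
            vol = np.zeros((nx * ny, n_t), dtype=np.float32)
            for i, ts in enumerate(run):
                vol[i] = ts.values
            img = nib.Nifti1Image(vol.reshape(nx, ny, 1, n_t), np.eye(4))
            img.header.set_zooms((1.0, 1.0, 1.0, run[0].dt))
            p = out_dir / f"{kind}_run-{r + 1}.nii.gz"
            img.to_filename(p)
            paths[f"{kind}_{r + 1}"] = str(p)

    truth_path = out_dir / "truth.tsv"
    subject.truth.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = str(truth_path)
    return paths


def _average_runs(runs: List[List[VoxelTimeSeries]]) -> List[VoxelTimeSeries]:
    out = []
    for series in zip(*runs):
        vals = np.mean([ts.values for ts in series], axis=0)
        out.append(
            VoxelTimeSeries(vals, dt=series[0].dt, run_kind=series[0].run_kind,
                            voxel_id=series[0].voxel_id)
        )
    return out


def _to_jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _to_jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def run_full_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the complete analysis on one (synthetic) subject.

    Stages: localize -> phase/groups -> resting features -> breath-hold
    latency -> classification/regression -> group comparisons. Deterministic
    for a fixed seed. Raises with the stage name on failure; if an output
    directory is configured, partial outputs plus a FAILED marker are kept.
    """
    if config.mode == "real":
        raise NotImplementedError(
            "real mode requires preprocessed NIfTI runs loaded via load_bold_run; "
            "compose the stage functions directly"
        )
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    stage = "generate"
    try:
        syn = config.synthetic
        if syn.seed != config.seed:
            syn = SyntheticConfig(**{**asdict_config(syn), "seed": config.seed})
        subject = generate_subject(syn)
        f_stim = syn.f_stim

        stage = "phase"
        if not subject.task_runs:
            raise ValueError("no task runs in subject")
        localizer_run = subject.task_runs[0]
        z = np.array(
            [
                fit_sin_cos_glm(ts, f_stim, baseline_discard=syn.task_baseline).z_stat
                for ts in localizer_run
            ]
        )
        # the anatomical masks mirror the study's segmentations: phase
        # grouping runs on cortical (V1-like) voxels only; LGN voxels form
        # their own anatomically defined group, also localizer-thresholded
        cortical_mask = (subject.truth.label != "lgn").to_numpy()
        selected = localize_voxels(z, threshold=config.z_threshold, anatomical_mask=cortical_mask)
        lgn_selected = localize_voxels(
            z, threshold=config.z_threshold, anatomical_mask=~cortical_mask
        )
        remaining = subject.task_runs[1:] or subject.task_runs[:1]
        avg_task = _average_runs(remaining)
        lags = np.array(
            [
                phase_lag_from_betas(
                    fit_sin_cos_glm(ts, f_stim, baseline_discard=syn.task_baseline), f_stim
                )
                for ts in avg_task
            ]
        )
        sel_idx = sorted(selected)
        hist_fit = fit_phase_histogram(lags[sel_idx])
        groups = assign_speed_groups(lags[sel_idx], hist_fit, voxel_ids=sel_idx)
        labels = pd.DataFrame({"voxel_id": np.arange(len(lags)), "lag": lags, "z_stat": z})
        labels = labels.merge(
            groups[["voxel_id", "label"]], on="voxel_id", how="left"
        ).fillna({"label": "unassigned"})
        labels.loc[labels.voxel_id.isin(sorted(lgn_selected)), "label"] = "lgn"

        stage = "features"
        features = build_feature_table(subject.rest_runs)

        stage = "breath_hold"
        regressor = make_bh_regressor(syn.bh_schedule, syn.tr)
        bh_avg = _average_runs(subject.bh_runs)
        latencies = latency_map(bh_avg, regressor)

        stage = "classify"
        feat_z = features[["slope_z", "aperiodic_exponent_z", "alff_z", "falff_z"]].to_numpy()
        truth_labels = subject.truth.label.to_numpy()
        clf_config = ClassifierConfig(
            **{**asdict_config(config.classifier), "seed": config.seed}
        )
        clf_report = train_classify_bootstrap(feat_z, truth_labels, clf_config, "four_features")
        bh_report = train_classify_bootstrap(
            latencies[["latency_s"]].to_numpy(), truth_labels, clf_config, "bh_latency"
        )
        reg_report = train_regress_latency(feat_z, lags, clf_config)

        stage = "compare"
        est_labels = labels.label.to_numpy()
        comp_rows = []
        for feat in ("slope_z", "aperiodic_exponent_z", "alff_z", "falff_z"):
            try:
                s, p = compare_groups(features, est_labels, feat)
                comp_rows.append({"feature": feat, "statistic": s, "pvalue": p})
            except ValueError as exc:
                warnings.warn(f"comparison skipped for {feat}: {exc}", stacklevel=2)
        comparisons = pd.DataFrame(comp_rows)

        stage = "recovery"
        truth = subject.truth
        driven_frac = float(np.mean(z > config.z_threshold))
        lag_mae = float(np.median(np.abs(lags - truth.lag_true.to_numpy())))
        assigned = est_labels != "unassigned"
        label_agreement = (
            float(np.mean(est_labels[assigned] == truth.label.to_numpy()[assigned]))
            if assigned.any()
            else np.nan
        )
        recovery = {
            "localizer_pass_fraction": driven_frac,
            "median_abs_lag_error_s": lag_mae,
            "assigned_label_agreement": label_agreement,
            "classification_accuracy": clf_report.mean_accuracy,
            "bh_latency_accuracy": bh_report.mean_accuracy,
        }
    except Exception as exc:
        if out_dir:
            (out_dir / "FAILED").write_text(f"stage={stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "package": "hemospec",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": _to_jsonable(config),
    }
    result = PipelineResult(
        labels=labels,
        features=features,
        latencies=latencies,
        classification={
            "four_features": _to_jsonable(
                {k: v for k, v in asdict_config(clf_report).items() if k != "accuracies"}
            ),
            "bh_latency": _to_jsonable(
                {k: v for k, v in asdict_config(bh_report).items() if k != "accuracies"}
            ),
        },
        regression=_to_jsonable(
            {
                k: v
                for k, v in asdict_config(reg_report).items()
                if k not in ("r2_values", "rmse_values")
            }
        ),
        comparisons=comparisons,
        recovery=recovery,
        manifest=manifest,
    )

    if out_dir:
        labels.to_csv(out_dir / "speed_labels.tsv", sep="\t", index=False)
        features.to_csv(out_dir / "spectral_features.tsv", sep="\t", index=False)
        latencies.to_csv(out_dir / "bh_latencies.tsv", sep="\t", index=False)
        comparisons.to_csv(out_dir / "group_comparisons.tsv", sep="\t", index=False)
        (out_dir / "reports.json").write_text(
            json.dumps(
                {
                    "classification": result.classification,
                    "regression": result.regression,
                    "recovery": _to_jsonable(recovery),
                },
                indent=2,
            )
        )
        (out_dir / "manifest.json").write_text(json.dumps(_to_jsonable(manifest), indent=2))
    return result


def asdict_config(obj) -> dict:
    """dataclass -> dict without deep-copying array fields."""
    return {k: getattr(obj, k) for k in obj.__dataclass_fields__}
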