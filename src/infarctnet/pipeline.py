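"""End-to-end orchestration: simulate/load -> preprocess -> cross-validate
-> evaluate -> report.

`run_pipeline` realizes the whole voxel-outcome analysis on a phantom
cohort (or on studies loaded from NIfTI): per-subject preprocessing, an
optional AUCCF architecture search, estimation of the common termination
error from a fixed-epoch validation run, the final leave-one-out loop
trained to that error, pooled evaluation (ROC/AUROC, half-angle operating
point, CCF, cluster-robust correlation) and standard-format outputs
(report JSON, CSV tables, PNG curves, predicted-map NIfTIs).  Everything
is driven by one global seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from pydantic import BaseModel

from . import phantom
from .crossval import (
    architecture_search,
    cross_validate,
    pooled_ccf_curve,
    stopping_epoch,
    termination_error,
)
from .metrics import (
    EvaluationConfig,
    cluster_adjusted_correlation,
    optimal_point,
    roc_curve,
)
from .mlp import NetworkArchitecture, TrainingConfig, predict_map, train
from .phantom import CohortTable, GridSpec, SubjectStudy, TissueModel, demographic_table
from .preprocess import SampleSet, preprocess_study

log = logging.getLogger(__name__)
__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """One config object for the whole run.

    Exactly one of ``input_dir`` (NIfTI studies on disk) or the simulation
    spec (``n_subjects``/``grid``/``tissue_model``) is used; ``input_dir``
    wins when set.  ``roi_threshold`` is the normalized chronic-T2 cutoff
    that outlines the infarct ROI (a required clinical input: the analysis
    does not choose it).
    """

    seed: int = 0
    # simulation spec
    n_subjects: int = 12
    grid: GridSpec = field(default_factory=GridSpec)
    tissue_model: TissueModel = field(default_factory=TissueModel)
    # or input paths
    input_dir: str | None = None
    subject_ids: list[str] | None = None
    # preprocessing
    roi_threshold: float = 1.4
    midline: float | None = None
    mask_fraction: float = 0.10
    target_prevalence: float | None = None
    # model and training
    arch: NetworkArchitecture = field(default_factory=NetworkArchitecture)
    # batch descent at lr 0.01 needs a few thousand epochs to saturate the
    # held-out CCF curve, so the pipeline default allows a larger epoch
    # budget than the bare library default
    training: TrainingConfig = field(
        default_factory=lambda: TrainingConfig(max_epochs=3000)
    )
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    validation_epochs: int = 2000  # fixed-epoch run for the plateau analysis
    search_candidates: list[int] | None = None   # e.g. [2, 3, 4]; None = off
    # outputs
    out_dir: str | None = None
    write_maps: bool = True
    write_plots: bool = True


class FoldReport(BaseModel):
    test_id: str
    n_epochs: int
    stopping_epoch: int | None = None
    stopping_mse: float | None = None
    final_mse: float
    heldout_ccf: float
    heldout_auroc: float | None


class RunReport(BaseModel):
    """Serializable summary of one pipeline run; complete enough to
    regenerate every figure from the accompanying CSV files."""

    software_version: str
    seed: int
    n_subjects: int
    n_slices: int
    n_voxels: int
    prevalence: float
    selected_hidden2: int
    architecture: list[int]
    termination_mse: float
    stopping_epoch: int
    pooled_auroc: float
    optimal_sensitivity: float
    optimal_specificity: float
    optimal_threshold: float
    pooled_ccf: float
    pearson_r: float
    regression_slope: float
    cluster_robust_se: float
    p_value: float
    folds: list[FoldReport]
    config_echo: dict


def _load_cohort(config: PipelineConfig) -> list[SubjectStudy]:
    if config.input_dir is not None:
        if not config.subject_ids:
            raise ValueError("subject_ids required when loading from input_dir")
        return [
            phantom.load_study(config.input_dir, sid) for sid in config.subject_ids
        ]
    return phantom.generate_cohort(
        config.n_subjects, config.seed, config.tissue_model, config.grid
    )


def run_pipeline(config: PipelineConfig | None = None) -> RunReport:
    """Execute the full analysis and (optionally) write all artifacts."""
    config = config or PipelineConfig()
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    log.info("stage: simulate/load")
    cohort = _stage("simulate/load", _load_cohort, config)

    log.info("stage: preprocess")

    def _preprocess():
        normalized, masks, roisets, sample_sets = {}, {}, {}, []
        for study in cohort:
            norm, mask, rois, samples = preprocess_study(
                study,
                config.roi_threshold,
                config.midline,
                config.mask_fraction,
                config.target_prevalence,
            )
            normalized[study.subject_id] = norm
            masks[study.subject_id] = mask
            roisets[study.subject_id] = rois
            sample_sets.append(samples)
            log.info(
                "  %s: prevalence %.3f (%d voxels)",
                study.subject_id, rois.prevalence, len(samples),
            )
        return normalized, masks, roisets, SampleSet.concatenate(sample_sets)

    normalized, masks, roisets, samples = _stage("preprocess", _preprocess)
    log.info(
        "assembled %d voxel samples from %d subjects, prevalence %.3f",
        len(samples), len(cohort), samples.prevalence,
    )

    # optional AUCCF architecture search for the second hidden layer
    arch = config.arch
    search = None
    if config.search_candidates:
        log.info("stage: architecture search over %s", config.search_candidates)
        search = _stage(
            "architecture search",
            architecture_search,
            samples,
            config.search_candidates,
            config.training,
            arch.layers[1],
            config.validation_epochs,
        )
        arch = NetworkArchitecture(
            (arch.layers[0], arch.layers[1], search.selected, 1), arch.output_range
        )
        log.info("selected architecture %s", arch.layers)

    # fixed-epoch validation run -> pooled CCF plateau -> termination error
    log.info("stage: crossval (termination-error estimation)")
    val_folds = _stage(
        "crossval/validation",
        cross_validate,
        samples, arch, config.training, None, config.validation_epochs,
    )
    term_mse = termination_error(val_folds)
    stop_epoch = stopping_epoch(pooled_ccf_curve(val_folds))

    # final leave-one-out loop trained to the common termination error
    log.info("stage: crossval (final, termination MSE %.4f)", term_mse)
    folds = _stage(
        "crossval/final", cross_validate, samples, arch, config.training, term_mse
    )

    log.info("stage: evaluate")
    pooled_pred = np.concatenate([f.predictions for f in folds])
    pooled_gold = np.concatenate([f.targets for f in folds])
    pooled_label = np.concatenate([f.labels for f in folds])
    pooled_subject = np.concatenate(
        [np.full(len(f.predictions), str(f.test_id)) for f in folds]
    )
    roc = roc_curve(pooled_pred, pooled_label)
    opt = optimal_point(roc)
    from .metrics import ccf as _ccf

    pooled_ccf_final = _ccf(pooled_pred, pooled_gold, config.evaluation)
    corr = cluster_adjusted_correlation(pooled_pred, pooled_gold, pooled_subject)

    report = RunReport(
        software_version=__version__,
        seed=config.seed,
        n_subjects=len(cohort),
        n_slices=sum(s.shape[0] for s in cohort),
        n_voxels=len(samples),
        prevalence=samples.prevalence,
        selected_hidden2=arch.layers[2],
        architecture=list(arch.layers),
        termination_mse=term_mse,
        stopping_epoch=stop_epoch,
        pooled_auroc=roc.auroc,
        optimal_sensitivity=opt.sensitivity,
        optimal_specificity=opt.specificity,
        optimal_threshold=opt.threshold,
        pooled_ccf=pooled_ccf_final,
        pearson_r=corr.r,
        regression_slope=corr.slope,
        cluster_robust_se=corr.se,
        p_value=corr.p_value,
        folds=[
            FoldReport(
                test_id=str(f.test_id),
                n_epochs=f.trace.n_epochs,
                stopping_epoch=v.stopping_epoch,
                stopping_mse=v.stopping_mse,
                final_mse=float(f.trace.mse[-1]),
                heldout_ccf=float(f.heldout_ccf),
                heldout_auroc=None if np.isnan(f.heldout_auroc) else float(f.heldout_auroc),
            )
            for f, v in zip(folds, val_folds)
        ],
        config_echo={
            "roi_threshold": config.roi_threshold,
            "learning_rate": config.training.learning_rate,
            "momentum": config.training.momentum,
            "validation_epochs": config.validation_epochs,
            "ccf_window": config.training.ccf_window,
            "grid": [config.grid.n_slices, *config.grid.shape],
        },
    )

    if out:
        _stage(
            "report",
            _write_outputs,
            config, out, report, cohort, normalized, masks, roisets, samples,
            folds, val_folds, roc, search,
        )
    return report


def _stage(name: str, fn, *args):
    """Run one pipeline stage, aborting with a stage-named message."""
    try:
        return fn(*args)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc


def _write_outputs(
    config, out, report, cohort, normalized, masks, roisets, samples,
    folds, val_folds, roc, search,
) -> None:
    import pandas as pd

    (out / "report.json").write_text(report.model_dump_json(indent=2))
    samples.to_csv(out / "samples.csv")
    pd.DataFrame([f.model_dump() for f in report.folds]).to_csv(
        out / "folds.csv", index=False
    )
    pd.DataFrame({"fpf": roc.fpf, "tpf": roc.tpf, "threshold": roc.thresholds}).to_csv(
        out / "roc.csv", index=False
    )
    curve = pooled_ccf_curve(val_folds)
    pd.DataFrame({"epoch": np.arange(1, len(curve) + 1), "ccf": curve}).to_csv(
        out / "ccf_curve.csv", index=False
    )
    scatter = pd.DataFrame(
        {
            "predicted": np.concatenate([f.predictions for f in folds]),
            "observed": np.concatenate([f.targets for f in folds]),
            "label": np.concatenate([f.labels for f in folds]),
            "subject": np.concatenate(
                [np.full(len(f.predictions), str(f.test_id)) for f in folds]
            ),
        }
    )
    scatter.to_csv(out / "scatter.csv", index=False)
    if search is not None:
        pd.DataFrame({"hidden2": search.candidates, "auccf": search.auccf}).to_csv(
            out / "architecture_search.csv", index=False
        )

    if config.write_maps:
        # one whole-cohort model for the predicted maps
        model, _ = train(samples, report_arch(report), config.training,
                         stop_mse=report.termination_mse)
        import nibabel as nib

        def _save(stack, path, dtype):
            vol = np.transpose(stack, (1, 2, 0)).astype(dtype)
            nib.save(nib.Nifti1Image(vol, np.eye(4)), path)

        for study in cohort:
            sid = study.subject_id
            pred = predict_map(model, normalized[sid], masks[sid])
            _save(pred, out / f"{sid}_predicted.nii.gz", np.float32)
            _save(roisets[sid].lesion, out / f"{sid}_lesion_mask.nii.gz", np.uint8)
            _save(roisets[sid].normal, out / f"{sid}_normal_mask.nii.gz", np.uint8)

    if config.write_plots:
        _plot_curves(out, roc, curve)


def report_arch(report: RunReport) -> NetworkArchitecture:
    return NetworkArchitecture(tuple(report.architecture))


def _plot_curves(out: Path, roc, ccf_curve: np.ndarray) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(roc.fpf, roc.tpf, "-", lw=1.5)
    ax.plot([0, 1], [1, 0], "--", color="gray", lw=0.8)
    ax.set_xlabel("FPF (1 - specificity)")
    ax.set_ylabel("TPF (sensitivity)")
    ax.set_title(f"ROC, AUROC = {roc.auroc:.3f}")
    fig.tight_layout()
    fig.savefig(out / "roc.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.plot(np.arange(1, len(ccf_curve) + 1), ccf_curve, lw=1.2)
    ax.set_xlabel("epoch")
    ax.set_ylabel("pooled held-out CCF")
    fig.tight_layout()
    fig.savefig(out / "ccf_curve.png", dpi=120)
    plt.close(fig)


def _round2(value: float) -> float:
    """Report to 2 decimals by truncation of the true decimal value
    (floating error snapped off first): 11.325 -> 11.32, 22.5474 -> 22.54.
    This is the convention the cohort's published summary statistics follow."""
    from decimal import ROUND_DOWN, Decimal

    snapped = Decimal(str(round(float(value), 8)))
    return float(snapped.quantize(Decimal("0.01"), rounding=ROUND_DOWN))


def demographic_summary(table: CohortTable | None = None) -> dict[str, tuple[float, float]]:
    """Mean and sample SD (n-1 denominator) of each numeric demographic
    column, rounded to 2 decimals."""
    table = table or demographic_table()
    frame = table.frame
    if len(frame) < 2:
        raise ValueError("summary needs at least 2 rows (sample SD undefined)")
    out = {}
    for col in ("age", "onset_to_acute_hours", "onset_to_outcome_days"):
        series = frame[col].dropna()
        if series.empty:
            raise ValueError(f"column {col} is empty")
        out[col] = (_round2(series.mean()), _round2(series.std(ddof=1)))
    return out


def read_study(directory: str | Path, subject_id: str) -> SubjectStudy:
    """Read one subject's NIfTI channel volumes (see phantom.load_study)."""
    return phantom.load_study(directory, subject_id)


def write_study(study: SubjectStudy, directory: str | Path) -> list[Path]:
    """Write one subject's channels as float32 NIfTI plus a JSON sidecar."""
    return phantom.save_study(study, directory)


def save_report(report: RunReport, path: str | Path) -> None:
    Path(path).write_text(report.model_dump_json(indent=2))


def load_report(path: str | Path) -> RunReport:
    """Read and validate a report against the packaged schema."""
    return RunReport.model_validate(json.loads(Path(path).read_text()))
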