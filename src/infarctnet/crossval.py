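"""Patient-level leave-one-out cross-validation and model selection.

Each fold holds out every voxel of one subject, so no subject contributes
to both training and testing of the same fold.  The held-out CCF traced
over epochs is pooled across folds into one validation curve; the stopping
epoch is where that curve first comes within 10% of its plateau, and the
mean of the per-fold MSEs at that epoch is the common termination error
used to train comparable networks.  Architecture search maximizes the
normalized area under the pooled CCF curve (AUCCF) over candidate sizes of
the second hidden layer, breaking ties toward the smaller network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .metrics import auccf, ccf, EvaluationConfig, roc_curve
from .mlp import NetworkArchitecture, TrainingConfig, TrainingTrace, WeightSet, train, _forward_batch
from .preprocess import SampleSet

log = logging.getLogger(__name__)


def loocv_folds(subjects) -> list[tuple[list, object]]:
    """Leave-one-subject-out folds ``(train_ids, test_id)``; accepts a list
    of subject ids or of objects with a ``subject_id`` attribute."""
    ids = [getattr(s, "subject_id", s) for s in subjects]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate subject ids")
    if len(ids) < 2:
        raise ValueError("need at least 2 subjects for cross-validation")
    return [([t for t in ids if t != held], held) for held in ids]


@dataclass
class FoldResult:
    """Outcome of one leave-one-out fold."""

    test_id: object
    trace: TrainingTrace
    model: WeightSet
    predictions: np.ndarray   # held-out voxel predictions at the final epoch
    targets: np.ndarray
    labels: np.ndarray
    stopping_epoch: int | None = None   # 1-based, set by termination_error
    stopping_mse: float | None = None
    heldout_ccf: float = np.nan         # at the final epoch
    heldout_auroc: float = np.nan


def cross_validate(
    samples: SampleSet,
    arch: NetworkArchitecture | None = None,
    config: TrainingConfig | None = None,
    stop_mse: float | None = None,
    n_epochs: int | None = None,
) -> list[FoldResult]:
    """Run the full leave-one-subject-out loop.

    Per-fold seeds are derived deterministically from ``(config.seed, fold
    index)``.  Training stops at ``stop_mse`` (default the config's
    termination MSE) or after ``n_epochs`` fixed epochs; the per-epoch
    held-out CCF is always traced for the plateau analysis.
    """
    arch = arch or NetworkArchitecture()
    config = config or TrainingConfig()
    folds = loocv_folds(samples.subject_ids)
    eval_cfg = EvaluationConfig(window=config.ccf_window, value_range=arch.output_range)
    results = []
    for k, (train_ids, test_id) in enumerate(folds):
        fold_seed = np.random.SeedSequence([config.seed, k])
        fold_cfg = TrainingConfig(**{**config.__dict__, "seed": fold_seed})
        train_set = samples.for_subjects(train_ids)
        test_set = samples.for_subjects([test_id])
        model, trace = train(
            train_set, arch, fold_cfg,
            stop_mse=stop_mse, n_epochs=n_epochs, heldout=test_set,
        )
        preds, _, _ = _forward_batch(model, test_set.features)
        res = FoldResult(
            test_id=test_id,
            trace=trace,
            model=model,
            predictions=preds,
            targets=test_set.target,
            labels=test_set.label,
            heldout_ccf=ccf(preds, test_set.target, eval_cfg),
            heldout_auroc=roc_curve(preds, test_set.label).auroc
            if test_set.label.min() != test_set.label.max()
            else np.nan,
        )
        results.append(res)
        log.info(
            "fold %d/%d (held out %s): %d epochs, final MSE %.4f, "
            "held-out CCF %.3f, AUROC %s",
            k + 1, len(folds), test_id, trace.n_epochs, trace.mse[-1],
            res.heldout_ccf, f"{res.heldout_auroc:.3f}",
        )
    return results


def pooled_ccf_curve(folds: list[FoldResult]) -> np.ndarray:
    """Held-out CCF per epoch pooled over folds.

    Fold curves are aligned by truncation to the shortest trace; pooling is
    voxel-weighted (total matching voxels / total voxels per epoch), which
    equals the CCF of the concatenated held-out predictions at that epoch.
    """
    if not folds:
        raise ValueError("no folds")
    n_epochs = min(f.trace.n_epochs for f in folds)
    matches = np.zeros(n_epochs)
    total = 0
    for f in folds:
        if f.trace.heldout_ccf is None:
            raise ValueError(f"fold {f.test_id} has no held-out trace")
        matches += f.trace.heldout_ccf[:n_epochs] * f.trace.heldout_n
        total += f.trace.heldout_n
    return matches / total


def stopping_epoch(
    ccf_by_epoch,
    plateau_window_fraction: float = 0.1,
    tolerance_fraction: float = 0.1,
) -> int:
    """First epoch (1-based) whose CCF is within ``tolerance_fraction`` of
    the plateau, with the plateau estimated as the mean CCF over the final
    ``plateau_window_fraction`` of epochs."""
    c = np.asarray(ccf_by_epoch, dtype=float)
    if c.size < 5:
        raise ValueError("need at least 5 epochs to locate a plateau")
    if not np.all(np.isfinite(c)):
        raise ValueError("non-finite CCF values")
    n_tail = max(1, int(np.ceil(plateau_window_fraction * c.size)))
    plateau = c[-n_tail:].mean()
    threshold = (1.0 - tolerance_fraction) * plateau
    hits = np.nonzero(c >= threshold)[0]
    if hits.size == 0:  # tolerance 0 and noisy tail: fall back to the argmax
        return int(np.argmax(c)) + 1
    return int(hits[0]) + 1


def termination_error(
    folds: list[FoldResult],
    plateau_window_fraction: float = 0.1,
    tolerance_fraction: float = 0.1,
) -> float:
    """Common termination (stopping) MSE from a fixed-epoch validation run.

    The stopping epoch is located once on the pooled held-out CCF curve;
    each fold's training MSE at that epoch is read off its trace (truncated
    traces use their last epoch) and the arithmetic mean over folds is the
    stopping error.  Fold results are annotated in place.
    """
    if not folds:
        raise ValueError("no folds")
    epoch = stopping_epoch(
        pooled_ccf_curve(folds), plateau_window_fraction, tolerance_fraction
    )
    mses = []
    for f in folds:
        e = min(epoch, f.trace.n_epochs)
        f.stopping_epoch = e
        f.stopping_mse = float(f.trace.mse[e - 1])
        mses.append(f.stopping_mse)
    err = float(np.mean(mses))
    log.info("stopping epoch %d on the pooled CCF curve; termination MSE %.4f", epoch, err)
    return err


@dataclass
class ArchitectureSearchResult:
    """AUCCF of each candidate second-hidden-layer size and the selected
    size (maximum AUCCF, ties toward fewer neurons)."""

    candidates: list[int]
    auccf: list[float]
    selected: int
    folds_by_candidate: dict[int, list[FoldResult]] = field(default_factory=dict)


def architecture_search(
    samples: SampleSet,
    candidates: list[int],
    config: TrainingConfig | None = None,
    hidden1: int = 3,
    n_epochs: int = 300,
    stop_mse: float | None = None,
    output_range: tuple[float, float] = (0.0, 3.0),
) -> ArchitectureSearchResult:
    """Pick the second hidden layer size by maximizing the pooled AUCCF.

    The first hidden layer is fixed (networks with fewer than 3 first-layer
    neurons fail to train on this task, so 3 is the floor).  For every
    candidate a full leave-one-out run is performed under the common
    stopping rule and the normalized area under the pooled held-out CCF
    curve is computed; the maximum wins, ties go to the smaller network.
    """
    if not candidates:
        raise ValueError("no candidate sizes")
    if any(c < 1 for c in candidates):
        raise ValueError("candidate layer sizes must be >= 1")
    config = config or TrainingConfig()
    areas: dict[int, float] = {}
    folds_by: dict[int, list[FoldResult]] = {}
    for n2 in sorted(set(candidates)):
        arch = NetworkArchitecture((4, hidden1, n2, 1), output_range)
        folds = cross_validate(
            samples, arch, config, stop_mse=stop_mse, n_epochs=n_epochs
        )
        curve = pooled_ccf_curve(folds)
        areas[n2] = auccf(curve) if curve.size >= 2 else float(curve[0])
        folds_by[n2] = folds
        log.info("candidate n2=%d: AUCCF %.4f", n2, areas[n2])
    ordered = sorted(areas)  # ascending size, so argmax picks the smallest tie
    best = max(ordered, key=lambda n2: (areas[n2], -n2))
    return ArchitectureSearchResult(
        candidates=ordered,
        auccf=[areas[n2] for n2 in ordered],
        selected=best,
        folds_by_candidate=folds_by,
    )
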