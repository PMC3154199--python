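"""Evaluation statistics for voxel-wise outcome prediction.

Implements the windowed correct-classification fraction (CCF) and its
normalized area (AUCCF), empirical ROC curves with the trapezoidal AUROC,
the half-angle optimal operating point (intersection of the ROC with the
sensitivity = specificity anti-diagonal), confusion fractions, and a
cluster-robust (patient-level sandwich) correlation between predicted and
observed chronic maps.

Continuous predictions and gold values on the normalized-intensity scale
are compared by discretizing both into small windows (default 0.05 over
[0, 3]); CCF is the fraction of voxels whose prediction falls in the same
window as the gold value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvaluationConfig:
    """Windowed-comparison settings: window width, value range for binning,
    and the match rule (same bin, or absolute tolerance of one window)."""

    window: float = 0.05
    value_range: tuple[float, float] = (0.0, 3.0)
    match_rule: str = "bin"  # "bin" | "tolerance"

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        if not self.value_range[1] > self.value_range[0]:
            raise ValueError("value range must be increasing")
        if self.match_rule not in ("bin", "tolerance"):
            raise ValueError(f"unknown match rule {self.match_rule!r}")

    @property
    def n_bins(self) -> int:
        lo, hi = self.value_range
        return int(np.ceil((hi - lo) / self.window - 1e-12))


def discretize(values, config: EvaluationConfig | None = None) -> np.ndarray | int:
    """Bin index ``floor((v - lo) / window)``; the exact upper range bound
    belongs to the last bin and out-of-range values are clipped (logged)."""
    config = config or EvaluationConfig()
    scalar = np.isscalar(values)
    v = np.atleast_1d(np.asarray(values, dtype=float))
    lo, hi = config.value_range
    n_out = int(np.sum((v < lo) | (v > hi)))
    if n_out:
        log.warning("%d values outside %s clipped before binning", n_out, config.value_range)
        v = np.clip(v, lo, hi)
    bins = np.minimum(np.floor((v - lo) / config.window).astype(int), config.n_bins - 1)
    return int(bins[0]) if scalar else bins


def ccf(predicted, gold, config: EvaluationConfig | None = None) -> float:
    """Correct classification fraction: share of voxels whose predicted and
    gold values land in the same discretization window."""
    config = config or EvaluationConfig()
    predicted = np.asarray(predicted, dtype=float)
    gold = np.asarray(gold, dtype=float)
    if predicted.shape != gold.shape or predicted.size == 0:
        raise ValueError("predicted and gold must be equal-length and non-empty")
    if config.match_rule == "tolerance":
        return float(np.mean(np.abs(predicted - gold) <= config.window))
    return float(np.mean(discretize(predicted, config) == discretize(gold, config)))


def auccf(values, x=None) -> float:
    """Normalized trapezoidal area under a CCF curve (vs epochs or vs a
    neuron count): a constant curve of height c yields exactly c."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 points")
    x = np.arange(values.size, dtype=float) if x is None else np.asarray(x, dtype=float)
    if x.shape != values.shape:
        raise ValueError("x and values must have equal length")
    return float(np.trapezoid(values, x) / (x[-1] - x[0]))


@dataclass
class RocCurve:
    """Threshold-swept operating points from (0,0) to (1,1).

    ``thresholds[i]`` is the cutoff (score >= threshold -> predicted
    lesion) generating point ``(fpf[i], tpf[i])``; sentinels +/-inf bound
    the sweep.  ``auroc`` is the trapezoidal area, identical to the
    tie-corrected probability that a random lesion voxel outscores a random
    normal voxel.
    """

    fpf: np.ndarray
    tpf: np.ndarray
    thresholds: np.ndarray
    auroc: float

    def __post_init__(self) -> None:
        for arr in (self.fpf, self.tpf):
            if arr[0] != 0 or arr[-1] != 1 or np.any(np.diff(arr) < -1e-12):
                raise ValueError("ROC points must run monotonically from (0,0) to (1,1)")
        if not 0 <= self.auroc <= 1:
            raise ValueError("AUROC must be in [0, 1]")

    @classmethod
    def from_points(cls, fpf, tpf, thresholds=None) -> "RocCurve":
        """Build a curve from precomputed (FPF, TPF) vertices (e.g. an
        analytic binormal curve); AUROC by trapezoid."""
        fpf = np.asarray(fpf, dtype=float)
        tpf = np.asarray(tpf, dtype=float)
        if thresholds is None:
            thresholds = np.full(fpf.shape, np.nan)
        return cls(fpf, tpf, np.asarray(thresholds, dtype=float),
                   float(np.trapezoid(tpf, fpf)))


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return labels


def roc_curve(scores, labels) -> RocCurve:
    """Empirical ROC: thresholds at the midpoints between consecutive
    distinct sorted scores plus +/-inf sentinels; tied scores move between
    operating points together, so the trapezoidal area equals the
    rank-statistic (Mann-Whitney) value with ties half-weighted."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    pos = labels[order] == 1
    n_pos = int(pos.sum())
    n_neg = len(pos) - n_pos
    # indices where a new distinct score starts (group boundaries)
    distinct = np.nonzero(np.diff(s))[0]
    tp = np.concatenate([[0], np.cumsum(pos)[distinct], [n_pos]])
    fp = np.concatenate([[0], np.cumsum(~pos)[distinct], [n_neg]])
    uniq = s[np.concatenate([distinct, [len(s) - 1]])]
    mids = (uniq[:-1] + uniq[1:]) / 2
    thresholds = np.concatenate([[np.inf], mids, [-np.inf]])
    tpf = tp / n_pos
    fpf = fp / n_neg
    return RocCurve(fpf, tpf, thresholds, float(np.trapezoid(tpf, fpf)))


@dataclass
class OperatingPoint:
    sensitivity: float
    specificity: float
    threshold: float

    def __post_init__(self) -> None:
        if not (0 <= self.sensitivity <= 1 and 0 <= self.specificity <= 1):
            raise ValueError("sensitivity and specificity must be in [0, 1]")


def optimal_point(roc: RocCurve) -> OperatingPoint:
    """Half-angle operating point: intersection of the piecewise-linear ROC
    with the descending diagonal TPF = 1 - FPF, linearly interpolated
    between curve vertices.  At this point sensitivity equals specificity
    (up to the interpolation itself, which is exact on the segment)."""
    g = roc.tpf + roc.fpf - 1.0  # monotone from -1 to +1 along the curve
    idx = int(np.searchsorted(g, 0.0, side="left"))
    if idx == 0:
        s_tpf, s_fpf, thr = roc.tpf[0], roc.fpf[0], roc.thresholds[0]
    else:
        i0, i1 = idx - 1, min(idx, len(g) - 1)
        denom = g[i1] - g[i0]
        frac = 0.5 if denom == 0 else (0.0 - g[i0]) / denom
        s_tpf = roc.tpf[i0] + frac * (roc.tpf[i1] - roc.tpf[i0])
        s_fpf = roc.fpf[i0] + frac * (roc.fpf[i1] - roc.fpf[i0])
        t0, t1 = roc.thresholds[i0], roc.thresholds[i1]
        if np.isfinite(t0) and np.isfinite(t1):
            thr = t0 + frac * (t1 - t0)
        else:
            thr = t1 if np.isfinite(t1) else t0
    return OperatingPoint(float(s_tpf), float(1.0 - s_fpf), float(thr))


def confusion_fractions(scores, labels, threshold: float) -> tuple[float, float, float]:
    """(TPF, TNF, FPF) at one cutoff; score >= threshold predicts lesion."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(labels)
    pred = scores >= threshold
    pos = labels == 1
    tpf = float(np.mean(pred[pos]))
    fpf = float(np.mean(pred[~pos]))
    return tpf, 1.0 - fpf, fpf


@dataclass
class ClusterCorrelation:
    """Voxel-level linear association with patient-level (cluster-robust)
    inference: Pearson r, OLS slope of gold on predicted, the sandwich
    standard error of the slope, and a two-sided p from a t reference with
    (clusters - 1) degrees of freedom."""

    r: float
    slope: float
    se: float
    p_value: float
    n_clusters: int
    n: int

    def __post_init__(self) -> None:
        if not -1 <= self.r <= 1 + 1e-12:
            raise ValueError("r must be in [-1, 1]")
        if self.n_clusters < 2:
            raise ValueError("robust inference needs >= 2 clusters")


def cluster_adjusted_correlation(predicted, gold, clusters) -> ClusterCorrelation:
    """OLS of gold on predicted with cluster-sandwich slope variance.

    The meat of the sandwich is the sum over clusters of the outer products
    of within-cluster score vectors X_g' e_g; voxels of one patient may be
    arbitrarily correlated, patients are independent.
    """
    predicted = np.asarray(predicted, dtype=float)
    gold = np.asarray(gold, dtype=float)
    clusters = np.asarray(clusters)
    if not (len(predicted) == len(gold) == len(clusters)):
        raise ValueError("predicted, gold and clusters must have equal length")
    ids = np.unique(clusters)
    if len(ids) < 2:
        raise ValueError("need at least 2 clusters")
    X = np.column_stack([np.ones(len(predicted)), predicted])
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ gold)
    resid = gold - X @ beta
    meat = np.zeros((2, 2))
    for cid in ids:
        sel = clusters == cid
        s = X[sel].T @ resid[sel]
        meat += np.outer(s, s)
    cov = xtx_inv @ meat @ xtx_inv
    se = float(np.sqrt(cov[1, 1]))
    slope = float(beta[1])
    dof = len(ids) - 1
    if se == 0:
        p = 0.0 if slope != 0 else 1.0
    else:
        p = float(2 * stats.t.sf(abs(slope) / se, dof))
    r = float(np.clip(np.corrcoef(predicted, gold)[0, 1], -1.0, 1.0))
    return ClusterCorrelation(r, slope, se, p, len(ids), len(predicted))
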