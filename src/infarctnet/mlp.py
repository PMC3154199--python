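"""From-scratch feed-forward multilayer perceptron with batch back-propagation.

The network maps a 4-vector of normalized acute MRI intensities to one
continuous output on the normalized chronic-T2 scale.  Hidden units use the
bipolar sigmoid, realized as tanh; the output unit is a tanh affinely
rescaled onto the configured output range (default [0, 3], centred on the
brain-mean value 1.5).  Training is plain batch gradient descent on the
mean squared error with an optional momentum term: the weight changes of
all training cases are accumulated and applied in a single update per
epoch.  No mini-batches, adaptive rates or regularization.

The cost is the *mean* (not sum) of squared residuals, so the meaning of
the learning rate does not depend on the sample count.  Reported per-epoch
MSE is always the pre-update value, and the termination check is applied to
it before the update, so a converged network is never perturbed further.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .metrics import EvaluationConfig, ccf
from .phantom import CHANNELS, SubjectStudy
from .preprocess import SampleSet

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetworkArchitecture:
    """Layer sizes input:hidden1:hidden2:output with a bias unit feeding
    every non-input layer; the default 4:3:3:1 has (4+1)*3 + (3+1)*3 +
    (3+1)*1 = 31 free parameters."""

    layers: tuple[int, ...] = (4, 3, 3, 1)
    output_range: tuple[float, float] = (0.0, 3.0)

    def __post_init__(self) -> None:
        if len(self.layers) < 2 or any(n < 1 for n in self.layers):
            raise ValueError(f"invalid layer sizes {self.layers}")
        if self.layers[-1] != 1:
            raise ValueError("network must have a single output unit")
        if not self.output_range[1] > self.output_range[0]:
            raise ValueError("output range must be increasing")

    @property
    def n_parameters(self) -> int:
        return sum(
            (fan_in + 1) * fan_out
            for fan_in, fan_out in zip(self.layers[:-1], self.layers[1:])
        )


class WeightSet:
    """Layered weight matrices; ``matrices[i]`` has shape
    ``(fan_out, fan_in + 1)`` with the bias in the last column."""

    def __init__(self, arch: NetworkArchitecture, matrices: list[np.ndarray]):
        expected = [
            (o, i + 1) for i, o in zip(arch.layers[:-1], arch.layers[1:])
        ]
        got = [m.shape for m in matrices]
        if got != expected:
            raise ValueError(f"weight shapes {got} do not match architecture {expected}")
        self.arch = arch
        self.matrices = [np.asarray(m, dtype=float) for m in matrices]

    @property
    def n_parameters(self) -> int:
        return sum(m.size for m in self.matrices)

    def zeros_like(self) -> list[np.ndarray]:
        return [np.zeros_like(m) for m in self.matrices]

    def copy(self) -> "WeightSet":
        return WeightSet(self.arch, [m.copy() for m in self.matrices])

    def to_json(self, path: str | Path, config: "TrainingConfig | None" = None) -> None:
        doc = {
            "layers": list(self.arch.layers),
            "output_range": list(self.arch.output_range),
            "weights": [m.tolist() for m in self.matrices],
        }
        if config is not None:
            doc["config"] = config.__dict__
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "WeightSet":
        doc = json.loads(Path(path).read_text())
        arch = NetworkArchitecture(tuple(doc["layers"]), tuple(doc["output_range"]))
        return cls(arch, [np.asarray(m) for m in doc["weights"]])


@dataclass
class TrainingConfig:
    """Batch-training hyperparameters.

    Defaults follow the operating point of the voxel-outcome study:
    learning rate 0.01, momentum 0, termination MSE 0.06 on the 0-3
    normalized-intensity scale, and a 0.05 discretization window for the
    correct-classification fraction.
    """

    learning_rate: float = 0.01
    momentum: float = 0.0
    termination_mse: float = 0.06
    max_epochs: int = 1000
    init_scale: float = 0.5
    seed: int = 0
    ccf_window: float = 0.05

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning rate must be >= 0")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        if self.termination_mse is not None and self.termination_mse <= 0:
            raise ValueError("termination MSE must be positive")


@dataclass
class TrainingTrace:
    """Per-epoch history: pre-update MSE, training CCF and (when a held-out
    set is supplied) held-out CCF.  ``converged`` is False when the epoch
    budget ran out before the termination MSE was reached."""

    mse: np.ndarray
    ccf: np.ndarray
    heldout_ccf: np.ndarray | None = None
    heldout_n: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        if len(self.mse) != len(self.ccf):
            raise ValueError("trace fields must have equal length")
        if np.any(self.mse < 0):
            raise ValueError("MSE must be >= 0")

    @property
    def n_epochs(self) -> int:
        return len(self.mse)

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        cols = {"epoch": np.arange(1, self.n_epochs + 1), "mse": self.mse, "ccf": self.ccf}
        if self.heldout_ccf is not None:
            cols["heldout_ccf"] = self.heldout_ccf
        pd.DataFrame(cols).to_csv(path, index=False)


def init_weights(arch: NetworkArchitecture, seed: int | np.random.SeedSequence, scale: float = 0.5) -> WeightSet:
    """Uniform [-scale, scale] initialization, biases included, seeded."""
    if scale <= 0:
        raise ValueError("init scale must be positive")
    rng = np.random.default_rng(seed)
    mats = [
        rng.uniform(-scale, scale, size=(fan_out, fan_in + 1))
        for fan_in, fan_out in zip(arch.layers[:-1], arch.layers[1:])
    ]
    return WeightSet(arch, mats)


def _forward_batch(weights: WeightSet, X: np.ndarray) -> tuple[np.ndarray, list[np.ndarray], list[np.ndarray]]:
    """Vectorized forward pass; returns (outputs, activations, pre-activations)."""
    lo, hi = weights.arch.output_range
    a = X
    activations = [a]
    zs = []
    last = len(weights.matrices) - 1
    for i, w in enumerate(weights.matrices):
        z = a @ w[:, :-1].T + w[:, -1]
        zs.append(z)
        a = np.tanh(z) if i < last else (hi - lo) / 2 * (np.tanh(z) + 1) + lo
        activations.append(a)
    return activations[-1][:, 0], activations, zs


def forward(weights: WeightSet, x: np.ndarray) -> tuple[float | np.ndarray, list[np.ndarray]]:
    """Network output for one feature vector (or a batch of them).

    Hidden activations are tanh; the output unit is affinely mapped onto
    the output range, so predictions lie strictly inside it.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[1] != weights.arch.layers[0]:
        raise ValueError(
            f"expected {weights.arch.layers[0]} features, got {X.shape[1]}"
        )
    y, activations, _ = _forward_batch(weights, X)
    if single:
        return float(y[0]), [a[0] for a in activations]
    return y, activations


def _gradients(weights: WeightSet, X: np.ndarray, t: np.ndarray) -> tuple[list[np.ndarray], float]:
    """Backprop gradients of the mean squared error; returns (grads, mse)."""
    lo, hi = weights.arch.output_range
    y, activations, zs = _forward_batch(weights, X)
    n = len(t)
    resid = y - t
    mse = float(np.mean(resid**2))
    grads: list[np.ndarray | None] = [None] * len(weights.matrices)
    # output unit: d y / d z = (hi-lo)/2 * (1 - tanh(z)^2)
    delta = (2.0 / n) * resid[:, None] * ((hi - lo) / 2) * (1 - np.tanh(zs[-1]) ** 2)
    for i in range(len(weights.matrices) - 1, -1, -1):
        a = activations[i]
        grads[i] = np.concatenate(
            [delta.T @ a, delta.sum(axis=0)[:, None]], axis=1
        )
        if i > 0:
            delta = (delta @ weights.matrices[i][:, :-1]) * (1 - np.tanh(zs[i - 1]) ** 2)
    return grads, mse  # type: ignore[return-value]


def batch_epoch(
    weights: WeightSet,
    X: np.ndarray,
    targets: np.ndarray,
    config: TrainingConfig,
    previous_update: list[np.ndarray] | None = None,
) -> tuple[WeightSet, float, list[np.ndarray]]:
    """One batch epoch: accumulate the MSE gradient over *all* samples, then
    apply a single update ``-lr * grad + momentum * previous_update``.

    Returns the post-update weights, the PRE-update epoch MSE, and the
    update (for the next epoch's momentum term).
    """
    X = np.asarray(X, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if len(X) == 0:
        raise ValueError("no training samples")
    if previous_update is None:
        previous_update = weights.zeros_like()
    grads, mse = _gradients(weights, X, targets)
    update = [
        -config.learning_rate * g + config.momentum * p
        for g, p in zip(grads, previous_update)
    ]
    new = WeightSet(weights.arch, [w + u for w, u in zip(weights.matrices, update)])
    return new, mse, update


def train(
    samples: SampleSet | tuple[np.ndarray, np.ndarray],
    arch: NetworkArchitecture | None = None,
    config: TrainingConfig | None = None,
    stop_mse: float | None = None,
    n_epochs: int | None = None,
    heldout: SampleSet | tuple[np.ndarray, np.ndarray] | None = None,
    initial: WeightSet | None = None,
) -> tuple[WeightSet, TrainingTrace]:
    """Batch-train a network on per-voxel samples.

    Stopping: after recording each epoch's pre-update MSE, stop when it is
    at or below ``stop_mse`` (default ``config.termination_mse``); pass
    ``n_epochs`` (and ``stop_mse=None``) to train for a fixed epoch count
    instead.  The trace records MSE and training CCF for every epoch, plus
    held-out CCF when ``heldout`` is given.  Fully deterministic given
    ``config.seed``.
    """
    arch = arch or NetworkArchitecture()
    config = config or TrainingConfig()
    if stop_mse is None and n_epochs is None:
        stop_mse = config.termination_mse
    max_epochs = n_epochs if n_epochs is not None else config.max_epochs

    X, t = _as_xy(samples)
    if len(X) < 2:
        raise ValueError("need at least 2 training samples")
    Xh, th = _as_xy(heldout) if heldout is not None else (None, None)

    eval_cfg = EvaluationConfig(window=config.ccf_window, value_range=arch.output_range)
    weights = initial.copy() if initial is not None else init_weights(arch, config.seed, config.init_scale)
    prev = weights.zeros_like()

    mses, ccfs, hccfs = [], [], []
    converged = False
    for _ in range(max_epochs):
        y, _, _ = _forward_batch(weights, X)
        mse = float(np.mean((y - t) ** 2))
        mses.append(mse)
        ccfs.append(ccf(y, t, eval_cfg))
        if Xh is not None:
            yh, _, _ = _forward_batch(weights, Xh)
            hccfs.append(ccf(yh, th, eval_cfg))
        if stop_mse is not None and mse <= stop_mse:
            converged = True
            break
        grads, _ = _gradients(weights, X, t)
        update = [
            -config.learning_rate * g + config.momentum * p
            for g, p in zip(grads, prev)
        ]
        weights = WeightSet(
            weights.arch, [w + u for w, u in zip(weights.matrices, update)]
        )
        prev = update
    else:
        converged = stop_mse is None
        if not converged:
            log.warning(
                "training did not reach MSE %.4g within %d epochs (final %.4g)",
                stop_mse, max_epochs, mses[-1],
            )
    trace = TrainingTrace(
        np.asarray(mses),
        np.asarray(ccfs),
        np.asarray(hccfs) if Xh is not None else None,
        heldout_n=0 if Xh is None else len(Xh),
        converged=converged,
    )
    return weights, trace


def _as_xy(samples) -> tuple[np.ndarray, np.ndarray]:
    if samples is None:
        return None, None
    if isinstance(samples, SampleSet):
        return samples.features, samples.target
    X, t = samples
    return np.asarray(X, dtype=float), np.asarray(t, dtype=float)


def predict_map(
    model: WeightSet,
    study: SubjectStudy,
    mask: np.ndarray,
    mean_tolerance: float = 1e-6,
) -> np.ndarray:
    """Voxel-wise predicted chronic-T2 stack of a *normalized* study.

    Every in-mask voxel is pushed through the network; outside-mask voxels
    are 0.  Raises if any acute channel's in-mask mean is not 1 (the study
    must be normalized first).
    """
    for ch in CHANNELS:
        m = study.images[ch][mask].mean()
        if abs(m - 1.0) > max(mean_tolerance, 1e-6):
            raise ValueError(
                f"study {study.subject_id} not normalized: channel {ch} "
                f"in-mask mean {m:.6f}"
            )
    sl, rows, cols = np.nonzero(mask)
    X = np.column_stack([study.images[ch][sl, rows, cols] for ch in CHANNELS])
    y, _, _ = _forward_batch(model, X)
    out = np.zeros(study.shape)
    out[sl, rows, cols] = y
    return out
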