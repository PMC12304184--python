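"""Feed-forward neural-network yield baseline.

The protocol: nine seasonal meteorology features (season means of tmax, tmin,
precipitation, solar radiation, wind, relative humidity and three soil
wetness layers), z-score standardisation, a 70/15/15 random
train/validation/test split, and a 9–10–1 network — one hidden layer of ten
sigmoidal (tanh) units and a linear output — trained with a resilient
("rapid") propagation scheme: full-batch gradients with per-weight adaptive
step sizes driven only by gradient signs (Rprop⁻).  Training early-stops on
validation MSE and restores the best-epoch weights, so the returned history
supports a performance plot.

Everything is seeded: the same spec, seed and data give identical weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import (
    DegenerateDataError,
    DivergenceError,
    InvalidConfigError,
    InvalidInputError,
)
from .types import FEATURE_NAMES, FeatureVector, SplitAssignment

__all__ = [
    "MLPSpec",
    "FeatureScaler",
    "standardize_features",
    "split_dataset",
    "train_mlp",
    "predict_yield",
    "MLPModel",
    "ANN_MODEL_NAME",
]

ANN_MODEL_NAME = "ann"


@dataclass(frozen=True)
class MLPSpec:
    """Architecture and training settings of the yield network."""

    n_input: int = 9
    n_hidden: int = 10
    n_output: int = 1
    n_hidden_layers: int = 1
    seed: int = 0
    max_epochs: int = 2000
    tolerance: float = 1e-12
    # Rprop's validation trace is non-monotone epoch to epoch, so the
    # stall counter needs a long horizon; the best epoch is restored anyway.
    patience: int = 100
    scaling: str = "zscore"  # or "minmax"

    def __post_init__(self) -> None:
        if min(self.n_input, self.n_hidden, self.n_output, self.n_hidden_layers) < 1:
            raise InvalidConfigError("layer sizes and depth must be positive")
        if self.scaling not in ("zscore", "minmax"):
            raise InvalidConfigError(f"unknown scaling {self.scaling!r}")


@dataclass(frozen=True)
class FeatureScaler:
    """Column-wise affine scaling fitted on training rows: (x − shift)/scale."""

    shift: tuple[float, ...]
    scale: tuple[float, ...]

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - np.asarray(self.shift)) / np.asarray(
            self.scale
        )

    def transform_rows(self, rows: Sequence[FeatureVector]) -> list[FeatureVector]:
        out = []
        for r in rows:
            z = self.transform(np.asarray(r.features))
            out.append(
                FeatureVector(r.region_id, r.year, tuple(z.tolist()), r.target)
            )
        return out


def features_matrix(rows: Sequence[FeatureVector]) -> np.ndarray:
    return np.asarray([r.features for r in rows], dtype=float)


def targets_vector(rows: Sequence[FeatureVector]) -> np.ndarray:
    if any(r.target is None for r in rows):
        raise InvalidInputError("row without a target yield")
    return np.asarray([r.target for r in rows], dtype=float)


def standardize_features(
    rows: Sequence[FeatureVector], scaling: str = "zscore"
) -> tuple[list[FeatureVector], FeatureScaler]:
    """Fit a column scaler on ``rows`` and return the transformed rows.

    ``zscore`` maps each column to mean 0, sd 1; ``minmax`` to [0, 1].  The
    returned scaler is reused verbatim on validation/test rows.  A constant
    column is unlearnable under either scaling and is rejected by name.
    """
    if len(rows) < 2:
        raise InvalidInputError("need >= 2 rows to standardize")
    x = features_matrix(rows)
    if scaling == "zscore":
        shift = x.mean(axis=0)
        scale = x.std(axis=0, ddof=0)
    elif scaling == "minmax":
        shift = x.min(axis=0)
        scale = x.max(axis=0) - x.min(axis=0)
    else:
        raise InvalidConfigError(f"unknown scaling {scaling!r}")
    bad = np.flatnonzero(scale == 0)
    if bad.size:
        names = ", ".join(FEATURE_NAMES[i] for i in bad)
        raise DegenerateDataError(f"constant feature column(s): {names}")
    scaler = FeatureScaler(tuple(shift.tolist()), tuple(scale.tolist()))
    return scaler.transform_rows(rows), scaler


def split_dataset(
    n: int, seed: int, fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
) -> SplitAssignment:
    """Seeded random train/validation/test partition of ``range(n)``.

    Subset sizes honour the fractions by largest-remainder rounding (ties
    broken in train → validation → test order), so n = 100 gives exactly
    (70, 15, 15) and n = 10 gives (7, 2, 1).
    """
    if n < 7:
        raise InvalidInputError(f"n={n} too small to split 70/15/15 (need >= 7)")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise InvalidConfigError("split fractions must sum to 1")
    quotas = [f * n for f in fractions]
    sizes = [int(q) for q in quotas]
    remainders = [q - s for q, s in zip(quotas, sizes)]
    for _ in range(n - sum(sizes)):
        i = int(np.argmax(remainders))
        sizes[i] += 1
        remainders[i] = -1.0
    perm = np.random.default_rng(seed).permutation(n)
    train = tuple(sorted(int(i) for i in perm[: sizes[0]]))
    val = tuple(sorted(int(i) for i in perm[sizes[0] : sizes[0] + sizes[1]]))
    test = tuple(sorted(int(i) for i in perm[sizes[0] + sizes[1] :]))
    return SplitAssignment(train=train, validation=val, test=test, seed=seed)


@dataclass
class MLPModel:
    """A fitted multilayer perceptron (tanh hidden layers, linear output).

    ``weights``/``biases`` hold one entry per layer.  Targets are scaled to
    zero mean, unit variance internally during training; ``y_shift``/``y_scale``
    undo that at prediction time.  ``history`` is a list of
    (epoch, train_mse, validation_mse) in original target units.
    """

    spec: MLPSpec
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    y_shift: float = 0.0
    y_scale: float = 1.0
    history: list[tuple[int, float, float]] = field(default_factory=list)
    best_epoch: int = 0

    def forward(self, x: np.ndarray) -> np.ndarray:
        a = np.asarray(x, dtype=float)
        if a.ndim == 1:
            a = a[None, :]
        if a.shape[1] != self.spec.n_input:
            raise InvalidInputError(
                f"expected {self.spec.n_input} features, got {a.shape[1]}"
            )
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.tanh(a @ w + b)
        out = a @ self.weights[-1] + self.biases[-1]
        return out[:, 0] * self.y_scale + self.y_shift


def _init_layers(spec: MLPSpec, rng: np.random.Generator):
    sizes = [spec.n_input] + [spec.n_hidden] * spec.n_hidden_layers + [spec.n_output]
    weights, biases = [], []
    for layer, (fan_in, fan_out) in enumerate(zip(sizes[:-1], sizes[1:])):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        w = rng.uniform(-limit, limit, size=(fan_in, fan_out))
        if layer == len(sizes) - 2:
            w *= 0.01  # start near the constant (mean) predictor
        weights.append(w)
        biases.append(np.zeros(fan_out))
    return weights, biases


def _mse_and_grads(weights, biases, x, y):
    """Full-batch MSE and its gradients by backprop (tanh hidden, linear out)."""
    acts = [x]
    a = x
    for w, b in zip(weights[:-1], biases[:-1]):
        a = np.tanh(a @ w + b)
        acts.append(a)
    out = acts[-1] @ weights[-1] + biases[-1]
    err = out[:, 0] - y
    n = y.size
    mse = float(np.mean(err**2))
    delta = (2.0 / n) * err[:, None]  # d MSE / d out
    gw, gb = [None] * len(weights), [None] * len(biases)
    gw[-1] = acts[-1].T @ delta
    gb[-1] = delta.sum(axis=0)
    for layer in range(len(weights) - 2, -1, -1):
        delta = (delta @ weights[layer + 1].T) * (1.0 - acts[layer + 1] ** 2)
        gw[layer] = acts[layer].T @ delta
        gb[layer] = delta.sum(axis=0)
    return mse, gw, gb


def train_mlp(
    spec: MLPSpec,
    train_rows: Sequence[FeatureVector],
    validation_rows: Sequence[FeatureVector],
) -> MLPModel:
    """Train the network on standardized rows, early-stopping on validation MSE.

    iRprop⁺ update: each weight keeps its own step size, multiplied by 1.2
    when the gradient keeps its sign and by 0.5 when it flips; the weight
    moves by −sign(gradient)·step, and a sign flip that worsened the training
    loss is undone (backtracking).  The best-validation-epoch weights are
    restored before returning.
    """
    if not train_rows:
        raise InvalidInputError("empty training set")
    x_tr, y_tr = features_matrix(train_rows), targets_vector(train_rows)
    x_va, y_va = features_matrix(validation_rows), targets_vector(validation_rows)

    y_shift = float(y_tr.mean())
    y_scale = float(y_tr.std(ddof=0)) or 1.0
    z_tr = (y_tr - y_shift) / y_scale
    z_va = (y_va - y_shift) / y_scale
    unit2 = y_scale**2  # standardized MSE -> original units

    rng = np.random.default_rng(spec.seed)
    weights, biases = _init_layers(spec, rng)
    steps_w = [np.full_like(w, 0.01) for w in weights]
    steps_b = [np.full_like(b, 0.01) for b in biases]
    prev_gw = [np.zeros_like(w) for w in weights]
    prev_gb = [np.zeros_like(b) for b in biases]
    prev_dw = [np.zeros_like(w) for w in weights]
    prev_db = [np.zeros_like(b) for b in biases]

    eta_plus, eta_minus, step_min, step_max = 1.2, 0.5, 1e-9, 1.0
    best_val = np.inf
    best = None
    best_epoch = 0
    stall = 0
    history: list[tuple[int, float, float]] = []
    prev_train = np.inf

    for epoch in range(1, spec.max_epochs + 1):
        train_mse, gw, gb = _mse_and_grads(weights, biases, x_tr, z_tr)
        if not np.isfinite(train_mse):
            raise DivergenceError(f"non-finite training loss at epoch {epoch}")
        val_mse = float(
            np.mean(((_forward_std(weights, biases, x_va)) - z_va) ** 2)
        ) if len(z_va) else train_mse
        history.append((epoch, train_mse * unit2, val_mse * unit2))

        if val_mse < best_val - 1e-15:
            best_val = val_mse
            best = ([w.copy() for w in weights], [b.copy() for b in biases])
            best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall > spec.patience:
                break
        if abs(prev_train - train_mse) < spec.tolerance:
            break

        worsened = train_mse > prev_train
        for layer in range(len(weights)):
            for g, pg, st, param, pd in (
                (gw[layer], prev_gw[layer], steps_w[layer], weights[layer], prev_dw[layer]),
                (gb[layer], prev_gb[layer], steps_b[layer], biases[layer], prev_db[layer]),
            ):
                sign = g * pg
                inc, dec = sign > 0, sign < 0
                st *= np.where(inc, eta_plus, np.where(dec, eta_minus, 1.0))
                np.clip(st, step_min, step_max, out=st)
                delta = np.where(dec, 0.0, -np.sign(g) * st)
                if worsened:  # undo last move where the gradient flipped
                    delta = np.where(dec, -pd, delta)
                param += delta
                pd[:] = delta
                pg[:] = np.where(dec, 0.0, g)
        prev_train = train_mse

    if best is not None:
        weights, biases = best
    return MLPModel(
        spec=spec,
        weights=weights,
        biases=biases,
        y_shift=y_shift,
        y_scale=y_scale,
        history=history,
        best_epoch=best_epoch,
    )


def _forward_std(weights, biases, x):
    a = x
    for w, b in zip(weights[:-1], biases[:-1]):
        a = np.tanh(a @ w + b)
    return (a @ weights[-1] + biases[-1])[:, 0]


def predict_yield(model: MLPModel, rows: Sequence[FeatureVector]) -> np.ndarray:
    """Deterministic forward pass on standardized rows, in ton ha⁻¹."""
    return model.forward(features_matrix(rows))
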