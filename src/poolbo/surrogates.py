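"""Surrogate structure-score models.

Each surrogate is a regressor trained on (fingerprint, objective) pairs from
the molecules evaluated so far and applied to the whole pool to produce a
predicted mean — and, when an uncertainty method is configured, a predictive
variance — per candidate.  Two architectures are provided:

``rf``
    scikit-learn random forest (100 trees, depth cap 8); uncertainty is the
    variance of the individual trees' predictions.
``nn``
    A from-scratch NumPy multilayer perceptron: two hidden layers of 100
    ReLU units with dropout p=0.2 after each, trained with Adam (lr 0.01),
    mean-squared-error loss with L2 penalty 0.01, batch size 4096, at most
    50 epochs with early stopping (patience 5) on a seeded 80/20 split.
    Uncertainty via Monte-Carlo dropout (10 stochastic forward passes) or a
    mean-variance-estimation (MVE) head trained with the Gaussian
    negative-log-likelihood.

Targets are used in the maximization convention throughout; the NN
standardizes them internally (zero mean, unit variance on the current
training set) to stabilize the fixed learning rate, and un-standardizes its
predictions.  The RF trains on raw targets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Protocol

import joblib
import numpy as np
from sklearn.ensemble import RandomForestRegressor

ARCHITECTURES = ("rf", "nn", "mpn")
UNCERTAINTY_METHODS = ("none", "ensemble-variance", "mc-dropout", "mve")


class SurrogateError(ValueError):
    """Raised for invalid surrogate configuration or training input."""


@dataclass(frozen=True)
class TrainingSet:
    """The acquired dataset: fingerprints and their observed objectives.

    Only successfully evaluated molecules belong here — candidates whose
    evaluation returned MISSING are excluded by the explorer before this
    object is built.
    """

    inputs: np.ndarray  # (n, 2048) fingerprints
    targets: np.ndarray  # (n,) objective values, maximization convention

    def __post_init__(self) -> None:
        if self.inputs.ndim != 2 or self.targets.ndim != 1:
            raise SurrogateError("inputs must be 2-D and targets 1-D")
        if len(self.inputs) != len(self.targets) or len(self.targets) < 1:
            raise SurrogateError("inputs/targets length mismatch or empty")
        if not np.all(np.isfinite(self.targets)):
            raise SurrogateError("targets must be finite (MISSING rows excluded)")

    def __len__(self) -> int:
        return len(self.targets)


@dataclass(frozen=True)
class Prediction:
    """Full-pool predictions: one mean per candidate, variance optional."""

    mean: np.ndarray
    variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.variance is not None:
            if self.variance.shape != self.mean.shape:
                raise SurrogateError("variance/mean shape mismatch")
            if np.any(self.variance < 0):
                raise SurrogateError("negative predictive variance")
        if not np.all(np.isfinite(self.mean)):
            raise SurrogateError("non-finite predictive mean")


_DEFAULT_UNCERTAINTY = {"rf": "ensemble-variance", "nn": "mc-dropout", "mpn": "mve"}
_ALLOWED_UNCERTAINTY = {
    "rf": {"none", "ensemble-variance"},
    "nn": {"none", "mc-dropout", "mve"},
    "mpn": {"none", "mve"},
}


@dataclass(frozen=True)
class SurrogateSpec:
    """Architecture, hyperparameters and uncertainty method for a surrogate.

    ``retrain_mode`` selects between full retraining from scratch on all
    acquired data each iteration (default; empirically the more reliable
    choice) and online fine-tuning on only the newly acquired batch.
    """

    architecture: str = "rf"
    uncertainty_method: str | None = None  # None -> architecture default
    retrain_mode: str = "full"
    # RF
    rf_trees: int = 100
    rf_depth: int | None = 8
    # NN
    nn_hidden: tuple[int, ...] = (100, 100)
    nn_dropout: float = 0.2
    nn_lr: float = 0.01
    nn_l2: float = 0.01
    nn_batch_size: int = 4096
    nn_epochs: int = 50
    nn_patience: int = 5
    nn_mc_passes: int = 10
    nn_val_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise SurrogateError(f"unknown architecture {self.architecture!r}")
        if self.retrain_mode not in ("full", "online"):
            raise SurrogateError(f"unknown retrain mode {self.retrain_mode!r}")
        u = self.uncertainty_method
        if u is not None and u not in _ALLOWED_UNCERTAINTY[self.architecture]:
            raise SurrogateError(
                f"uncertainty {u!r} incompatible with {self.architecture!r}"
            )

    @property
    def resolved_uncertainty(self) -> str:
        if self.uncertainty_method is None:
            return _DEFAULT_UNCERTAINTY[self.architecture]
        return self.uncertainty_method


class SurrogateModel(Protocol):
    """Interface every surrogate implements."""

    spec: SurrogateSpec

    def predict(self, fingerprints: np.ndarray) -> Prediction: ...


# ---------------------------------------------------------------------------
# Mean-variance estimation loss (Gaussian negative log-likelihood)
# ---------------------------------------------------------------------------


def mve_loss(mean, variance, target):
    """Gaussian negative log-likelihood for a mean-variance head.

    ``L = 1/2 log(2 pi variance) + (target - mean)^2 / (2 variance)``,
    averaged over examples when arrays are passed.  Variance must be
    strictly positive (the network head enforces this with a softplus).
    """
    mean = np.asarray(mean, dtype=float)
    variance = np.asarray(variance, dtype=float)
    target = np.asarray(target, dtype=float)
    if np.any(variance <= 0):
        raise SurrogateError("mve_loss requires variance > 0")
    per_example = 0.5 * np.log(2.0 * math.pi * variance) + (target - mean) ** 2 / (
        2.0 * variance
    )
    return float(np.mean(per_example))


# ---------------------------------------------------------------------------
# Random forest surrogate
# ---------------------------------------------------------------------------


class RandomForestSurrogate:
    """Random forest on fingerprints; uncertainty = across-tree variance."""

    def __init__(self, spec: SurrogateSpec, seed: int = 0):
        if spec.architecture != "rf":
            raise SurrogateError("spec is not an RF spec")
        self.spec = spec
        self.seed = int(seed)
        self._forest: RandomForestRegressor | None = None

    def fit(self, data: TrainingSet) -> "RandomForestSurrogate":
        self._forest = RandomForestRegressor(
            n_estimators=self.spec.rf_trees,
            max_depth=self.spec.rf_depth,
            random_state=self.seed % (2**31),
            n_jobs=1,
        )
        self._forest.fit(data.inputs, data.targets)
        return self

    def predict(self, fingerprints: np.ndarray) -> Prediction:
        if self._forest is None:
            raise SurrogateError("model not trained")
        if self.spec.resolved_uncertainty == "ensemble-variance":
            per_tree = np.stack(
                [t.predict(fingerprints) for t in self._forest.estimators_]
            )
            return Prediction(per_tree.mean(axis=0), per_tree.var(axis=0))
        return Prediction(self._forest.predict(fingerprints))


# ---------------------------------------------------------------------------
# NumPy multilayer perceptron with dropout, Adam, and an optional MVE head
# ---------------------------------------------------------------------------


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


class NeuralNetSurrogate:
    """Feedforward network on fingerprints, written in NumPy.

    Inference with dropout disabled is deterministic.  With
    ``uncertainty_method="mc-dropout"`` prediction runs ``nn_mc_passes``
    stochastic forward passes with dropout active and reports their mean and
    variance; with ``"mve"`` the output layer has two units, (mean, raw
    variance), the raw variance is mapped through a softplus, and training
    minimizes the Gaussian negative log-likelihood.
    """

    _VAR_FLOOR = 1e-6  # keeps the NLL finite at the softplus tail

    def __init__(self, spec: SurrogateSpec, seed: int = 0):
        if spec.architecture != "nn":
            raise SurrogateError("spec is not an NN spec")
        self.spec = spec
        self.seed = int(seed)
        self._rng = np.random.default_rng(seed)
        self._weights: list[np.ndarray] | None = None
        self._biases: list[np.ndarray] | None = None
        self._y_mean = 0.0
        self._y_std = 1.0
        self._adam: _Adam | None = None

    # -- architecture -------------------------------------------------------
    @property
    def _n_outputs(self) -> int:
        return 2 if self.spec.resolved_uncertainty == "mve" else 1

    def _init_params(self, n_features: int) -> None:
        sizes = (n_features, *self.spec.nn_hidden, self._n_outputs)
        self._weights, self._biases = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            # He initialization for the ReLU stack
            scale = math.sqrt(2.0 / fan_in)
            self._weights.append(
                self._rng.normal(0.0, scale, size=(fan_in, fan_out))
            )
            self._biases.append(np.zeros(fan_out))
        self._adam = _Adam(self._params(), self.spec.nn_lr)

    def _params(self) -> list[np.ndarray]:
        assert self._weights is not None and self._biases is not None
        return [*self._weights, *self._biases]

    # -- forward / backward -------------------------------------------------
    def _forward(
        self, x: np.ndarray, dropout_rng: np.random.Generator | None
    ) -> tuple[np.ndarray, list]:
        """Forward pass; dropout active iff ``dropout_rng`` given (inverted
        dropout, so eval needs no rescaling).  Returns output and the cache
        for backprop."""
        assert self._weights is not None and self._biases is not None
        p = self.spec.nn_dropout
        cache = []
        h = x.astype(float)
        n_layers = len(self._weights)
        for i, (w, b) in enumerate(zip(self._weights, self._biases)):
            z = h @ w + b
            if i < n_layers - 1:
                a = np.maximum(z, 0.0)
                if dropout_rng is not None and p > 0:
                    keep = dropout_rng.random(a.shape) >= p
                    a = a * keep / (1.0 - p)
                else:
                    keep = None
                cache.append((h, z, keep))
                h = a
            else:
                cache.append((h, z, None))
                h = z
        return h, cache

    def _backward(
        self, cache: list, d_out: np.ndarray
    ) -> tuple[list[np.ndarray], list[np.ndarray]]:
        assert self._weights is not None
        p = self.spec.nn_dropout
        gw = [np.zeros_like(w) for w in self._weights]
        gb = [np.zeros_like(b) for b in self._biases]
        delta = d_out
        for i in range(len(self._weights) - 1, -1, -1):
            h_in, z, keep = cache[i]
            gw[i] = h_in.T @ delta + self.spec.nn_l2 * self._weights[i]
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self._weights[i].T
                if keep is not None:
                    delta = delta * keep / (1.0 - p)
                delta = delta * (cache[i - 1][1] > 0)
        return gw, gb

    def _loss_grad(
        self, out: np.ndarray, y: np.ndarray
    ) -> tuple[float, np.ndarray]:
        """Loss and d(loss)/d(output) for one batch (standardized y)."""
        n = len(y)
        if self._n_outputs == 1:
            resid = out[:, 0] - y
            loss = float(np.mean(resid**2))
            d = np.zeros_like(out)
            d[:, 0] = 2.0 * resid / n
            return loss, d
        mu, raw = out[:, 0], out[:, 1]
        var = _softplus(raw) + self._VAR_FLOOR
        resid = mu - y
        loss = float(np.mean(0.5 * np.log(2 * math.pi * var) + resid**2 / (2 * var)))
        d = np.zeros_like(out)
        d[:, 0] = resid / var / n
        dvar = (0.5 / var - resid**2 / (2 * var**2)) / n
        d[:, 1] = dvar * (1.0 / (1.0 + np.exp(-raw)))  # softplus'
        return loss, d

    # -- training -----------------------------------------------------------
    def fit(self, data: TrainingSet, reinitialize: bool = True) -> "NeuralNetSurrogate":
        x, y_raw = data.inputs.astype(float), data.targets.astype(float)
        if reinitialize or self._weights is None:
            self._y_mean = float(y_raw.mean())
            self._y_std = float(y_raw.std())
            if self._y_std == 0.0:
                self._y_std = 1.0
            self._init_params(x.shape[1])
        y = (y_raw - self._y_mean) / self._y_std

        spec = self.spec
        n = len(y)
        # seeded validation split for early stopping, re-drawn each fit
        use_val = n >= 5 and len(np.unique(y_raw)) >= 2 and spec.nn_val_fraction > 0
        if use_val:
            perm = self._rng.permutation(n)
            n_val = max(1, int(round(spec.nn_val_fraction * n)))
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
        else:
            if n >= 5:
                warnings.warn(
                    "fewer than 2 distinct targets: training without early stopping",
                    stacklevel=2,
                )
            tr_idx = np.arange(n)
            val_idx = np.array([], dtype=int)
        xt, yt = x[tr_idx], y[tr_idx]
        xv, yv = x[val_idx], y[val_idx]

        best_val = math.inf
        best_params: list[np.ndarray] | None = None
        patience_left = spec.nn_patience
        batch = min(spec.nn_batch_size, len(yt))
        assert self._adam is not None
        for _epoch in range(spec.nn_epochs):
            order = self._rng.permutation(len(yt))
            for start in range(0, len(yt), batch):
                idx = order[start : start + batch]
                out, cache = self._forward(xt[idx], self._rng)
                _, d_out = self._loss_grad(out, yt[idx])
                gw, gb = self._backward(cache, d_out)
                self._adam.step(self._params(), [*gw, *gb])
            if use_val:
                out, _ = self._forward(xv, None)
                val_loss, _ = self._loss_grad(out, yv)
                if val_loss < best_val - 1e-12:
                    best_val = val_loss
                    best_params = [p.copy() for p in self._params()]
                    patience_left = spec.nn_patience
                else:
                    patience_left -= 1
                    if patience_left <= 0:
                        break
        if best_params is not None:
            n_w = len(self._weights)
            self._weights = best_params[:n_w]
            self._biases = best_params[n_w:]
            self._adam = _Adam(self._params(), spec.nn_lr)
        return self

    # -- inference ----------------------------------------------------------
    def predict(
        self, fingerprints: np.ndarray, mc_seed: int | None = None
    ) -> Prediction:
        if self._weights is None:
            raise SurrogateError("model not trained")
        x = fingerprints.astype(float)
        method = self.spec.resolved_uncertainty
        if method == "mc-dropout":
            if self.spec.nn_dropout == 0.0:
                # all passes coincide: mean is the deterministic forward
                # pass and the variance is exactly zero
                out, _ = self._forward(x, None)
                mean = out[:, 0] * self._y_std + self._y_mean
                return Prediction(mean, np.zeros_like(mean))
            seed = self.seed + 1 if mc_seed is None else mc_seed
            rng = np.random.default_rng(seed)
            passes = np.stack(
                [
                    self._forward(x, rng)[0][:, 0]
                    for _ in range(self.spec.nn_mc_passes)
                ]
            )
            mean = passes.mean(axis=0) * self._y_std + self._y_mean
            var = passes.var(axis=0) * self._y_std**2
            return Prediction(mean, var)
        out, _ = self._forward(x, None)
        mean = out[:, 0] * self._y_std + self._y_mean
        if method == "mve":
            var = (_softplus(out[:, 1]) + self._VAR_FLOOR) * self._y_std**2
            return Prediction(mean, var)
        return Prediction(mean)


# ---------------------------------------------------------------------------
# Factory, training entry point, checkpointing
# ---------------------------------------------------------------------------


def create_surrogate(spec: SurrogateSpec, seed: int = 0):
    if spec.architecture == "rf":
        return RandomForestSurrogate(spec, seed)
    if spec.architecture == "nn":
        return NeuralNetSurrogate(spec, seed)
    raise NotImplementedError(
        "the message-passing (mpn) architecture is not implemented in this "
        "package; use 'rf' or 'nn'"
    )


def train(
    spec: SurrogateSpec,
    data: TrainingSet,
    seed: int = 0,
    previous=None,
):
    """Train a surrogate on the acquired dataset.

    In full mode (default) a fresh model is fit from scratch on all of
    ``data``.  In online mode an existing ``previous`` model is trained
    further on only the (new) rows of ``data`` without reinitializing.
    """
    if spec.retrain_mode == "online" and previous is not None:
        if isinstance(previous, NeuralNetSurrogate):
            return previous.fit(data, reinitialize=False)
        # forests cannot be incrementally grown; refit on the given rows
        return previous.fit(data)
    model = create_surrogate(spec, seed)
    return model.fit(data)


def save_checkpoint(model, path: str | Path) -> None:
    joblib.dump(model, path)


def load_checkpoint(path: str | Path):
    return joblib.load(path)
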