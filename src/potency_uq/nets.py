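"""Feed-forward networks with dropout-based and mean-variance uncertainty.

Two network families are provided, implemented as a compact numpy
feed-forward stack (ReLU hidden layers, Adam, mini-batches of 32):

* **FFNN with Monte-Carlo dropout** — trained with MSE; dropout layers sit
  between all hidden layers and stay ACTIVE at prediction time, so repeated
  stochastic forward passes sample the predictive distribution. The
  prediction is the mean over ``n_mc_trials`` passes, the uncertainty the
  population variance across them.
* **MVE (mean-variance estimation)** — two output heads (mean and
  log-variance, exponentiated to keep the variance positive) trained on the
  per-sample Gaussian negative log-likelihood, with early termination when
  the training loss has not decreased for ``patience`` consecutive epochs.

Architectures follow the two standard variants for fingerprint inputs:
*large* = hidden layers (1000, 1000, 100, 10), *small* = (300, 300).
Networks consume raw 0/1 fingerprint bits without scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from ._rng import stream
from .types import ActivityClass, PredictionSet

_ARCHITECTURES = {"small": (300, 300), "large": (1000, 1000, 100, 10)}

#: floor applied to the MVE variance head (pIC50^2 units)
MVE_VAR_FLOOR = 1e-6
_LOGVAR_MIN = math.log(MVE_VAR_FLOOR)
_LOGVAR_MAX = 20.0


@dataclass(frozen=True)
class NetworkConfig:
    """Training configuration for one network variant."""

    family: str  # {"ffnn", "mve"}
    size: str = "small"  # {"small", "large"}
    hidden_sizes: tuple[int, ...] = ()
    dropout_rate: float = 0.2  # ffnn only
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 0  # 0 -> family default (ffnn 600, mve 4000)
    patience: int = 100  # mve only
    n_mc_trials: int = 100  # ffnn only
    early_stop_on: str = "train"  # mve only: {"train", "validation"}
    val_fraction: float = 0.1  # mve only, used when early_stop_on="validation"

    def resolved(self) -> "NetworkConfig":
        hidden = self.hidden_sizes or _ARCHITECTURES[self.size]
        epochs = self.max_epochs or (600 if self.family == "ffnn" else 4000)
        return replace(self, hidden_sizes=tuple(hidden), max_epochs=epochs)

    def validate(self) -> None:
        if self.family not in ("ffnn", "mve"):
            raise ValueError(f"unknown network family {self.family!r}")
        if self.size not in _ARCHITECTURES and not self.hidden_sizes:
            raise ValueError(f"unknown size {self.size!r}")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")


def ffnn_config(size: str = "small", dropout_rate: float = 0.2, **kw) -> NetworkConfig:
    return NetworkConfig(family="ffnn", size=size, dropout_rate=dropout_rate, **kw)


def mve_config(size: str = "small", **kw) -> NetworkConfig:
    return NetworkConfig(family="mve", size=size, **kw)


def desk_profile(config: NetworkConfig) -> NetworkConfig:
    """Scaled-down named profile for interactive/CI-sized runs.

    Small architecture, 50 (ffnn) / 300-with-patience-50 (mve) epochs.
    Never substituted silently; callers opt in by name.
    """
    if config.family == "ffnn":
        return replace(config, size="small", hidden_sizes=(), max_epochs=50)
    # over-parameterized MVE nets interpolate small training sets within a
    # few epochs, collapsing the variance head; at desk scale the early
    # stop therefore monitors a held-out split (best weights restored)
    return replace(
        config, size="small", hidden_sizes=(), max_epochs=50, patience=10,
        early_stop_on="validation",
    )


# ---------------------------------------------------------------------------
# numpy MLP core


class _MLP:
    """Plain feed-forward stack with ReLU hiddens and an Adam optimizer."""

    def __init__(self, n_in: int, hidden: tuple[int, ...], n_out: int, rng: np.random.Generator):
        sizes = [n_in, *hidden, n_out]
        self.W = [
            rng.normal(0.0, math.sqrt(2.0 / sizes[i]), (sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        self.n_hidden = len(hidden)
        # Adam state
        self._m = [np.zeros_like(w) for w in self.W + self.b]
        self._v = [np.zeros_like(w) for w in self.W + self.b]
        self._t = 0

    def forward(
        self,
        X: np.ndarray,
        dropout_rate: float = 0.0,
        rng: Optional[np.random.Generator] = None,
        keep_cache: bool = False,
    ):
        """Forward pass; dropout masks sit between consecutive hidden layers."""
        a = X.astype(np.float64, copy=False)
        cache = {"a": [a], "mask": []}
        for layer in range(self.n_hidden):
            h = np.maximum(a @ self.W[layer] + self.b[layer], 0.0)
            if dropout_rate > 0.0 and layer < self.n_hidden - 1:
                mask = (rng.random(h.shape) >= dropout_rate) / (1.0 - dropout_rate)
                h = h * mask
                cache["mask"].append(mask)
            else:
                cache["mask"].append(None)
            cache["a"].append(h)
            a = h
        out = a @ self.W[-1] + self.b[-1]
        return (out, cache) if keep_cache else out

    def backward(self, cache: dict, dout: np.ndarray) -> list[np.ndarray]:
        """Gradients of all W then all b, given dLoss/dOutput."""
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        delta = dout
        gW[-1] = cache["a"][-1].T @ delta
        gb[-1] = delta.sum(axis=0)
        da = delta @ self.W[-1].T
        for layer in range(self.n_hidden - 1, -1, -1):
            h = cache["a"][layer + 1]
            mask = cache["mask"][layer]
            if mask is not None:
                da = da * mask
                pre_act = h / np.where(mask == 0, 1.0, mask)  # undo mask for ReLU gate
            else:
                pre_act = h
            dz = da * (pre_act > 0)
            gW[layer] = cache["a"][layer].T @ dz
            gb[layer] = dz.sum(axis=0)
            da = dz @ self.W[layer].T
        return gW + gb

    def adam_step(self, grads: list[np.ndarray], lr: float, clip_norm: float = 5.0) -> None:
        norm = math.sqrt(sum(float(np.sum(g * g)) for g in grads))
        if norm > clip_norm:
            grads = [g * (clip_norm / norm) for g in grads]
        self._t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        params = self.W + self.b
        for i, (p, g) in enumerate(zip(params, grads)):
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            m_hat = self._m[i] / (1 - b1**self._t)
            v_hat = self._v[i] / (1 - b2**self._t)
            p -= lr * m_hat / (np.sqrt(v_hat) + eps)


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


# ---------------------------------------------------------------------------
# FFNN with MC dropout


@dataclass
class FFNNDropoutModel:
    net: _MLP
    config: NetworkConfig
    seed: int
    epochs_run: int = 0

    def mc_passes(
        self, X: np.ndarray, n_trials: int | None = None, seed: int | None = None
    ) -> np.ndarray:
        """(n_trials, n_test) matrix of stochastic forward passes."""
        n_trials = n_trials or self.config.n_mc_trials
        rng = stream(self.seed if seed is None else seed, "mc-dropout")
        return np.stack(
            [
                self.net.forward(X, self.config.dropout_rate, rng)[:, 0]
                for _ in range(n_trials)
            ]
        )


def fit_ffnn_dropout(config: NetworkConfig, train: ActivityClass, seed: int) -> FFNNDropoutModel:
    """Train a dropout FFNN with MSE loss; dropout is active during training."""
    config.validate()
    config = config.resolved()
    if config.family != "ffnn":
        raise ValueError("fit_ffnn_dropout needs family='ffnn'")
    X, y = train.fingerprints.astype(np.float64), train.pic50
    net = _MLP(X.shape[1], config.hidden_sizes, 1, stream(seed, "init"))
    net.b[-1][:] = y.mean()  # start at the label mean to avoid huge first steps
    batch_rng = stream(seed, "batches")
    drop_rng = stream(seed, "train-dropout")
    epochs = 0
    for epoch in range(config.max_epochs):
        for idx in _batches(len(y), config.batch_size, batch_rng):
            out, cache = net.forward(X[idx], config.dropout_rate, drop_rng, keep_cache=True)
            err = out[:, 0] - y[idx]
            loss = float(np.mean(err**2))
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"non-finite MSE loss at epoch {epoch} (|err| max "
                    f"{np.abs(err).max():.3g}); lower the learning rate"
                )
            dout = (2.0 * err / len(idx))[:, None]
            net.adam_step(net.backward(cache, dout), config.learning_rate)
        epochs = epoch + 1
    return FFNNDropoutModel(net=net, config=config, seed=seed, epochs_run=epochs)


def mc_dropout_predict(
    model: FFNNDropoutModel, test: ActivityClass, seed: int | None = None
) -> PredictionSet:
    """Mean/variance over ``n_mc_trials`` stochastic passes (dropout active)."""
    passes = model.mc_passes(test.fingerprints.astype(np.float64), seed=seed)
    variance = passes.var(axis=0)  # population convention, as for ensembles
    variance[np.ptp(passes, axis=0) == 0.0] = 0.0  # identical passes: exactly 0
    return PredictionSet(
        y_true=test.pic50,
        y_pred=passes.mean(axis=0),
        variance=variance,
        compound_ids=list(test.compound_ids),
        model=f"ffnn-{model.config.size}-d{int(round(model.config.dropout_rate * 100))}",
    )


# ---------------------------------------------------------------------------
# mean-variance estimation


@dataclass
class MVEModel:
    net: _MLP
    config: NetworkConfig
    seed: int
    epochs_run: int = 0
    stopped_early: bool = False

    def predict_heads(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        out = self.net.forward(X.astype(np.float64))
        logvar = np.clip(out[:, 1], _LOGVAR_MIN, _LOGVAR_MAX)
        return out[:, 0], np.exp(logvar)


def fit_mve(config: NetworkConfig, train: ActivityClass, seed: int) -> MVEModel:
    """Train a two-head network on the Gaussian negative log-likelihood.

    The variance head emits log-variance (exponentiated, floored at
    ``MVE_VAR_FLOOR``); its bias starts at ln var(y) so the initial
    predictive distribution matches the label spread. Training stops early
    once the monitored loss has not improved for ``patience`` consecutive
    epochs: by default the epoch-mean TRAINING loss is monitored; with
    ``early_stop_on="validation"`` a held-out ``val_fraction`` of the
    training compounds is monitored instead and the best-epoch weights are
    restored (guards against variance-head collapse when the network is
    over-parameterized enough to interpolate its training set).
    """
    config.validate()
    config = config.resolved()
    if config.family != "mve":
        raise ValueError("fit_mve needs family='mve'")
    if config.early_stop_on not in ("train", "validation"):
        raise ValueError(f"unknown early_stop_on {config.early_stop_on!r}")
    X, y = train.fingerprints.astype(np.float64), train.pic50
    X_val = y_val = None
    if config.early_stop_on == "validation":
        n_val = max(1, int(round(config.val_fraction * len(y))))
        if n_val >= len(y):
            raise ValueError("val_fraction leaves no training data")
        perm = stream(seed, "val-split").permutation(len(y))
        X_val, y_val = X[perm[:n_val]], y[perm[:n_val]]
        X, y = X[perm[n_val:]], y[perm[n_val:]]
    net = _MLP(X.shape[1], config.hidden_sizes, 2, stream(seed, "init"))
    net.b[-1][0] = y.mean()
    net.b[-1][1] = math.log(max(float(y.var()), MVE_VAR_FLOOR))
    batch_rng = stream(seed, "batches")
    best_loss, stale, epochs, stopped = np.inf, 0, 0, False
    best_params = None
    for epoch in range(config.max_epochs):
        epoch_losses = []
        for idx in _batches(len(y), config.batch_size, batch_rng):
            out, cache = net.forward(X[idx], keep_cache=True)
            mu, logvar = out[:, 0], np.clip(out[:, 1], _LOGVAR_MIN, _LOGVAR_MAX)
            var = np.exp(logvar)
            err = mu - y[idx]
            loss = float(np.mean(math.log(2 * math.pi) + logvar + err**2 / var) / 2.0)
            if not math.isfinite(loss):
                raise RuntimeError(f"non-finite NLL loss at epoch {epoch}")
            n_b = len(idx)
            dout = np.empty((n_b, 2))
            dout[:, 0] = err / var / n_b
            dout[:, 1] = 0.5 * (1.0 - err**2 / var) / n_b
            dout[:, 1] *= (out[:, 1] > _LOGVAR_MIN) & (out[:, 1] < _LOGVAR_MAX)
            net.adam_step(net.backward(cache, dout), config.learning_rate)
            epoch_losses.append(loss)
        epochs = epoch + 1
        if config.early_stop_on == "validation":
            monitored = _gaussian_nll(net, X_val, y_val)
        else:
            monitored = float(np.mean(epoch_losses))
        if monitored < best_loss - 1e-6:
            best_loss, stale = monitored, 0
            if config.early_stop_on == "validation":
                best_params = ([w.copy() for w in net.W], [b.copy() for b in net.b])
        else:
            stale += 1
            if stale >= config.patience:
                stopped = True
                break
    if best_params is not None:
        net.W, net.b = best_params
    return MVEModel(net=net, config=config, seed=seed, epochs_run=epochs, stopped_early=stopped)


def _gaussian_nll(net: _MLP, X: np.ndarray, y: np.ndarray) -> float:
    out = net.forward(X)
    logvar = np.clip(out[:, 1], _LOGVAR_MIN, _LOGVAR_MAX)
    err = out[:, 0] - y
    return float(np.mean(math.log(2 * math.pi) + logvar + err**2 / np.exp(logvar)) / 2.0)


def mve_predict(model: MVEModel, test: ActivityClass) -> PredictionSet:
    mu, var = model.predict_heads(test.fingerprints)
    return PredictionSet(
        y_true=test.pic50,
        y_pred=mu,
        variance=np.maximum(var, MVE_VAR_FLOOR),
        compound_ids=list(test.compound_ids),
        model=f"mve-{model.config.size}",
    )
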