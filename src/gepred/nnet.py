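"""Multilayer perceptron for genomic prediction with random architecture search.

A fully connected feed-forward net maps standardized SNP dosages to the
pre-adjusted phenotype: ReLU hidden units, a single linear output unit, and
a ridge-penalized sum-of-squares loss

    L(y, o) = (y - o)'(y - o) + lambda w'w        (biases unpenalized).

Training is mini-batch Adam (default learning rate 1e-4, batch 256); weights
start N(0, 1e-4), biases at 0.  Overfitting control: inverted dropout on the
input and hidden layers (the rate is the KEEP probability, 1 = no dropout),
and early stopping that evaluates the tuning-set MSE every 5 epochs and
halts after 5 consecutive evaluations without strict improvement, returning
the best-evaluation snapshot.  Hyperparameters (depth, width per layer, L2
strength, dropout keep-rate) are selected by random search over fixed grids,
scored by prediction correlation on the tuning set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Architecture", "TrainConfig", "TrainResult", "SearchSpace",
           "forward", "penalized_loss", "apply_dropout", "train",
           "random_search", "MLPRegressor", "MLPResults"]

UNITS_GRID = (1, 100, 200, 300, 400, 500, 600, 700, 800, 900, 1000,
              2000, 3000, 4000, 5000)
LAYERS_GRID = (1, 2, 3, 4)
DROPOUT_GRID = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
L2_GRID = tuple(np.round(np.arange(0.0, 0.100001, 0.0025), 4))


@dataclass
class Architecture:
    """One candidate network: depth, widths, L2 strength, dropout keep-rate."""

    n_hidden_layers: int
    units_per_layer: tuple
    l2_lambda: float
    dropout_keep: float

    def __post_init__(self):
        self.units_per_layer = tuple(int(u) for u in self.units_per_layer)
        if len(self.units_per_layer) != self.n_hidden_layers:
            raise ValueError("units list length must equal n_hidden_layers")
        if any(u < 1 for u in self.units_per_layer):
            raise ValueError("units must be positive")
        if not 0 < self.dropout_keep <= 1:
            raise ValueError("dropout_keep must be in (0, 1]")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be >= 0")

    def describe(self) -> str:
        units = "-".join(str(u) for u in self.units_per_layer)
        return (f"{self.n_hidden_layers} layer(s) [{units}], "
                f"L2={self.l2_lambda}, keep={self.dropout_keep}")


@dataclass
class SearchSpace:
    """Hyperparameter grids for the random search (defaults: full grids)."""

    layers: tuple = LAYERS_GRID
    units: tuple = UNITS_GRID
    l2: tuple = L2_GRID
    dropout: tuple = DROPOUT_GRID


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 256
    max_epochs: int = 1000
    eval_every: int = 5
    patience: int = 5
    init_sd: float = 1e-2
    seed: int = 0

    def __post_init__(self):
        for name in ("learning_rate", "batch_size", "max_epochs",
                     "eval_every", "patience", "init_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TrainResult:
    weights: list
    history: list
    stopped_epoch: int
    stop_reason: str
    best_tune_mse: float
    architecture: Architecture = None

    def predict(self, X) -> np.ndarray:
        return forward(self.architecture, self.weights, X, mode="predict")

    def save_weights(self, path) -> None:
        """Portable array container (.npz) with one pair per layer."""
        arrays = {}
        for k, (W, b) in enumerate(self.weights):
            arrays[f"W{k}"] = W
            arrays[f"b{k}"] = b
        np.savez(path, **arrays)

    @staticmethod
    def load_weights(path) -> list:
        data = np.load(path)
        n_layers = sum(1 for key in data.files if key.startswith("W"))
        return [(data[f"W{k}"], data[f"b{k}"]) for k in range(n_layers)]


# ----------------------------------------------------------------------
# core numerics


def _init_weights(arch: Architecture, n_inputs: int, rng, init_sd=1e-2) -> list:
    sizes = [n_inputs, *arch.units_per_layer, 1]
    return [(rng.normal(0.0, init_sd, size=(sizes[k], sizes[k + 1])),
             np.zeros(sizes[k + 1])) for k in range(len(sizes) - 1)]


def apply_dropout(activations, keep_rate, rng):
    """Inverted dropout: keep each unit w.p. keep_rate, rescale by 1/keep.

    Expectations match predict mode, so no rescaling is needed at
    prediction time.  keep_rate = 1 is the identity.
    """
    if keep_rate <= 0 or keep_rate > 1:
        raise ValueError("keep_rate must be in (0, 1]")
    if keep_rate == 1.0:
        return np.asarray(activations, dtype=float)
    mask = rng.random(np.shape(activations)) < keep_rate
    return np.asarray(activations, dtype=float) * mask / keep_rate


def _forward_cache(arch, weights, X, mode, rng):
    """Forward pass keeping pre-activations and dropout masks for backprop."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    keep = arch.dropout_keep
    train_mode = mode == "train" and keep < 1.0
    masks, pre_acts, acts = [], [], []
    h = X
    if train_mode:
        mask = (rng.random(h.shape) < keep) / keep
        h = h * mask
        masks.append(mask)
    else:
        masks.append(None)
    acts.append(h)
    n_layers = len(weights)
    for k, (W, b) in enumerate(weights):
        z = h @ W + b
        pre_acts.append(z)
        if k < n_layers - 1:            # hidden: ReLU then dropout
            h = np.maximum(z, 0.0)
            if train_mode:
                mask = (rng.random(h.shape) < keep) / keep
                h = h * mask
                masks.append(mask)
            else:
                masks.append(None)
            acts.append(h)
        else:                            # output: linear, never dropped
            h = z
    return h[:, 0], acts, pre_acts, masks


def forward(arch: Architecture, weights, x, mode="predict", rng=None):
    """Network output for inputs ``x`` (vector or matrix of rows).

    ``mode="train"`` applies dropout (requires ``rng``); predict mode is
    deterministic.
    """
    single = np.ndim(x) == 1
    if mode == "train" and arch.dropout_keep < 1.0 and rng is None:
        raise ValueError("train-mode forward with dropout needs an rng")
    out = _forward_cache(arch, weights, np.atleast_2d(x), mode, rng)[0]
    return float(out[0]) if single else out


def penalized_loss(y, y_hat, weights, l2_lambda):
    """Sum of squared residuals + lambda * sum of squared weights (no biases)."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if len(y) != len(y_hat):
        raise ValueError("y and y_hat lengths differ")
    sse = float(np.sum((y - y_hat) ** 2))
    wtw = sum(float(np.sum(W ** 2)) for W, _ in weights)
    return sse + l2_lambda * wtw


def _backprop(arch, weights, X, y, rng=None, mode="predict"):
    """Penalized loss and its gradients w.r.t. every weight and bias."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat, acts, pre_acts, masks = _forward_cache(arch, weights, X, mode, rng)
    loss = penalized_loss(y, y_hat, weights, arch.l2_lambda)
    grads = [None] * len(weights)
    delta = 2.0 * (y_hat - y)[:, None]          # d SSE / d output
    for k in range(len(weights) - 1, -1, -1):
        W, b = weights[k]
        gW = acts[k].T @ delta + 2.0 * arch.l2_lambda * W
        gb = delta.sum(axis=0)
        grads[k] = (gW, gb)
        if k > 0:
            delta = delta @ W.T
            delta = delta * (pre_acts[k - 1] > 0)          # ReLU gate
            if masks[k] is not None:
                delta = delta * masks[k]
    return loss, grads, y_hat


class EarlyStopper:
    """Patience rule on a stream of tuning-set MSE evaluations.

    "No improvement" means not strictly lower than the best MSE seen so
    far; after ``patience`` consecutive non-improving evaluations
    :meth:`update` returns True (stop).  ``best_index`` marks the
    evaluation whose snapshot should be returned.
    """

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_index = -1
        self.bad = 0
        self.n_seen = 0

    def update(self, mse: float) -> bool:
        if mse < self.best:
            self.best = mse
            self.best_index = self.n_seen
            self.bad = 0
        else:
            self.bad += 1
        self.n_seen += 1
        return self.bad >= self.patience


def train(arch: Architecture, train_xy, tune_xy,
          config: TrainConfig = TrainConfig()) -> TrainResult:
    """Mini-batch Adam with tuning-set early stopping.

    ``train_xy`` and ``tune_xy`` are (X, y) pairs on disjoint individuals.
    The tuning MSE (unpenalized) is evaluated every ``eval_every`` epochs;
    training halts after ``patience`` consecutive evaluations that fail to
    strictly improve the best MSE so far, or at ``max_epochs``.  The weights
    returned are the snapshot from the best tuning evaluation.
    """
    X, y = train_xy
    Xt, yt = tune_xy
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    Xt = np.atleast_2d(np.asarray(Xt, dtype=float))
    yt = np.asarray(yt, dtype=float).ravel()
    if len(yt) == 0:
        raise ValueError("empty tuning set: early stopping undefined")
    rng = np.random.default_rng(config.seed)
    weights = _init_weights(arch, X.shape[1], rng, config.init_sd)
    m_state = [(np.zeros_like(W), np.zeros_like(b)) for W, b in weights]
    v_state = [(np.zeros_like(W), np.zeros_like(b)) for W, b in weights]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    n = len(y)
    history = []
    stopper = EarlyStopper(config.patience)
    best_weights = [(W.copy(), b.copy()) for W, b in weights]
    stop_reason = "max-epochs"
    stopped_epoch = config.max_epochs
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = order[start:start + config.batch_size]
            _, grads, _ = _backprop(arch, weights, X[batch], y[batch],
                                    rng=rng, mode="train")
            t += 1
            for k, ((W, b), (gW, gb)) in enumerate(zip(weights, grads)):
                mW, mb = m_state[k]
                vW, vb = v_state[k]
                mW = beta1 * mW + (1 - beta1) * gW
                mb = beta1 * mb + (1 - beta1) * gb
                vW = beta2 * vW + (1 - beta2) * gW ** 2
                vb = beta2 * vb + (1 - beta2) * gb ** 2
                m_state[k] = (mW, mb)
                v_state[k] = (vW, vb)
                mW_hat = mW / (1 - beta1 ** t)
                mb_hat = mb / (1 - beta1 ** t)
                vW_hat = vW / (1 - beta2 ** t)
                vb_hat = vb / (1 - beta2 ** t)
                weights[k] = (
                    W - config.learning_rate * mW_hat / (np.sqrt(vW_hat) + eps),
                    b - config.learning_rate * mb_hat / (np.sqrt(vb_hat) + eps),
                )
        if epoch % config.eval_every == 0:
            pred = _forward_cache(arch, weights, Xt, "predict", None)[0]
            mse = float(np.mean((yt - pred) ** 2))
            history.append(mse)
            improved = mse < stopper.best
            stop = stopper.update(mse)
            if improved:
                best_weights = [(W.copy(), b.copy()) for W, b in weights]
            if stop:
                stop_reason = "early-stop"
                stopped_epoch = epoch
                break
    if not history:       # max_epochs < eval_every: evaluate once at the end
        pred = _forward_cache(arch, weights, Xt, "predict", None)[0]
        history.append(float(np.mean((yt - pred) ** 2)))
        stopper.update(history[0])
        best_weights = [(W.copy(), b.copy()) for W, b in weights]
    return TrainResult(weights=best_weights, history=history,
                       stopped_epoch=stopped_epoch, stop_reason=stop_reason,
                       best_tune_mse=stopper.best, architecture=arch)


def sample_architecture(space: SearchSpace, rng) -> Architecture:
    """Independent uniform draws from each hyperparameter grid."""
    depth = int(rng.choice(space.layers))
    units = tuple(int(rng.choice(space.units)) for _ in range(depth))
    return Architecture(n_hidden_layers=depth, units_per_layer=units,
                        l2_lambda=float(rng.choice(space.l2)),
                        dropout_keep=float(rng.choice(space.dropout)))


def random_search(space: SearchSpace, n_candidates, train_xy, tune_xy,
                  config: TrainConfig = TrainConfig(), seed=0):
    """Random architecture search scored by tuning-set prediction correlation.

    Each of ``n_candidates`` architectures is drawn by independent uniform
    choices from the grids, trained with :func:`train`, and scored by the
    Pearson correlation between tuning targets and predictions.  Ties break
    by lower tuning MSE, then draw order.  Returns
    (best Architecture, leaderboard DataFrame, best TrainResult).
    """
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    rng = np.random.default_rng(seed)
    Xt, yt = tune_xy
    yt = np.asarray(yt, dtype=float).ravel()
    rows, results = [], []
    n_failed = 0
    for i in range(n_candidates):
        arch = sample_architecture(space, rng)
        cand_config = TrainConfig(**{**config.__dict__,
                                     "seed": int(rng.integers(2**31))})
        try:
            res = train(arch, train_xy, tune_xy, cand_config)
            pred = res.predict(Xt)
            if np.std(pred) == 0 or np.std(yt) == 0:
                corr = -np.inf
            else:
                corr = float(np.corrcoef(yt, pred)[0, 1])
            mse = float(np.mean((yt - pred) ** 2))
        except Exception:
            n_failed += 1
            res, corr, mse = None, -np.inf, np.inf
        results.append(res)
        rows.append({
            "candidate": i,
            "layers": arch.n_hidden_layers,
            "units": "-".join(str(u) for u in arch.units_per_layer),
            "l2": arch.l2_lambda,
            "dropout_keep": arch.dropout_keep,
            "tune_correlation": corr,
            "tune_msep": mse,
        })
    if n_failed == n_candidates:
        raise RuntimeError("every candidate architecture failed to train")
    board = pd.DataFrame(rows)
    ranked = board.sort_values(["tune_correlation", "tune_msep", "candidate"],
                               ascending=[False, True, True], kind="stable")
    best_i = int(ranked.iloc[0]["candidate"])
    return results[best_i].architecture, board, results[best_i]


# ----------------------------------------------------------------------
# model-object surface


class MLPRegressor:
    """Model object wrapping :func:`train` / :func:`random_search`."""

    def __init__(self, y_train, X_train, y_tune, X_tune):
        self.train_xy = (np.atleast_2d(np.asarray(X_train, dtype=float)),
                         np.asarray(y_train, dtype=float).ravel())
        self.tune_xy = (np.atleast_2d(np.asarray(X_tune, dtype=float)),
                        np.asarray(y_tune, dtype=float).ravel())

    def fit(self, arch: Architecture, config: TrainConfig = TrainConfig()):
        res = train(arch, self.train_xy, self.tune_xy, config)
        return MLPResults(res)

    def fit_search(self, space: SearchSpace = SearchSpace(), n_candidates=200,
                   config: TrainConfig = TrainConfig(), seed=0):
        arch, board, res = random_search(space, n_candidates, self.train_xy,
                                         self.tune_xy, config, seed)
        out = MLPResults(res)
        out.leaderboard = board
        return out


class MLPResults:
    """Fitted network: predictions, training history, summary table."""

    def __init__(self, result: TrainResult):
        self.result = result
        self.architecture = result.architecture
        self.leaderboard = None

    def predict(self, X) -> np.ndarray:
        return self.result.predict(X)

    def summary(self) -> str:
        r = self.result
        lines = [
            "MLP training results",
            "=" * 44,
            f"architecture   {r.architecture.describe()}",
            f"stopped epoch  {r.stopped_epoch} ({r.stop_reason})",
            f"tuning MSE     {r.best_tune_mse:.4f}",
            f"evaluations    {len(r.history)}",
            "=" * 44,
        ]
        return "\n".join(lines)
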