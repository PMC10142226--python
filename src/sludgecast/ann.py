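"""Shallow neural-network regressor for community-feature prediction.

One model per target: a single hidden layer of 2n+1 relu units over n
environmental factors and a sigmoid output unit, trained with Adam
(L2-coupled weight decay) on mini-batches; targets are min-max scaled to
(0, 1) on the training split so the sigmoid output is coherent, and
predictions are inverse-scaled for reporting. Accuracy is measured with the
1:1-line coefficient of determination R2_1:1 = 1 - SS_res/SS_tot (computed
against the identity line, so it can be negative), alongside the best-fit
R2 (squared Pearson correlation) and MSE, averaged over repeated seeded
train/test splits.

The network is sized for metadata on the pipeline's 1-100 normalised scale;
weight initialisation assumes inputs of that magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

#: expected magnitude of 1-100 normalised inputs, used to scale initial weights
_INPUT_SCALE = 50.0


@dataclass
class TrainConfig:
    """Training protocol: topology, optimiser and evaluation settings.

    ``hidden_width`` defaults to 2n+1 over ``n_inputs`` factors. The Adam
    settings (batch 256, learning rate 1e-5, weight decay 0.01, dropout 0,
    10,000 iterations) are the study protocol; ``n_iterations`` counts
    optimiser steps, not epochs.
    """

    n_inputs: int
    hidden_width: int | None = None
    batch_size: int = 256
    learning_rate: float = 1e-5
    weight_decay: float = 0.01
    dropout: float = 0.0
    n_iterations: int = 10_000
    cv_folds: int = 4
    train_fraction: float = 0.8
    n_seeds: int = 20

    def __post_init__(self) -> None:
        if self.n_inputs < 1:
            raise ValueError("n_inputs must be >= 1")
        if self.hidden_width is not None and self.hidden_width < 1:
            raise ValueError("hidden_width must be >= 1")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")

    @property
    def width(self) -> int:
        """Effective hidden width: 2n+1 unless overridden."""
        return self.hidden_width if self.hidden_width is not None else 2 * self.n_inputs + 1


@dataclass
class PredictiveModel:
    """Weights and target scaling of a trained single-hidden-layer network."""

    W: np.ndarray  # (n_inputs, hidden)
    b_h: np.ndarray  # (hidden,)
    v: np.ndarray  # (hidden,)
    b_o: float
    target_min: float
    target_max: float
    columns: list[str] | None = None

    @property
    def constant_target(self) -> bool:
        return self.target_max <= self.target_min

    def scale_y(self, y: np.ndarray) -> np.ndarray:
        if self.constant_target:
            return np.full_like(np.asarray(y, dtype=float), 0.5)
        return (np.asarray(y, dtype=float) - self.target_min) / (
            self.target_max - self.target_min
        )

    def unscale_y(self, s: np.ndarray) -> np.ndarray:
        if self.constant_target:
            return np.full_like(np.asarray(s, dtype=float), self.target_min)
        return self.target_min + np.asarray(s, dtype=float) * (
            self.target_max - self.target_min
        )


def build_network(config: TrainConfig, seed: int = 0) -> PredictiveModel:
    """Initialise a network deterministically per seed.

    He-style input-hidden weights divided by the expected 1-100 input
    magnitude keep hidden pre-activations O(1); hidden-output weights are
    Glorot-scaled so the sigmoid starts in its active range.
    """
    rng = np.random.default_rng(seed)
    n, h = config.n_inputs, config.width
    W = rng.normal(0.0, np.sqrt(2.0 / n) / _INPUT_SCALE, size=(n, h))
    v = rng.normal(0.0, np.sqrt(1.0 / h), size=h)
    return PredictiveModel(
        W=W,
        b_h=np.zeros(h),
        v=v,
        b_o=0.0,
        target_min=0.0,
        target_max=1.0,
    )


def _as_matrix(X) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    return np.asarray(X, dtype=float), None


def _forward(model: PredictiveModel, X: np.ndarray) -> np.ndarray:
    h = np.maximum(X @ model.W + model.b_h, 0.0)
    return expit(h @ model.v + model.b_o)


def predict(model: PredictiveModel, X) -> np.ndarray:
    """Predictions on the original target scale."""
    arr, cols = _as_matrix(X)
    if model.columns is not None and cols is not None and cols != model.columns:
        raise ValueError("prediction columns do not match training columns")
    if arr.shape[1] != model.W.shape[0]:
        raise ValueError(
            f"expected {model.W.shape[0]} features, got {arr.shape[1]}"
        )
    if model.constant_target:
        return np.full(arr.shape[0], model.target_min)
    return model.unscale_y(_forward(model, arr))


def split_train_test(
    sample_ids, train_fraction: float = 0.8, seed: int = 0
) -> tuple[list, list]:
    """Random train/test split; train size is round(train_fraction * n)."""
    ids = list(sample_ids)
    if len(ids) < 5:
        raise ValueError("need at least 5 samples to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(round(train_fraction * len(ids)))
    n_train = min(max(n_train, 1), len(ids) - 1)
    train = [ids[i] for i in perm[:n_train]]
    test = [ids[i] for i in perm[n_train:]]
    return train, test


def _adam_train(
    model: PredictiveModel,
    X: np.ndarray,
    ys: np.ndarray,
    config: TrainConfig,
    rng: np.random.Generator,
    loss_every: int = 0,
) -> list[tuple[int, float]]:
    """Run ``config.n_iterations`` Adam steps in place; optionally log loss."""
    lr, wd = config.learning_rate, config.weight_decay
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    params = [model.W, model.b_h, model.v, np.array([model.b_o])]
    m = [np.zeros_like(p) for p in params]
    v2 = [np.zeros_like(p) for p in params]
    n = X.shape[0]
    bs = min(config.batch_size, n)
    order = rng.permutation(n)
    cursor = 0
    history: list[tuple[int, float]] = []

    for t in range(1, config.n_iterations + 1):
        if cursor + bs > n:
            order = rng.permutation(n)
            cursor = 0
        idx = order[cursor : cursor + bs]
        cursor += bs
        xb, yb = X[idx], ys[idx]

        z_h = xb @ params[0] + params[1]
        h = np.maximum(z_h, 0.0)
        if config.dropout > 0:
            keep = rng.random(h.shape) >= config.dropout
            h = h * keep / (1.0 - config.dropout)
        o = expit(h @ params[2] + params[3][0])
        resid = o - yb

        if loss_every and (t == 1 or t % loss_every == 0):
            history.append((t, float(np.mean(resid**2))))

        g_o = (2.0 / bs) * resid * o * (1.0 - o)
        grads = [None] * 4
        grads[2] = h.T @ g_o
        grads[3] = np.array([g_o.sum()])
        g_h = np.outer(g_o, params[2]) * (z_h > 0)
        grads[0] = xb.T @ g_h
        grads[1] = g_h.sum(axis=0)

        for k in range(4):
            g = grads[k] + wd * params[k]
            m[k] = beta1 * m[k] + (1 - beta1) * g
            v2[k] = beta2 * v2[k] + (1 - beta2) * g * g
            mhat = m[k] / (1 - beta1**t)
            vhat = v2[k] / (1 - beta2**t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    model.b_o = float(params[3][0])
    return history


def train_model(
    X,
    y,
    config: TrainConfig,
    seed: int = 0,
    run_cv: bool = False,
    loss_every: int = 0,
) -> tuple[PredictiveModel, dict]:
    """Train one network on (X, y).

    Targets are min-max scaled to (0, 1) on the supplied data; a constant
    target short-circuits to a degenerate model that predicts the constant.
    With ``run_cv`` a fourfold cross-validation inside the training data is
    reported (per-fold validation MSE and R2_1:1) before the final model is
    refit on all rows. ``loss_every`` > 0 records the training loss curve.
    """
    arr, cols = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    if arr.shape[0] != y.shape[0]:
        raise ValueError("X and y length mismatch")
    if np.isnan(arr).any() or not np.all(np.isfinite(y)):
        raise ValueError("X must be imputed and y finite")

    ymin, ymax = float(y.min()), float(y.max())
    report: dict = {"cv": None, "loss_history": None}

    model = build_network(config, seed)
    model.target_min, model.target_max = ymin, ymax
    model.columns = cols
    if model.constant_target:
        return model, report

    rng = np.random.default_rng(seed)

    if run_cv:
        folds = _kfold(arr.shape[0], config.cv_folds, rng)
        cv_rows = []
        for i, val_idx in enumerate(folds):
            tr_idx = np.setdiff1d(np.arange(arr.shape[0]), val_idx)
            sub = build_network(config, seed)
            sub.target_min = float(y[tr_idx].min())
            sub.target_max = float(y[tr_idx].max())
            if not sub.constant_target:
                _adam_train(sub, arr[tr_idx], sub.scale_y(y[tr_idx]), config, rng)
            pred = (
                np.full(len(val_idx), sub.target_min)
                if sub.constant_target
                else sub.unscale_y(_forward(sub, arr[val_idx]))
            )
            ev = evaluate(y[val_idx], pred)
            cv_rows.append({"fold": i, "mse": ev["mse"], "r2_1to1": ev["r2_1to1"]})
        report["cv"] = pd.DataFrame(cv_rows)

    history = _adam_train(model, arr, model.scale_y(y), config, rng, loss_every)
    if loss_every:
        report["loss_history"] = pd.DataFrame(history, columns=["iteration", "mse"])
    return model, report


def _kfold(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [perm[i::k] for i in range(k)]


def evaluate(observed, predicted) -> dict:
    """R2_1:1, best-fit R2 and MSE for one observed/predicted pair.

    r2_1to1 = 1 - sum((o-p)^2)/sum((o-mean(o))^2) judges predictions against
    the identity line and is negative when they do worse than the observed
    mean; r2_bestfit is the squared Pearson correlation and is NaN when
    either side is constant.
    """
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.ndim != 1 or len(o) < 2:
        raise ValueError("observed and predicted must be equal-length 1-D, n >= 2")
    mse = float(np.mean((o - p) ** 2))
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0:
        return {"r2_1to1": np.nan, "r2_bestfit": np.nan, "mse": mse}
    r2_1to1 = 1.0 - float(np.sum((o - p) ** 2)) / ss_tot
    if np.std(p) == 0:
        r2_bestfit = np.nan
    else:
        r2_bestfit = float(stats.pearsonr(o, p)[0] ** 2)
    return {"r2_1to1": r2_1to1, "r2_bestfit": r2_bestfit, "mse": mse}


@dataclass
class EvalResult:
    """Per-seed and averaged metrics from repeated train/test experiments."""

    target_id: str
    per_seed: pd.DataFrame  # columns: seed, r2_1to1, r2_bestfit, mse
    models: list[PredictiveModel] = field(default_factory=list, repr=False)

    @property
    def seeds(self) -> list[int]:
        return [int(s) for s in self.per_seed["seed"]]

    def mean(self, metric: str = "r2_1to1") -> float:
        return float(self.per_seed[metric].mean())

    def ci95(self, metric: str = "r2_1to1") -> tuple[float, float]:
        """95% t-interval of the mean over seeds."""
        vals = self.per_seed[metric].to_numpy(dtype=float)
        if len(vals) < 2 or np.std(vals, ddof=1) == 0:
            mu = float(np.mean(vals))
            return (mu, mu)
        mu = float(np.mean(vals))
        half = stats.t.ppf(0.975, len(vals) - 1) * stats.sem(vals)
        return (mu - half, mu + half)


def repeated_experiment(
    X,
    y,
    config: TrainConfig,
    seeds: list[int] | None = None,
    target_id: str = "target",
    keep_models: bool = True,
    run_cv: bool = False,
) -> EvalResult:
    """The repeated-seed protocol: split, train, evaluate per seed.

    Each seed governs the train/test split, weight initialisation and batch
    shuffling. Metrics are reported per seed and averaged over raw
    (unclipped) values.
    """
    if seeds is None:
        seeds = list(range(config.n_seeds))
    if not seeds:
        raise ValueError("need at least one seed")
    arr, cols = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    ids = np.arange(arr.shape[0])

    rows, models = [], []
    for seed in seeds:
        tr, te = split_train_test(ids, config.train_fraction, seed)
        Xtr = pd.DataFrame(arr[tr], columns=cols) if cols else arr[np.asarray(tr)]
        model, _ = train_model(Xtr, y[np.asarray(tr)], config, seed, run_cv=run_cv)
        pred = predict(model, arr[np.asarray(te)])
        ev = evaluate(y[np.asarray(te)], pred)
        rows.append({"seed": seed, **ev})
        if keep_models:
            models.append(model)
    return EvalResult(target_id=target_id, per_seed=pd.DataFrame(rows), models=models)
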