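"""A from-scratch shallow feed-forward network with backpropagation.

This is the unit of the inference swarm: a single-hidden-layer perceptron
mapping an expression vector of predictor genes to one output gene, trained
by full-batch gradient descent on mean-squared error with classical momentum,
an L2 weight penalty, and early stopping on a held-out validation split. The
network is intentionally tiny (two hidden units by default): its job is not
prediction accuracy but a stable, differentiable map whose input gradients —
the *linearized influence* — read out how strongly, and in which direction,
each predictor gene drives the output gene.

Full-batch (rather than stochastic) descent is used because the sample sizes
are tens of columns and determinism keeps the reproducibility contract
simple. Influence is defined as the output gradient averaged over a reference
matrix; for a linear activation it reduces exactly to the weight product
``sum_h W_in[i, h] * W_out[h]`` independent of the reference data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, ParameterError, ShapeError, TrainingDivergenceError

__all__ = [
    "MLPModel",
    "TrainConfig",
    "TrainResult",
    "init_mlp",
    "forward",
    "train_mlp",
    "linearized_influence",
    "standardize_train_val",
]

_ACTIVATIONS = ("tanh", "linear")


@dataclass
class TrainConfig:
    """Hyperparameters for one MLP fit.

    ``momentum`` is classical momentum on the gradient step; ``l2_penalty``
    multiplies the sum of squared weights (biases are not penalized);
    ``patience`` is the number of consecutive epochs without validation
    improvement tolerated before stopping; ``init_scale`` bounds the uniform
    weight initialization. Defaults are tuned for standardized inputs.

    With ``early_stopping=False`` the fit runs the full ``max_epochs`` and
    returns the final-epoch parameters (training to convergence); the
    validation history is still recorded but does not select the model.
    """

    n_hidden: int = 2
    learning_rate: float = 0.05
    momentum: float = 0.9
    l2_penalty: float = 1e-3
    max_epochs: int = 400
    patience: int = 30
    init_scale: float = 0.5
    seed: int = 0
    activation: str = "tanh"
    early_stopping: bool = True

    def __post_init__(self) -> None:
        if self.n_hidden < 1:
            raise ShapeError("n_hidden must be >= 1")
        if self.learning_rate <= 0:
            raise ParameterError("learning_rate must be > 0")
        if not (0.0 <= self.momentum < 1.0):
            raise ParameterError("momentum must be in [0, 1)")
        if self.l2_penalty < 0:
            raise ParameterError("l2_penalty must be >= 0")
        if self.patience > self.max_epochs:
            raise ParameterError("patience must not exceed max_epochs")
        if self.patience < 1 or self.max_epochs < 1:
            raise ParameterError("patience and max_epochs must be >= 1")
        if self.init_scale < 0:
            raise ParameterError("init_scale must be >= 0")
        if self.activation not in _ACTIVATIONS:
            raise ParameterError(f"activation must be one of {_ACTIVATIONS}")


@dataclass
class MLPModel:
    """Parameters of one inputs -> hidden -> scalar-output network."""

    W_in: np.ndarray  # (n_inputs, n_hidden)
    b_hidden: np.ndarray  # (n_hidden,)
    W_out: np.ndarray  # (n_hidden,)
    b_out: float
    activation: str = "tanh"

    def __post_init__(self) -> None:
        self.W_in = np.asarray(self.W_in, dtype=float)
        self.b_hidden = np.asarray(self.b_hidden, dtype=float)
        self.W_out = np.asarray(self.W_out, dtype=float)
        self.b_out = float(self.b_out)
        if self.W_in.ndim != 2 or self.W_in.shape[1] < 1:
            raise ShapeError("W_in must be (n_inputs, n_hidden) with n_hidden >= 1")
        n_hidden = self.W_in.shape[1]
        if self.b_hidden.shape != (n_hidden,) or self.W_out.shape != (n_hidden,):
            raise ShapeError("b_hidden and W_out must have shape (n_hidden,)")
        if self.activation not in _ACTIVATIONS:
            raise ParameterError(f"activation must be one of {_ACTIVATIONS}")
        for arr in (self.W_in, self.b_hidden, self.W_out):
            if not np.all(np.isfinite(arr)):
                raise DataError("model parameters must be finite")
        if not np.isfinite(self.b_out):
            raise DataError("model parameters must be finite")

    @property
    def n_inputs(self) -> int:
        return self.W_in.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W_in.shape[1]

    def copy(self) -> "MLPModel":
        return MLPModel(self.W_in.copy(), self.b_hidden.copy(), self.W_out.copy(), self.b_out, self.activation)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Outputs for a (samples, n_inputs) matrix."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_inputs:
            raise ShapeError(f"expected {self.n_inputs} inputs, got {X.shape[1]}")
        return _hidden(self, X) @ self.W_out + self.b_out

    # -- JSON round trip (debugging aid) -----------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "W_in": self.W_in.tolist(),
                "b_hidden": self.b_hidden.tolist(),
                "W_out": self.W_out.tolist(),
                "b_out": self.b_out,
                "activation": self.activation,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MLPModel":
        d = json.loads(text)
        return cls(
            np.asarray(d["W_in"]), np.asarray(d["b_hidden"]),
            np.asarray(d["W_out"]), d["b_out"], d["activation"],
        )


@dataclass
class TrainResult:
    """Outcome of :func:`train_mlp`: best-validation snapshot plus histories."""

    model: MLPModel
    train_loss_history: list[float] = field(default_factory=list)
    val_loss_history: list[float] = field(default_factory=list)
    stopped_epoch: int = 0


def _hidden(model: MLPModel, X: np.ndarray) -> np.ndarray:
    pre = X @ model.W_in + model.b_hidden
    return np.tanh(pre) if model.activation == "tanh" else pre


def init_mlp(n_inputs: int, config: TrainConfig) -> MLPModel:
    """Uniform ``[-init_scale, +init_scale]`` weights under ``config.seed``; zero biases."""
    if n_inputs < 1:
        raise ShapeError("n_inputs must be >= 1")
    rng = np.random.default_rng(config.seed)
    s = config.init_scale
    return MLPModel(
        W_in=rng.uniform(-s, s, size=(n_inputs, config.n_hidden)),
        b_hidden=np.zeros(config.n_hidden),
        W_out=rng.uniform(-s, s, size=config.n_hidden),
        b_out=0.0,
        activation=config.activation,
    )


def forward(model: MLPModel, x: np.ndarray) -> float:
    """Scalar network output ``W_out . act(W_in^T x + b_hidden) + b_out``."""
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != model.n_inputs:
        raise ShapeError(f"expected input of length {model.n_inputs}, got {x.shape[0]}")
    return float(model.predict(x[None, :])[0])


def _mse(model: MLPModel, X: np.ndarray, y: np.ndarray) -> float:
    r = model.predict(X) - y
    return float(np.mean(r * r))


def train_mlp(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: TrainConfig,
    initial_model: MLPModel | None = None,
) -> TrainResult:
    """Fit by full-batch gradient descent with momentum, L2 and early stopping.

    The objective is ``MSE + l2_penalty * (|W_in|^2 + |W_out|^2)``; biases are
    unpenalized. Each epoch the current parameters are evaluated (train
    objective and plain validation MSE are appended to the histories, and the
    best-validation parameters are snapshotted) before one gradient step.
    Training stops once validation MSE has failed to improve for ``patience``
    consecutive epochs, or at ``max_epochs``. The returned model is the
    snapshot from the epoch of minimum validation MSE (the final-epoch
    parameters when ``early_stopping`` is off). ``initial_model`` overrides
    the default seeded initialization (used by the swarm to key initial
    weights to gene identities; also handy for warm starts).

    Raises
    ------
    DataError
        On non-finite inputs or empty splits.
    TrainingDivergenceError
        If the training loss becomes non-finite; names the epoch.
    """
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    X_val = np.atleast_2d(np.asarray(X_val, dtype=float))
    y_train = np.asarray(y_train, dtype=float).ravel()
    y_val = np.asarray(y_val, dtype=float).ravel()
    if X_train.shape[0] < 1 or X_val.shape[0] < 1:
        raise DataError("need at least one training and one validation sample")
    if X_train.shape[1] != X_val.shape[1]:
        raise ShapeError("train and validation matrices have different input counts")
    if X_train.shape[0] != y_train.shape[0] or X_val.shape[0] != y_val.shape[0]:
        raise ShapeError("target length does not match sample count")
    for arr in (X_train, y_train, X_val, y_val):
        if not np.all(np.isfinite(arr)):
            raise DataError("training data contain non-finite values")

    if initial_model is None:
        model = init_mlp(X_train.shape[1], config)
    else:
        if initial_model.n_inputs != X_train.shape[1]:
            raise ShapeError("initial_model input count does not match the data")
        model = initial_model.copy()
    lam, lr, mom = config.l2_penalty, config.learning_rate, config.momentum
    n = X_train.shape[0]
    vel = [np.zeros_like(model.W_in), np.zeros_like(model.b_hidden),
           np.zeros_like(model.W_out), 0.0]

    best_val = np.inf
    best_model = model.copy()
    since_improve = 0
    train_hist: list[float] = []
    val_hist: list[float] = []
    stopped = config.max_epochs

    for epoch in range(config.max_epochs + 1):
        # overflow here is the divergence signal, caught explicitly below
        with np.errstate(over="ignore", invalid="ignore"):
            train_mse = _mse(model, X_train, y_train)
            train_loss = train_mse + lam * (np.sum(model.W_in**2) + np.sum(model.W_out**2))
            val_mse = _mse(model, X_val, y_val)
        if not np.isfinite(train_loss):
            raise TrainingDivergenceError(epoch)
        train_hist.append(float(train_loss))
        val_hist.append(float(val_mse))
        if val_mse < best_val:
            best_val = val_mse
            best_model = model.copy()
            since_improve = 0
        else:
            since_improve += 1
            if config.early_stopping and since_improve >= config.patience:
                stopped = epoch
                break
        if epoch == config.max_epochs:
            stopped = epoch
            break

        # Backpropagation on the full batch.
        pre = X_train @ model.W_in + model.b_hidden
        H = np.tanh(pre) if model.activation == "tanh" else pre
        resid = (H @ model.W_out + model.b_out) - y_train
        d_out = 2.0 * resid / n  # d(MSE)/d(yhat)
        g_Wout = H.T @ d_out + 2.0 * lam * model.W_out
        g_bout = float(np.sum(d_out))
        dH = np.outer(d_out, model.W_out)
        d_pre = dH * (1.0 - H * H) if model.activation == "tanh" else dH
        g_Win = X_train.T @ d_pre + 2.0 * lam * model.W_in
        g_bh = d_pre.sum(axis=0)

        vel[0] = mom * vel[0] - lr * g_Win
        vel[1] = mom * vel[1] - lr * g_bh
        vel[2] = mom * vel[2] - lr * g_Wout
        vel[3] = mom * vel[3] - lr * g_bout
        model.W_in = model.W_in + vel[0]
        model.b_hidden = model.b_hidden + vel[1]
        model.W_out = model.W_out + vel[2]
        model.b_out = model.b_out + vel[3]

    return TrainResult(
        model=best_model if config.early_stopping else model,
        train_loss_history=train_hist,
        val_loss_history=val_hist,
        stopped_epoch=stopped,
    )


def linearized_influence(model: MLPModel, X_ref: np.ndarray) -> np.ndarray:
    """Signed per-input influence: output gradient averaged over ``X_ref`` rows.

    For input i this is ``mean_s d f(x_s) / d x_i``. With a linear activation
    the gradient is constant and equals ``sum_h W_in[i, h] * W_out[h]``; with
    tanh it depends on where the network is evaluated, hence the reference
    matrix (typically the training inputs).
    """
    X_ref = np.atleast_2d(np.asarray(X_ref, dtype=float))
    if X_ref.size == 0:
        raise DataError("X_ref must be non-empty")
    if X_ref.shape[1] != model.n_inputs:
        raise ShapeError(f"expected {model.n_inputs} inputs, got {X_ref.shape[1]}")
    if model.activation == "linear":
        return model.W_in @ model.W_out
    H = _hidden(model, X_ref)
    # d f / d x = W_in @ (W_out * (1 - h^2)) per sample; average over samples.
    S = (1.0 - H * H) * model.W_out
    return (S @ model.W_in.T).mean(axis=0)


def standardize_train_val(
    X_train: np.ndarray, X_val: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-column z-scoring with statistics from the training split only.

    Returns ``(Z_train, Z_val, mean, sd)``; columns that are constant on the
    training split get sd 1 so they pass through centred but unscaled.
    """
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    X_val = np.atleast_2d(np.asarray(X_val, dtype=float))
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X_train - mu) / sd, (X_val - mu) / sd, mu, sd
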