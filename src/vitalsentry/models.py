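"""Reconstruction models: 3-layer GRU autoencoder and feedforward baseline.

The GRU-AE stacks three GRU layers in an encode/decode shape (default
128 → 32 → 128 hidden units) over the hourly multichannel signal, followed by
a fully connected sigmoid head mapping the last hidden state back to the
input channel count:

    h¹_t = g¹(x_t, h¹_{t−1});  h²_t = g²(h¹_t, h²_{t−1});  h³_t = g³(h²_t, h³_{t−1})
    y_t  = σ(W_y h³_t + b_y)

Training minimises the summed per-timestep reconstruction loss
Loss_t = ½‖y_t − x_t‖², on healthy data only; at monitoring time Loss_t is
the anomaly score.  The feedforward baseline applies a per-sample
2 → 128 → 32 → 128 → 2 sigmoid stack with squared-error loss and, having no
state, is blind to when in the day a sample occurs — the asymmetry the
comparison is designed to expose.

Both models are scikit-learn style estimators (``fit`` / ``score_samples``,
``get_params``) and train with seeded mini-batch Adam by default (plain
gradient descent available via ``optimizer="sgd"``; the learning-rate and
epoch defaults are 0.01 and 4000).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator

from .exceptions import ConfigurationError, ShapeError, TrainingError
from .gru import GruLayerParams, gru_layer_backward, gru_layer_forward_batch
from .preprocessing import WindowBatch

_PLAUSIBLE_BAND = (-1.0, 2.0)  # normalized units; exceeded only by gross outliers


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class GruAeParams:
    """All weights of the stacked GRU-AE: three GRU layers plus the head."""

    layers: list[GruLayerParams]
    Wy: np.ndarray  # (n_channels, hidden3)
    by: np.ndarray  # (n_channels,)

    def __post_init__(self) -> None:
        for lo, hi in zip(self.layers[:-1], self.layers[1:]):
            if hi.input_size != lo.hidden_size:
                raise ShapeError(
                    f"layer chain broken: {lo.hidden_size} -> input {hi.input_size}"
                )
        if self.Wy.shape[1] != self.layers[-1].hidden_size:
            raise ShapeError("Wy columns must match last hidden size")
        if self.by.shape != (self.Wy.shape[0],):
            raise ShapeError("by must match Wy rows")

    @property
    def n_channels(self) -> int:
        return self.Wy.shape[0]

    def arrays(self) -> list[np.ndarray]:
        out = []
        for lp in self.layers:
            out.extend([lp.Wu, lp.Wr, lp.W, lp.Uu, lp.Ur, lp.U])
        out.extend([self.Wy, self.by])
        return out


@dataclass
class AeParams:
    """Feedforward autoencoder weights: per-layer (W, b) with sigmoid units."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    def arrays(self) -> list[np.ndarray]:
        return [*self.weights, *self.biases]


@dataclass
class TrainConfig:
    """Optimization settings (defaults: learning rate 0.01, 4000 epochs)."""

    learning_rate: float = 0.01
    epochs: int = 4000
    optimizer: str = "adam"
    batch_size: int = 64
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.optimizer not in ("adam", "sgd"):
            raise ConfigurationError("optimizer must be 'adam' or 'sgd'")


@dataclass
class LossTrace:
    """Per-timestep reconstruction losses aligned to the scored sequence."""

    per_timestep: np.ndarray
    hour_index: np.ndarray | None = None

    @property
    def total(self) -> float:
        return float(self.per_timestep.sum())


def reconstruction_loss(x: np.ndarray, y: np.ndarray) -> LossTrace:
    """Loss_t = ½ Σ_channels (y_t − x_t)², summed over channels per timestep."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ShapeError(f"shape mismatch: {x.shape} vs {y.shape}")
    per_t = 0.5 * np.sum((y - x) ** 2, axis=-1)
    return LossTrace(per_timestep=np.atleast_1d(per_t))


# ---------------------------------------------------------------------------
# optimizers


class _Adam:
    def __init__(self, arrays, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.arrays = arrays
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for a, g, m, v in zip(self.arrays, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            a -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class _Sgd:
    def __init__(self, arrays, lr):
        self.arrays, self.lr = arrays, lr

    def step(self, grads):
        for a, g in zip(self.arrays, grads):
            a -= self.lr * g


def _make_optimizer(name, arrays, lr):
    return _Adam(arrays, lr) if name == "adam" else _Sgd(arrays, lr)


# ---------------------------------------------------------------------------
# GRU-AE forward / backward over the full stack


def _stack_forward(X, params: GruAeParams, states=None, need_cache=False):
    """Returns (Y, H3, new_states, caches); X is (B, T, C)."""
    inp = X
    caches, new_states = [], []
    for i, lp in enumerate(params.layers):
        h0 = None if states is None else states[i]
        H, h_last, cache = gru_layer_forward_batch(inp, lp, h0, need_cache)
        caches.append(cache)
        new_states.append(h_last)
        inp = H
    B, T, h3 = inp.shape
    A = inp.reshape(B * T, h3) @ params.Wy.T + params.by
    Y = expit(A).reshape(B, T, params.n_channels)
    return Y, inp, new_states, caches


def _stack_backward(X, Y, H3, caches, params: GruAeParams):
    """Gradient of Σ_t ½‖y_t − x_t‖² w.r.t. every weight; returns array list."""
    B, T, C = X.shape
    dtype = params.Wy.dtype
    dY = (Y - X).astype(dtype)
    dA = dY * Y * (1.0 - Y)  # sigmoid head
    dAf = dA.reshape(B * T, C)
    H3f = H3.reshape(B * T, -1)
    dWy = dAf.T @ H3f
    dby = dAf.sum(axis=0)
    dH = (dAf @ params.Wy).reshape(B, T, -1)
    layer_grads = [None, None, None]
    for i in (2, 1, 0):
        grads, dX, _ = gru_layer_backward(caches[i], params.layers[i], dH)
        layer_grads[i] = grads
        dH = dX
    out = []
    for g in layer_grads:
        out.extend([g.Wu, g.Wr, g.W, g.Uu, g.Ur, g.U])
    out.extend([dWy, dby])
    return out


def _init_gru_ae(n_channels, hidden_sizes, rng, dtype) -> GruAeParams:
    sizes = [n_channels, *hidden_sizes]
    layers = [
        GruLayerParams.init(sizes[i], sizes[i + 1], rng, dtype=dtype)
        for i in range(len(hidden_sizes))
    ]
    s = np.sqrt(1.0 / hidden_sizes[-1])
    Wy = rng.uniform(-s, s, (n_channels, hidden_sizes[-1])).astype(dtype)
    by = np.zeros(n_channels, dtype=dtype)
    return GruAeParams(layers=layers, Wy=Wy, by=by)


def _check_band(X):
    if X.size and (X.min() < _PLAUSIBLE_BAND[0] or X.max() > _PLAUSIBLE_BAND[1]):
        warnings.warn(
            "input values outside the plausible normalized band (-1, 2); "
            "was the scaler fitted on training data?",
            stacklevel=3,
        )


class GruAutoencoder(BaseEstimator):
    """Recurrent autoencoder scoring each hour by reconstruction loss.

    Parameters
    ----------
    hidden_sizes : encode/decode hidden widths, default (128, 32, 128).
    learning_rate, n_epochs : optimization defaults 0.01 / 4000.
    optimizer : "adam" (default) or "sgd" (literal fixed-rate descent).
    batch_size : windows per update (None = full batch).
    random_state : seeds both initialization and batch shuffling.
    dtype : training precision; "float32" default, use "float64" for
        gradient-check work.

    Attributes
    ----------
    params_ : GruAeParams — fitted weights.
    loss_history_ : per-epoch mean per-timestep loss.
    n_channels_ : input channel count seen in fit.
    """

    def __init__(
        self,
        hidden_sizes=(128, 32, 128),
        learning_rate=0.01,
        n_epochs=4000,
        optimizer="adam",
        batch_size=64,
        shuffle=True,
        random_state=0,
        dtype="float32",
        verbose=0,
    ):
        self.hidden_sizes = hidden_sizes
        self.learning_rate = learning_rate
        self.n_epochs = n_epochs
        self.optimizer = optimizer
        self.batch_size = batch_size
        self.shuffle = shuffle
        self.random_state = random_state
        self.dtype = dtype
        self.verbose = verbose

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y=None):
        """Fit on healthy windows, X of shape (n_windows, T, n_channels)."""
        X = self._as_windows(X)
        cfg = TrainConfig(
            learning_rate=self.learning_rate,
            epochs=self.n_epochs,
            optimizer=self.optimizer,
            batch_size=self.batch_size or len(X),
            seed=self.random_state,
        )
        cfg.validate()
        dtype = np.dtype(self.dtype)
        rng = np.random.default_rng(self.random_state)
        self.n_channels_ = X.shape[2]
        self.params_ = _init_gru_ae(self.n_channels_, tuple(self.hidden_sizes), rng, dtype)
        opt = _make_optimizer(cfg.optimizer, self.params_.arrays(), cfg.learning_rate)
        Xd = X.astype(dtype)
        n = len(Xd)
        bs = min(cfg.batch_size, n)
        self.loss_history_ = []
        for epoch in range(cfg.epochs):
            order = rng.permutation(n) if self.shuffle else np.arange(n)
            total = 0.0
            for lo in range(0, n, bs):
                idx = order[lo : lo + bs]
                xb = Xd[idx]
                Y, H3, _, caches = _stack_forward(xb, self.params_, need_cache=True)
                total += float(0.5 * np.sum((Y.astype(np.float64) - xb) ** 2))
                grads = _stack_backward(xb, Y, H3, caches, self.params_)
                opt.step(grads)
            mean_loss = total / (n * X.shape[1])
            if not np.isfinite(mean_loss):
                raise TrainingError(
                    "training diverged (non-finite loss); try a smaller learning rate"
                )
            self.loss_history_.append(mean_loss)
            if self.verbose and (epoch % max(1, cfg.epochs // 20) == 0):
                print(f"epoch {epoch}: mean per-timestep loss {mean_loss:.6f}")
        return self

    def reconstruct(self, X, states=None):
        """Reconstruction of (n, T, C) windows (or one (T, C) series).

        Inference runs in float64 whatever the training dtype, so hour-by-hour
        streaming and whole-sequence scoring agree to machine precision.
        """
        single = np.asarray(X).ndim == 2
        Xb = self._as_windows(X)
        _check_band(Xb)
        p = self._inference_params()
        Y, _, new_states, _ = _stack_forward(Xb.astype(np.float64), p, states)
        return (Y[0], new_states) if single else (Y, new_states)

    def _inference_params(self) -> GruAeParams:
        if self.params_.Wy.dtype == np.float64:
            return self.params_
        cached = getattr(self, "_params64", None)
        if cached is None or cached[0] is not self.params_:
            p64 = GruAeParams(
                layers=[lp.astype(np.float64) for lp in self.params_.layers],
                Wy=self.params_.Wy.astype(np.float64),
                by=self.params_.by.astype(np.float64),
            )
            self._params64 = (self.params_, p64)
            cached = self._params64
        return cached[1]

    def score_samples(self, X):
        """Per-timestep reconstruction loss, shape (n, T) (or (T,) for one series)."""
        single = np.asarray(X).ndim == 2
        Xb = self._as_windows(X)
        Y, _ = self.reconstruct(Xb)
        per_t = 0.5 * np.sum((Y.astype(np.float64) - Xb) ** 2, axis=-1)
        return per_t[0] if single else per_t

    def forward_stream(self, x_t, states=None):
        """Advance one hour: x_t is (C,); returns (y_t, new_states)."""
        x = np.asarray(x_t, dtype=float)
        Y, new_states = self.reconstruct(x[None, :], states)
        return Y[0], new_states

    def _as_windows(self, X):
        if isinstance(X, WindowBatch):
            X = X.windows
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        if X.ndim != 3:
            raise ShapeError("X must be (n_windows, T, n_channels)")
        if hasattr(self, "n_channels_") and X.shape[2] != self.n_channels_:
            raise ShapeError(
                f"expected {self.n_channels_} channels, got {X.shape[2]}"
            )
        return X


# ---------------------------------------------------------------------------
# feedforward baseline


def _ae_forward_cached(X, params: AeParams):
    acts = [X]
    a = X
    for W, b in zip(params.weights, params.biases):
        a = expit(a @ W.T + b)
        acts.append(a)
    return a, acts


def ae_forward(x, params: AeParams):
    """Memoryless per-sample reconstruction through the sigmoid stack."""
    x = np.asarray(x, dtype=params.weights[0].dtype)
    single = x.ndim == 1
    y, _ = _ae_forward_cached(np.atleast_2d(x), params)
    return y[0] if single else y


def _ae_backward(X, acts, params: AeParams):
    """Gradient of Σ_samples ‖x − x′‖² (squared-error training objective)."""
    y = acts[-1]
    delta = 2.0 * (y - X)
    gW, gb = [], []
    for i in range(len(params.weights) - 1, -1, -1):
        a = acts[i + 1]
        da = delta * a * (1.0 - a)
        gW.append(da.T @ acts[i])
        gb.append(da.sum(axis=0))
        delta = da @ params.weights[i]
    return [*gW[::-1], *gb[::-1]]


class Autoencoder(BaseEstimator):
    """Per-sample feedforward autoencoder baseline (2 → 128 → 32 → 128 → 2).

    Scores each hourly sample independently of its neighbours; shares the
    training defaults of :class:`GruAutoencoder`.
    """

    def __init__(
        self,
        hidden_sizes=(128, 32, 128),
        learning_rate=0.01,
        n_epochs=4000,
        optimizer="adam",
        batch_size=64,
        shuffle=True,
        random_state=0,
        dtype="float32",
        verbose=0,
    ):
        self.hidden_sizes = hidden_sizes
        self.learning_rate = learning_rate
        self.n_epochs = n_epochs
        self.optimizer = optimizer
        self.batch_size = batch_size
        self.shuffle = shuffle
        self.random_state = random_state
        self.dtype = dtype
        self.verbose = verbose

    def fit(self, X, y=None):
        """Fit on healthy samples, X of shape (n_samples, n_channels)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:  # accept windowed input; the model is per-sample anyway
            X = X.reshape(-1, X.shape[-1])
        cfg = TrainConfig(
            learning_rate=self.learning_rate,
            epochs=self.n_epochs,
            optimizer=self.optimizer,
            batch_size=self.batch_size or len(X),
            seed=self.random_state,
        )
        cfg.validate()
        dtype = np.dtype(self.dtype)
        rng = np.random.default_rng(self.random_state)
        self.n_channels_ = X.shape[1]
        sizes = [self.n_channels_, *self.hidden_sizes, self.n_channels_]
        weights, biases = [], []
        for din, dout in zip(sizes[:-1], sizes[1:]):
            s = np.sqrt(1.0 / din)
            weights.append(rng.uniform(-s, s, (dout, din)).astype(dtype))
            biases.append(np.zeros(dout, dtype=dtype))
        self.params_ = AeParams(weights=weights, biases=biases)
        opt = _make_optimizer(cfg.optimizer, self.params_.arrays(), cfg.learning_rate)
        Xd = X.astype(dtype)
        n = len(Xd)
        bs = min(cfg.batch_size, n)
        self.loss_history_ = []
        for epoch in range(cfg.epochs):
            order = rng.permutation(n) if self.shuffle else np.arange(n)
            total = 0.0
            for lo in range(0, n, bs):
                xb = Xd[order[lo : lo + bs]]
                y, acts = _ae_forward_cached(xb, self.params_)
                total += float(np.sum((y.astype(np.float64) - xb) ** 2))
                opt.step(_ae_backward(xb, acts, self.params_))
            mean_loss = total / n
            if not np.isfinite(mean_loss):
                raise TrainingError(
                    "training diverged (non-finite loss); try a smaller learning rate"
                )
            self.loss_history_.append(mean_loss)
        return self

    def reconstruct(self, X):
        X = np.asarray(X, dtype=float)
        _check_band(X)
        return ae_forward(X, self.params_)

    def score_samples(self, X):
        """Per-sample loss ½‖x − x′‖² (same scale as the GRU-AE hourly score)."""
        X = np.asarray(X, dtype=float)
        shp = X.shape
        flat = X.reshape(-1, shp[-1])
        y = self.reconstruct(flat)
        per = 0.5 * np.sum((y.astype(np.float64) - flat) ** 2, axis=-1)
        return per.reshape(shp[:-1])


# ---------------------------------------------------------------------------
# functional wrappers


def gru_ae_forward(window, params: GruAeParams, states=None):
    """Forward one (T, C) normalized segment; returns (y sequence, states)."""
    X = np.asarray(window, dtype=params.Wy.dtype)
    _check_band(X)
    Y, _, new_states, _ = _stack_forward(X[None], params, states)
    return Y[0], new_states


def train_gru_ae(train_windows, config: TrainConfig | None = None):
    """Train a GRU-AE; returns (GruAeParams, per-epoch loss history)."""
    cfg = config or TrainConfig()
    cfg.validate()
    est = GruAutoencoder(
        learning_rate=cfg.learning_rate,
        n_epochs=cfg.epochs,
        optimizer=cfg.optimizer,
        batch_size=cfg.batch_size,
        random_state=cfg.seed,
    ).fit(train_windows)
    return est.params_, est.loss_history_


def train_ae(train_samples, config: TrainConfig | None = None):
    """Train the feedforward baseline; returns (AeParams, loss history)."""
    cfg = config or TrainConfig()
    cfg.validate()
    est = Autoencoder(
        learning_rate=cfg.learning_rate,
        n_epochs=cfg.epochs,
        optimizer=cfg.optimizer,
        batch_size=cfg.batch_size,
        random_state=cfg.seed,
    ).fit(train_samples)
    return est.params_, est.loss_history_
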