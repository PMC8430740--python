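"""Gated recurrent unit: cell step, layer forward pass, and exact gradients.

The gate equations used here carry no bias terms:

    u_t = σ(W_u x_t + U_u h_{t−1})          (update gate)
    r_t = σ(W_r x_t + U_r h_{t−1})          (reset gate)
    h̃_t = tanh(W x_t + r_t ⊙ (U h_{t−1}))   (candidate memory)
    h_t = u_t ⊙ h_{t−1} + (1 − u_t) ⊙ h̃_t

With h_0 = 0 every hidden component stays in (−1, 1): each update is a convex
combination of the previous state and a tanh output.

Gradients are computed by backpropagation through time, written so the
input-side weight gradients and the input gradients collapse into single
large matrix products over all timesteps; only the hidden-to-hidden terms
stay inside the time loop.  Correctness is pinned by finite-difference tests,
not by the derivation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .exceptions import ShapeError, TrainingError


@dataclass
class GruLayerParams:
    """The six weight matrices of one GRU layer (no gate biases).

    W* are (hidden, input) input-to-hidden maps, U* are (hidden, hidden)
    hidden-to-hidden maps, for the update gate (Wu, Uu), reset gate (Wr, Ur)
    and candidate memory (W, U).
    """

    Wu: np.ndarray
    Wr: np.ndarray
    W: np.ndarray
    Uu: np.ndarray
    Ur: np.ndarray
    U: np.ndarray

    def __post_init__(self) -> None:
        h, d = self.Wu.shape
        for name in ("Wr", "W"):
            if getattr(self, name).shape != (h, d):
                raise ShapeError(f"{name} must have shape {(h, d)}")
        for name in ("Uu", "Ur", "U"):
            if getattr(self, name).shape != (h, h):
                raise ShapeError(f"{name} must have shape {(h, h)}")
        for name in ("Wu", "Wr", "W", "Uu", "Ur", "U"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ShapeError(f"{name} contains non-finite values")

    @property
    def hidden_size(self) -> int:
        return self.Wu.shape[0]

    @property
    def input_size(self) -> int:
        return self.Wu.shape[1]

    @classmethod
    def init(
        cls,
        input_size: int,
        hidden_size: int,
        rng: np.random.Generator,
        dtype=np.float64,
    ) -> "GruLayerParams":
        """Uniform init in ±sqrt(1/hidden_size)."""
        s = np.sqrt(1.0 / hidden_size)

        def m(rows, cols):
            return rng.uniform(-s, s, (rows, cols)).astype(dtype)

        return cls(
            Wu=m(hidden_size, input_size),
            Wr=m(hidden_size, input_size),
            W=m(hidden_size, input_size),
            Uu=m(hidden_size, hidden_size),
            Ur=m(hidden_size, hidden_size),
            U=m(hidden_size, hidden_size),
        )

    def zeros_like(self) -> "GruLayerParams":
        return GruLayerParams(*(np.zeros_like(getattr(self, n)) for n in _FIELDS))

    def astype(self, dtype) -> "GruLayerParams":
        return GruLayerParams(*(getattr(self, n).astype(dtype) for n in _FIELDS))


_FIELDS = ("Wu", "Wr", "W", "Uu", "Ur", "U")


def gru_cell_step(
    x_t: np.ndarray, h_prev: np.ndarray, params: GruLayerParams
) -> np.ndarray:
    """One GRU update; accepts a single vector or a (batch, dim) array."""
    x_t = np.asarray(x_t, dtype=float)
    h_prev = np.asarray(h_prev, dtype=float)
    if x_t.shape[-1] != params.input_size or h_prev.shape[-1] != params.hidden_size:
        raise ShapeError(
            f"expected input {params.input_size}, hidden {params.hidden_size}; "
            f"got x {x_t.shape}, h {h_prev.shape}"
        )
    u = expit(x_t @ params.Wu.T + h_prev @ params.Uu.T)
    r = expit(x_t @ params.Wr.T + h_prev @ params.Ur.T)
    c = np.tanh(x_t @ params.W.T + r * (h_prev @ params.U.T))
    return u * h_prev + (1.0 - u) * c


@dataclass
class _LayerCache:
    X: np.ndarray        # (B, T, in)
    H_prev: np.ndarray   # (B, T, h) — h_{t−1} for each t
    U_gate: np.ndarray   # (B, T, h)
    R_gate: np.ndarray   # (B, T, h)
    C: np.ndarray        # (B, T, h)
    HU: np.ndarray       # (B, T, h) — U·h_{t−1}


def gru_layer_forward_batch(
    X: np.ndarray,
    params: GruLayerParams,
    h0: np.ndarray | None = None,
    need_cache: bool = False,
):
    """Run one GRU layer over (B, T, input); returns (H, h_last, cache).

    Input-side products for all timesteps are computed as one matrix product;
    the time loop carries only the hidden-to-hidden terms.
    """
    B, T, d = X.shape
    h = params.hidden_size
    dtype = params.Wu.dtype
    if d != params.input_size:
        raise ShapeError(f"input size {d} != expected {params.input_size}")
    Wall = np.vstack([params.Wu, params.Wr, params.W])  # (3h, d)
    Gx = X.reshape(B * T, d) @ Wall.T
    Gx = Gx.reshape(B, T, 3 * h)
    Uur = np.vstack([params.Uu, params.Ur])  # (2h, h)

    ht = np.zeros((B, h), dtype=dtype) if h0 is None else np.asarray(h0, dtype=dtype)
    if ht.shape != (B, h):
        raise ShapeError(f"h0 must have shape {(B, h)}")
    H = np.empty((B, T, h), dtype=dtype)
    cache = (
        _LayerCache(
            X=X,
            H_prev=np.empty((B, T, h), dtype=dtype),
            U_gate=np.empty((B, T, h), dtype=dtype),
            R_gate=np.empty((B, T, h), dtype=dtype),
            C=np.empty((B, T, h), dtype=dtype),
            HU=np.empty((B, T, h), dtype=dtype),
        )
        if need_cache
        else None
    )
    for t in range(T):
        g = ht @ Uur.T
        u = expit(Gx[:, t, :h] + g[:, :h])
        r = expit(Gx[:, t, h : 2 * h] + g[:, h:])
        hU = ht @ params.U.T
        c = np.tanh(Gx[:, t, 2 * h :] + r * hU)
        if cache is not None:
            cache.H_prev[:, t] = ht
            cache.U_gate[:, t] = u
            cache.R_gate[:, t] = r
            cache.C[:, t] = c
            cache.HU[:, t] = hU
        ht = u * ht + (1.0 - u) * c
        H[:, t] = ht
    return H, ht, cache


def gru_layer_forward(
    sequence: np.ndarray, params: GruLayerParams, h0: np.ndarray | None = None
):
    """Hidden-state sequence for a single (T, input) series; returns (H, h_last)."""
    X = np.asarray(sequence, dtype=params.Wu.dtype)
    if X.ndim != 2:
        raise ShapeError("sequence must be (T, input_size)")
    h0b = None if h0 is None else np.asarray(h0, dtype=params.Wu.dtype)[None, :]
    H, hl, _ = gru_layer_forward_batch(X[None], params, h0b)
    return H[0], hl[0]


def gru_layer_backward(
    cache: _LayerCache,
    params: GruLayerParams,
    dH: np.ndarray,
    dh_last: np.ndarray | None = None,
):
    """BPTT through one layer.

    dH holds ∂loss/∂h_t from the layer's consumers at every t (in addition to
    the recurrence); ``dh_last`` adds a gradient flowing into the final state.
    Returns (grads: GruLayerParams, dX, dh0).
    """
    B, T, h = dH.shape
    dtype = params.Wu.dtype
    DA = np.empty((B, T, 3 * h), dtype=dtype)   # (dau, dar, dac): input-side
    DR = np.empty((B, T, 3 * h), dtype=dtype)   # (dau, dar, dac⊙r): hidden-side
    dh_next = (
        np.zeros((B, h), dtype=dtype) if dh_last is None else dh_last.astype(dtype)
    )
    for t in range(T - 1, -1, -1):
        dh = dH[:, t] + dh_next
        h_prev = cache.H_prev[:, t]
        u = cache.U_gate[:, t]
        r = cache.R_gate[:, t]
        c = cache.C[:, t]
        dau = dh * (h_prev - c) * u * (1.0 - u)
        dac = dh * (1.0 - u) * (1.0 - c * c)
        dar = dac * cache.HU[:, t] * r * (1.0 - r)
        dacr = dac * r
        DA[:, t, :h] = dau
        DA[:, t, h : 2 * h] = dar
        DA[:, t, 2 * h :] = dac
        DR[:, t, :h] = dau
        DR[:, t, h : 2 * h] = dar
        DR[:, t, 2 * h :] = dacr
        dh_next = dh * u + dau @ params.Uu + dar @ params.Ur + dacr @ params.U

    d = params.input_size
    Wall = np.vstack([params.Wu, params.Wr, params.W])          # (3h, d)
    DAf = DA.reshape(B * T, 3 * h)
    dWall = DAf.T @ cache.X.reshape(B * T, d).astype(dtype)     # (3h, d)
    dX = (DAf @ Wall).reshape(B, T, d)
    dUall = DR.reshape(B * T, 3 * h).T @ cache.H_prev.reshape(B * T, h)
    grads = GruLayerParams(
        Wu=dWall[:h],
        Wr=dWall[h : 2 * h],
        W=dWall[2 * h :],
        Uu=dUall[:h],
        Ur=dUall[h : 2 * h],
        U=dUall[2 * h :],
    )
    return grads, dX, dh_next


def gru_gradients(loss_fn, sequence: np.ndarray, params: GruLayerParams, h0=None):
    """Gradients of a scalar loss of the hidden-state sequence w.r.t. weights.

    ``loss_fn(H) -> (loss, dLoss_dH)`` maps the (T, hidden) state sequence to
    a scalar and its gradient.  Returns (loss, grads: GruLayerParams).
    """
    X = np.asarray(sequence, dtype=params.Wu.dtype)
    h0b = None if h0 is None else np.asarray(h0, dtype=params.Wu.dtype)[None, :]
    H, _, cache = gru_layer_forward_batch(X[None], params, h0b, need_cache=True)
    loss, dH = loss_fn(H[0])
    if not np.isfinite(loss):
        raise TrainingError(f"loss is non-finite: {loss}")
    grads, _, _ = gru_layer_backward(cache, params, np.asarray(dH)[None].astype(params.Wu.dtype))
    return float(loss), grads
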