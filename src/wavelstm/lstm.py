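"""LSTM cell and sequence kernels with hand-written backpropagation.

One cell step computes, for input ``x_t`` and previous state ``(h_{t-1},
C_{t-1})``, with ``[h, x]`` the concatenation:

    f_t = sigmoid(W_f [h_{t-1}, x_t] + b_f)        (forget gate)
    i_t = sigmoid(W_i [h_{t-1}, x_t] + b_i)        (input gate)
    c~_t = tanh(W_c [h_{t-1}, x_t] + b_c)          (candidate memory)
    C_t = C_{t-1} * f_t + i_t * c~_t               (memory update, elementwise)
    o_t = sigmoid(W_o [h_{t-1}, x_t] + b_o)        (output gate)
    h_t = o_t * tanh(C_t)                          (hidden output)

:func:`lstm_cell_step` exposes a single step on one sample for inspection and
testing.  Training uses the packed batched kernels below, which run a whole
minibatch through a full sequence and backpropagate a gradient arriving at the
final hidden state — the only state the sequence-to-label readout consumes.
The packed weight layout concatenates the four gates in f, i, c, o order so
each timestep costs one recurrent matrix product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit as _sigmoid  # stable on both tails

__all__ = ["LSTMParameters", "LSTMState", "GateActivations", "lstm_cell_step"]


@dataclass
class LSTMParameters:
    """Per-gate weights over the concatenation ``[h_{t-1}, x_t]`` and biases.

    Every weight matrix has shape ``(hidden, hidden + input_dim)``; every bias
    has length ``hidden``.
    """

    W_f: np.ndarray
    W_i: np.ndarray
    W_c: np.ndarray
    W_o: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_c: np.ndarray
    b_o: np.ndarray

    def __post_init__(self) -> None:
        for name in ("W_f", "W_i", "W_c", "W_o", "b_f", "b_i", "b_c", "b_o"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        shapes = {self.W_f.shape, self.W_i.shape, self.W_c.shape, self.W_o.shape}
        if len(shapes) != 1:
            raise ValueError("all gate weight matrices must share one shape")
        H = self.W_f.shape[0]
        if self.W_f.shape[1] <= H:
            raise ValueError("weight width must exceed hidden size (need input dim)")
        for b in (self.b_f, self.b_i, self.b_c, self.b_o):
            if b.shape != (H,):
                raise ValueError("bias length must equal hidden size")
        for name in ("W_f", "W_i", "W_c", "W_o", "b_f", "b_i", "b_c", "b_o"):
            if not np.isfinite(getattr(self, name)).all():
                raise ValueError(f"{name} contains non-finite entries")

    @property
    def hidden(self) -> int:
        return self.W_f.shape[0]

    @property
    def input_dim(self) -> int:
        return self.W_f.shape[1] - self.W_f.shape[0]

    @classmethod
    def initialize(
        cls,
        hidden: int,
        input_dim: int,
        rng: np.random.Generator,
        forget_bias: float = 1.0,
    ) -> "LSTMParameters":
        """Glorot-uniform weights, zero biases except forget bias (default 1).

        The positive forget bias keeps the memory path open early in training,
        the conventional stabilizer for long sequences.
        """
        width = hidden + input_dim
        limit = np.sqrt(6.0 / (hidden + width))
        def w() -> np.ndarray:
            return rng.uniform(-limit, limit, size=(hidden, width))
        z = np.zeros(hidden)
        return cls(W_f=w(), W_i=w(), W_c=w(), W_o=w(),
                   b_f=np.full(hidden, float(forget_bias)),
                   b_i=z.copy(), b_c=z.copy(), b_o=z.copy())


@dataclass
class LSTMState:
    """Hidden output ``h`` (inside (-1, 1)) and cell memory ``C``."""

    h: np.ndarray
    C: np.ndarray


@dataclass
class GateActivations:
    """Gate values of one step: f, i, o in (0, 1); candidate c~ in (-1, 1)."""

    f: np.ndarray
    i: np.ndarray
    c_tilde: np.ndarray
    o: np.ndarray


def lstm_cell_step(
    x_t: np.ndarray, prev: LSTMState, params: LSTMParameters
) -> tuple[LSTMState, GateActivations]:
    """Advance one LSTM cell step for a single sample."""
    x_t = np.atleast_1d(np.asarray(x_t, dtype=np.float64))
    if x_t.shape != (params.input_dim,):
        raise ValueError(
            f"x_t has shape {x_t.shape}, expected ({params.input_dim},)"
        )
    if prev.h.shape != (params.hidden,) or prev.C.shape != (params.hidden,):
        raise ValueError("previous state size does not match parameters")
    hx = np.concatenate([prev.h, x_t])
    f = _sigmoid(params.W_f @ hx + params.b_f)
    i = _sigmoid(params.W_i @ hx + params.b_i)
    c_tilde = np.tanh(params.W_c @ hx + params.b_c)
    C = prev.C * f + i * c_tilde
    o = _sigmoid(params.W_o @ hx + params.b_o)
    h = o * np.tanh(C)
    return LSTMState(h=h, C=C), GateActivations(f=f, i=i, c_tilde=c_tilde, o=o)


# ---------------------------------------------------------------------------
# Packed batched kernels (training fast path)
# ---------------------------------------------------------------------------

def pack_parameters(params: LSTMParameters) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split per-gate matrices into recurrent/input blocks, gates stacked
    in f, i, o, c order — the three sigmoid gates contiguous, the tanh
    candidate last, so each can be activated in a single vectorized call.

    Returns ``(Wr, Wx, b)`` with shapes ``(H, 4H)``, ``(D, 4H)``, ``(4H,)``
    laid out for right-multiplication by row-vector batches.
    """
    H = params.hidden
    Wfull = np.concatenate([params.W_f, params.W_i, params.W_o, params.W_c], axis=0)
    Wr = np.ascontiguousarray(Wfull[:, :H].T)
    Wx = np.ascontiguousarray(Wfull[:, H:].T)
    b = np.concatenate([params.b_f, params.b_i, params.b_o, params.b_c])
    return Wr, Wx, b


def unpack_gradients(
    dWr: np.ndarray, dWx: np.ndarray, db: np.ndarray, hidden: int
) -> dict[str, np.ndarray]:
    """Reassemble packed (f, i, o, c) gradients into the per-gate layout."""
    Wfull = np.concatenate([dWr.T, dWx.T], axis=1)  # (4H, H + D)
    H = hidden
    return {
        "W_f": Wfull[:H], "W_i": Wfull[H:2 * H],
        "W_o": Wfull[2 * H:3 * H], "W_c": Wfull[3 * H:],
        "b_f": db[:H], "b_i": db[H:2 * H],
        "b_o": db[2 * H:3 * H], "b_c": db[3 * H:],
    }


@dataclass
class _SequenceCache:
    """Workspace + per-timestep activations retained for backpropagation.

    One cache serves one direction of one (T, B, D) problem; reusing it
    across minibatches avoids re-faulting tens of megabytes per step.  Gate
    blocks are stored in the packed f, i, o, c order.
    """

    Xt: np.ndarray       # (T, B, D) inputs, time-major
    xz: np.ndarray       # (T, B, 4H) input contributions W_x x_t + b
    gates: np.ndarray    # (T, B, 4H) gate activations, f/i/o/c blocks
    C: np.ndarray        # (T, B, H) cell states
    TC: np.ndarray       # tanh(cell states)
    Hs: np.ndarray       # hidden states
    dZ: np.ndarray       # (T, B, 4H) backward scratch
    zbuf: np.ndarray     # (B, 4H) step scratch
    tmp: np.ndarray      # (B, H) step scratch

    @classmethod
    def allocate(cls, T: int, B: int, D: int, H: int, dtype) -> "_SequenceCache":
        return cls(
            Xt=np.empty((T, B, D), dtype=dtype),
            xz=np.empty((T, B, 4 * H), dtype=dtype),
            gates=np.empty((T, B, 4 * H), dtype=dtype),
            C=np.empty((T, B, H), dtype=dtype),
            TC=np.empty((T, B, H), dtype=dtype),
            Hs=np.empty((T, B, H), dtype=dtype),
            dZ=np.empty((T, B, 4 * H), dtype=dtype),
            zbuf=np.empty((B, 4 * H), dtype=dtype),
            tmp=np.empty((B, H), dtype=dtype),
        )

    def matches(self, T: int, B: int, D: int, H: int, dtype) -> bool:
        return self.Xt.shape == (T, B, D) and self.Xt.dtype == dtype \
            and self.gates.shape == (T, B, 4 * H)


def _sigmoid_block_into(z: np.ndarray, out: np.ndarray) -> None:
    """sigmoid(z) = (tanh(z/2) + 1) / 2 written into ``out`` (z is clobbered).

    tanh neither overflows nor produces subnormal outputs, which keeps
    single-precision training off the orders-of-magnitude-slower denormal
    arithmetic path."""
    np.multiply(z, 0.5, out=z)
    np.tanh(z, out=out)
    out += 1.0
    np.multiply(out, 0.5, out=out)


def lstm_sequence_forward(
    X: np.ndarray, Wr: np.ndarray, Wx: np.ndarray, b: np.ndarray,
    return_cache: bool = True,
    cache: _SequenceCache | None = None,
) -> tuple[np.ndarray, _SequenceCache | None]:
    """Run a batch of sequences from zero initial state; return final hidden.

    ``X`` has shape ``(batch, time, input_dim)``.  Returns ``h_T`` of shape
    ``(batch, hidden)`` and, when requested, the cache consumed by
    :func:`lstm_sequence_backward`.  Passing a previously returned ``cache``
    of matching shape reuses its buffers (and invalidates its old contents).
    """
    B, T, D = X.shape
    H = Wr.shape[0]
    dt = X.dtype
    H3 = 3 * H
    if return_cache:
        if cache is None or not cache.matches(T, B, D, H, dt):
            cache = _SequenceCache.allocate(T, B, D, H, dt)
        ws = cache
        np.copyto(ws.Xt, X.transpose(1, 0, 2))
    else:
        ws = _SequenceCache.allocate(T, B, D, H, dt)
        np.copyto(ws.Xt, X.transpose(1, 0, 2))
    np.matmul(ws.Xt.reshape(T * B, D), Wx, out=ws.xz.reshape(T * B, 4 * H))
    ws.xz += b
    h = np.zeros((B, H), dtype=dt)
    C = np.zeros((B, H), dtype=dt)
    zbuf, tmp = ws.zbuf, ws.tmp
    g_step = None if return_cache else np.empty((B, 4 * H), dtype=dt)
    tc_step = None if return_cache else np.empty((B, H), dtype=dt)
    h_step = None if return_cache else np.empty((B, H), dtype=dt)
    for t in range(T):
        np.matmul(h, Wr, out=zbuf)
        zbuf += ws.xz[t]
        if return_cache:
            g, tc, hnew = ws.gates[t], ws.TC[t], ws.Hs[t]
        else:
            g, tc, hnew = g_step, tc_step, h_step
        _sigmoid_block_into(zbuf[:, :H3], g[:, :H3])   # forget, input, output
        np.tanh(zbuf[:, H3:], out=g[:, H3:])           # candidate c~
        np.multiply(C, g[:, :H], out=C)                # C *= f
        np.multiply(g[:, H:2 * H], g[:, H3:], out=tmp)
        C += tmp                                       # C += i * c~
        np.tanh(C, out=tc)
        np.multiply(g[:, 2 * H:H3], tc, out=hnew)      # h = o * tanh(C)
        h = hnew
        if return_cache:
            ws.C[t] = C
    return h.copy(), (ws if return_cache else None)


def lstm_sequence_backward(
    dh_final: np.ndarray, cache: _SequenceCache,
    Wr: np.ndarray,
    truncation_rtol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Backpropagate a gradient at the final hidden state through all steps.

    Returns packed gradients ``(dWr, dWx, db)`` matching
    :func:`pack_parameters`.  When the backpropagated signal has decayed below
    ``truncation_rtol`` times its initial magnitude, the remaining (earlier)
    timesteps are skipped: their contributions are beneath the resolution of
    the accumulated weight gradients, and letting them underflow toward
    subnormal numbers makes the arithmetic dramatically slower.
    """
    T, B, H = cache.C.shape
    D = cache.Xt.shape[2]
    dt = cache.C.dtype
    H3 = 3 * H
    dZ = cache.dZ
    dh = dh_final.astype(dt, copy=False)
    dC = np.zeros((B, H), dtype=dt)
    cutoff = float(np.abs(dh).max()) * truncation_rtol
    t_stop = 0
    for t in range(T - 1, -1, -1):
        g = cache.gates[t]
        f, i = g[:, :H], g[:, H:2 * H]
        o, cand = g[:, 2 * H:H3], g[:, H3:]
        tc = cache.TC[t]
        do = dh * tc
        dC = dC + dh * o * (1.0 - tc * tc)
        C_prev = cache.C[t - 1] if t > 0 else 0.0
        dz = dZ[t]
        np.multiply(dC * C_prev * f, 1.0 - f, out=dz[:, :H])
        np.multiply(dC * cand * i, 1.0 - i, out=dz[:, H:2 * H])
        np.multiply(do * o, 1.0 - o, out=dz[:, 2 * H:H3])
        np.multiply(dC * i, 1.0 - cand * cand, out=dz[:, H3:])
        dh = dz @ Wr.T
        dC = dC * f
        if t > 0 and (t & 63) == 0:
            if max(np.abs(dh).max(), np.abs(dC).max()) < cutoff:
                t_stop = t
                break
    # weight gradients in large products over the retained timesteps at once
    n = (T - t_stop) * B
    dZ2 = dZ[t_stop:].reshape(n, 4 * H)
    if t_stop == 0:
        Hprev = np.concatenate(
            [np.zeros((1, B, H), dtype=dt), cache.Hs[:-1]], axis=0
        ).reshape(n, H)
    else:
        Hprev = cache.Hs[t_stop - 1:T - 1].reshape(n, H)
    dWr = Hprev.T @ dZ2
    dWx = cache.Xt[t_stop:].reshape(n, D).T @ dZ2
    db = dZ2.sum(axis=0)
    return dWr, dWx, db
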