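"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This is the numerical core under :mod:`dcan.model` and
:mod:`dcan.training`: a small define-by-run graph of :class:`Tensor` nodes
over ``numpy.ndarray`` storage, with the handful of primitives the fusion
architecture needs (batched matmul, layer normalization, masked softmax,
GELU, a fused LSTM layer with in-node backpropagation-through-time, Huber
loss) plus an AdamW optimizer with decoupled weight decay and global
gradient-norm clipping.

Coarse primitives are deliberate: one graph node per LSTM layer and per
normalization keeps graphs small enough that full training runs are
CPU-friendly. Every primitive's gradient is exercised against central
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

# ---------------------------------------------------------------------------
# graph core


class Tensor:
    """A node in the autodiff graph wrapping a floating ndarray.

    The storage dtype is preserved (float32 training halves memory
    bandwidth; float64 is used wherever gradients are checked against
    finite differences); non-floating input is promoted to float64.
    """

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        self.data = arr if arr.dtype.kind == "f" else arr.astype(float)
        self.grad: np.ndarray | None = None
        self.parents: tuple[Tensor, ...] = ()
        self._backward = None
        self.requires_grad = bool(requires_grad)

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(self, other)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -np.asarray(other))

    def __neg__(self):
        return mul(self, -1.0)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def backward(self):
        """Reverse pass from this (scalar) node through the graph."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    live = tuple(p for p in parents if isinstance(p, Tensor))
    if any(p.requires_grad or p.parents for p in live):
        out.parents = live
        out._backward = backward
        out.requires_grad = True
    return out


def _accum(t: Tensor, g) -> None:
    if not (t.requires_grad or t.parents):
        return
    if t.grad is None:
        t.grad = np.array(np.broadcast_to(g, t.data.shape), dtype=t.data.dtype)
    else:
        t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient ``g`` back down to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _as_array(x):
    if isinstance(x, Tensor):
        return x.data
    if isinstance(x, (int, float)):
        return x  # python scalars are dtype-neutral under numpy promotion
    arr = np.asarray(x)
    return arr if arr.dtype.kind == "f" else arr.astype(float)


# ---------------------------------------------------------------------------
# elementwise / structural primitives


def add(a, b):
    av, bv = _as_array(a), _as_array(b)
    out_data = av + bv

    def backward(g):
        if isinstance(a, Tensor):
            _accum(a, _unbroadcast(g, av.shape))
        if isinstance(b, Tensor):
            _accum(b, _unbroadcast(g, bv.shape))

    return _node(out_data, (a, b), backward)


def mul(a, b):
    av, bv = _as_array(a), _as_array(b)
    out_data = av * bv

    def backward(g):
        if isinstance(a, Tensor):
            _accum(a, _unbroadcast(g * bv, av.shape))
        if isinstance(b, Tensor):
            _accum(b, _unbroadcast(g * av, bv.shape))

    return _node(out_data, (a, b), backward)


def matmul(a, b):
    av, bv = _as_array(a), _as_array(b)
    out_data = av @ bv

    def backward(g):
        if isinstance(a, Tensor):
            ga = g @ np.swapaxes(bv, -1, -2)
            _accum(a, _unbroadcast(ga, av.shape))
        if isinstance(b, Tensor):
            if bv.ndim == 2 and av.ndim > 2:
                # batched-input @ shared-weight: contract leading axes directly
                axes = list(range(av.ndim - 1))
                gb = np.tensordot(av, g, axes=(axes, axes))
            else:
                gb = _unbroadcast(np.swapaxes(av, -1, -2) @ g, bv.shape)
            _accum(b, gb)

    return _node(out_data, (a, b), backward)


def reshape(a, shape):
    av = _as_array(a)

    def backward(g):
        _accum(a, g.reshape(av.shape))

    return _node(av.reshape(shape), (a,), backward)


def transpose(a, axes):
    av = _as_array(a)
    inv = np.argsort(axes)

    def backward(g):
        _accum(a, g.transpose(inv))

    return _node(av.transpose(axes), (a,), backward)


def getitem(a, idx):
    av = _as_array(a)

    def backward(g):
        full = np.zeros_like(av)
        np.add.at(full, idx, g)
        _accum(a, full)

    return _node(av[idx], (a,), backward)


def concat(tensors, axis=-1):
    arrays = [_as_array(t) for t in tensors]
    sizes = [arr.shape[axis] for arr in arrays]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if isinstance(t, Tensor):
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                _accum(t, g[tuple(sl)])

    return _node(np.concatenate(arrays, axis=axis), tuple(tensors), backward)


def sum_(a, axis=None, keepdims=False):
    av = _as_array(a)

    def backward(g):
        if axis is None:
            _accum(a, np.full_like(av, g))
            return
        gg = g if keepdims else np.expand_dims(g, axis)
        _accum(a, np.broadcast_to(gg, av.shape).copy())

    return _node(av.sum(axis=axis, keepdims=keepdims), (a,), backward)


def mean_(a, axis=None, keepdims=False):
    av = _as_array(a)
    n = av.size if axis is None else av.shape[axis]
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / n)


_SQRT_2PI = float(np.sqrt(2.0 * np.pi))
_SQRT_2 = float(np.sqrt(2.0))


def gelu(a):
    """Exact GELU: x * Phi(x) with Phi the standard normal CDF."""
    av = _as_array(a)
    phi_cdf = 0.5 * (1.0 + erf(av / _SQRT_2))
    out_data = av * phi_cdf

    def backward(g):
        pdf = np.exp(-0.5 * av * av) / _SQRT_2PI
        _accum(a, g * (phi_cdf + av * pdf))

    return _node(out_data, (a,), backward)


def tanh(a):
    av = _as_array(a)
    out_data = np.tanh(av)

    def backward(g):
        _accum(a, g * (1.0 - out_data**2))

    return _node(out_data, (a,), backward)


def masked_softmax(logits, mask=None, axis=-1):
    """Row-wise softmax with boolean masking (True = position allowed).

    Masked positions get exactly zero weight (treated as -inf logits before
    normalization), so no gradient flows through them. A row with no
    allowed position yields an all-zero row rather than NaN.
    """
    lv = _as_array(logits)
    if mask is not None:
        m = np.broadcast_to(np.asarray(mask, dtype=bool), lv.shape)
        shifted = np.where(m, lv, -np.inf)
    else:
        m = None
        shifted = lv
    mx = np.max(shifted, axis=axis, keepdims=True)
    mx = np.where(np.isfinite(mx), mx, 0.0)  # fully masked rows
    e = np.exp(shifted - mx)
    e = np.where(np.isfinite(e), e, 0.0)
    denom = e.sum(axis=axis, keepdims=True)
    w = np.divide(e, denom, out=np.zeros_like(e), where=denom > 0)

    def backward(g):
        inner = (g * w).sum(axis=axis, keepdims=True)
        _accum(logits, w * (g - inner))

    return _node(w, (logits,), backward)


def layer_norm(x, gamma, beta, eps: float = 1e-5):
    """Layer normalization over the last axis with affine parameters."""
    xv = _as_array(x)
    mu = xv.mean(axis=-1, keepdims=True)
    xm = xv - mu
    var = (xm**2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xm * inv
    gv, bv = _as_array(gamma), _as_array(beta)
    out_data = gv * xhat + bv

    def backward(g):
        if isinstance(gamma, Tensor):
            _accum(gamma, _unbroadcast(g * xhat, gv.shape))
        if isinstance(beta, Tensor):
            _accum(beta, _unbroadcast(g, bv.shape))
        gx = g * gv
        dx = inv * (gx - gx.mean(axis=-1, keepdims=True)
                    - xhat * (gx * xhat).mean(axis=-1, keepdims=True))
        _accum(x, dx)

    return _node(out_data, (x, gamma, beta), backward)


def dropout(x, p: float, rng: np.random.Generator | None, training: bool):
    """Inverted dropout; identity when not training or p == 0."""
    if not training or p <= 0.0:
        return x
    xv = _as_array(x)
    keep = rng.random(xv.shape) >= p
    return mul(x, keep.astype(xv.dtype) / (1.0 - p))


# ---------------------------------------------------------------------------
# fused LSTM layer (one graph node per direction)


def _sigmoid(z):
    with np.errstate(over="ignore"):  # exp overflow saturates to 0 exactly
        return 1.0 / (1.0 + np.exp(-z))


def lstm(x, Wx, Wh, b, reverse: bool = False):
    """A full unidirectional LSTM layer as a single graph node.

    ``x`` is (B, T, D); ``Wx`` (D, 4H), ``Wh`` (H, 4H), ``b`` (4H,) with
    gate order [input, forget, output, cell]. Initial state is zero. With
    ``reverse=True`` the sequence is processed back-to-front and the output
    realigned, giving the backward half of a bidirectional layer. The
    backward pass is classic backpropagation-through-time, done in-node;
    the input projections are batched over time in both passes.
    """
    xv, Wxv, Whv, bv = _as_array(x), _as_array(Wx), _as_array(Wh), _as_array(b)
    B, T, _ = xv.shape
    H = Whv.shape[0]
    seq = xv[:, ::-1] if reverse else xv

    zx = seq @ Wxv + bv  # (B, T, 4H): input projections for every step
    dt = xv.dtype
    hs = np.zeros((B, T, H), dtype=dt)
    gates = np.empty((B, T, 4 * H), dtype=dt)  # sigma(i), sigma(f), sigma(o), tanh(g)
    cs = np.empty((B, T, H), dtype=dt)
    tcs = np.empty((B, T, H), dtype=dt)
    h = np.zeros((B, H), dtype=dt)
    c = np.zeros((B, H), dtype=dt)
    for t in range(T):
        z = zx[:, t] + h @ Whv
        z[:, : 3 * H] = _sigmoid(z[:, : 3 * H])
        z[:, 3 * H :] = np.tanh(z[:, 3 * H :])
        i, f, o, gg = z[:, :H], z[:, H : 2 * H], z[:, 2 * H : 3 * H], z[:, 3 * H :]
        c = f * c + i * gg
        tc = np.tanh(c)
        h = o * tc
        gates[:, t] = z
        cs[:, t] = c
        tcs[:, t] = tc
        hs[:, t] = h

    out_data = hs[:, ::-1] if reverse else hs

    def backward(g):
        gseq = np.ascontiguousarray(g[:, ::-1] if reverse else g)
        dzs = np.empty((B, T, 4 * H), dtype=dt)
        dh_next = np.zeros((B, H), dtype=dt)
        dc_next = np.zeros((B, H), dtype=dt)
        for t in range(T - 1, -1, -1):
            z = gates[:, t]
            i, f, o, gg = z[:, :H], z[:, H : 2 * H], z[:, 2 * H : 3 * H], z[:, 3 * H :]
            tc = tcs[:, t]
            c_prev = cs[:, t - 1] if t > 0 else np.zeros((B, H), dtype=dt)
            dh = gseq[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc**2) + dc_next
            dc_next = dc * f
            dz = dzs[:, t]
            dz[:, :H] = dc * gg * i * (1.0 - i)
            dz[:, H : 2 * H] = dc * c_prev * f * (1.0 - f)
            dz[:, 2 * H : 3 * H] = do * o * (1.0 - o)
            dz[:, 3 * H :] = dc * i * (1.0 - gg**2)
            dh_next = dz @ Whv.T
        if isinstance(x, Tensor):
            dx_seq = dzs @ Wxv.T
            _accum(x, dx_seq[:, ::-1] if reverse else dx_seq)
        if isinstance(Wx, Tensor):
            _accum(Wx, np.tensordot(seq, dzs, axes=([0, 1], [0, 1])))
        if isinstance(Wh, Tensor):
            h_prevs = np.concatenate([np.zeros((B, 1, H)), hs[:, :-1]], axis=1)
            _accum(Wh, np.tensordot(h_prevs, dzs, axes=([0, 1], [0, 1])))
        if isinstance(b, Tensor):
            _accum(b, dzs.sum(axis=(0, 1)))

    return _node(out_data, (x, Wx, Wh, b), backward)


def bilstm(x, params: dict, prefix: str):
    """Bidirectional LSTM layer; concatenates forward and backward halves."""
    fw = lstm(x, params[f"{prefix}.fw.Wx"], params[f"{prefix}.fw.Wh"], params[f"{prefix}.fw.b"])
    bw = lstm(x, params[f"{prefix}.bw.Wx"], params[f"{prefix}.bw.Wh"], params[f"{prefix}.bw.b"],
              reverse=True)
    return concat([fw, bw], axis=-1)


# ---------------------------------------------------------------------------
# losses


def huber_loss_t(pred, target, delta: float = 2.0):
    """Mean Huber loss as a graph node; ``target`` is a constant array."""
    pv = _as_array(pred)
    tv = np.asarray(target, dtype=float)
    r = pv - tv
    absr = np.abs(r)
    quad = absr <= delta
    vals = np.where(quad, 0.5 * r**2, delta * (absr - 0.5 * delta))
    n = pv.size

    def backward(g):
        dr = np.where(quad, r, delta * np.sign(r))
        _accum(pred, g * dr / n)

    return _node(vals.mean(), (pred,), backward)


# ---------------------------------------------------------------------------
# parameters and optimization


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape if shape is not None else (fan_in, fan_out))


def clip_global_norm(grads: dict[str, np.ndarray], max_norm: float) -> tuple[dict, float]:
    """Scale the whole gradient set so its global L2 norm is <= max_norm."""
    total = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
    if total > max_norm and total > 0:
        scale = max_norm / total
        grads = {k: g * scale for k, g in grads.items()}
        return grads, max_norm
    return grads, total


class AdamW:
    """Adam with decoupled weight decay (decay skipped for biases/gains)."""

    def __init__(self, params: dict[str, Tensor], lr: float = 3e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.005):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    @staticmethod
    def _decayable(name: str) -> bool:
        return not (name.endswith(".b") or name.endswith(".beta")
                    or name.endswith(".gamma") or name.endswith(".bc"))

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            g = grads.get(k)
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay > 0 and self._decayable(k):
                p.data -= self.lr * self.weight_decay * p.data
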