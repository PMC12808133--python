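"""The Enhanced Dynamic Context-Aware Network (Enhanced DCAN).

Four modality branches (voice / clinical / meta / text) are encoded to a
common hidden width h_d, fused by a dynamic attention mechanism, passed
through a causally masked temporal block, and read out as a single
motor-UPDRS prediction per window:

* voice: two stacked bidirectional LSTM layers (h_d/2 units per direction)
  followed by multi-head self-attention with residual + layer norm;
* clinical / meta / text: two position-wise dense layers with exact GELU,
  then layer norm;
* fusion: per-modality multi-head self-attention; temporal mean-pooling of
  each attended stream; the pooled vectors are concatenated into a context
  vector whose softmax-projected weights alpha (one per modality, summing
  to 1) convexly combine the *full* attended sequences;
* temporal block: two bidirectional LSTM layers with residual connections,
  then self-attention under a strictly causal mask (position i may attend
  only to j <= i), residual + layer norm;
* head: three dense layers with GELU and dropout, layer norm, and a linear
  output neuron on the final-timestep representation.

Padded (masked) timesteps are zeroed at the input, excluded from attention
keys and from temporal pooling, so predictions are exactly invariant to
whatever values the padding once held.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import nn
from .errors import ConfigError
from .features import SequenceSample

MODALITIES = ("voice", "clinical", "meta", "text")


@dataclass
class ModelConfig:
    """Architecture hyperparameters (defaults follow the published setup)."""

    hidden_dim: int = 256
    fusion_heads: int = 4
    encoder_heads: int = 4
    temporal_heads: int = 4
    temporal_layers: int = 2
    voice_lstm_layers: int = 2
    dropout_attn: float = 0.15
    dropout_dense: float = 0.2
    dropout_temporal: float = 0.3
    dropout_head: float = 0.15
    l2_lambda: float = 3e-4
    d_voice: int = 146
    d_clinical: int = 9
    d_meta: int = 3
    d_text: int = 768
    sequence_length: int = 10
    modalities: tuple[str, ...] = MODALITIES
    residual_per_layer: bool = True
    per_timestep_supervision: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for heads in (self.fusion_heads, self.encoder_heads, self.temporal_heads):
            if self.hidden_dim % heads != 0:
                raise ConfigError("hidden_dim must be divisible by every head count")
        if self.hidden_dim % 2 != 0:
            raise ConfigError("hidden_dim must be even (bidirectional halves)")
        for p in (self.dropout_attn, self.dropout_dense, self.dropout_temporal, self.dropout_head):
            if not (0.0 <= p < 1.0):
                raise ConfigError("dropout rates must lie in [0, 1)")
        if self.l2_lambda < 0:
            raise ConfigError("l2_lambda must be >= 0")
        unknown = set(self.modalities) - set(MODALITIES)
        if unknown or not self.modalities:
            raise ConfigError(f"modalities must be a nonempty subset of {MODALITIES}")

    def ablation_preset(self, modalities: tuple[str, ...] | None = None) -> "ModelConfig":
        """The reduced configuration used for the ablation experiments."""
        return replace(
            self,
            hidden_dim=128,
            dropout_attn=0.2,
            dropout_dense=0.2,
            dropout_temporal=0.2,
            dropout_head=0.2,
            l2_lambda=5e-4,
            fusion_heads=4,
            encoder_heads=4,
            temporal_heads=4,
            modalities=modalities if modalities is not None else self.modalities,
        )


@dataclass
class ModalityWeights:
    """Per-sample convex modality weights from the dynamic fusion layer."""

    names: tuple[str, ...]
    alpha: np.ndarray  # (B, n_modalities)

    def __post_init__(self) -> None:
        assert np.all(self.alpha >= -1e-9)
        assert np.allclose(self.alpha.sum(axis=-1), 1.0, atol=1e-6)


# ---------------------------------------------------------------------------
# standalone numeric primitives (inspectable outside the graph)


def gelu(x):
    """Exact GELU, x * Phi(x), as a plain numpy function."""
    x = np.asarray(x, dtype=float)
    from scipy.special import erf

    return x * 0.5 * (1.0 + erf(x / np.sqrt(2.0)))


def causal_mask(T: int) -> np.ndarray:
    """(T, T) boolean mask; True where attention is allowed (j <= i)."""
    if T < 1:
        raise ConfigError("T must be >= 1")
    return np.tril(np.ones((T, T), dtype=bool))


def scaled_dot_attention(Q, K, V, mask=None) -> np.ndarray:
    """softmax(Q K^T / sqrt(d_k)) V with optional boolean masking.

    Masked positions receive -inf logits; a fully masked row outputs zeros.
    Plain numpy reference used both by tests and by the graph version.
    """
    Q, K, V = (np.asarray(a, dtype=float) for a in (Q, K, V))
    d_k = Q.shape[-1]
    logits = Q @ np.swapaxes(K, -1, -2) / np.sqrt(d_k)
    w = nn.masked_softmax(nn.Tensor(logits), mask).data
    return w @ V


# ---------------------------------------------------------------------------
# parameter construction


#: network compute dtype; float32 halves memory traffic on CPU
DTYPE = np.float32


def _param(data) -> nn.Tensor:
    return nn.Tensor(np.asarray(data, dtype=DTYPE), requires_grad=True)


def _init_lstm(params, rng, prefix, d_in, h):
    for direction in ("fw", "bw"):
        params[f"{prefix}.{direction}.Wx"] = _param(
            nn.glorot(rng, d_in, 4 * h, shape=(d_in, 4 * h)))
        params[f"{prefix}.{direction}.Wh"] = _param(
            nn.glorot(rng, h, 4 * h, shape=(h, 4 * h)))
        b = np.zeros(4 * h)
        b[h : 2 * h] = 1.0  # forget-gate bias
        params[f"{prefix}.{direction}.b"] = _param(b)


def _init_attn(params, rng, prefix, h):
    for w in ("Wq", "Wk", "Wv"):
        params[f"{prefix}.{w}"] = _param(nn.glorot(rng, h, h))


def _init_dense(params, rng, prefix, d_in, d_out):
    params[f"{prefix}.W"] = _param(nn.glorot(rng, d_in, d_out))
    params[f"{prefix}.b"] = _param(np.zeros(d_out))


def _init_ln(params, prefix, h):
    params[f"{prefix}.gamma"] = _param(np.ones(h))
    params[f"{prefix}.beta"] = _param(np.zeros(h))


def _dense(x, params, prefix):
    return nn.add(nn.matmul(x, params[f"{prefix}.W"]), params[f"{prefix}.b"])


def _mha(x, params, prefix, n_heads, attn_mask):
    """Multi-head self-attention over (B, T, H) with a (B, 1, T, T) mask."""
    B, T, H = x.shape
    dk = H // n_heads

    def split_heads(t):
        return nn.transpose(nn.reshape(t, (B, T, n_heads, dk)), (0, 2, 1, 3))

    q = split_heads(nn.matmul(x, params[f"{prefix}.Wq"]))
    k = split_heads(nn.matmul(x, params[f"{prefix}.Wk"]))
    v = split_heads(nn.matmul(x, params[f"{prefix}.Wv"]))
    logits = nn.mul(nn.matmul(q, nn.transpose(k, (0, 1, 3, 2))), 1.0 / float(np.sqrt(dk)))
    w = nn.masked_softmax(logits, attn_mask)
    out = nn.matmul(w, v)  # (B, nh, T, dk)
    return nn.reshape(nn.transpose(out, (0, 2, 1, 3)), (B, T, H))


class EnhancedDCAN:
    """Assembled model: callable on batches of :class:`SequenceSample`."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.params: dict[str, nn.Tensor] = {}
        self.last_alpha: np.ndarray | None = None
        rng = np.random.default_rng(config.seed)
        h = config.hidden_dim
        dims = {"voice": config.d_voice, "clinical": config.d_clinical,
                "meta": config.d_meta, "text": config.d_text}

        for mod in config.modalities:
            if mod == "voice":
                d_in = dims["voice"]
                for layer in range(config.voice_lstm_layers):
                    _init_lstm(self.params, rng, f"voice.lstm{layer}", d_in, h // 2)
                    d_in = h
                _init_attn(self.params, rng, "voice.attn", h)
                _init_ln(self.params, "voice.ln", h)
            else:
                _init_dense(self.params, rng, f"{mod}.fc1", dims[mod], h)
                _init_dense(self.params, rng, f"{mod}.fc2", h, h)
                _init_ln(self.params, f"{mod}.ln", h)
            _init_attn(self.params, rng, f"fusion.{mod}", h)

        n_mod = len(config.modalities)
        self.params["fusion.Wc"] = _param(nn.glorot(rng, n_mod * h, n_mod))
        self.params["fusion.bc"] = _param(np.zeros(n_mod))

        for layer in range(config.temporal_layers):
            _init_lstm(self.params, rng, f"temporal.lstm{layer}", h, h // 2)
        _init_attn(self.params, rng, "temporal.attn", h)
        _init_ln(self.params, "temporal.ln", h)

        _init_dense(self.params, rng, "head.fc1", h, h)
        _init_dense(self.params, rng, "head.fc2", h, h // 2)
        _init_dense(self.params, rng, "head.fc3", h // 2, h // 4)
        _init_ln(self.params, "head.ln", h // 4)
        _init_dense(self.params, rng, "head.out", h // 4, 1)

    # -- bookkeeping -------------------------------------------------------

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.params.values()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            p.data = state[k].copy()

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def gradients(self) -> dict[str, np.ndarray]:
        return {k: p.grad for k, p in self.params.items() if p.grad is not None}

    def l2_penalty(self) -> float:
        """lambda * sum of squared dense/recurrent kernels (reported value)."""
        lam = self.config.l2_lambda
        return lam * sum(
            float((p.data**2).sum()) for k, p in self.params.items() if self._kernel(k)
        )

    @staticmethod
    def _kernel(name: str) -> bool:
        # dense and recurrent kernels (anything but biases and norm affines)
        return name.rsplit(".", 1)[-1].startswith("W")

    def l2_gradients(self) -> dict[str, np.ndarray]:
        lam = self.config.l2_lambda
        return {k: 2.0 * lam * p.data for k, p in self.params.items() if self._kernel(k)}

    # -- branches ------------------------------------------------------------

    def _encode_voice(self, X, pad_mask, training, rng):
        cfg = self.config
        hcur = X
        for layer in range(cfg.voice_lstm_layers):
            hcur = nn.bilstm(hcur, self.params, f"voice.lstm{layer}")
        attn = self._self_attention(hcur, "voice.attn", cfg.encoder_heads, pad_mask)
        res = nn.add(hcur, nn.dropout(attn, cfg.dropout_attn, rng, training))
        return nn.layer_norm(res, self.params["voice.ln.gamma"], self.params["voice.ln.beta"])

    def _encode_dense(self, X, mod, training, rng):
        cfg = self.config
        h1 = nn.gelu(_dense(X, self.params, f"{mod}.fc1"))
        h1 = nn.dropout(h1, cfg.dropout_dense, rng, training)
        h2 = nn.gelu(_dense(h1, self.params, f"{mod}.fc2"))
        return nn.layer_norm(h2, self.params[f"{mod}.ln.gamma"], self.params[f"{mod}.ln.beta"])

    def _self_attention(self, x, prefix, heads, pad_mask, causal=False):
        B, T, _ = x.shape
        key_ok = pad_mask[:, None, None, :]  # (B,1,1,T): may attend TO real steps
        mask = np.broadcast_to(key_ok, (B, 1, T, T))
        if causal:
            mask = mask & causal_mask(T)[None, None]
        return _mha(x, self.params, prefix, heads, mask)

    def _fusion(self, encoded: dict[str, nn.Tensor], pad_mask, training, rng):
        cfg = self.config
        attended = {}
        pooled = []
        denom = pad_mask.sum(axis=1, keepdims=True).astype(DTYPE)  # (B,1) valid steps
        for mod in cfg.modalities:
            a = self._self_attention(encoded[mod], f"fusion.{mod}", cfg.fusion_heads, pad_mask)
            attended[mod] = a
            masked = nn.mul(a, pad_mask[:, :, None].astype(DTYPE))
            pooled.append(nn.mul(nn.sum_(masked, axis=1), 1.0 / denom))
        h_context = nn.concat(pooled, axis=-1)  # (B, n_mod * h)
        logits = nn.add(nn.matmul(h_context, self.params["fusion.Wc"]), self.params["fusion.bc"])
        alpha = nn.masked_softmax(logits)  # (B, n_mod)
        fused = None
        for j, mod in enumerate(cfg.modalities):
            w = nn.reshape(alpha[:, j : j + 1], (-1, 1, 1))
            term = nn.mul(attended[mod], w)
            fused = term if fused is None else nn.add(fused, term)
        return fused, alpha

    def _temporal(self, H_f, pad_mask, training, rng):
        cfg = self.config
        hcur = H_f
        for layer in range(cfg.temporal_layers):
            out = nn.bilstm(hcur, self.params, f"temporal.lstm{layer}")
            out = nn.dropout(out, cfg.dropout_temporal, rng, training)
            hcur = nn.add(hcur, out) if cfg.residual_per_layer else out
        if not cfg.residual_per_layer:
            hcur = nn.add(H_f, hcur)  # residual around the pair instead
        attn = self._self_attention(hcur, "temporal.attn", cfg.temporal_heads,
                                    pad_mask, causal=True)
        res = nn.add(hcur, nn.dropout(attn, cfg.dropout_attn, rng, training))
        return nn.layer_norm(res, self.params["temporal.ln.gamma"],
                             self.params["temporal.ln.beta"])

    def _head(self, h, training, rng):
        cfg = self.config
        z = nn.gelu(_dense(h, self.params, "head.fc1"))
        z = nn.dropout(z, cfg.dropout_head, rng, training)
        z = nn.gelu(_dense(z, self.params, "head.fc2"))
        z = nn.dropout(z, cfg.dropout_head, rng, training)
        z = nn.gelu(_dense(z, self.params, "head.fc3"))
        z = nn.layer_norm(z, self.params["head.ln.gamma"], self.params["head.ln.beta"])
        return _dense(z, self.params, "head.out")

    # -- forward -------------------------------------------------------------

    def forward(self, batch: dict, training: bool = False,
                rng: np.random.Generator | None = None) -> nn.Tensor:
        """Run a batch dict through the network.

        ``batch`` carries arrays ``X_v`` (B,T,D_v), ``X_c`` (B,T,9), ``X_m``
        (B,T,3), ``X_t`` (B,T,768) and boolean ``mask`` (B,T). Returns the
        (B,) prediction tensor; per-sample fusion weights are stashed on
        ``self.last_alpha``.
        """
        cfg = self.config
        pad_mask = np.asarray(batch["mask"], dtype=bool)
        m3 = pad_mask[:, :, None].astype(DTYPE)
        inputs = {"voice": batch["X_v"], "clinical": batch["X_c"],
                  "meta": batch["X_m"], "text": batch["X_t"]}
        if rng is None:
            rng = np.random.default_rng(0)

        encoded = {}
        for mod in cfg.modalities:
            X = nn.Tensor(np.asarray(inputs[mod], dtype=DTYPE) * m3)
            if mod == "voice":
                encoded[mod] = self._encode_voice(X, pad_mask, training, rng)
            else:
                encoded[mod] = self._encode_dense(X, mod, training, rng)

        fused, alpha = self._fusion(encoded, pad_mask, training, rng)
        self.last_alpha = alpha.data.copy()
        temporal = self._temporal(fused, pad_mask, training, rng)
        if cfg.per_timestep_supervision:
            out = self._head(temporal, training, rng)  # (B, T, 1)
            return nn.reshape(out, temporal.shape[:2])
        final = temporal[:, -1, :]
        out = self._head(final, training, rng)  # (B, 1)
        return nn.reshape(out, (-1,))

    def predict(self, samples: list[SequenceSample], batch_size: int = 256) -> np.ndarray:
        """Inference-mode predictions (no dropout), in input order."""
        preds = []
        for lo in range(0, len(samples), batch_size):
            chunk = samples[lo : lo + batch_size]
            preds.append(self.forward(batch_from_samples(chunk), training=False).data)
        return np.concatenate(preds) if preds else np.zeros(0)

    def modality_weights(self) -> ModalityWeights:
        if self.last_alpha is None:
            raise ConfigError("run a forward pass before reading modality weights")
        return ModalityWeights(names=self.config.modalities, alpha=self.last_alpha)


def batch_from_samples(samples: list[SequenceSample]) -> dict:
    """Stack a list of windows into the batch dict the model consumes."""
    return {
        "X_v": np.stack([s.X_v for s in samples]).astype(DTYPE),
        "X_c": np.stack([s.X_c for s in samples]).astype(DTYPE),
        "X_m": np.stack([s.X_m for s in samples]).astype(DTYPE),
        "X_t": np.stack([s.X_t for s in samples]).astype(DTYPE),
        "mask": np.stack([s.mask for s in samples]),
        "y": np.array([s.y for s in samples], dtype=float),
    }


def slice_batch(data: dict, idx) -> dict:
    """Index a pre-stacked batch dict (see :func:`batch_from_samples`)."""
    return {k: v[idx] for k, v in data.items()}


def build_model(config: ModelConfig) -> EnhancedDCAN:
    """Wire the branch encoders, fusion, temporal block and head."""
    return EnhancedDCAN(config)
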