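"""Attention-only encoder-decoder for SMILES-to-SMILES translation.

The architecture is the standard attention-based translation stack: token
embeddings scaled by sqrt(d_model) plus sinusoidal positional encodings, then
N encoder layers (multi-head self-attention, position-wise feed-forward) and
N decoder layers (causally masked self-attention, cross-attention over the
encoder memory, feed-forward).  Every sub-layer is wrapped in a residual
connection followed by layer normalization (post-norm).

Parameters live in a flat name -> array mapping (:class:`ParameterSet`) so
that checkpoint averaging can operate name-by-name.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from ._autograd import Tensor, constant

NEG_INF = -np.inf


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    n_layers
        Encoder and decoder depth N (same for both stacks).
    d_model
        Embedding / residual-stream width.
    n_heads
        Attention head count h; ``h * d_k == d_model`` is enforced.
    d_ff
        Inner width of the position-wise feed-forward sub-layer.
    max_len
        Longest source or target sequence the positional table covers.
    dropout
        Dropout rate applied during training only.
    """

    n_layers: int = 2
    d_model: int = 128
    n_heads: int = 4
    d_ff: int = 256
    max_len: int = 128
    dropout: float = 0.1

    def __post_init__(self):
        for name in ("n_layers", "d_model", "n_heads", "d_ff", "max_len"):
            v = getattr(self, name)
            if not isinstance(v, int) or v <= 0:
                if name == "n_layers" and v == 0:
                    continue  # depth 0 is a legal degenerate stack
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.d_model % self.n_heads != 0:
            raise ValueError(
                f"d_model ({self.d_model}) must be divisible by n_heads ({self.n_heads})"
            )
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    @property
    def d_k(self) -> int:
        """Per-head key/query/value width."""
        return self.d_model // self.n_heads

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


@dataclass
class AttentionInputs:
    """One scaled dot-product attention call: Q, K, V and the allowed mask."""

    q: np.ndarray
    k: np.ndarray
    v: np.ndarray
    mask: np.ndarray | None = None  # boolean, True = allowed; (..., n_q, n_k)

    def __post_init__(self):
        if self.k.shape[-2] != self.v.shape[-2]:
            raise ValueError("K and V must have the same number of rows")
        if self.mask is not None and not self.mask.any(axis=-1).all():
            raise ValueError("every query row needs at least one allowed key")


# ---------------------------------------------------------------------------
# parameters


def parameter_names(config: ModelConfig) -> list[str]:
    """The full, config-determined name set of a ParameterSet."""
    names = ["embed", "out_proj_b"]
    for side, extra in (("enc", ()), ("dec", ("cross",))):
        for i in range(config.n_layers):
            for sub in ("self",) + extra:
                for w in ("wq", "wk", "wv", "wo"):
                    names.append(f"{side}.{i}.{sub}.{w}")
                names.append(f"{side}.{i}.{sub}.ln_g")
                names.append(f"{side}.{i}.{sub}.ln_b")
            names += [
                f"{side}.{i}.ff.w1",
                f"{side}.{i}.ff.b1",
                f"{side}.{i}.ff.w2",
                f"{side}.{i}.ff.b2",
                f"{side}.{i}.ff.ln_g",
                f"{side}.{i}.ff.ln_b",
            ]
    return names


def parameter_shape(name: str, config: ModelConfig, vocab_size: int) -> tuple[int, ...]:
    d, f = config.d_model, config.d_ff
    if name == "embed":
        return (vocab_size, d)
    if name == "out_proj_b":
        return (vocab_size,)
    leaf = name.rsplit(".", 1)[-1]
    return {
        "wq": (d, d), "wk": (d, d), "wv": (d, d), "wo": (d, d),
        "ln_g": (d,), "ln_b": (d,),
        "w1": (d, f), "b1": (f,), "w2": (f, d), "b2": (d,),
    }[leaf]


def init_parameters(config: ModelConfig, vocab_size: int, seed: int) -> dict[str, np.ndarray]:
    """Glorot-uniform initialization with a recorded seed.

    The output projection is tied to the (transposed) embedding table, so the
    only vocabulary-sized weights are ``embed`` and the output bias.
    """
    rng = np.random.default_rng(seed)
    params: dict[str, np.ndarray] = {}
    for name in parameter_names(config):
        shape = parameter_shape(name, config, vocab_size)
        if name.endswith(("ln_g",)):
            params[name] = np.ones(shape)
        elif name.endswith(("ln_b", "b1", "b2", "out_proj_b")):
            params[name] = np.zeros(shape)
        else:
            limit = math.sqrt(6.0 / sum(shape))
            params[name] = rng.uniform(-limit, limit, size=shape)
    return params


def check_shapes(params: dict[str, np.ndarray], config: ModelConfig, vocab_size: int) -> None:
    """Audit a ParameterSet's names and shapes against its config."""
    expected = set(parameter_names(config))
    got = set(params)
    if expected != got:
        missing, extra = expected - got, got - expected
        raise ValueError(f"parameter name mismatch: missing={sorted(missing)} extra={sorted(extra)}")
    for name, arr in params.items():
        want = parameter_shape(name, config, vocab_size)
        if tuple(arr.shape) != want:
            raise ValueError(f"{name}: shape {arr.shape}, expected {want}")


# ---------------------------------------------------------------------------
# building blocks


def positional_encoding(length: int, d_model: int) -> np.ndarray:
    """Sinusoidal position table: (pos, 2i) -> sin, (pos, 2i+1) -> cos.

    The argument of both is pos / 10000^(2i/d_model); every entry lies in
    [-1, 1].
    """
    if length <= 0 or d_model <= 0:
        raise ValueError("length and d_model must be positive")
    pos = np.arange(length)[:, None].astype(np.float64)
    i = np.arange(0, d_model, 2).astype(np.float64)
    angle = pos / np.power(10000.0, i / d_model)
    pe = np.zeros((length, d_model))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle[:, : d_model // 2])
    return pe


def scaled_dot_product_attention(inputs: AttentionInputs) -> tuple[np.ndarray, np.ndarray]:
    """Plain-array attention: returns (output, weights).

    Logits are Q K^T / sqrt(d_k); disallowed (query, key) pairs get -inf
    before the softmax, so each weight row is a probability vector over the
    allowed keys and the output is weights @ V.
    """
    out, w = _attention(constant(inputs.q), constant(inputs.k), constant(inputs.v),
                        _mask_bias(inputs.mask))
    return out.value, w.value


def _mask_bias(mask: np.ndarray | None) -> np.ndarray | None:
    if mask is None:
        return None
    bias = np.zeros(mask.shape)
    bias[~mask] = NEG_INF
    return bias


def _attention(q: Tensor, k: Tensor, v: Tensor, bias: np.ndarray | None):
    d_k = q.shape[-1]
    logits = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(d_k))
    weights = logits.softmax_last(additive_mask=bias)
    return weights @ v, weights


def _split_heads(x: Tensor, n_heads: int) -> Tensor:
    # (B, T, d) -> (B, h, T, d_k)
    b, t, d = x.shape
    return x.reshape(b, t, n_heads, d // n_heads).swapaxes(1, 2)


def _merge_heads(x: Tensor) -> Tensor:
    b, h, t, dk = x.shape
    return x.swapaxes(1, 2).reshape(b, t, h * dk)


def multi_head_attention(
    x_q: np.ndarray | Tensor,
    x_kv: np.ndarray | Tensor,
    params: dict,
    prefix: str,
    n_heads: int,
    mask: np.ndarray | None = None,
) -> Tensor:
    """h parallel attentions over per-head projections of x_q / x_kv.

    `params` holds Tensors or arrays under `{prefix}.wq|wk|wv|wo`; `mask` is
    boolean (True = allowed) broadcastable to (B, h, T_q, T_kv).
    """
    x_q = x_q if isinstance(x_q, Tensor) else constant(x_q)
    x_kv = x_kv if isinstance(x_kv, Tensor) else constant(x_kv)
    try:
        wq, wk, wv, wo = (
            _as_tensor(params[f"{prefix}.{w}"]) for w in ("wq", "wk", "wv", "wo")
        )
    except KeyError as e:
        raise KeyError(f"missing attention parameter {e.args[0]!r}") from None
    q = _split_heads(x_q @ wq, n_heads)
    k = _split_heads(x_kv @ wk, n_heads)
    v = _split_heads(x_kv @ wv, n_heads)
    bias = _mask_bias(mask)
    out, _ = _attention(q, k, v, bias)
    return _merge_heads(out) @ wo


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else constant(x)


def _sublayer(x: Tensor, fx: Tensor, params: dict, prefix: str,
              dropout: float, rng) -> Tensor:
    """Residual connection around the sub-layer output, then layer norm."""
    if rng is not None and dropout > 0:
        fx = fx.dropout(dropout, rng)
    return (x + fx).layer_norm(_as_tensor(params[f"{prefix}.ln_g"]),
                               _as_tensor(params[f"{prefix}.ln_b"]))


def _feed_forward(x: Tensor, params: dict, prefix: str) -> Tensor:
    h = (x @ _as_tensor(params[f"{prefix}.w1"]) + _as_tensor(params[f"{prefix}.b1"])).relu()
    return h @ _as_tensor(params[f"{prefix}.w2"]) + _as_tensor(params[f"{prefix}.b2"])


def _embed(ids: np.ndarray, params: dict, config: ModelConfig) -> Tensor:
    if ids.shape[-1] > config.max_len:
        raise ValueError(
            f"sequence length {ids.shape[-1]} exceeds max_len {config.max_len}"
        )
    emb = Tensor.embedding(_as_tensor(params["embed"]), ids) * math.sqrt(config.d_model)
    return emb + constant(positional_encoding(ids.shape[-1], config.d_model))


def encode_batch(
    src_ids: np.ndarray,
    params: dict,
    config: ModelConfig,
    pad_id: int = 0,
    dropout_rng=None,
) -> tuple[Tensor, np.ndarray]:
    """Run the encoder stack on a (B, T) id batch.

    Returns (memory Tensor of shape (B, T, d_model), source key-padding mask
    of shape (B, T), True where attendable).  PAD keys are masked out of
    self-attention so padding never alters non-pad rows.
    """
    src_ids = np.atleast_2d(np.asarray(src_ids))
    key_ok = src_ids != pad_id
    if not key_ok.any(axis=-1).all():
        raise ValueError("an all-PAD source sequence cannot be encoded")
    attn_mask = key_ok[:, None, None, :]  # (B, 1, 1, T)
    dr = config.dropout if dropout_rng is not None else 0.0
    x = _embed(src_ids, params, config)
    if dropout_rng is not None and dr > 0:
        x = x.dropout(dr, dropout_rng)
    for i in range(config.n_layers):
        p = f"enc.{i}"
        sa = multi_head_attention(x, x, params, f"{p}.self", config.n_heads, attn_mask)
        x = _sublayer(x, sa, params, f"{p}.self", dr, dropout_rng)
        ff = _feed_forward(x, params, f"{p}.ff")
        x = _sublayer(x, ff, params, f"{p}.ff", dr, dropout_rng)
    return x, key_ok


def decode_batch(
    memory: Tensor | np.ndarray,
    src_key_ok: np.ndarray,
    tgt_ids: np.ndarray,
    params: dict,
    config: ModelConfig,
    dropout_rng=None,
) -> Tensor:
    """Teacher-forced decoder pass: logits of shape (B, T_tgt, vocab).

    Decoder self-attention is causally masked; cross-attention sees every
    non-PAD memory row.  The output projection is the tied (transposed)
    embedding plus a bias.
    """
    tgt_ids = np.atleast_2d(np.asarray(tgt_ids))
    t = tgt_ids.shape[-1]
    causal = np.tril(np.ones((t, t), dtype=bool))[None, None]
    cross_mask = np.asarray(src_key_ok)[:, None, None, :]
    dr = config.dropout if dropout_rng is not None else 0.0
    x = _embed(tgt_ids, params, config)
    if dropout_rng is not None and dr > 0:
        x = x.dropout(dr, dropout_rng)
    mem = memory if isinstance(memory, Tensor) else constant(memory)
    for i in range(config.n_layers):
        p = f"dec.{i}"
        sa = multi_head_attention(x, x, params, f"{p}.self", config.n_heads, causal)
        x = _sublayer(x, sa, params, f"{p}.self", dr, dropout_rng)
        ca = multi_head_attention(x, mem, params, f"{p}.cross", config.n_heads, cross_mask)
        x = _sublayer(x, ca, params, f"{p}.cross", dr, dropout_rng)
        ff = _feed_forward(x, params, f"{p}.ff")
        x = _sublayer(x, ff, params, f"{p}.ff", dr, dropout_rng)
    embed = _as_tensor(params["embed"])
    return x @ embed.swapaxes(0, 1) + _as_tensor(params["out_proj_b"])


# ---------------------------------------------------------------------------
# spec-level inference surface (plain arrays, dropout off)


def encode(src_ids, params: dict, config: ModelConfig, pad_id: int = 0) -> np.ndarray:
    """Encode one source id sequence into a (T, d_model) memory matrix."""
    mem, _ = encode_batch(np.asarray(src_ids)[None, :], params, config, pad_id)
    return mem.value[0]


def decode_step(
    memory: np.ndarray,
    prefix_ids,
    params: dict,
    config: ModelConfig,
    bos_id: int | None = None,
) -> np.ndarray:
    """Next-token log-probability vector given a BOS-started prefix.

    Returns a normalized log-distribution (logsumexp == 0) over the
    vocabulary for the position following the prefix.
    """
    prefix = np.asarray(prefix_ids)
    if prefix.size == 0:
        raise ValueError("decoder prefix must be non-empty (start with BOS)")
    if bos_id is not None and prefix[0] != bos_id:
        raise ValueError("decoder prefix must begin with BOS")
    mem = np.asarray(memory)[None]
    key_ok = np.ones((1, mem.shape[1]), dtype=bool)
    logits = decode_batch(mem, key_ok, prefix[None, :], params, config).value[0, -1]
    zmax = logits.max()
    return logits - (zmax + math.log(np.exp(logits - zmax).sum()))


def batched_next_logprobs(
    memory: np.ndarray,
    src_key_ok: np.ndarray,
    prefixes: np.ndarray,
    params: dict,
    config: ModelConfig,
) -> np.ndarray:
    """Vectorized decode_step over a batch of equal-length prefixes."""
    logits = decode_batch(memory, src_key_ok, prefixes, params, config).value[:, -1]
    zmax = logits.max(axis=-1, keepdims=True)
    return logits - (zmax + np.log(np.exp(logits - zmax).sum(axis=-1, keepdims=True)))
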