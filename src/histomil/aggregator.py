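"""Aggregation networks that map a bag of tile embeddings to a slide-level
prediction.

Three aggregators are provided:

``TransformerAggregator``
    A small pre-norm transformer encoder. Tile embeddings (n x d_in) are
    linearly projected to d_model with a ReLU, one or more learned class
    tokens are prepended, and the sequence runs through L transformer
    layers (layer norm -> multi-head self-attention, layer norm -> MLP,
    residual connections across each block). The transformed class token
    feeds an MLP head producing one logit per target. The default
    configuration is two layers of eight heads with d_model = 512 and
    per-head dimension d_k = d_v = 64, on 768-dimensional inputs.

``AttentionMILModel``
    The gated attention-pooling baseline: per-tile scalar weights
    a_i = softmax_i( w^T (tanh(V e_i) * sigmoid(U e_i)) ), bag embedding
    sum_i a_i e_i, followed by a linear classifier.

``MeanPoolModel``
    A linear classifier on the tile-mean embedding, the classic
    average-pooling aggregation.

All aggregators are permutation-invariant in exact arithmetic: no
positional information is attached to the tiles.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .nn import Tensor, bce_with_logits, concat, layer_norm, softmax

__all__ = [
    "AggregatorConfig",
    "AttentionMILConfig",
    "AttentionRecord",
    "BagPrediction",
    "TransformerAggregator",
    "AttentionMILModel",
    "MeanPoolModel",
    "self_attention",
    "multi_head_attention",
    "forward_bag",
    "attention_mil_forward",
    "mean_pool_forward",
    "save_checkpoint",
    "load_checkpoint",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class AggregatorConfig:
    """Architecture of the transformer aggregator.

    d_model must be divisible by n_heads; each head then has dimension
    d_k = d_v = d_model / n_heads so that n_heads * d_v = d_model.
    """

    d_in: int = 768
    d_model: int = 512
    n_layers: int = 2
    n_heads: int = 8
    mlp_hidden: int = 2048
    head_hidden: int = 512
    n_class_tokens: int = 1
    pooling_mode: str = "class_token"  # or "mean_token"
    dropout: float = 0.0
    qkv_bias: bool = True

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if self.n_class_tokens < 1:
            raise ValueError("n_class_tokens must be >= 1")
        if self.pooling_mode not in ("class_token", "mean_token"):
            raise ValueError(f"unknown pooling_mode {self.pooling_mode!r}")

    @property
    def d_k(self) -> int:
        return self.d_model // self.n_heads

    @property
    def d_v(self) -> int:
        return self.d_model // self.n_heads


@dataclass
class AttentionMILConfig:
    d_in: int = 768
    d_hidden: int = 256
    d_attn: int = 128


@dataclass
class AttentionRecord:
    """Per-layer, per-head attention matrices from one forward pass.

    layers[l] has shape (n_heads, m, m) with m = n_tiles + n_class_tokens
    (or m = n_tiles in mean-token mode); every row is a softmax
    distribution and sums to one.
    """

    layers: list[np.ndarray] = field(default_factory=list)
    n_class_tokens: int = 1

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def n_heads(self) -> int:
        return self.layers[0].shape[0]


@dataclass
class BagPrediction:
    """Slide-level prediction: one logit/probability per target."""

    logits: np.ndarray
    probabilities: np.ndarray
    attention: AttentionRecord | None = None
    tile_weights: np.ndarray | None = None  # AttentionMIL pooling weights


# ---------------------------------------------------------------------------
# Core attention math (plain numpy; the models mirror it on the tape)
# ---------------------------------------------------------------------------

def self_attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Scaled dot-product attention softmax(Q K^T / sqrt(d_k)) V.

    Row-wise softmax is stabilized by subtracting the row maximum.
    """
    Q, K, V = (np.asarray(a, dtype=np.float64) for a in (Q, K, V))
    if not (np.isfinite(Q).all() and np.isfinite(K).all()
            and np.isfinite(V).all()):
        raise ValueError("non-finite values in attention inputs")
    if Q.shape[-1] != K.shape[-1]:
        raise ValueError("query/key dimension mismatch")
    scores = Q @ np.swapaxes(K, -1, -2) / np.sqrt(Q.shape[-1])
    scores -= scores.max(axis=-1, keepdims=True)
    e = np.exp(scores)
    A = e / e.sum(axis=-1, keepdims=True)
    return A @ V


# ---------------------------------------------------------------------------
# Parameter initialisation helpers
# ---------------------------------------------------------------------------

def _linear_init(rng: np.random.Generator, fan_in: int,
                 fan_out: int) -> np.ndarray:
    # Glorot-uniform, the torch.nn.Linear-style default scale
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


class _Module:
    """Shared parameter-dict plumbing for the three aggregators."""

    config: object

    def __init__(self) -> None:
        self.params: dict[str, Tensor] = {}

    def _param(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self.params[name] = t
        return t

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            if k not in self.params:
                raise KeyError(f"unexpected parameter {k!r}")
            if self.params[k].data.shape != v.shape:
                raise ValueError(f"shape mismatch for parameter {k!r}")
            self.params[k].data = np.asarray(v, dtype=np.float64).copy()

    def loss(self, x: np.ndarray, y: float | np.ndarray,
             rng: np.random.Generator | None = None) -> Tensor:
        """Binary cross-entropy training loss for one bag (summed over
        targets in the multi-target case). `rng` drives dropout when the
        model configures it; without it the forward pass is
        deterministic."""
        logit = self._forward_tensor(x, train_rng=rng)
        y = np.broadcast_to(np.asarray(y, dtype=np.float64),
                            logit.data.shape)
        return bce_with_logits(logit, y) * float(logit.data.size)

    def _forward_tensor(self, x: np.ndarray,
                        train_rng=None) -> Tensor:  # pragma: no cover
        raise NotImplementedError


# ---------------------------------------------------------------------------
# Transformer aggregator
# ---------------------------------------------------------------------------

class TransformerAggregator(_Module):
    """Pre-norm transformer encoder over a bag of tile embeddings."""

    def __init__(self, config: AggregatorConfig | None = None,
                 seed: int = 0):
        super().__init__()
        self.config = config or AggregatorConfig()
        cfg = self.config
        rng = np.random.default_rng(seed)
        self._param("proj_W", _linear_init(rng, cfg.d_in, cfg.d_model))
        self._param("proj_b", np.zeros(cfg.d_model))
        # class tokens: zero-mean, small variance
        self._param("cls", rng.normal(0.0, 0.02,
                                      size=(cfg.n_class_tokens, cfg.d_model)))
        for l in range(cfg.n_layers):
            p = f"layer{l}_"
            self._param(p + "ln1_g", np.ones(cfg.d_model))
            self._param(p + "ln1_b", np.zeros(cfg.d_model))
            for nm in ("Wq", "Wk", "Wv", "Wo"):
                self._param(p + nm,
                            _linear_init(rng, cfg.d_model, cfg.d_model))
            for nm in ("bq", "bk", "bv"):
                self._param(p + nm, np.zeros(cfg.d_model))
            self._param(p + "bo", np.zeros(cfg.d_model))
            self._param(p + "ln2_g", np.ones(cfg.d_model))
            self._param(p + "ln2_b", np.zeros(cfg.d_model))
            self._param(p + "mlp_W1",
                        _linear_init(rng, cfg.d_model, cfg.mlp_hidden))
            self._param(p + "mlp_b1", np.zeros(cfg.mlp_hidden))
            self._param(p + "mlp_W2",
                        _linear_init(rng, cfg.mlp_hidden, cfg.d_model))
            self._param(p + "mlp_b2", np.zeros(cfg.d_model))
        self._param("lnf_g", np.ones(cfg.d_model))
        self._param("lnf_b", np.zeros(cfg.d_model))
        for t in range(cfg.n_class_tokens):
            p = f"head{t}_"
            self._param(p + "W1", _linear_init(rng, cfg.d_model,
                                               cfg.head_hidden))
            self._param(p + "b1", np.zeros(cfg.head_hidden))
            self._param(p + "W2", _linear_init(rng, cfg.head_hidden, 1))
            self._param(p + "b2", np.zeros(1))

    # -- internals ----------------------------------------------------------
    def _dropout(self, t: Tensor, rng) -> Tensor:
        p = self.config.dropout
        if rng is None or p <= 0.0:
            return t
        mask = (rng.random(t.shape) >= p) / (1.0 - p)
        return t * Tensor(mask)

    def _msa(self, y: Tensor, layer: int,
             capture: list[np.ndarray] | None, rng=None) -> Tensor:
        cfg = self.config
        p = self.params
        pre = f"layer{layer}_"
        m = y.shape[0]
        h, dk = cfg.n_heads, cfg.d_k
        q = y @ p[pre + "Wq"]
        k = y @ p[pre + "Wk"]
        v = y @ p[pre + "Wv"]
        if cfg.qkv_bias:
            q = q + p[pre + "bq"]
            k = k + p[pre + "bk"]
            v = v + p[pre + "bv"]
        # (m, h*dk) -> (h, m, dk)
        q = q.reshape(m, h, dk).transpose(1, 0, 2)
        k = k.reshape(m, h, dk).transpose(1, 0, 2)
        v = v.reshape(m, h, dk).transpose(1, 0, 2)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dk))
        A = softmax(scores, axis=-1)  # (h, m, m)
        if capture is not None:
            capture.append(A.data.copy())
        out = (A @ v).transpose(1, 0, 2).reshape(m, h * dk)
        return self._dropout(out @ p[pre + "Wo"] + p[pre + "bo"], rng)

    def _encode(self, x: np.ndarray,
                capture: list[np.ndarray] | None, rng=None) -> Tensor:
        cfg = self.config
        p = self.params
        hproj = (Tensor(x) @ p["proj_W"] + p["proj_b"]).relu()
        if cfg.pooling_mode == "class_token":
            seq = concat([p["cls"], hproj], axis=0)
        else:
            seq = hproj
        for l in range(cfg.n_layers):
            pre = f"layer{l}_"
            normed = layer_norm(seq, p[pre + "ln1_g"], p[pre + "ln1_b"])
            seq = seq + self._msa(normed, l, capture, rng)
            normed = layer_norm(seq, p[pre + "ln2_g"], p[pre + "ln2_b"])
            hidden = self._dropout(
                (normed @ p[pre + "mlp_W1"] + p[pre + "mlp_b1"]).relu(),
                rng)
            seq = seq + (hidden @ p[pre + "mlp_W2"] + p[pre + "mlp_b2"])
        return layer_norm(seq, p["lnf_g"], p["lnf_b"])

    def _forward_tensor(self, x: np.ndarray,
                        capture: list[np.ndarray] | None = None,
                        train_rng=None) -> Tensor:
        cfg = self.config
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 2 or x.shape[0] < 1:
            raise ValueError("bag must be a non-empty n x d_in matrix")
        if x.shape[1] != cfg.d_in:
            raise ValueError(
                f"bag dimension {x.shape[1]} != configured d_in {cfg.d_in}")
        if not np.isfinite(x).all():
            raise ValueError("bag contains non-finite embeddings")
        seq = self._encode(x, capture, train_rng)
        p = self.params
        logits = []
        for t in range(cfg.n_class_tokens):
            if cfg.pooling_mode == "class_token":
                token = seq[t:t + 1]
            else:
                token = seq.mean(axis=0, keepdims=True)
            pre = f"head{t}_"
            hid = (token @ p[pre + "W1"] + p[pre + "b1"]).relu()
            logits.append(hid @ p[pre + "W2"] + p[pre + "b2"])
        return concat(logits, axis=0).reshape(cfg.n_class_tokens)

    # -- public API ---------------------------------------------------------
    def predict(self, x: np.ndarray,
                capture_attention: bool = False) -> BagPrediction:
        capture: list[np.ndarray] | None = [] if capture_attention else None
        logit = self._forward_tensor(x, capture)
        record = None
        if capture_attention:
            t = (self.config.n_class_tokens
                 if self.config.pooling_mode == "class_token" else 0)
            record = AttentionRecord(layers=capture, n_class_tokens=t)
        probs = 1.0 / (1.0 + np.exp(-logit.data))
        return BagPrediction(logits=logit.data.copy(), probabilities=probs,
                             attention=record)


def multi_head_attention(
        x_seq: np.ndarray, model: TransformerAggregator,
        layer_index: int) -> tuple[np.ndarray, np.ndarray]:
    """Apply one layer's multi-head self-attention block to `x_seq`
    ((n+t) x d_model), returning the output and the captured per-head
    attention matrices of shape (n_heads, n+t, n+t)."""
    cfg = model.config
    x_seq = np.asarray(x_seq, dtype=np.float64)
    if not 1 <= layer_index <= cfg.n_layers:
        raise ValueError(f"layer_index must be in 1..{cfg.n_layers}")
    if x_seq.ndim != 2 or x_seq.shape[1] != cfg.d_model:
        raise ValueError("x_seq must be (n+t) x d_model")
    capture: list[np.ndarray] = []
    out = model._msa(Tensor(x_seq), layer_index - 1, capture)
    return out.data, capture[0]


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------

class AttentionMILModel(_Module):
    """Gated attention-pooling MIL aggregator."""

    def __init__(self, config: AttentionMILConfig | None = None,
                 seed: int = 0):
        super().__init__()
        self.config = config or AttentionMILConfig()
        cfg = self.config
        rng = np.random.default_rng(seed)
        self._param("proj_W", _linear_init(rng, cfg.d_in, cfg.d_hidden))
        self._param("proj_b", np.zeros(cfg.d_hidden))
        self._param("V", _linear_init(rng, cfg.d_hidden, cfg.d_attn))
        self._param("U", _linear_init(rng, cfg.d_hidden, cfg.d_attn))
        self._param("w", _linear_init(rng, cfg.d_attn, 1))
        self._param("clf_W", _linear_init(rng, cfg.d_hidden, 1))
        self._param("clf_b", np.zeros(1))

    def _forward_tensor(self, x: np.ndarray,
                        capture: list[np.ndarray] | None = None,
                        train_rng=None) -> Tensor:
        cfg = self.config
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 2 or x.shape[0] < 1:
            raise ValueError("bag must be a non-empty n x d_in matrix")
        if x.shape[1] != cfg.d_in:
            raise ValueError(
                f"bag dimension {x.shape[1]} != configured d_in {cfg.d_in}")
        if not np.isfinite(x).all():
            raise ValueError("bag contains non-finite embeddings")
        p = self.params
        e = (Tensor(x) @ p["proj_W"] + p["proj_b"]).relu()  # (n, d_hidden)
        gate = (e @ p["V"]).tanh() * (e @ p["U"]).sigmoid()
        scores = (gate @ p["w"]).reshape(1, x.shape[0])
        a = softmax(scores, axis=-1)  # (1, n): tile weights, sum to 1
        if capture is not None:
            capture.append(a.data.reshape(-1).copy())
        bag = a @ e  # (1, d_hidden)
        return (bag @ p["clf_W"] + p["clf_b"]).reshape(1)

    def predict(self, x: np.ndarray,
                capture_attention: bool = False) -> BagPrediction:
        capture: list[np.ndarray] | None = [] if capture_attention else None
        logit = self._forward_tensor(x, capture)
        probs = 1.0 / (1.0 + np.exp(-logit.data))
        weights = capture[0] if capture_attention else None
        return BagPrediction(logits=logit.data.copy(), probabilities=probs,
                             tile_weights=weights)


class MeanPoolModel(_Module):
    """Linear classifier on the tile-mean embedding."""

    def __init__(self, d_in: int = 768, seed: int = 0):
        super().__init__()
        self.config = {"d_in": d_in}
        rng = np.random.default_rng(seed)
        self._param("W", _linear_init(rng, d_in, 1))
        self._param("b", np.zeros(1))

    @property
    def d_in(self) -> int:
        return self.config["d_in"]

    def _forward_tensor(self, x: np.ndarray, capture=None,
                        train_rng=None) -> Tensor:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 2 or x.shape[0] < 1:
            raise ValueError("bag must be a non-empty n x d_in matrix")
        if x.shape[1] != self.d_in:
            raise ValueError(
                f"bag dimension {x.shape[1]} != configured d_in {self.d_in}")
        if not np.isfinite(x).all():
            raise ValueError("bag contains non-finite embeddings")
        pooled = Tensor(x).mean(axis=0, keepdims=True)
        return (pooled @ self.params["W"] + self.params["b"]).reshape(1)

    def predict(self, x: np.ndarray, **_) -> BagPrediction:
        logit = self._forward_tensor(x)
        probs = 1.0 / (1.0 + np.exp(-logit.data))
        return BagPrediction(logits=logit.data.copy(), probabilities=probs)


# ---------------------------------------------------------------------------
# Functional entry points (accept a TileBag or a raw matrix)
# ---------------------------------------------------------------------------

def _embeddings_of(bag) -> np.ndarray:
    return bag.embeddings if hasattr(bag, "embeddings") else np.asarray(bag)


def forward_bag(bag, model: TransformerAggregator,
                capture_attention: bool = False) -> BagPrediction:
    """Score one bag with the transformer aggregator."""
    return model.predict(_embeddings_of(bag),
                         capture_attention=capture_attention)


def attention_mil_forward(bag, model: AttentionMILModel,
                          capture_attention: bool = True) -> BagPrediction:
    """Score one bag with the gated AttentionMIL baseline."""
    return model.predict(_embeddings_of(bag),
                         capture_attention=capture_attention)


def mean_pool_forward(bag, model: MeanPoolModel) -> BagPrediction:
    """Score one bag with the mean-pooling baseline."""
    return model.predict(_embeddings_of(bag))


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

_MODEL_CLASSES = {
    "TransformerAggregator": TransformerAggregator,
    "AttentionMILModel": AttentionMILModel,
    "MeanPoolModel": MeanPoolModel,
}


def save_checkpoint(path, model: _Module,
                    metadata: dict | None = None) -> None:
    """Serialize model weights + config + run metadata to one .npz file."""
    cfg = model.config
    if isinstance(cfg, dict):
        cfg_dict = cfg
    else:
        cfg_dict = asdict(cfg)
    header = {
        "model_class": type(model).__name__,
        "config": cfg_dict,
        "metadata": metadata or {},
    }
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    arrays["__header__"] = np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> tuple[_Module, dict]:
    """Load a checkpoint written by :func:`save_checkpoint`."""
    with np.load(path) as npz:
        header = json.loads(bytes(npz["__header__"]).decode())
        state = {k[len("param/"):]: npz[k] for k in npz.files
                 if k.startswith("param/")}
    cls = _MODEL_CLASSES[header["model_class"]]
    cfg = header["config"]
    if cls is TransformerAggregator:
        model = cls(AggregatorConfig(**cfg))
    elif cls is AttentionMILModel:
        model = cls(AttentionMILConfig(**cfg))
    else:
        model = cls(d_in=cfg["d_in"])
    model.load_state_dict(state)
    return model, header["metadata"]
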