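"""Pluggable classifier-with-dropout backbones.

The regularization scheme only needs a model that (a) maps a feature batch
to a row-stochastic probability matrix and (b) exposes dropout driven by an
explicit random generator, so that two forward passes of one training step
see different sub-models while remaining exactly reproducible.  The default
backbone is a depth-5 MLP with hidden size 256; an alternative treats each
feature as a token and runs a small single-head transformer encoder
(embedding size 96).  Inference (``predict``) disables dropout entirely.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import List, Optional, Union

import numpy as np

from .autodiff import Tensor

MLP = "mlp"
TRANSFORMER_ENCODER = "transformer_encoder"


@dataclass(frozen=True)
class BackboneConfig:
    """Architecture hyperparameters shared by all backbones."""

    n_features: int
    n_classes: int
    kind: str = MLP
    hidden_size: int = 256
    depth: int = 5               # number of linear layers (mlp) / 2 blocks (encoder)
    embedding_size: int = 96     # transformer encoder only
    dropout_rate: float = 0.3

    def __post_init__(self):
        if self.kind not in (MLP, TRANSFORMER_ENCODER):
            raise ValueError(f"unknown backbone kind {self.kind!r}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        for f in ("n_features", "n_classes", "hidden_size", "depth", "embedding_size"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be positive")


def _dropout(t: Tensor, rate: float, rng: Optional[np.random.Generator],
             train: bool) -> Tensor:
    """Inverted dropout; a no-op (consuming no randomness) when rate is 0
    or the model is in inference mode."""
    if not train or rate == 0.0:
        return t
    if rng is None:
        raise ValueError("training-mode dropout requires a random generator")
    mask = (rng.random(t.shape) >= rate) / (1.0 - rate)
    return t * Tensor(mask)


class _Backbone:
    """Shared parameter plumbing; subclasses implement ``_graph``."""

    def __init__(self, config: BackboneConfig):
        self.config = config
        self.params: List[Tensor] = []

    def _param(self, array: np.ndarray) -> Tensor:
        t = Tensor(array, requires_grad=True)
        self.params.append(t)
        return t

    def _graph(self, x: Tensor, rng: Optional[np.random.Generator],
               train: bool) -> Tensor:
        raise NotImplementedError

    def forward(self, x: np.ndarray, rng: Optional[np.random.Generator] = None,
                train: bool = False) -> Tensor:
        """Probability matrix as a graph node (for training losses)."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 2 or x.shape[1] != self.config.n_features:
            raise ValueError(f"expected batch of {self.config.n_features} features, "
                             f"got shape {x.shape}")
        return self._graph(Tensor(x), rng, train)

    def state_arrays(self) -> List[np.ndarray]:
        return [p.data for p in self.params]

    def load_state_arrays(self, arrays: List[np.ndarray]) -> None:
        if len(arrays) != len(self.params):
            raise ValueError("checkpoint parameter count mismatch")
        for p, a in zip(self.params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("checkpoint parameter shape mismatch")
            p.data = np.asarray(a, dtype=np.float64)


class MLPBackbone(_Backbone):
    """``depth`` linear layers with ReLU and dropout after each hidden one."""

    def __init__(self, config: BackboneConfig, seed: int):
        super().__init__(config)
        rng = np.random.default_rng(seed)
        sizes = ([config.n_features]
                 + [config.hidden_size] * (config.depth - 1)
                 + [config.n_classes])
        self.weights, self.biases = [], []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
            self.weights.append(self._param(w))
            self.biases.append(self._param(np.zeros(fan_out)))

    def _graph(self, x: Tensor, rng, train: bool) -> Tensor:
        h = x
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if i < last:
                h = _dropout(h.relu(), self.config.dropout_rate, rng, train)
        return h.log_softmax(axis=-1).exp()


class TransformerEncoderBackbone(_Backbone):
    """Features-as-tokens encoder: per-feature value embedding, single-head
    self-attention blocks with layer norm and a feed-forward sublayer, mean
    pooling, linear head."""

    def __init__(self, config: BackboneConfig, seed: int):
        super().__init__(config)
        rng = np.random.default_rng(seed)
        d, f = config.embedding_size, config.n_features
        s = 1.0 / np.sqrt(d)
        self.value_emb = self._param(rng.normal(0.0, 1.0, size=(f, d)))
        self.feat_emb = self._param(rng.normal(0.0, 1.0, size=(f, d)))
        self.n_blocks = max(1, config.depth // 2)
        self.blocks = []
        for _ in range(self.n_blocks):
            blk = {
                "wq": self._param(rng.normal(0.0, s, size=(d, d))),
                "wk": self._param(rng.normal(0.0, s, size=(d, d))),
                "wv": self._param(rng.normal(0.0, s, size=(d, d))),
                "wo": self._param(rng.normal(0.0, s, size=(d, d))),
                "ln1_g": self._param(np.ones(d)), "ln1_b": self._param(np.zeros(d)),
                "ln2_g": self._param(np.ones(d)), "ln2_b": self._param(np.zeros(d)),
                "ff1": self._param(rng.normal(0.0, s, size=(d, 2 * d))),
                "ff1_b": self._param(np.zeros(2 * d)),
                "ff2": self._param(rng.normal(0.0, np.sqrt(1.0 / (2 * d)), size=(2 * d, d))),
                "ff2_b": self._param(np.zeros(d)),
            }
            self.blocks.append(blk)
        self.head_w = self._param(rng.normal(0.0, s, size=(d, config.n_classes)))
        self.head_b = self._param(np.zeros(config.n_classes))

    @staticmethod
    def _layer_norm(t: Tensor, gain: Tensor, bias: Tensor) -> Tensor:
        mu = t.mean(axis=-1, keepdims=True)
        var = ((t - mu) ** 2).mean(axis=-1, keepdims=True)
        return (t - mu) / (var + 1e-5).sqrt() * gain + bias

    def _graph(self, x: Tensor, rng, train: bool) -> Tensor:
        cfg = self.config
        b, f = x.shape
        d = cfg.embedding_size
        tokens = x.reshape(b, f, 1) * self.value_emb + self.feat_emb  # (b, f, d)
        scale = 1.0 / np.sqrt(d)
        for blk in self.blocks:
            q = tokens @ blk["wq"]
            k = tokens @ blk["wk"]
            v = tokens @ blk["wv"]
            att = ((q @ k.swapaxes(-1, -2)) * scale).softmax(axis=-1)
            attended = _dropout((att @ v) @ blk["wo"], cfg.dropout_rate, rng, train)
            tokens = self._layer_norm(tokens + attended, blk["ln1_g"], blk["ln1_b"])
            ff = (tokens @ blk["ff1"] + blk["ff1_b"]).relu() @ blk["ff2"] + blk["ff2_b"]
            ff = _dropout(ff, cfg.dropout_rate, rng, train)
            tokens = self._layer_norm(tokens + ff, blk["ln2_g"], blk["ln2_b"])
        pooled = tokens.mean(axis=1)
        logits = pooled @ self.head_w + self.head_b
        return logits.log_softmax(axis=-1).exp()


Backbone = Union[MLPBackbone, TransformerEncoderBackbone]


def build_backbone(config: BackboneConfig, seed: int) -> Backbone:
    """Instantiate the configured backbone with seeded initialization."""
    if config.kind == MLP:
        return MLPBackbone(config, seed)
    return TransformerEncoderBackbone(config, seed)


def forward_with_dropout(model: Backbone, batch: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    """One stochastic forward pass; identical rng state gives identical output."""
    return model.forward(batch, rng, train=True).data


def predict(model: Backbone, batch: np.ndarray) -> np.ndarray:
    """Deterministic dropout-free probabilities (inference mode)."""
    return model.forward(batch, train=False).data


def config_hash(config: BackboneConfig) -> str:
    return hashlib.sha256(json.dumps(asdict(config), sort_keys=True).encode()).hexdigest()[:16]


def save_checkpoint(model: Backbone, path: Union[str, Path]) -> None:
    """Serialize parameters plus a config hash guarding against mismatched loads."""
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    meta = dict(asdict(model.config), _hash=config_hash(model.config))
    np.savez(path, _meta=json.dumps(meta), **arrays)


def load_checkpoint(path: Union[str, Path]) -> Backbone:
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["_meta"]))
        stored_hash = meta.pop("_hash")
        config = BackboneConfig(**meta)
        if config_hash(config) != stored_hash:
            raise ValueError("checkpoint config hash mismatch")
        model = build_backbone(config, seed=0)
        model.load_state_arrays([archive[f"p{i}"] for i in range(len(model.params))])
    return model
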