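"""Dual-stream spatial-temporal transformer for grouped EEG epochs.

Input is a group of G consecutive 4-s epochs (G = 8) of one emotion label.
Each epoch's 32 electrodes are cut into slabs of H = 5 consecutive
montage rows spanning the full W = 512-sample window; a slab, flattened,
is one token.  Both streams see the same G x n_slabs tokens but in
different orders:

* spatial stream  — tokens enumerate electrode slabs within each epoch
  (slab index varies fastest), so attention mixes across the scalp;
* temporal stream — tokens enumerate the G successive epochs per slab
  (epoch index varies fastest), so token order encodes temporal
  succession within the group.

Each stream is an independent ViT-style encoder (learnable class token,
learned position embedding, L pre-norm blocks of multi-head self-attention
and a GELU MLP, final layer norm, affine head on the class token).  The
fused logits are an affine map of the layer-normalized concatenation of
the two stream heads' logits; all three logit sets can drive a
classification on their own.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .eeg_io import EpochGroup
from .errors import ConfigError, DataError, TrainingError

__all__ = ["ModelConfig", "SttOutputs", "TokenSequence", "SttModel",
           "tokenize_spatial", "tokenize_temporal", "n_slabs"]

STREAMS = ("spatial", "temporal")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``H`` x ``W`` is the slab (token) geometry: H consecutive electrodes by
    W samples, C channels deep (C = 1 for raw voltage).  Defaults
    ``n_heads = 4`` and ``L = 8`` are the best head/depth combination of
    the ablation grid; ``alpha`` weights the spatial stream's loss in the
    composite objective.
    """

    n_classes: int = 2
    H: int = 5
    W: int = 512
    C: int = 1
    D: int = 64
    L: int = 8
    n_heads: int = 4
    G: int = 8
    n_channels: int = 32
    mlp_ratio: int = 4
    alpha: float = 0.3
    dropout: float = 0.1
    normalize: bool = True
    pad_mode: str = "zero"  # zero-pad last slab, or "overlap" the last H rows
    seed: int = 0

    def __post_init__(self) -> None:
        if self.D % self.n_heads != 0:
            raise ConfigError(f"D={self.D} not divisible by n_heads={self.n_heads}")
        if self.H * self.W * self.C <= 0:
            raise ConfigError("H, W, C must be positive")
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.n_classes < 2:
            raise ConfigError("need at least two classes")
        if self.pad_mode not in ("zero", "overlap"):
            raise ConfigError(f"unknown pad_mode {self.pad_mode!r}")
        if self.L < 0:
            raise ConfigError("L must be >= 0")

    @property
    def n_slabs(self) -> int:
        return math.ceil(self.n_channels / self.H)

    @property
    def n_tokens(self) -> int:
        return self.n_slabs * self.G

    @property
    def patch_dim(self) -> int:
        return self.H * self.W * self.C


def n_slabs(cfg: ModelConfig) -> int:
    return cfg.n_slabs


@dataclass
class TokenSequence:
    """Embedded tokens with the class token at index 0."""

    tokens: Tensor  # [batch x (n_tokens + 1) x D]


@dataclass
class SttOutputs:
    """The three logit sets of one forward pass."""

    y_spatial: Tensor  # [batch x n_classes]
    y_temporal: Tensor
    y: Tensor          # fused

    def logits(self, variant: str) -> Tensor:
        return {"spatial": self.y_spatial, "temporal": self.y_temporal,
                "combined": self.y}[variant]


# ---------------------------------------------------------------------------
# Tokenization

def _group_array(group: EpochGroup | np.ndarray) -> np.ndarray:
    arr = group.as_array() if isinstance(group, EpochGroup) else np.asarray(group)
    if arr.ndim != 3:
        raise DataError("group must be [G x epoch_len x channels]")
    return arr.astype(np.float32)


def _slab_stack(batch: np.ndarray, cfg: ModelConfig) -> np.ndarray:
    """[B, G, W, ch] -> [B, G, S, H*W*C] slabs of H consecutive electrodes."""
    B, G, W, ch = batch.shape
    if G != cfg.G:
        raise DataError(f"group size {G} != configured G={cfg.G}")
    if W != cfg.W:
        raise DataError(f"epoch length {W} != configured W={cfg.W}")
    if ch != cfg.n_channels:
        raise DataError(f"{ch} channels != configured {cfg.n_channels}")
    if cfg.normalize:
        mu = batch.mean(axis=(2, 3), keepdims=True)
        sd = batch.std(axis=(2, 3), keepdims=True)
        batch = (batch - mu) / (sd + 1e-8)
    S = cfg.n_slabs
    padded = S * cfg.H
    if padded != ch:
        if cfg.pad_mode == "zero":
            pad = np.zeros(batch.shape[:3] + (padded - ch,), dtype=batch.dtype)
            batch = np.concatenate([batch, pad], axis=3)
        else:  # overlap: last slab re-uses the final H electrodes
            full = batch[..., : (S - 1) * cfg.H]
            last = batch[..., ch - cfg.H:]
            batch = np.concatenate([full, last], axis=3)
    # electrodes -> (slab, row); token rows are electrodes, columns samples
    x = batch.reshape(B, G, W, S, cfg.H)
    x = x.transpose(0, 1, 3, 4, 2)          # [B, G, S, H, W]
    return x.reshape(B, G, S, cfg.H * cfg.W * cfg.C)


def _tokenize_batch(batch: np.ndarray, cfg: ModelConfig, stream: str) -> np.ndarray:
    slabs = _slab_stack(batch, cfg)  # [B, G, S, P]
    B, G, S, P = slabs.shape
    if stream == "spatial":
        return slabs.reshape(B, G * S, P)           # slab varies fastest
    return slabs.transpose(0, 2, 1, 3).reshape(B, S * G, P)  # epoch fastest


def tokenize_spatial(group: EpochGroup | np.ndarray, cfg: ModelConfig) -> np.ndarray:
    """Flat patch matrix [n_tokens x H*W*C]; tokens enumerate electrode
    slabs within each epoch, concatenated over the G epochs."""
    return _tokenize_batch(_group_array(group)[None], cfg, "spatial")[0]


def tokenize_temporal(group: EpochGroup | np.ndarray, cfg: ModelConfig) -> np.ndarray:
    """Flat patch matrix [n_tokens x H*W*C]; tokens enumerate the G
    successive epochs per electrode slab, encoding temporal order."""
    return _tokenize_batch(_group_array(group)[None], cfg, "temporal")[0]


# ---------------------------------------------------------------------------
# Model

def _trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    x = rng.standard_normal(shape) * std
    return np.clip(x, -2 * std, 2 * std).astype(np.float32)


class SttModel:
    """Two weight-independent encoder streams plus the fusion head.

    Parameters live in ``self.params`` (name -> Tensor); stream parameter
    names are prefixed ``spatial.`` / ``temporal.`` so the two streams'
    tensors are disjoint objects.
    """

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.params: dict[str, Tensor] = {}
        for stream in STREAMS:
            self._init_stream(stream)
        k = 2 * cfg.n_classes
        self._add("fuse.ln_g", np.ones(k, dtype=np.float32))
        self._add("fuse.ln_b", np.zeros(k, dtype=np.float32))
        self._add("fuse.W", _trunc_normal(self.rng, (k, cfg.n_classes)))
        self._add("fuse.b", np.zeros(cfg.n_classes, dtype=np.float32))

    def _add(self, name: str, data: np.ndarray) -> None:
        self.params[name] = ag.parameter(data)

    def _init_stream(self, s: str) -> None:
        cfg, rng = self.cfg, self.rng
        D, P = cfg.D, cfg.patch_dim
        self._add(f"{s}.patch.W", _trunc_normal(rng, (P, D)))
        # non-zero "anchor" bias: layer norm discards token magnitude, but
        # with an O(1) bias the normalized direction rotates away from the
        # anchor as patch energy grows, keeping slab amplitude linearly
        # decodable downstream
        self._add(f"{s}.patch.b", _trunc_normal(rng, (D,), std=1.0))
        self._add(f"{s}.cls", _trunc_normal(rng, (1, 1, D)))
        self._add(f"{s}.pos", _trunc_normal(rng, (cfg.n_tokens + 1, D)))
        for l in range(cfg.L):
            p = f"{s}.block{l}"
            self._add(f"{p}.ln1_g", np.ones(D, dtype=np.float32))
            self._add(f"{p}.ln1_b", np.zeros(D, dtype=np.float32))
            self._add(f"{p}.Wqkv", _trunc_normal(rng, (D, 3 * D)))
            self._add(f"{p}.bqkv", np.zeros(3 * D, dtype=np.float32))
            self._add(f"{p}.Wo", _trunc_normal(rng, (D, D)))
            self._add(f"{p}.bo", np.zeros(D, dtype=np.float32))
            self._add(f"{p}.ln2_g", np.ones(D, dtype=np.float32))
            self._add(f"{p}.ln2_b", np.zeros(D, dtype=np.float32))
            m = cfg.mlp_ratio * D
            self._add(f"{p}.W1", _trunc_normal(rng, (D, m)))
            self._add(f"{p}.b1", np.zeros(m, dtype=np.float32))
            self._add(f"{p}.W2", _trunc_normal(rng, (m, D)))
            self._add(f"{p}.b2", np.zeros(D, dtype=np.float32))
        self._add(f"{s}.ln_f_g", np.ones(D, dtype=np.float32))
        self._add(f"{s}.ln_f_b", np.zeros(D, dtype=np.float32))
        self._add(f"{s}.head.W", _trunc_normal(rng, (D, cfg.n_classes)))
        self._add(f"{s}.head.b", np.zeros(cfg.n_classes, dtype=np.float32))

    # -- introspection ------------------------------------------------------
    def n_parameters(self) -> int:
        """Total trainable scalar count; a function of cfg only."""
        return int(sum(p.data.size for p in self.params.values()))

    def stream_parameters(self, stream: str) -> dict[str, Tensor]:
        return {k: v for k, v in self.params.items() if k.startswith(stream + ".")}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    # -- forward pieces -----------------------------------------------------
    def embed(self, patches: np.ndarray | Tensor, stream: str) -> TokenSequence:
        """Affine-map flat patches to D, prepend the class token, add the
        position embedding.  ``patches``: [batch x n_tokens x patch_dim]."""
        if not isinstance(patches, Tensor):
            patches = Tensor(patches)
        if patches.data.ndim == 2:
            patches = patches.reshape(1, *patches.shape)
        if patches.data.shape[-1] != self.cfg.patch_dim:
            raise DataError(
                f"patch width {patches.data.shape[-1]} != H*W*C={self.cfg.patch_dim}"
            )
        p = self.params
        B = patches.data.shape[0]
        x = patches @ p[f"{stream}.patch.W"] + p[f"{stream}.patch.b"]
        cls = p[f"{stream}.cls"] * np.ones((B, 1, 1), dtype=np.float32)
        x = ag.concat([cls, x], axis=1)
        x = x + p[f"{stream}.pos"]
        return TokenSequence(tokens=x)

    def _attention(self, x: Tensor, prefix: str, train: bool,
                   attn_sink: list | None) -> Tensor:
        cfg, p = self.cfg, self.params
        B, T, D = x.data.shape
        h, dh = cfg.n_heads, cfg.D // cfg.n_heads
        qkv = x @ p[f"{prefix}.Wqkv"] + p[f"{prefix}.bqkv"]  # [B,T,3D]
        qkv = qkv.reshape(B, T, 3, h, dh).transpose(2, 0, 3, 1, 4)  # [3,B,h,T,dh]
        q, k, v = qkv[0], qkv[1], qkv[2]
        scores = (q @ k.transpose(0, 1, 3, 2)) * np.float32(1.0 / np.sqrt(dh))
        attn = ag.softmax(scores, axis=-1)  # [B,h,T,T]
        if attn_sink is not None:
            attn_sink.append(attn.data)
        attn = ag.dropout(attn, cfg.dropout, self.rng, train)
        out = attn @ v                                # [B,h,T,dh]
        out = out.transpose(0, 2, 1, 3).reshape(B, T, D)
        return out @ p[f"{prefix}.Wo"] + p[f"{prefix}.bo"]

    def encoder_forward(self, seq: TokenSequence, stream: str,
                        train: bool = False,
                        attn_sink: list | None = None) -> TokenSequence:
        """L pre-norm blocks: x += MSA(LN(x)); x += MLP(LN(x)).  L = 0 is
        the identity.  Raises TrainingError on non-finite activations."""
        cfg, p = self.cfg, self.params
        x = seq.tokens
        for l in range(cfg.L):
            pre = f"{stream}.block{l}"
            a = self._attention(
                ag.layer_norm(x, p[f"{pre}.ln1_g"], p[f"{pre}.ln1_b"]),
                pre, train, attn_sink,
            )
            x = x + ag.dropout(a, cfg.dropout, self.rng, train)
            hdn = ag.layer_norm(x, p[f"{pre}.ln2_g"], p[f"{pre}.ln2_b"])
            hdn = ag.gelu(hdn @ p[f"{pre}.W1"] + p[f"{pre}.b1"])
            hdn = ag.dropout(hdn, cfg.dropout, self.rng, train)
            hdn = hdn @ p[f"{pre}.W2"] + p[f"{pre}.b2"]
            x = x + ag.dropout(hdn, cfg.dropout, self.rng, train)
            if not np.all(np.isfinite(x.data)):
                raise TrainingError(f"non-finite activations in {stream} layer {l}")
        return TokenSequence(tokens=x)

    def _stream_logits(self, patches: np.ndarray, stream: str, train: bool,
                       attn_sink: list | None) -> Tensor:
        p = self.params
        seq = self.embed(patches, stream)
        seq = self.encoder_forward(seq, stream, train=train, attn_sink=attn_sink)
        cls = seq.tokens[:, 0, :]
        cls = ag.layer_norm(cls, p[f"{stream}.ln_f_g"], p[f"{stream}.ln_f_b"])
        return cls @ p[f"{stream}.head.W"] + p[f"{stream}.head.b"]

    def forward_slabs(self, slabs: np.ndarray, train: bool = False,
                      attn_sink: list | None = None) -> SttOutputs:
        """Forward from a precomputed slab stack ``[batch, G, S, patch_dim]``
        (see :func:`_slab_stack`); both streams read the same slabs in
        their own token order.  Lets training loops tokenize a dataset
        once instead of once per step."""
        B, G, S, P = slabs.shape
        p = self.params
        spatial = slabs.reshape(B, G * S, P)
        temporal = slabs.transpose(0, 2, 1, 3).reshape(B, S * G, P)
        ys = self._stream_logits(spatial, "spatial", train, attn_sink)
        yt = self._stream_logits(temporal, "temporal", train, attn_sink)
        z = ag.concat([ys, yt], axis=-1)
        z = ag.layer_norm(z, p["fuse.ln_g"], p["fuse.ln_b"])
        y = z @ p["fuse.W"] + p["fuse.b"]
        return SttOutputs(y_spatial=ys, y_temporal=yt, y=y)

    def forward(self, groups: Sequence[EpochGroup] | np.ndarray,
                train: bool = False,
                attn_sink: list | None = None) -> SttOutputs:
        """Run both streams and fuse.  ``groups``: a list of EpochGroup or
        an array ``[batch, G, epoch_len, n_channels]``."""
        if isinstance(groups, np.ndarray):
            batch = groups.astype(np.float32)
        else:
            batch = np.stack([_group_array(g) for g in groups])
        return self.forward_slabs(_slab_stack(batch, self.cfg), train=train,
                                  attn_sink=attn_sink)

    # -- persistence ---------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Single-file .npz archive of parameters + config JSON."""
        arrays = {k.replace(".", "__"): v.data for k, v in self.params.items()}
        arrays["config_json"] = np.array(json.dumps(asdict(self.cfg)))
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "SttModel":
        npz = np.load(path, allow_pickle=False)
        cfg = ModelConfig(**json.loads(str(npz["config_json"])))
        model = cls(cfg)
        for k in model.params:
            model.params[k].data = npz[k.replace(".", "__")].astype(np.float32)
        return model
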