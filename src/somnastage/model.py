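"""Hybrid attention network for sleep staging.

One *tower* per input channel, three stages per tower:

1. **Feature extraction** — two parallel 1-D CNN branches over the raw 30 s
   epoch (3000 samples at 100 Hz).  Branch 1 uses a short kernel (size 50,
   stride 6) capturing fast activity; branch 2 a long kernel (size 400)
   capturing slow waves.  Each branch is conv -> ReLU -> max-pool ->
   dropout -> conv(128, k=7) -> ReLU -> max-pool -> dropout; the two branch
   outputs are concatenated along the time axis.  With the default geometry
   the concatenated time width is exactly 80, matching the 80-unit
   feed-forward stack downstream.  (The long-branch stride defaults to 50:
   it is the only stride for which the published layer widths cohere at 80;
   see docs/methods.md.)
2. **Feature optimization** — squeeze-and-excitation residual blocks
   (repeated twice) reduce the 128 feature channels to 30 and re-weight
   them; causal convolutions (kernel 7, left-padded so time step t never
   sees the future) produce Query/Key/Value; multi-head scaled dot-product
   attention over the 30 feature channels (embeddings are the 80-wide time
   axis, split across d=5 heads) followed by an add-&-norm and a
   position-wise 80 -> 120 -> 80 feed-forward with 10% dropout.  As printed
   in the source architecture, attention logits are scaled by d (the head
   count), not sqrt(d_k); a config switch restores the Transformer
   convention.
3. **Fusion & classification** — tower outputs are flattened, concatenated
   along the feature dimension, and passed through FC(80) -> FC(n_classes)
   -> softmax.

The ablated variant (``feature_optimization=False``) keeps the extractor
and SE blocks but drops the causal-attention/feed-forward stage.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import (Conv1d, Dropout, LayerNorm, Linear, MaxPool1d, Module,
                 Tensor, concat, matmul, relu, sigmoid, softmax)

EPOCH_SAMPLES = 3000  # 30 s at 100 Hz


def _conv_len(length: int, k: int, stride: int, pad: int) -> int:
    out = (length + 2 * pad - k) // stride + 1
    if out <= 0:
        raise ValueError("layer geometry yields non-positive length")
    return out


@dataclass(frozen=True)
class BranchSpec:
    """Geometry of one extractor branch."""

    n_kernels: int = 64
    kernel_size: int = 50
    stride: int = 6
    conv_pad: int = 28
    pool1: tuple[int, int, int] = (8, 2, 4)   # (kernel, stride, pad)
    pool2: tuple[int, int, int] = (4, 4, 2)

    def time_width(self, n_in: int, k7_pad: int = 3) -> int:
        t = _conv_len(n_in, self.kernel_size, self.stride, self.conv_pad)
        t = _conv_len(t, self.pool1[0], self.pool1[1], self.pool1[2])
        t = _conv_len(t, 7, 1, k7_pad)
        t = _conv_len(t, self.pool2[0], self.pool2[1], self.pool2[2])
        return t


@dataclass(frozen=True)
class ModelConfig:
    """Every architecture hyperparameter of the staging network.

    Defaults reproduce the published geometry; paddings are the package's
    own completion, chosen so the concatenated extractor output has time
    width 64 + 16 = 80 (the only width at which the published 80-neuron
    feed-forward type-checks).
    """

    n_channels: int = 1
    n_classes: int = 5
    branch1: BranchSpec = field(default_factory=lambda: BranchSpec(
        n_kernels=64, kernel_size=50, stride=6, conv_pad=28,
        pool1=(8, 2, 4), pool2=(4, 4, 2)))
    branch2: BranchSpec = field(default_factory=lambda: BranchSpec(
        n_kernels=64, kernel_size=400, stride=50, conv_pad=200,
        pool1=(4, 2, 2), pool2=(2, 2, 1)))
    other_conv_kernels: int = 128
    other_conv_size: int = 7
    dropout_extract: float = 0.5
    se_channels: int = 30
    se_squeeze: int = 2
    se_repeats: int = 2
    causal_kernel: int = 7
    d_heads: int = 5
    ff_dims: tuple[int, int, int] = (80, 120, 80)
    dropout_ff: float = 0.10
    fusion_hidden: int = 80
    feature_optimization: bool = True
    attention_scale: str = "d"      # "d" (as printed) or "sqrt_dk"
    input_gain: float = 0.02        # µV⁻¹; scales ~50 µV signals to O(1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes not in (2, 3, 4, 5):
            raise ValueError("n_classes must be one of {2,3,4,5}")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.attention_scale not in ("d", "sqrt_dk"):
            raise ValueError("attention_scale must be 'd' or 'sqrt_dk'")
        if self.extractor_width % self.d_heads:
            raise ValueError(
                f"d_heads={self.d_heads} must divide the attention width "
                f"{self.extractor_width}")

    @property
    def extractor_width(self) -> int:
        """Concatenated time width of the two extractor branches (80)."""
        pad = self.other_conv_size // 2
        return (self.branch1.time_width(EPOCH_SAMPLES, pad)
                + self.branch2.time_width(EPOCH_SAMPLES, pad))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("branch1", "branch2"):
            if key in d and isinstance(d[key], dict):
                bd = dict(d[key])
                for pk in ("pool1", "pool2"):
                    if pk in bd:
                        bd[pk] = tuple(bd[pk])
                d[key] = BranchSpec(**bd)
        if "ff_dims" in d:
            d["ff_dims"] = tuple(d["ff_dims"])
        return cls(**d)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

class _Branch(Module):
    def __init__(self, spec: BranchSpec, n_other: int, other_k: int,
                 p_drop: float, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv1d(1, spec.n_kernels, spec.kernel_size,
                            stride=spec.stride, pad=spec.conv_pad, rng=rng)
        self.pool1 = MaxPool1d(*spec.pool1)
        self.drop1 = Dropout(p_drop, rng)
        self.conv2 = Conv1d(spec.n_kernels, n_other, other_k,
                            stride=1, pad=other_k // 2, rng=rng)
        self.pool2 = MaxPool1d(*spec.pool2)
        self.drop2 = Dropout(p_drop, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.drop1(self.pool1(relu(self.conv1(x))))
        x = self.drop2(self.pool2(relu(self.conv2(x))))
        return x


class MultiBranchExtractor(Module):
    """Two parallel CNN branches; outputs concatenated along the time axis.

    Input: [batch, 1, 3000]; output: [batch, 128, extractor_width].
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.branch_a = _Branch(config.branch1, config.other_conv_kernels,
                                config.other_conv_size,
                                config.dropout_extract, rng)
        self.branch_b = _Branch(config.branch2, config.other_conv_kernels,
                                config.other_conv_size,
                                config.dropout_extract, rng)

    def __call__(self, x: Tensor) -> Tensor:
        if x.data.ndim != 3 or x.data.shape[1] != 1 \
                or x.data.shape[2] != EPOCH_SAMPLES:
            raise ValueError(
                f"extractor expects [batch, 1, {EPOCH_SAMPLES}], "
                f"got {x.data.shape}")
        return concat([self.branch_a(x), self.branch_b(x)], axis=2)


class SEResidualBlock(Module):
    """Two 1x1 convolutions with a squeeze-and-excitation gate and a
    residual shortcut (1x1 projection when the channel count changes).

    The gate pools each feature channel globally over time, squeezes 30 ->
    2 -> 30 through two FC layers and a sigmoid, and re-scales the
    channels; the gate values always lie in (0, 1).
    """

    def __init__(self, in_channels: int, config: ModelConfig,
                 rng: np.random.Generator):
        super().__init__()
        c = config.se_channels
        self.conv1 = Conv1d(in_channels, c, 1, rng=rng)
        self.conv2 = Conv1d(c, c, 1, rng=rng)
        self.fc_squeeze = Linear(c, config.se_squeeze, rng=rng)
        self.fc_excite = Linear(config.se_squeeze, c, rng=rng)
        self.shortcut = (Conv1d(in_channels, c, 1, rng=rng)
                         if in_channels != c else None)

    def gate(self, h: Tensor) -> Tensor:
        """Channel weights in (0,1) from globally pooled statistics."""
        s = h.mean(axis=2)                      # [N, C] global average pool
        return sigmoid(self.fc_excite(relu(self.fc_squeeze(s))))

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv2(relu(self.conv1(x)))
        w = self.gate(h)                        # [N, C]
        h = h * w.reshape(w.data.shape[0], w.data.shape[1], 1)
        res = self.shortcut(x) if self.shortcut is not None else x
        return relu(h + res)


class CausalQKV(Module):
    """Three causal convolutions producing Query, Key and Value.

    Each is Conv1d(30 -> 30, kernel 7) left-padded by 6, so the output at
    time step t depends only on inputs at time steps <= t.
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        c, k = config.se_channels, config.causal_kernel
        self.q_conv = Conv1d(c, c, k, causal=True, rng=rng)
        self.k_conv = Conv1d(c, c, k, causal=True, rng=rng)
        self.v_conv = Conv1d(c, c, k, causal=True, rng=rng)

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        return self.q_conv(x), self.k_conv(x), self.v_conv(x)


def multi_head_attention(q: Tensor | np.ndarray, k: Tensor | np.ndarray,
                         v: Tensor | np.ndarray, d_heads: int = 5,
                         scale: str = "d") -> Tensor:
    """Multi-head scaled dot-product attention.

    ``q``, ``k``, ``v``: [batch, positions, width]; ``width`` must be
    divisible by ``d_heads``.  The width axis is split into ``d_heads``
    subspaces; per head, ``softmax(Q K^T / s) V`` with ``s = d_heads``
    (``scale="d"``, as printed in the source description) or
    ``s = sqrt(width / d_heads)`` (``scale="sqrt_dk"``); head outputs are
    concatenated back to the full width.
    """
    q = q if isinstance(q, Tensor) else Tensor(q)
    k = k if isinstance(k, Tensor) else Tensor(k)
    v = v if isinstance(v, Tensor) else Tensor(v)
    n, p, width = q.data.shape
    if width % d_heads:
        raise ValueError(f"width {width} not divisible by d_heads {d_heads}")
    dk = width // d_heads
    s = float(d_heads) if scale == "d" else float(np.sqrt(dk))

    def split(t: Tensor) -> Tensor:
        return t.reshape(n, p, d_heads, dk).transpose(0, 2, 1, 3)

    qh, kh, vh = split(q), split(k), split(v)
    scores = matmul(qh, kh.transpose(0, 1, 3, 2)).scale(1.0 / s)
    attn = softmax(scores, axis=-1)             # rows are probabilities
    out = matmul(attn, vh)                      # [N, H, P, dk]
    return out.transpose(0, 2, 1, 3).reshape(n, p, width)


def attention_weights(q: np.ndarray, k: np.ndarray, d_heads: int = 5,
                      scale: str = "d") -> np.ndarray:
    """Per-head attention matrices [batch, heads, P, P] (rows sum to 1)."""
    n, p, width = q.shape
    dk = width // d_heads
    s = float(d_heads) if scale == "d" else float(np.sqrt(dk))
    qh = q.reshape(n, p, d_heads, dk).transpose(0, 2, 1, 3)
    kh = k.reshape(n, p, d_heads, dk).transpose(0, 2, 1, 3)
    z = qh @ kh.transpose(0, 1, 3, 2) / s
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class FeedForward(Module):
    """Position-wise 80 -> 80 -> 120 -> 80 stack (ReLU, 10% mid dropout)."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        d0, d1, d2 = config.ff_dims
        width = config.extractor_width
        if d0 != width or d2 != width:
            raise ValueError(
                f"feed-forward outer width {d0}/{d2} must equal the "
                f"extractor time width {width}")
        self.fc1 = Linear(width, d0, rng=rng)
        self.fc2 = Linear(d0, d1, rng=rng)
        self.drop = Dropout(config.dropout_ff, rng)
        self.fc3 = Linear(d1, d2, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = relu(self.fc1(x))
        h = self.drop(relu(self.fc2(h)))
        return self.fc3(h)


class FeatureOptimizer(Module):
    """Causal Q/K/V + multi-head attention + add-&-norm + feed-forward."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.qkv = CausalQKV(config, rng)
        self.norm1 = LayerNorm(config.extractor_width)
        self.ff = FeedForward(config, rng)
        self.norm2 = LayerNorm(config.extractor_width)

    def __call__(self, x: Tensor) -> Tensor:
        q, k, v = self.qkv(x)
        a = multi_head_attention(q, k, v, self.config.d_heads,
                                 self.config.attention_scale)
        x = self.norm1(x + a)
        return self.norm2(x + self.ff(x))


class Tower(Module):
    """Per-channel pipeline: extractor -> SE blocks (-> optimizer)."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.extract = MultiBranchExtractor(config, rng)
        blocks = [SEResidualBlock(config.other_conv_kernels, config, rng)]
        for _ in range(config.se_repeats - 1):
            blocks.append(SEResidualBlock(config.se_channels, config, rng))
        self.se_blocks = blocks
        self.optimizer = (FeatureOptimizer(config, rng)
                          if config.feature_optimization else None)
        self.out_width = config.se_channels * config.extractor_width

    def __call__(self, x: Tensor) -> Tensor:
        h = self.extract(x)
        for blk in self.se_blocks:
            h = blk(h)
        if self.optimizer is not None:
            h = self.optimizer(h)
        return h


class SleepStagingModel(Module):
    """n_channels independent towers fused into a softmax classifier."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        ss = np.random.SeedSequence(config.seed)
        rngs = [np.random.default_rng(s) for s in ss.spawn(config.n_channels + 1)]
        self.towers = [Tower(config, rngs[i]) for i in range(config.n_channels)]
        fused = self.towers[0].out_width * config.n_channels
        self.fc_fuse = Linear(fused, config.fusion_hidden, rng=rngs[-1])
        self.fc_out = Linear(config.fusion_hidden, config.n_classes,
                             rng=rngs[-1])

    def fuse_and_classify(self, feats: list[Tensor]) -> Tensor:
        """Flatten per-tower feature maps, concatenate along the feature
        dimension and classify; returns logits [batch, n_classes]."""
        if len(feats) != self.config.n_channels:
            raise ValueError("one feature map per channel required")
        shapes = {f.data.shape for f in feats}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent tower output shapes: {shapes}")
        n = feats[0].data.shape[0]
        flat = concat([f.reshape(n, -1) for f in feats], axis=1)
        return self.fc_out(relu(self.fc_fuse(flat)))

    def __call__(self, x: Tensor | np.ndarray) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(x)
        if x.data.ndim != 3 or x.data.shape[1] != self.config.n_channels:
            raise ValueError(
                f"expected [batch, {self.config.n_channels}, "
                f"{EPOCH_SAMPLES}], got {x.data.shape}")
        xs = x.data * self.config.input_gain
        feats = [tower(Tensor(xs[:, i:i + 1, :]))
                 for i, tower in enumerate(self.towers)]
        return self.fuse_and_classify(feats)

    def predict_proba(self, x: np.ndarray, batch_size: int = 128) -> np.ndarray:
        """Class probabilities [n, n_classes] in evaluation mode."""
        was_training = self.training
        self.eval()
        outs = []
        for i in range(0, len(x), batch_size):
            logits = self(x[i:i + batch_size])
            outs.append(softmax(logits, axis=1).data)
        if was_training:
            self.train()
        return np.concatenate(outs, axis=0)

    def predict(self, x: np.ndarray, batch_size: int = 128) -> np.ndarray:
        """Predicted class indices; argmax ties break to the lowest index."""
        return self.predict_proba(x, batch_size).argmax(axis=1)


def build_model(config: ModelConfig) -> SleepStagingModel:
    """Instantiate the staging network (or its ablated variant) from config."""
    return SleepStagingModel(config)


def save_checkpoint(model: SleepStagingModel, path) -> None:
    """Save parameters with the config embedded."""
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, __config__=json.dumps(model.config.to_dict()), **arrays)


def load_checkpoint(path) -> SleepStagingModel:
    with np.load(path, allow_pickle=False) as z:
        config = ModelConfig.from_dict(json.loads(str(z["__config__"])))
        model = build_model(config)
        arrays = [z[f"p{i}"] for i in range(len(model.parameters()))]
    model.load_state_arrays(arrays)
    return model
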