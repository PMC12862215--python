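"""The per-nucleotide TIS/TTS labelling network.

Architecture (all convolutions length-preserving):

* embedding: tokens 0..4 -> 128-d vectors, padding row frozen at zero;
* local module: conv(k=3) 128->32, BatchNorm, ReLU;
* three dilated residual stages of four pre-activation blocks each,
  with (kernel, dilation) = (26, 1), (26, 2), (36, 5) and channel
  widths 32, 64, 128; a 1x1 conv + BatchNorm + ReLU expands channels
  between stages (32->64, 64->128);
* head: 1x1 conv 128->32, ReLU, 1x1 conv 32->3.

The output is a logit per position over three classes (TIS, TTS,
non-site).  When sequence lengths are supplied, activations at padded
positions are zeroed before every wide convolution, so a transcript
produces identical logits over its valid positions whether it is run
alone or inside a padded batch (evaluation mode, where batch-norm uses
running statistics).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .layers import BatchNorm, Conv1d, Embedding, Param
from .records import NONE, TIS, TTS

CONVS_PER_BLOCK = 2  # pre-activation residual blocks contain two convolutions


@dataclass
class ModelConfig:
    vocab_size: int = 5
    embedding_dim: int = 128
    padding_index: int = 0
    local_channels: int = 32
    local_kernel: int = 3
    stage_channels: Tuple[int, int, int] = (32, 64, 128)
    blocks_per_stage: Tuple[int, int, int] = (4, 4, 4)
    stage_kernels: Tuple[int, int, int] = (26, 26, 36)
    stage_dilations: Tuple[int, int, int] = (1, 2, 5)
    head_channels: int = 32
    n_classes: int = 3
    # initial output bias = log of these class priors (TIS, TTS, non-site);
    # start/stop codons cover a few percent of positions at most, and
    # starting from the prior spares the optimiser the first epochs of
    # learning the majority class.  None -> zero bias.
    head_bias_prior: Optional[Tuple[float, float, float]] = (0.02, 0.02, 0.96)

    def __post_init__(self) -> None:
        n = len(self.stage_channels)
        if not (len(self.stage_kernels) == len(self.stage_dilations)
                == len(self.blocks_per_stage) == n):
            raise ValueError("stage tuples must have equal lengths")
        dims = (self.vocab_size, self.embedding_dim, self.local_channels,
                self.local_kernel, self.head_channels, self.n_classes,
                *self.stage_channels, *self.blocks_per_stage,
                *self.stage_kernels, *self.stage_dilations)
        if any(d <= 0 for d in dims):
            raise ValueError("all architecture dimensions must be positive")
        if self.head_bias_prior is not None:
            if len(self.head_bias_prior) != self.n_classes or any(
                p <= 0 for p in self.head_bias_prior
            ):
                raise ValueError("head_bias_prior needs one positive value per class")
        if self.stage_channels[0] != self.local_channels:
            raise ValueError("first stage must match local_channels")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        d = json.loads(text)
        for key in ("stage_channels", "blocks_per_stage", "stage_kernels",
                    "stage_dilations", "head_bias_prior"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def receptive_field_span(config: ModelConfig) -> int:
    """Span (nt) of input positions one output logit can depend on.

    1 + sum over all convolutions of dilation * (kernel - 1); the 1x1
    expansion and head convolutions contribute nothing.
    """
    span = 1 + 1 * (config.local_kernel - 1)
    for blocks, k, d in zip(config.blocks_per_stage, config.stage_kernels,
                            config.stage_dilations):
        span += blocks * CONVS_PER_BLOCK * d * (k - 1)
    return span


class _PreActBlock:
    """Pre-activation residual block: BN-ReLU-conv, BN-ReLU-conv, +identity."""

    def __init__(self, channels: int, kernel: int, dilation: int,
                 rng: np.random.Generator):
        self.bn1 = BatchNorm(channels)
        self.conv1 = Conv1d(channels, channels, kernel, rng, dilation)
        self.bn2 = BatchNorm(channels)
        self.conv2 = Conv1d(channels, channels, kernel, rng, dilation)
        # zero-init the branch's last conv so every block starts as the
        # identity; with a deep stack of wide dilated blocks this is the
        # difference between optimisable and not at small batch sizes
        self.conv2.W.value[...] = 0.0
        self._relu1 = None
        self._relu2 = None

    def sublayers(self):
        return [("bn1", self.bn1), ("conv1", self.conv1),
                ("bn2", self.bn2), ("conv2", self.conv2)]

    def forward(self, x: np.ndarray, mask: Optional[np.ndarray],
                train: bool) -> np.ndarray:
        h = self.bn1.forward(x, train)
        np.maximum(h, 0.0, out=h)
        if train:
            self._relu1 = h > 0
        if mask is not None:
            h *= mask
        h = self.conv1.forward(h)
        h = self.bn2.forward(h, train)
        np.maximum(h, 0.0, out=h)
        if train:
            self._relu2 = h > 0
        if mask is not None:
            h *= mask
        h = self.conv2.forward(h)
        return x + h

    def backward(self, dy: np.ndarray, mask: Optional[np.ndarray]) -> np.ndarray:
        dh = self.conv2.backward(dy)
        if mask is not None:
            dh *= mask
        dh *= self._relu2
        dh = self.bn2.backward(dh)
        dh = self.conv1.backward(dh)
        if mask is not None:
            dh *= mask
        dh *= self._relu1
        dh = self.bn1.backward(dh)
        return dy + dh


class SiteLabeler:
    """The full network; see module docstring for the layout."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        self.embed = Embedding(c.vocab_size, c.embedding_dim, rng, c.padding_index)
        self.conv_local = Conv1d(c.embedding_dim, c.local_channels, c.local_kernel, rng)
        self.bn_local = BatchNorm(c.local_channels)
        self.stages: List[List[_PreActBlock]] = []
        self.expand_convs: List[Conv1d] = []
        self.expand_bns: List[BatchNorm] = []
        for s, (ch, blocks, k, d) in enumerate(
            zip(c.stage_channels, c.blocks_per_stage, c.stage_kernels,
                c.stage_dilations)
        ):
            self.stages.append([_PreActBlock(ch, k, d, rng) for _ in range(blocks)])
            if s + 1 < len(c.stage_channels):
                self.expand_convs.append(
                    Conv1d(ch, c.stage_channels[s + 1], 1, rng)
                )
                self.expand_bns.append(BatchNorm(c.stage_channels[s + 1]))
        self.head1 = Conv1d(c.stage_channels[-1], c.head_channels, 1, rng)
        self.head2 = Conv1d(c.head_channels, c.n_classes, 1, rng)
        if c.head_bias_prior is not None:
            self.head2.b.value[...] = np.log(c.head_bias_prior)
        self._relu_local = None
        self._relu_expand: List[np.ndarray] = []
        self._relu_head = None
        self._mask = None

    # -- bookkeeping -------------------------------------------------

    def named_layers(self):
        yield "embed", self.embed
        yield "conv_local", self.conv_local
        yield "bn_local", self.bn_local
        for s, stage in enumerate(self.stages):
            for b, block in enumerate(stage):
                for name, layer in block.sublayers():
                    yield f"stage{s}.block{b}.{name}", layer
            if s < len(self.expand_convs):
                yield f"expand{s}.conv", self.expand_convs[s]
                yield f"expand{s}.bn", self.expand_bns[s]
        yield "head1", self.head1
        yield "head2", self.head2

    def params(self) -> List[Param]:
        out = []
        for _, layer in self.named_layers():
            out.extend(layer.params())
        return out

    def state_dict(self):
        state = {}
        for name, layer in self.named_layers():
            for key, arr in layer.state().items():
                state[f"{name}.{key}"] = arr.copy()
        return state

    def load_state_dict(self, state) -> None:
        for name, layer in self.named_layers():
            layer.load_state({key: state[f"{name}.{key}"]
                              for key in layer.state()})

    # -- forward / backward ------------------------------------------

    def forward(self, tokens: np.ndarray,
                lengths: Optional[Sequence[int]] = None,
                train: bool = False) -> np.ndarray:
        """Map token sequences (B, L) to logits (B, L, 3)."""
        tokens = np.asarray(tokens)
        if tokens.ndim == 1:
            tokens = tokens[None, :]
        if tokens.min() < 0 or tokens.max() >= self.config.vocab_size:
            raise ValueError("token out of range 0..4")
        B, L = tokens.shape
        mask = None
        if lengths is not None:
            mask = (np.arange(L)[None, :] < np.asarray(lengths)[:, None])
            mask = mask.astype(np.float32)[:, :, None]
        self._mask = mask

        x = self.embed.forward(tokens)
        x = self.conv_local.forward(x)
        x = self.bn_local.forward(x, train)
        np.maximum(x, 0.0, out=x)
        if train:
            self._relu_local = x > 0
        if mask is not None:
            x *= mask

        self._relu_expand = []
        for s, stage in enumerate(self.stages):
            for block in stage:
                x = block.forward(x, mask, train)
            if s < len(self.expand_convs):
                x = self.expand_convs[s].forward(x)
                x = self.expand_bns[s].forward(x, train)
                np.maximum(x, 0.0, out=x)
                if train:
                    self._relu_expand.append(x > 0)
                if mask is not None:
                    x *= mask

        h = self.head1.forward(x)
        np.maximum(h, 0.0, out=h)
        if train:
            self._relu_head = h > 0
        return self.head2.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        mask = self._mask
        dh = self.head2.backward(dlogits)
        dh *= self._relu_head
        dx = self.head1.backward(dh)
        for s in range(len(self.stages) - 1, -1, -1):
            if s < len(self.expand_convs):
                if mask is not None:
                    dx *= mask
                dx *= self._relu_expand[s]
                dx = self.expand_bns[s].backward(dx)
                dx = self.expand_convs[s].backward(dx)
            for block in reversed(self.stages[s]):
                dx = block.backward(dx, mask)
        if mask is not None:
            dx *= mask
        dx *= self._relu_local
        dx = self.bn_local.backward(dx)
        dx = self.conv_local.backward(dx)
        self.embed.backward(dx)


def build_model(config: Optional[ModelConfig] = None, seed: int = 0) -> SiteLabeler:
    """Construct a randomly initialised network from a config."""
    return SiteLabeler(config or ModelConfig(), seed=seed)


def to_probabilities(logits: np.ndarray) -> np.ndarray:
    """Softmax over the class axis; rows sum to 1."""
    if not np.all(np.isfinite(logits)):
        raise ValueError("non-finite logits")
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _runs(classes: np.ndarray, value: int) -> List[Tuple[int, int]]:
    """Maximal runs of ``value`` in a 1-D class array as (start, length)."""
    hits = np.flatnonzero(classes == value)
    runs = []
    if hits.size:
        breaks = np.flatnonzero(np.diff(hits) > 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [hits.size - 1]))
        for s, e in zip(starts, ends):
            runs.append((int(hits[s]), int(hits[e] - hits[s] + 1)))
    return runs


@dataclass
class RawDecoding:
    """Argmax decoding of a probability track: per-position classes plus
    the maximal runs of predicted TIS and TTS positions."""

    classes: np.ndarray
    tis_runs: List[Tuple[int, int]] = field(default_factory=list)
    tts_runs: List[Tuple[int, int]] = field(default_factory=list)


def raw_argmax_decode(probs: np.ndarray) -> RawDecoding:
    """Per-position argmax with conservative tie-breaking.

    Ties involving the non-site class resolve to NONE (the network's
    softmax already favours the majority class, and a non-call is the
    safer default); a TIS/TTS tie resolves to TIS.
    """
    probs = np.asarray(probs)
    m = probs.max(axis=-1)
    classes = np.where(
        probs[..., NONE] == m,
        NONE,
        np.where(probs[..., TIS] == m, TIS, TTS),
    ).astype(np.int8)
    return RawDecoding(
        classes=classes,
        tis_runs=_runs(classes, TIS),
        tts_runs=_runs(classes, TTS),
    )


# -- checkpointing ----------------------------------------------------


def save_checkpoint(model: SiteLabeler, path, metadata: Optional[dict] = None) -> None:
    """Write weights + config + metadata to a single .npz container."""
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        model.config.to_json().encode(), dtype=np.uint8
    )
    state["__meta__"] = np.frombuffer(
        json.dumps(metadata or {}).encode(), dtype=np.uint8
    )
    np.savez(path, **state)


def load_checkpoint(path):
    """Load a checkpoint; returns (model, metadata)."""
    with np.load(path) as data:
        config = ModelConfig.from_json(bytes(data["__config__"]).decode())
        metadata = json.loads(bytes(data["__meta__"]).decode())
        model = SiteLabeler(config, seed=0)
        state = {k: data[k] for k in data.files if not k.startswith("__")}
    model.load_state_dict(state)
    return model, metadata
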