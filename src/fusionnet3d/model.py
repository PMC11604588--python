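"""Dual-decoder 3D segmentation network with a fusion head.

The architecture pairs one shared VGG16-style encoder with two decoders
that differ in how they recover resolution:

* a *skip-connection* decoder (U-Net style): trilinear 2x upsampling,
  concatenation with the encoder feature map saved at the same resolution,
  then convolutions;
* a *pooling-index* decoder (SegNet style): max-unpooling driven by the
  argmax indices recorded during encoding, then convolutions, with no skip
  concatenation anywhere.

The two full-resolution feature maps are combined by the fusion head —
additive (``A``), elementwise multiplicative (``M``) or channel
concatenation (``C``) — and a single shared 1x1x1 convolution maps the
fused features to class scores, normalized per voxel to probabilities.

With the default five blocks the encoder has 13 convolutional layers in
the VGG16 layout (2, 2, 3, 3, 3); each block ends in a 2x max-pooling that
records its indices.  Channel widths start at ``base_width`` in the first
block and double per block, capped at ``max_width``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .data import ModalityStack, SegmentationMap

__all__ = [
    "FusionNetConfig",
    "EncoderState",
    "FusionNet",
    "build_fusionnet",
    "fuse",
    "save_checkpoint",
    "load_checkpoint",
]

#: convolutions per encoder block, VGG16 convolutional layout
_VGG16_CONVS = (2, 2, 3, 3, 3)

FUSION_MODES = ("A", "M", "C")


@dataclass(frozen=True)
class FusionNetConfig:
    """Architecture hyperparameters.

    Parameters
    ----------
    in_channels : number of input modalities (1–4).
    num_classes : number of output labels (default 4: background/NC/ED/ET).
    base_width : channels in the first encoder block (default 8).
    num_blocks : encoder blocks, each ending in a 2x pooling (default 5).
    fusion_mode : ``"A"`` (add), ``"M"`` (multiply) or ``"C"`` (concatenate).
    input_edge : cubic input edge length in voxels; must be divisible by
        ``2**num_blocks``.  Default 256; desk-scale runs use 32 or 64.
    max_width : cap on the doubling channel progression (default 128).
    """

    in_channels: int
    num_classes: int = 4
    base_width: int = 8
    num_blocks: int = 5
    fusion_mode: str = "A"
    input_edge: int = 256
    max_width: int = 128

    def __post_init__(self):
        if self.in_channels < 1:
            raise ValueError("in_channels must be >= 1")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.base_width < 1 or self.num_blocks < 1:
            raise ValueError("base_width and num_blocks must be >= 1")
        if self.fusion_mode not in FUSION_MODES:
            raise ValueError(f"fusion_mode must be one of {FUSION_MODES}")
        factor = 2 ** self.num_blocks
        if self.input_edge % factor:
            raise ValueError(
                f"input_edge={self.input_edge} not divisible by "
                f"2**num_blocks={factor}: downsampling would be fractional")

    @property
    def block_widths(self) -> tuple[int, ...]:
        return tuple(min(self.base_width * 2 ** b, self.max_width)
                     for b in range(self.num_blocks))

    @property
    def conv_counts(self) -> tuple[int, ...]:
        counts = _VGG16_CONVS + (3,) * max(0, self.num_blocks - len(_VGG16_CONVS))
        return counts[:self.num_blocks]


@dataclass
class EncoderState:
    """Everything one encoder pass hands to the two decoders."""

    bottleneck: np.ndarray
    skip_features: list = field(default_factory=list)
    pool_indices: list = field(default_factory=list)


class _ConvBlock:
    """conv -> batchnorm -> ReLU, repeated; channels given per conv."""

    def __init__(self, channels: list[tuple[int, int]], rng, name,
                 dtype=np.float32):
        self.layers = []
        for i, (cin, cout) in enumerate(channels):
            self.layers.append(nn.Conv3d(cin, cout, 3, rng=rng,
                                         name=f"{name}.c{i}", dtype=dtype))
            self.layers.append(nn.BatchNorm3d(cout, name=f"{name}.bn{i}",
                                              dtype=dtype))
            self.layers.append(nn.ReLU())

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def buffers(self):
        out = {}
        for l in self.layers:
            out.update(l.buffers())
        return out


class FusionNet:
    """The trainable network.  Use :func:`build_fusionnet` to construct."""

    def __init__(self, config: FusionNetConfig, rng: np.random.Generator,
                 dtype=np.float32):
        self.config = config
        self.dtype = dtype
        widths = config.block_widths
        counts = config.conv_counts
        B = config.num_blocks

        # shared encoder
        self.enc_blocks, self.enc_pools = [], []
        cin = config.in_channels
        for b in range(B):
            chans = [(cin if i == 0 else widths[b], widths[b])
                     for i in range(counts[b])]
            self.enc_blocks.append(_ConvBlock(chans, rng, f"enc.b{b}", dtype))
            self.enc_pools.append(nn.MaxPool3d())
            cin = widths[b]

        # skip-connection decoder: upsample, concat skip, convolve
        self.skip_ups, self.skip_blocks, self._skip_split = [], [], []
        cur = widths[B - 1]
        for b in reversed(range(B)):
            self.skip_ups.append(nn.Upsample2x())
            self._skip_split.append(cur)  # channels arriving from below
            chans = [(cur + widths[b] if i == 0 else widths[b], widths[b])
                     for i in range(counts[b])]
            self.skip_blocks.append(_ConvBlock(chans, rng, f"dec_skip.b{b}", dtype))
            cur = widths[b]

        # pooling-index decoder: unpool with recorded indices, convolve
        self.idx_unpools, self.idx_blocks = [], []
        cur = widths[B - 1]
        for b in reversed(range(B)):
            self.idx_unpools.append(nn.MaxUnpool3d())
            out_w = widths[b - 1] if b > 0 else widths[0]
            chans = []
            for i in range(counts[b]):
                cout = out_w if i == counts[b] - 1 else widths[b]
                chans.append((cur if i == 0 else widths[b], cout))
                # note: for counts[b] == 1 the single conv maps cur -> out_w
            self.idx_blocks.append(_ConvBlock(chans, rng, f"dec_idx.b{b}", dtype))
            cur = out_w

        head_in = widths[0] * (2 if config.fusion_mode == "C" else 1)
        self.classifier = nn.Conv3d(head_in, config.num_classes, 1,
                                    rng=rng, name="head", dtype=dtype)
        self._fusion_cache = None

    # ------------------------------------------------------------------ #
    # forward ops
    # ------------------------------------------------------------------ #
    def _check_input(self, x: np.ndarray) -> None:
        cfg = self.config
        if x.ndim != 5:
            raise ValueError(f"expected (N, C, D, H, W) input; got shape {x.shape}")
        if x.shape[1] != cfg.in_channels:
            raise ValueError(f"channel axis has {x.shape[1]} channels; "
                             f"config requires in_channels={cfg.in_channels}")
        for name, axis in (("depth", 2), ("height", 3), ("width", 4)):
            if x.shape[axis] != cfg.input_edge:
                raise ValueError(f"{name} axis has length {x.shape[axis]}; "
                                 f"config requires input_edge={cfg.input_edge}")

    def encode(self, x: np.ndarray, train: bool = True) -> EncoderState:
        """Run the shared encoder, collecting skip features and pool indices."""
        self._check_input(x)
        skips, indices = [], []
        for block, pool in zip(self.enc_blocks, self.enc_pools):
            x = block.forward(x, train=train)
            skips.append(x)
            x = pool.forward(x, train=train)
            indices.append(pool.indices)
        return EncoderState(bottleneck=x, skip_features=skips,
                            pool_indices=indices)

    def _check_state(self, state: EncoderState) -> None:
        B = self.config.num_blocks
        if len(state.skip_features) != B or len(state.pool_indices) != B:
            raise ValueError(f"encoder state has {len(state.skip_features)} skip "
                             f"tensors and {len(state.pool_indices)} index sets; "
                             f"expected {B} of each")

    def decode_skip(self, state: EncoderState, train: bool = True) -> np.ndarray:
        """U-Net-style decoding: upsample, concatenate skip, convolve."""
        self._check_state(state)
        B = self.config.num_blocks
        x = state.bottleneck
        for stage, b in enumerate(reversed(range(B))):
            x = self.skip_ups[stage].forward(x, train=train)
            skip = state.skip_features[b]
            if skip.shape[2:] != x.shape[2:]:
                raise ValueError(f"skip tensor {b} has spatial shape "
                                 f"{skip.shape[2:]}; expected {x.shape[2:]}")
            x = np.concatenate([x, skip], axis=1)
            x = self.skip_blocks[stage].forward(x, train=train)
        return x

    def decode_index(self, state: EncoderState, train: bool = True) -> np.ndarray:
        """SegNet-style decoding: max-unpool with recorded indices, convolve."""
        self._check_state(state)
        B = self.config.num_blocks
        x = state.bottleneck
        for stage, b in enumerate(reversed(range(B))):
            x = self.idx_unpools[stage].forward(x, state.pool_indices[b],
                                                train=train)
            x = self.idx_blocks[stage].forward(x, train=train)
        return x

    def forward_logits(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Full pass up to (unnormalized) class scores; caches for backward."""
        state = self.encode(x, train=train)
        a = self.decode_skip(state, train=train)
        b = self.decode_index(state, train=train)
        fused = fuse(a, b, self.config.fusion_mode)
        if train:
            self._fusion_cache = (a, b)
        return self.classifier.forward(fused, train=train)

    def forward_probs(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        logits = self.forward_logits(x, train=train)
        return softmax_channels(logits)

    def predict(self, stack: ModalityStack | np.ndarray):
        """Segment one subject.

        Returns ``(probabilities, SegmentationMap)``: probabilities have one
        channel per class and sum to 1 at every voxel; the label map is the
        per-voxel argmax with ties broken toward the lowest class index.
        """
        spacing = (1.0, 1.0, 1.0)
        if isinstance(stack, ModalityStack):
            spacing = stack.spacing
            x = stack.data
        else:
            x = np.asarray(stack, dtype=np.float32)
        probs = self.forward_probs(x[None], train=False)[0]
        labels = np.argmax(probs, axis=0).astype(np.int16)
        return probs, SegmentationMap(labels, spacing)

    # ------------------------------------------------------------------ #
    # backward
    # ------------------------------------------------------------------ #
    def backward(self, g_logits: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the logits through the whole net."""
        if self._fusion_cache is None:
            raise RuntimeError("backward requires a prior forward_logits(train=True)")
        g = self.classifier.backward(g_logits)
        a, b = self._fusion_cache
        self._fusion_cache = None
        mode = self.config.fusion_mode
        if mode == "A":
            ga, gb = g, g
        elif mode == "M":
            ga, gb = g * b, g * a
        else:  # C
            w = a.shape[1]
            ga, gb = g[:, :w], g[:, w:]

        # skip decoder (reverse of its forward stage order)
        B = self.config.num_blocks
        g = ga
        gskips = [None] * B
        for stage in reversed(range(B)):
            b_idx = B - 1 - stage
            g = self.skip_blocks[stage].backward(g)
            split = self._skip_split[stage]
            g_up, gskips[b_idx] = g[:, :split], g[:, split:]
            g = self.skip_ups[stage].backward(np.ascontiguousarray(g_up))
        g_bottleneck = g

        # index decoder
        g = gb
        for stage in reversed(range(B)):
            g = self.idx_blocks[stage].backward(g)
            g = self.idx_unpools[stage].backward(g)
        g_bottleneck = g_bottleneck + g

        # shared encoder
        g = g_bottleneck
        for b_idx in reversed(range(B)):
            g = self.enc_pools[b_idx].backward(g)
            g = g + gskips[b_idx]
            g = self.enc_blocks[b_idx].backward(g)

    # ------------------------------------------------------------------ #
    # parameters / persistence
    # ------------------------------------------------------------------ #
    def params(self) -> list[nn.Param]:
        out = []
        for block in (*self.enc_blocks, *self.skip_blocks, *self.idx_blocks):
            out.extend(block.params())
        out.extend(self.classifier.params())
        return out

    def buffers(self) -> dict[str, np.ndarray]:
        out = {}
        for block in (*self.enc_blocks, *self.skip_blocks, *self.idx_blocks):
            out.update(block.buffers())
        return out

    def num_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.value for p in self.params()}
        dup = len(state) != len(self.params())
        if dup:
            raise RuntimeError("duplicate parameter names")
        state.update(self.buffers())
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.value[...] = state[p.name]
        for name, buf in self.buffers().items():
            buf[...] = state[name]


def build_fusionnet(config: FusionNetConfig, seed: int = 0,
                    dtype=np.float32) -> FusionNet:
    """Construct the network with He-normal initial weights drawn from ``seed``."""
    return FusionNet(config, np.random.default_rng(seed), dtype=dtype)


def fuse(a: np.ndarray, b: np.ndarray, mode: str) -> np.ndarray:
    """Combine the two decoder outputs.

    ``A`` sums elementwise, ``M`` multiplies elementwise, ``C`` concatenates
    along the channel axis (channel counts add).
    """
    if mode not in FUSION_MODES:
        raise ValueError(f"fusion mode must be one of {FUSION_MODES}")
    if a.shape[2:] != b.shape[2:] or a.shape[0] != b.shape[0]:
        raise ValueError(f"spatial/batch shapes differ: {a.shape} vs {b.shape}")
    if mode in ("A", "M") and a.shape[1] != b.shape[1]:
        raise ValueError(f"modes A and M require equal channel counts; "
                         f"got {a.shape[1]} and {b.shape[1]}")
    if mode == "A":
        return a + b
    if mode == "M":
        return a * b
    return np.concatenate([a, b], axis=1)


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the channel axis of (N, C, ...)."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def save_checkpoint(model: FusionNet, path, extra: dict | None = None) -> None:
    """Serialize weights + config (self-describing checkpoint)."""
    meta = {"config": asdict(model.config), "extra": extra or {}}
    arrays = {k.replace(".", "__"): v for k, v in model.state_dict().items()}
    with open(path, "wb") as fh:
        np.savez(fh, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[FusionNet, dict]:
    """Rebuild a network from a checkpoint written by :func:`save_checkpoint`."""
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        state = {k.replace("__", "."): npz[k] for k in npz.files if k != "__meta__"}
    config = FusionNetConfig(**meta["config"])
    model = build_fusionnet(config, seed=0)
    model.load_state_dict(state)
    return model, meta["extra"]
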