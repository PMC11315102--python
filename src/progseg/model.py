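"""LSTM-UNet: a 3D U-Net with a convolutional LSTM at every skip connection.

The network segments the current fraction's image given a 3-channel input
(previous fraction's image, previous contours as a label map, current
image).  Each encoder level feeds its feature map as x(t) into a 3D
convolutional LSTM cell whose (h, c) state persists across the fractions
of one patient; the cell outputs c(t) are what the decoder consumes
through the skip connections.  Memory is zeroed at patient boundaries so
each course starts blank.

Two memory-free baselines share the same U-Net topology: ``unet_prior``
(3-channel input, plain skip connections) and ``unet_ds`` (current image
only, 1 channel).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import nn
from .nn import Module, Parameter, Tensor

VARIANTS = ("lstm_unet", "unet_prior", "unet_ds")


@dataclasses.dataclass
class ModelConfig:
    in_channels: int = 3
    out_channels: int = 8
    base_features: int = 32
    levels: int = 5
    variant: str = "lstm_unet"
    skip_source: str = "c"  # what the decoder consumes from the LSTM: "c" or "h"
    seed: int = 0

    def __post_init__(self):
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.base_features < 1:
            raise ValueError("base_features must be >= 1")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.skip_source not in ("c", "h"):
            raise ValueError("skip_source must be 'c' or 'h'")
        if self.variant == "unet_ds" and self.in_channels != 1:
            raise ValueError("unet_ds takes a single image channel")
        if self.variant in ("lstm_unet", "unet_prior") and self.in_channels != 3:
            raise ValueError(f"{self.variant} takes a 3-channel input")

    def features(self, level: int) -> int:
        """Channel count at 1-based ``level`` (doubling per level)."""
        return self.base_features * 2 ** (level - 1)

    def check_spatial(self, spatial: tuple[int, int, int]) -> None:
        div = 2 ** (self.levels - 1)
        if any(s % div for s in spatial):
            raise ValueError(
                f"spatial shape {spatial} not divisible by 2^(levels-1)={div}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


MemoryState = list[tuple]  # per level: (h, c), numpy arrays or Tensors


def _he(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def _xavier(rng, shape, fan_in, fan_out):
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape)


class ConvBlock(Module):
    """conv(3^3) -> instance norm -> ReLU."""

    def __init__(self, cin: int, cout: int, rng):
        super().__init__()
        fan_in = cin * 27
        self.w = Parameter(_he(rng, (cout, cin, 3, 3, 3), fan_in))
        self.b = Parameter(np.zeros(cout))
        self.gamma = Parameter(np.ones(cout))
        self.beta = Parameter(np.zeros(cout))

    def __call__(self, x: Tensor) -> Tensor:
        return nn.relu(nn.instance_norm(nn.conv3d(x, self.w, self.b), self.gamma, self.beta))


class DoubleConv(Module):
    def __init__(self, cin: int, cout: int, rng):
        super().__init__()
        self.block1 = ConvBlock(cin, cout, rng)
        self.block2 = ConvBlock(cout, cout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.block2(self.block1(x))


class ConvLSTMCell(Module):
    """3D convolutional LSTM (input/forget/output/candidate gates, no peepholes).

        i = sigmoid(Wxi*x + Whi*h + bi)      f = sigmoid(Wxf*x + Whf*h + bf)
        o = sigmoid(Wxo*x + Who*h + bo)      g = tanh(Wxg*x + Whg*h + bg)
        c = f . c_prev + i . g               h = o . tanh(c)

    All convolutions are 3^3, resolution-preserving; hidden channels equal
    input channels.  The forget-gate bias starts at 1 so that fresh cells
    retain early-course memory.
    """

    GATES = ("i", "f", "o", "g")

    def __init__(self, channels: int, rng):
        super().__init__()
        self.channels = channels
        fan = channels * 27
        for gate in self.GATES:
            setattr(self, f"wx_{gate}", Parameter(_xavier(rng, (channels, channels, 3, 3, 3), fan, fan)))
            setattr(self, f"wh_{gate}", Parameter(_xavier(rng, (channels, channels, 3, 3, 3), fan, fan)))
            bias = np.ones(channels) if gate == "f" else np.zeros(channels)
            setattr(self, f"b_{gate}", Parameter(bias))

    def __call__(self, x: Tensor, h_prev: Tensor, c_prev: Tensor) -> tuple[Tensor, Tensor]:
        if x.shape != h_prev.shape or x.shape != c_prev.shape:
            raise ValueError(
                f"conv_lstm_cell: shapes disagree x={x.shape} h={h_prev.shape} c={c_prev.shape}")
        # one fused convolution over [x; h] for all four gates (same algebra,
        # one GEMM); per-gate parameters stay separately addressable
        xh = nn.concat([x, h_prev], axis=0)
        w_all = nn.concat(
            [nn.concat([getattr(self, f"wx_{g}"), getattr(self, f"wh_{g}")], axis=1)
             for g in self.GATES], axis=0)
        b_all = nn.concat([getattr(self, f"b_{g}") for g in self.GATES], axis=0)
        pre = nn.conv3d(xh, w_all, b_all)
        C = self.channels
        i = nn.sigmoid(nn.narrow(pre, 0, 0, C))
        f = nn.sigmoid(nn.narrow(pre, 0, C, C))
        o = nn.sigmoid(nn.narrow(pre, 0, 2 * C, C))
        g = nn.tanh(nn.narrow(pre, 0, 3 * C, C))
        c = f * c_prev + i * g
        h = o * nn.tanh(c)
        return h, c


class UpConv(Module):
    """Transposed conv, kernel 2 stride 2: exact x2 upsampling."""

    def __init__(self, cin: int, cout: int, rng):
        super().__init__()
        fan_in = cin * 8
        self.w = Parameter(_he(rng, (cout, cin, 2, 2, 2), fan_in))
        self.b = Parameter(np.zeros(cout))

    def __call__(self, x: Tensor) -> Tensor:
        return nn.conv_transpose3d(x, self.w, self.b)


class SegmentationUNet(Module):
    """U-Net trunk shared by LSTM-UNet and both baselines.

    ``config.variant`` decides whether skip connections pass through
    convolutional LSTM cells (lstm_unet) or directly (unet_prior/unet_ds).
    """

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        L = config.levels
        feats = [config.features(l) for l in range(1, L + 1)]

        self.encoders = [
            DoubleConv(config.in_channels if l == 0 else feats[l - 1], feats[l], rng)
            for l in range(L)
        ]
        self.has_lstm = config.variant == "lstm_unet"
        if self.has_lstm:
            self.lstm_cells = [ConvLSTMCell(feats[l], rng) for l in range(L)]
        self.upconvs = [UpConv(feats[l + 1], feats[l], rng) for l in range(L - 1)]
        self.decoders = [DoubleConv(2 * feats[l], feats[l], rng) for l in range(L - 1)]
        fan_head = feats[0]
        self.head_w = Parameter(_he(rng, (config.out_channels, feats[0], 1, 1, 1), fan_head))
        self.head_b = Parameter(np.zeros(config.out_channels))

    # -- memory ---------------------------------------------------------
    def init_memory(self, spatial: tuple[int, int, int]) -> MemoryState:
        """All-zero (h, c) at every level; shapes follow the encoder pyramid."""
        self.config.check_spatial(spatial)
        memory = []
        for l in range(1, self.config.levels + 1):
            sub = tuple(s // 2 ** (l - 1) for s in spatial)
            shape = (self.config.features(l),) + sub
            memory.append((np.zeros(shape), np.zeros(shape)))
        return memory

    @staticmethod
    def detach_memory(memory: MemoryState) -> MemoryState:
        """Memory as plain arrays, cut from any autograd graph."""
        out = []
        for h, c in memory:
            h = h.data if isinstance(h, Tensor) else h
            c = c.data if isinstance(c, Tensor) else c
            out.append((h.copy(), c.copy()))
        return out

    # -- forward --------------------------------------------------------
    def __call__(self, x, memory: MemoryState | None = None):
        """Segment one fraction.

        ``x``: (in_channels, D, H, W) array or Tensor.  Returns
        ``(probabilities, new_memory)`` for the LSTM variant and
        ``(probabilities, None)`` for the stateless baselines.
        Probabilities are per-structure sigmoids in [0, 1].
        """
        x = nn.as_tensor(x)
        if x.shape[0] != self.config.in_channels:
            raise ValueError(
                f"expected {self.config.in_channels} input channels, got {x.shape[0]}")
        self.config.check_spatial(x.shape[1:])
        L = self.config.levels

        if self.has_lstm:
            if memory is None:
                memory = self.init_memory(x.shape[1:])
            if len(memory) != L:
                raise ValueError(f"memory has {len(memory)} levels, model has {L}")

        skips, new_memory = [], []
        feat = x
        for l in range(L):
            if l > 0:
                feat = nn.max_pool3d(feat)
            feat = self.encoders[l](feat)
            if self.has_lstm:
                h_prev, c_prev = memory[l]
                h, c = self.lstm_cells[l](feat, nn.as_tensor(h_prev), nn.as_tensor(c_prev))
                new_memory.append((h, c))
                skips.append(c if self.config.skip_source == "c" else h)
            else:
                skips.append(feat)

        y = skips[-1]  # bottom level feeds the decoder trunk
        for l in range(L - 2, -1, -1):
            y = self.upconvs[l](y)
            y = self.decoders[l](nn.concat([y, skips[l]], axis=0))
        probs = nn.sigmoid(nn.conv3d(y, self.head_w, self.head_b))
        return probs, (new_memory if self.has_lstm else None)

    def predict(self, x, memory: MemoryState | None = None):
        """Inference: numpy probabilities plus detached numpy memory."""
        with nn.no_grad():
            probs, mem = self(x, memory)
        return probs.data, (self.detach_memory(mem) if mem is not None else None)


def build_model(config: ModelConfig) -> SegmentationUNet:
    return SegmentationUNet(config)


def count_parameters(model_or_config) -> int:
    """Total trainable scalar parameter count."""
    model = (build_model(model_or_config)
             if isinstance(model_or_config, ModelConfig) else model_or_config)
    return int(sum(p.data.size for p in model.parameters()))


# -- checkpoints --------------------------------------------------------

def save_checkpoint(model: SegmentationUNet, path: str | Path, extra: dict | None = None) -> None:
    """Single-file checkpoint with the config embedded."""
    payload = {f"param/{k}": v for k, v in model.state_dict().items()}
    payload["config_json"] = np.frombuffer(
        json.dumps({"config": model.config.to_dict(), "extra": extra or {}}).encode(), dtype=np.uint8)
    np.savez_compressed(str(path), **payload)


def load_checkpoint(path: str | Path) -> tuple[SegmentationUNet, dict]:
    with np.load(str(path)) as z:
        meta = json.loads(bytes(z["config_json"].tobytes()).decode())
        state = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    model = build_model(ModelConfig(**meta["config"]))
    model.load_state_dict(state)
    return model, meta.get("extra", {})


def save_memory(memory: MemoryState, path: str | Path) -> None:
    arrays = {}
    for l, (h, c) in enumerate(memory):
        arrays[f"h{l}"] = h.data if isinstance(h, Tensor) else h
        arrays[f"c{l}"] = c.data if isinstance(c, Tensor) else c
    np.savez_compressed(str(path), **arrays)


def load_memory(path: str | Path) -> MemoryState:
    with np.load(str(path)) as z:
        L = sum(1 for k in z.files if k.startswith("h"))
        return [(z[f"h{l}"].copy(), z[f"c{l}"].copy()) for l in range(L)]
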