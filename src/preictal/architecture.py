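"""Declarative CNN-BiLSTM architecture and shape-propagation verifier.

The reference network is dual-branch: a convolutional branch over the
[22 x 10 x 256] epoch grid (1x1 conv, 3x3 conv to 44 maps, batch norm,
2x4 max pool, activation, 3x3 conv to 5 maps, batch norm, 2x4 max pool,
activation) in parallel with a five-layer stacked bidirectional LSTM that
reads the same epoch as 22 time steps of 2560 features (per-direction
hidden sizes 640, 320, 80, 20, 1). The flattened branch outputs
(5*1*15 = 75 and 22*2 = 44) are concatenated into a 119-wide fused vector
and mapped to two logits.

Max pooling uses stride equal to the pool size with floor division of the
spatial dims — the only reading consistent with the reference output
dimensions (8 -> 4 and 254 -> 63 under 2x4 pools).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from . import nn

Kind = Literal["conv2d", "batchnorm", "maxpool", "activation", "bilstm", "fully_connected"]
Branch = Literal["cnn", "bilstm", "fusion"]

__all__ = [
    "LayerSpec",
    "ShapeState",
    "TrainHyperparams",
    "table1_spec",
    "reduced_spec",
    "propagate_shapes",
    "build_model",
    "format_shape_table",
    "REFERENCE_OUTPUT_DIMS",
]


@dataclass(frozen=True)
class LayerSpec:
    kind: Kind
    branch: Branch
    in_channels: int | None = None
    out_channels: int | None = None
    kernel: tuple[int, int] | None = None
    pool: tuple[int, int] | None = None
    hidden: int | None = None

    def __post_init__(self) -> None:
        if self.kind == "conv2d" and (not self.kernel or min(self.kernel) < 1):
            raise ValueError("conv2d requires a positive kernel")
        if self.kind == "maxpool" and (not self.pool or min(self.pool) < 1):
            raise ValueError("maxpool requires a positive pool")
        if self.kind == "bilstm":
            if not self.hidden or self.hidden < 1:
                raise ValueError("bilstm requires a positive per-direction hidden size")
            if self.out_channels != 2 * self.hidden:
                raise ValueError("bilstm output width must be 2 * hidden")


@dataclass(frozen=True)
class ShapeState:
    """Propagated tensor shape after one layer (None dims unused)."""

    label: str
    shape: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.shape):
            raise ValueError(f"{self.label}: non-positive dimension in {self.shape}")


@dataclass(frozen=True)
class TrainHyperparams:
    """Training settings of the multi-patient reference run."""

    activation: str = "leaky_relu"
    loss: str = "cross_entropy"
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    batch_size: int = 128
    epochs: int = 250
    weight_decay: float = 0.9
    leaky_slope: float = 0.01
    seed: int = 42

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def table1_spec() -> list[LayerSpec]:
    """The full-size reference architecture, row for row."""
    c = lambda i, o, k: LayerSpec("conv2d", "cnn", i, o, kernel=k)  # noqa: E731
    return [
        c(22, 22, (1, 1)),
        c(22, 44, (3, 3)),
        LayerSpec("batchnorm", "cnn", 44, 44),
        LayerSpec("maxpool", "cnn", 44, 44, pool=(2, 4)),
        LayerSpec("activation", "cnn"),
        c(44, 5, (3, 3)),
        LayerSpec("batchnorm", "cnn", 5, 5),
        LayerSpec("maxpool", "cnn", 5, 5, pool=(2, 4)),
        LayerSpec("activation", "cnn"),
        LayerSpec("bilstm", "bilstm", 2560, 1280, hidden=640),
        LayerSpec("bilstm", "bilstm", 1280, 640, hidden=320),
        LayerSpec("bilstm", "bilstm", 640, 160, hidden=80),
        LayerSpec("bilstm", "bilstm", 160, 40, hidden=20),
        LayerSpec("bilstm", "bilstm", 40, 2, hidden=1),
        LayerSpec("activation", "bilstm"),
        LayerSpec("fully_connected", "fusion", None, 119),
        LayerSpec("fully_connected", "fusion", 119, 2),
    ]


#: Output dimension column of the reference table at batch size 128
#: (input row first, then one entry per layer of :func:`table1_spec`).
REFERENCE_OUTPUT_DIMS: list[tuple[int, ...]] = [
    (128, 22, 10, 256),
    (128, 22, 10, 256),
    (128, 44, 8, 254),
    (128, 44, 8, 254),
    (128, 44, 4, 63),
    (128, 44, 4, 63),
    (128, 5, 2, 61),
    (128, 5, 2, 61),
    (128, 5, 1, 15),
    (128, 5, 1, 15),
    (128, 22, 1280),
    (128, 22, 640),
    (128, 22, 160),
    (128, 22, 40),
    (128, 22, 2),
    (128, 22, 2),
    (128, 119),
    (128, 2),
]


def reduced_spec(
    in_channels: int = 22,
    conv_channels: tuple[int, int] = (8, 4),
    lstm_hidden: int = 8,
    rows: int = 10,
    cols: int = 256,
) -> list[LayerSpec]:
    """A scaled-down variant of the reference network for CPU-scale runs.

    Same topology (dual branch, pooled convolutions, BiLSTM over channel
    steps, fused head), far fewer parameters.
    """
    c1, c2 = conv_channels
    after_conv1 = (rows - 2, cols - 2)
    after_pool1 = (after_conv1[0] // 2, after_conv1[1] // 4)
    after_conv2 = (after_pool1[0] - 2, after_pool1[1] - 2)
    after_pool2 = (after_conv2[0] // 2, after_conv2[1] // 4)
    cnn_flat = c2 * after_pool2[0] * after_pool2[1]
    lstm_flat = in_channels * 2 * lstm_hidden
    return [
        LayerSpec("conv2d", "cnn", in_channels, c1, kernel=(3, 3)),
        LayerSpec("batchnorm", "cnn", c1, c1),
        LayerSpec("maxpool", "cnn", c1, c1, pool=(2, 4)),
        LayerSpec("activation", "cnn"),
        LayerSpec("conv2d", "cnn", c1, c2, kernel=(3, 3)),
        LayerSpec("batchnorm", "cnn", c2, c2),
        LayerSpec("maxpool", "cnn", c2, c2, pool=(2, 4)),
        LayerSpec("activation", "cnn"),
        LayerSpec("bilstm", "bilstm", rows * cols, 2 * lstm_hidden, hidden=lstm_hidden),
        LayerSpec("activation", "bilstm"),
        LayerSpec("fully_connected", "fusion", None, cnn_flat + lstm_flat),
        LayerSpec("fully_connected", "fusion", cnn_flat + lstm_flat, 2),
    ]


class SpecError(ValueError):
    """Raised when a layer spec cannot propagate a valid shape."""


def propagate_shapes(
    spec: Sequence[LayerSpec],
    input_shape: tuple[int, int, int, int] = (128, 22, 10, 256),
) -> list[ShapeState]:
    """Propagate tensor shapes through the spec; the input row comes first.

    Valid convolutions shrink each spatial dim by ``kernel - 1``; pooling
    floor-divides by the pool size; batch norm and activations preserve
    shape; each BiLSTM keeps the sequence length and doubles its hidden
    size; the first fusion row concatenates the flattened branches and
    must match its declared width.
    """
    B, C, H, W = input_shape
    states = [ShapeState("input", input_shape)]
    ch, h, w = C, H, W
    seq_len, feat = C, H * W
    cnn_done = lstm_done = False

    for idx, layer in enumerate(spec):
        label = f"{idx}:{layer.kind}"
        if layer.branch == "cnn":
            if layer.kind == "conv2d":
                if layer.in_channels != ch:
                    raise SpecError(f"{label}: expects {layer.in_channels} channels, has {ch}")
                kh, kw = layer.kernel
                ch, h, w = layer.out_channels, h - (kh - 1), w - (kw - 1)
            elif layer.kind == "maxpool":
                ph, pw = layer.pool
                h, w = h // ph, w // pw
            elif layer.kind not in ("batchnorm", "activation"):
                raise SpecError(f"{label}: kind not valid in the cnn branch")
            states.append(ShapeState(label, (B, ch, h, w)))
            cnn_done = True
        elif layer.branch == "bilstm":
            if layer.kind == "bilstm":
                if layer.in_channels != feat:
                    raise SpecError(f"{label}: expects {layer.in_channels} features, has {feat}")
                feat = 2 * layer.hidden
            elif layer.kind != "activation":
                raise SpecError(f"{label}: kind not valid in the recurrent branch")
            states.append(ShapeState(label, (B, seq_len, feat)))
            lstm_done = True
        else:  # fusion
            if not (cnn_done and lstm_done):
                raise SpecError(f"{label}: fusion before both branches are complete")
            fused = ch * h * w + seq_len * feat
            if layer.in_channels is None:
                if layer.out_channels != fused:
                    raise SpecError(
                        f"{label}: declared fused width {layer.out_channels} != "
                        f"{ch}*{h}*{w} + {seq_len}*{feat} = {fused}"
                    )
                states.append(ShapeState(label, (B, fused)))
            else:
                prev = states[-1].shape[-1]
                if layer.in_channels != prev:
                    raise SpecError(f"{label}: expects width {layer.in_channels}, has {prev}")
                states.append(ShapeState(label, (B, layer.out_channels)))
    return states


def build_model(
    spec: Sequence[LayerSpec],
    hyperparams: TrainHyperparams | None = None,
    input_shape: tuple[int, int, int, int] = (128, 22, 10, 256),
    dtype=np.float64,
) -> nn.DualBranchNet:
    """Construct the trainable network; shape propagation must succeed first."""
    hp = hyperparams or TrainHyperparams()
    propagate_shapes(spec, input_shape)  # raises SpecError on any mismatch
    rng = np.random.default_rng(hp.seed)

    cnn_layers: list[nn.Layer] = []
    lstm_layers: list[nn.Layer] = []
    fusion_rows: list[LayerSpec] = []
    for layer in spec:
        if layer.branch == "cnn":
            if layer.kind == "conv2d":
                cnn_layers.append(nn.Conv2d(layer.in_channels, layer.out_channels,
                                            layer.kernel, rng, dtype))
            elif layer.kind == "batchnorm":
                cnn_layers.append(nn.BatchNorm2d(layer.out_channels, dtype=dtype))
            elif layer.kind == "maxpool":
                cnn_layers.append(nn.MaxPool2d(layer.pool))
            else:
                cnn_layers.append(nn.LeakyReLU(hp.leaky_slope))
        elif layer.branch == "bilstm":
            if layer.kind == "bilstm":
                lstm_layers.append(nn.BiLSTM(layer.in_channels, layer.hidden, rng, dtype))
            else:
                lstm_layers.append(nn.LeakyReLU(hp.leaky_slope))
        else:
            fusion_rows.append(layer)

    if not fusion_rows:
        raise SpecError("spec has no fusion head")
    fused_width = fusion_rows[0].out_channels if fusion_rows[0].in_channels is None \
        else fusion_rows[0].in_channels
    out_width = fusion_rows[-1].out_channels
    head = nn.Linear(fused_width, out_width, rng, dtype)
    return nn.DualBranchNet(cnn_layers, lstm_layers, head)


def format_shape_table(
    spec: Sequence[LayerSpec],
    input_shape: tuple[int, int, int, int] = (128, 22, 10, 256),
    reference: Sequence[tuple[int, ...]] | None = None,
) -> str:
    """Human-readable propagated-shape table, optionally with a reference column."""
    states = propagate_shapes(spec, input_shape)
    lines = [f"{'layer':<24}{'output dimension':<24}" + ("reference" if reference else "")]
    for i, st in enumerate(states):
        ref = ""
        if reference:
            ref = str(reference[i]) + ("  OK" if tuple(reference[i]) == st.shape else "  MISMATCH")
        lines.append(f"{st.label:<24}{str(st.shape):<24}{ref}")
    return "\n".join(lines)
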