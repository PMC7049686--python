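"""Architecture families for differential-binding sequence models.

Two families are provided:

* a shallow, DeepBind-style CNN — one convolution followed by concatenated
  global max- and average-pooling and fully connected layers;
* a deep, Basenji-style CNN — repeated pooling blocks (conv → batch-norm →
  ReLU → 1x bottleneck conv → dropout → max-pool) followed by dilated
  convolution blocks whose outputs are concatenated channel-wise onto the
  running representation (hyper-residual), ending in a linear 1x convolution
  and global average pooling.

Both expose named heads.  Classification heads emit pre-softmax logits;
probabilities are a separate view, so attribution always operates on raw
logits.  Structural calculators (receptive field, convolution-layer count,
input-length sampling) live here because model selection depends on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

MIN_INPUT_LENGTH = 200
MAX_INPUT_LENGTH = 2000

__all__ = [
    "ShallowCNNSpec",
    "DeepModelSpec",
    "HeadSpec",
    "ModelGraph",
    "build_shallow_cnn",
    "build_deep_cnn",
    "count_conv_layers",
    "compute_receptive_field",
    "sample_input_length",
]


@dataclass
class ShallowCNNSpec:
    """Hyper-parameters of the one-convolution CNN."""

    n_filters: int = 32
    filter_width: int = 12
    fc_sizes: tuple[int, ...] = (32,)
    dropout: float = 0.1
    input_length: int = 300

    def __post_init__(self):
        if self.filter_width > self.input_length:
            raise ValueError("filter_width must not exceed input_length")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class DeepModelSpec:
    """Hyper-parameters of the deep pooling/dilation architecture.

    ``channels`` and ``kernel_widths`` give per-block values for the
    ``n_pool_blocks + n_dil_blocks`` blocks in order; an int is broadcast.
    The dilation rate of dilation block j is
    ``min(dilation_base * dilation_growth**j, max_dilation)`` (rounded).
    """

    n_pool_blocks: int = 2
    n_dil_blocks: int = 2
    channels: int | tuple[int, ...] = 32
    kernel_widths: int | tuple[int, ...] = 5
    pool_width: int = 4
    bottleneck: str = "relu"  # off | linear | relu
    bottleneck_ratio: float = 0.5
    dropout: float = 0.1
    dilation_base: int = 2
    dilation_growth: float = 2.0
    max_dilation: int = 4
    input_length: int = 300

    def __post_init__(self):
        n = self.n_pool_blocks + self.n_dil_blocks
        if isinstance(self.channels, int):
            self.channels = (self.channels,) * n
        if isinstance(self.kernel_widths, int):
            self.kernel_widths = (self.kernel_widths,) * n
        if len(self.channels) != n or len(self.kernel_widths) != n:
            raise ValueError("channels/kernel_widths must give one value per block")
        if self.bottleneck not in ("off", "linear", "relu"):
            raise ValueError(f"unknown bottleneck mode {self.bottleneck!r}")
        if not 0.0 < self.bottleneck_ratio <= 1.0:
            raise ValueError("bottleneck_ratio must be in (0, 1]")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.dilation_base < 1:
            raise ValueError("dilation_base must be >= 1")

    def dilation_rates(self) -> list[int]:
        rates = []
        for j in range(self.n_dil_blocks):
            rates.append(int(min(round(self.dilation_base * self.dilation_growth ** j),
                                 self.max_dilation)))
        return rates


@dataclass
class HeadSpec:
    """A named model output: classification over ``names`` or regression
    onto ``names`` (replicate identifiers)."""

    name: str
    kind: str  # "classification" | "regression"
    names: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in ("classification", "regression"):
            raise ValueError(f"unknown head kind {self.kind!r}")
        if not self.names:
            raise ValueError("head needs at least one output name")

    @property
    def size(self) -> int:
        return len(self.names)


class _HyperResidualBlock(nn.Layer):
    """y = concat([x, body(x)]) along the channel axis."""

    def __init__(self, body: nn.Sequential, in_channels: int):
        self.body = body
        self.in_channels = in_channels

    def params(self):
        return self.body.params()

    def forward(self, x, train=False):
        return np.concatenate([x, self.body.forward(x, train)], axis=1)

    def backward(self, dout):
        c = self.in_channels
        return dout[:, :c] + self.body.backward(dout[:, c:])


def _iter_layers(layer: nn.Layer):
    yield layer
    if isinstance(layer, nn.Sequential):
        for sub in layer.layers:
            yield from _iter_layers(sub)
    elif isinstance(layer, _HyperResidualBlock):
        yield from _iter_layers(layer.body)
    elif isinstance(layer, nn.GlobalMaxAvgPool):
        yield layer.gmp
        yield layer.gap


class ModelGraph:
    """A trunk shared by one or more named heads.

    ``forward``/``backward`` support training on a single head per batch
    (the parallel multitask mode alternates heads across batches).
    ``input_gradients`` backpropagates a chosen logit to the one-hot input
    with the network in evaluation mode.
    """

    def __init__(self, trunk: nn.Layer, heads: dict[str, tuple[HeadSpec, nn.Layer]],
                 spec, family: str):
        self.trunk = trunk
        self.heads = heads
        self.spec = spec
        self.family = family

    # -- introspection -------------------------------------------------

    @property
    def input_length(self) -> int:
        return self.spec.input_length

    def head_spec(self, head: str) -> HeadSpec:
        return self.heads[head][0]

    def parameters(self) -> list[nn.Parameter]:
        seen: list[nn.Parameter] = list(self.trunk.params())
        for _, layer in self.heads.values():
            seen.extend(layer.params())
        return seen

    def _all_layers(self):
        yield from _iter_layers(self.trunk)
        for _, layer in self.heads.values():
            yield from _iter_layers(layer)

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- state (for best-epoch restore and model cloning) --------------

    def get_state(self) -> list[np.ndarray]:
        state = [p.data.copy() for p in self.parameters()]
        for layer in self._all_layers():
            if isinstance(layer, nn.BatchNorm1d):
                state.append(layer.running_mean.copy())
                state.append(layer.running_var.copy())
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        it = iter(state)
        for p in self.parameters():
            p.data[...] = next(it)
        for layer in self._all_layers():
            if isinstance(layer, nn.BatchNorm1d):
                layer.running_mean[...] = next(it)
                layer.running_var[...] = next(it)

    def freeze(self) -> None:
        for p in self.parameters():
            p.trainable = False

    # -- forward / backward --------------------------------------------

    def forward(self, x: np.ndarray, head: str, train: bool = False) -> np.ndarray:
        h = self.trunk.forward(x, train)
        return self.heads[head][1].forward(h, train)

    def backward(self, dout: np.ndarray, head: str) -> np.ndarray:
        dh = self.heads[head][1].backward(dout)
        return self.trunk.backward(dh)

    def predict_logits(self, x: np.ndarray, head: str, batch_size: int = 256) -> np.ndarray:
        """Evaluation-mode outputs: pre-softmax logits for classification
        heads, raw predictions for regression heads."""
        outs = []
        for i in range(0, x.shape[0], batch_size):
            outs.append(self.forward(x[i:i + batch_size], head, train=False))
        return np.concatenate(outs, axis=0)

    def predict_proba(self, x: np.ndarray, head: str, batch_size: int = 256) -> np.ndarray:
        if self.head_spec(head).kind != "classification":
            raise ValueError("probabilities are defined for classification heads only")
        return nn.softmax(self.predict_logits(x, head, batch_size))

    def input_gradients(self, x: np.ndarray, head: str, class_index: int,
                        batch_size: int = 256) -> np.ndarray:
        """d logit[class_index] / d input, per example, evaluation mode."""
        grads = []
        for i in range(0, x.shape[0], batch_size):
            xb = x[i:i + batch_size]
            out = self.forward(xb, head, train=False)
            dout = np.zeros_like(out)
            dout[:, class_index] = 1.0
            grads.append(self.backward(dout, head))
        return np.concatenate(grads, axis=0)


# -- structural calculators --------------------------------------------


def count_conv_layers(spec: DeepModelSpec) -> int:
    """Total convolutional layers, counting 1x bottleneck convolutions and
    the final linear 1x output convolution."""
    if spec.bottleneck == "off":
        return spec.n_pool_blocks + spec.n_dil_blocks + 1
    return 2 * spec.n_pool_blocks + 2 * spec.n_dil_blocks + 1


def compute_receptive_field(spec: DeepModelSpec | ShallowCNNSpec) -> int:
    """Maximum input span that can affect one activation just before global
    pooling: RF = 1 + sum_i (k_i - 1) * d_i * prod_{j<i} s_j over conv and
    pool layers in order (1x convolutions contribute nothing)."""
    if isinstance(spec, ShallowCNNSpec):
        return spec.filter_width
    rf = 1
    stride = 1
    for i in range(spec.n_pool_blocks):
        rf += (spec.kernel_widths[i] - 1) * stride
        rf += (spec.pool_width - 1) * stride
        stride *= spec.pool_width
    for j, d in enumerate(spec.dilation_rates()):
        k = spec.kernel_widths[spec.n_pool_blocks + j]
        rf += (k - 1) * d * stride
    return rf


def sample_input_length(rf: int, rng: np.random.Generator) -> int:
    """Draw an input length uniformly from [RF, 2*RF], clipped to the
    200–2000 nt sequence-length bounds."""
    if rf < 1:
        raise ValueError("receptive field must be >= 1")
    if rf > MAX_INPUT_LENGTH:
        raise ValueError(f"receptive field {rf} exceeds the {MAX_INPUT_LENGTH} nt input bound")
    length = int(rng.integers(rf, 2 * rf + 1))
    return int(np.clip(length, MIN_INPUT_LENGTH, MAX_INPUT_LENGTH))


# -- builders ----------------------------------------------------------


def _check_input_length(length: int) -> None:
    if not MIN_INPUT_LENGTH <= length <= MAX_INPUT_LENGTH:
        raise ValueError(
            f"input_length {length} outside [{MIN_INPUT_LENGTH}, {MAX_INPUT_LENGTH}]")


def build_shallow_cnn(spec: ShallowCNNSpec, heads: list[HeadSpec],
                      rng: np.random.Generator | None = None) -> ModelGraph:
    """One convolution (ReLU), concatenated global max/average pooling
    (2 * n_filters features), then fully connected layers per head."""
    rng = rng or np.random.default_rng()
    _check_input_length(spec.input_length)
    if not heads:
        raise ValueError("at least one head is required")
    trunk = nn.Sequential([
        nn.Conv1d(4, spec.n_filters, spec.filter_width, rng=rng),
        nn.ReLU(),
        nn.GlobalMaxAvgPool(),
    ])
    head_map: dict[str, tuple[HeadSpec, nn.Layer]] = {}
    for h in heads:
        layers: list[nn.Layer] = []
        size_in = 2 * spec.n_filters
        for width in spec.fc_sizes:
            layers += [nn.Dense(size_in, width, rng=rng), nn.ReLU(),
                       nn.Dropout(spec.dropout, rng=rng)]
            size_in = width
        layers.append(nn.Dense(size_in, h.size, rng=rng))
        head_map[h.name] = (h, nn.Sequential(layers))
    return ModelGraph(trunk, head_map, spec, family="shallow")


def bottleneck_channels(ratio: float, preceding: int) -> int:
    return max(1, int(round(ratio * preceding)))


def build_deep_cnn(spec: DeepModelSpec, heads: list[HeadSpec],
                   rng: np.random.Generator | None = None) -> ModelGraph:
    """Pooling blocks, hyper-residual dilation blocks, then per head a
    linear 1x convolution and global average pooling."""
    rng = rng or np.random.default_rng()
    _check_input_length(spec.input_length)
    if not heads:
        raise ValueError("at least one head is required")

    layers: list[nn.Layer] = []
    ch_in = 4
    length = spec.input_length
    for i in range(spec.n_pool_blocks):
        ch = spec.channels[i]
        layers += [nn.Conv1d(ch_in, ch, spec.kernel_widths[i], rng=rng),
                   nn.BatchNorm1d(ch), nn.ReLU()]
        if spec.bottleneck != "off":
            bch = bottleneck_channels(spec.bottleneck_ratio, ch)
            layers.append(nn.Conv1d(ch, bch, 1, rng=rng))
            if spec.bottleneck == "relu":
                layers.append(nn.ReLU())
            ch = bch
        layers += [nn.Dropout(spec.dropout, rng=rng), nn.MaxPool1d(spec.pool_width)]
        ch_in = ch
        length //= spec.pool_width
        if length < 1:
            raise ValueError("pooled length fell below 1; too many pooling blocks")

    for j, d in enumerate(spec.dilation_rates()):
        k = spec.kernel_widths[spec.n_pool_blocks + j]
        if (k - 1) * d + 1 > length:
            raise ValueError("dilation window exceeds the pooled length")
        ch = spec.channels[spec.n_pool_blocks + j]
        body: list[nn.Layer] = [nn.Conv1d(ch_in, ch, k, dilation=d, rng=rng),
                                nn.BatchNorm1d(ch), nn.ReLU()]
        if spec.bottleneck != "off":
            bch = bottleneck_channels(spec.bottleneck_ratio, ch)
            body.append(nn.Conv1d(ch, bch, 1, rng=rng))
            if spec.bottleneck == "relu":
                body.append(nn.ReLU())
            ch = bch
        body.append(nn.Dropout(spec.dropout, rng=rng))
        layers.append(_HyperResidualBlock(nn.Sequential(body), in_channels=ch_in))
        ch_in = ch_in + ch

    trunk = nn.Sequential(layers)
    head_map: dict[str, tuple[HeadSpec, nn.Layer]] = {}
    for h in heads:
        head_map[h.name] = (h, nn.Sequential([
            nn.Conv1d(ch_in, h.size, 1, rng=rng),  # linear 1x output conv
            nn.GlobalAvgPool(),
        ]))
    return ModelGraph(trunk, head_map, spec, family="deep")
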