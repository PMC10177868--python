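"""Declarative network specifications, exact shape arithmetic, and model building.

A network is one or three parallel convolution channels, each a stack of
Conv → BN → ReLU → MaxPool repeated twice, followed by (for the multiscale
variant) concatenation along the length axis, a flatten, a batch-normalized
fully connected layer and a single linear output neuron.

``trace_shapes`` performs the integer feature-map arithmetic — valid
convolution shortens a length-``l`` map to ``l − k + 1``; 2:1 valid pooling
takes ``floor(l / 2)`` — and is cross-checked at runtime against the built
model.  With a 1000-point input the single-scale (5, 3) network flattens to
32 × 248 = 7936 features and the default three-channel multiscale network
to 16 × (246 + 247 + 248) = 11,856.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ArchitectureError
from . import nn

DEFAULT_MULTI_CHANNELS: tuple[tuple[int, int], ...] = ((7, 5), (7, 3), (5, 3))


@dataclass
class NetworkSpec:
    """Hyperparameters that define a single- or multiscale network."""

    mode: str = "multi"
    #: (first kernel, second kernel) per convolution channel
    channels: tuple[tuple[int, int], ...] = DEFAULT_MULTI_CHANNELS
    #: kernels per convolution layer; None → 32 (single) / 16 (multi)
    kernels_per_conv: int | None = None
    fc_units: int = 16
    output_units: int = 1
    input_length: int = 1000
    #: 'conv_bn_relu' (default) or 'conv_relu_bn'
    bn_placement: str = "conv_bn_relu"
    fc_activation: str = "relu"
    flatten_batchnorm: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("single", "multi"):
            raise ArchitectureError(f"unknown mode {self.mode!r}")
        self.channels = tuple(tuple(int(k) for k in pair) for pair in self.channels)
        if self.mode == "single" and len(self.channels) != 1:
            raise ArchitectureError("single mode takes exactly one kernel pair")
        if self.mode == "multi" and len(self.channels) < 2:
            raise ArchitectureError("multi mode needs at least two channels")
        if self.kernels_per_conv is None:
            self.kernels_per_conv = 32 if self.mode == "single" else 16
        if self.bn_placement not in ("conv_bn_relu", "conv_relu_bn"):
            raise ArchitectureError(f"unknown bn_placement {self.bn_placement!r}")
        if self.fc_activation not in ("relu", "linear"):
            raise ArchitectureError(f"unknown fc_activation {self.fc_activation!r}")

    @classmethod
    def single(cls, kernels: tuple[int, int] = (5, 3), **kwargs) -> "NetworkSpec":
        return cls(mode="single", channels=(tuple(kernels),), **kwargs)

    @classmethod
    def multi(cls, channels=DEFAULT_MULTI_CHANNELS, **kwargs) -> "NetworkSpec":
        return cls(mode="multi", channels=tuple(channels), **kwargs)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "channels": [list(pair) for pair in self.channels],
            "kernels_per_conv": self.kernels_per_conv,
            "fc_units": self.fc_units,
            "output_units": self.output_units,
            "input_length": self.input_length,
            "bn_placement": self.bn_placement,
            "fc_activation": self.fc_activation,
            "flatten_batchnorm": self.flatten_batchnorm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        d = dict(d)
        if "channels" in d:
            d["channels"] = tuple(tuple(pair) for pair in d["channels"])
        return cls(**d)


@dataclass
class LayerShape:
    name: str
    depth: int
    length: int
    width: int = 1


@dataclass
class LayerShapeTrace:
    """Per-layer (depth, length, width) bookkeeping for one network."""

    layers: list[LayerShape]
    channel_lengths: list[int]
    concat_length: int
    flatten_size: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.name, s.depth, s.length, s.width) for s in self.layers],
            columns=["layer", "depth", "length", "width"],
        )

    def __str__(self) -> str:
        lines = [f"{'layer':<24}{'depth':>6}{'length':>8}{'width':>7}"]
        for s in self.layers:
            lines.append(f"{s.name:<24}{s.depth:>6}{s.length:>8}{s.width:>7}")
        lines.append(f"flatten size: {self.flatten_size}")
        return "\n".join(lines)


def _conv_length(length: int, kernel: int, where: str) -> int:
    out = length - kernel + 1
    if out < 1:
        raise ArchitectureError(
            f"{where}: kernel {kernel} does not fit input of length {length}"
        )
    return out


def _pool_length(length: int, where: str) -> int:
    out = length // 2
    if out < 1:
        raise ArchitectureError(f"{where}: length {length} too short to pool")
    return out


def trace_shapes(spec: NetworkSpec) -> LayerShapeTrace:
    """Exact integer shape arithmetic for every layer of ``spec``."""
    layers = [LayerShape("input", 1, spec.input_length)]
    channel_lengths: list[int] = []
    depth = spec.kernels_per_conv
    for ci, (k1, k2) in enumerate(spec.channels, start=1):
        tag = f"ch{ci}" if spec.mode == "multi" else "conv"
        length = _conv_length(spec.input_length, k1, f"{tag}.conv1")
        layers.append(LayerShape(f"{tag}.conv1(k={k1})", depth, length))
        length = _pool_length(length, f"{tag}.pool1")
        layers.append(LayerShape(f"{tag}.pool1", depth, length))
        length = _conv_length(length, k2, f"{tag}.conv2")
        layers.append(LayerShape(f"{tag}.conv2(k={k2})", depth, length))
        length = _pool_length(length, f"{tag}.pool2")
        layers.append(LayerShape(f"{tag}.pool2", depth, length))
        channel_lengths.append(length)
    concat_length = sum(channel_lengths)
    if spec.mode == "multi":
        layers.append(LayerShape("concat", depth, concat_length))
    flatten_size = depth * concat_length
    layers.append(LayerShape("flatten", 1, flatten_size))
    layers.append(LayerShape("fc", 1, spec.fc_units))
    layers.append(LayerShape("output", 1, spec.output_units))
    return LayerShapeTrace(layers, channel_lengths, concat_length, flatten_size)


class DeepSpectraNet:
    """A built, trainable network; forward maps (n, 1, L) → (n, 1)."""

    def __init__(self, spec: NetworkSpec, seed: int, dtype=np.float32) -> None:
        self.spec = spec
        self.trace = trace_shapes(spec)
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        k_per = spec.kernels_per_conv

        def stage(c_in: int, c_out: int, kernel: int) -> list[nn.Layer]:
            conv = nn.Conv1d(c_in, c_out, kernel, rng, dtype)
            bn = nn.BatchNorm(c_out, dtype=dtype)
            if spec.bn_placement == "conv_bn_relu":
                return [conv, bn, nn.ReLU(), nn.MaxPool1d()]
            return [conv, nn.ReLU(), bn, nn.MaxPool1d()]

        self.channels = [
            nn.Sequential(stage(1, k_per, k1) + stage(k_per, k_per, k2))
            for k1, k2 in spec.channels
        ]
        head: list[nn.Layer] = [nn.Flatten()]
        if spec.flatten_batchnorm:
            head.append(nn.BatchNorm(self.trace.flatten_size, dtype=dtype))
        head.append(nn.Dense(self.trace.flatten_size, spec.fc_units, rng, dtype))
        if spec.fc_activation == "relu":
            head.append(nn.ReLU())
        head.append(nn.Dense(spec.fc_units, spec.output_units, rng, dtype))
        self.head = nn.Sequential(head)
        self._named: dict[str, tuple[nn.Layer, str]] = {}
        for i, ch in enumerate(self.channels):
            nn.collect_named(f"channel{i}", ch, self._named)
        nn.collect_named("head", self.head, self._named)

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 2:
            x = x[:, None, :]
        outs = [ch.forward(x, training) for ch in self.channels]
        self._channel_lengths = [o.shape[2] for o in outs]
        fused = outs[0] if len(outs) == 1 else np.concatenate(outs, axis=2)
        self._flat = fused.reshape(fused.shape[0], -1)  # runtime flatten introspection
        return self.head.forward(fused, training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.head.backward(np.asarray(grad, dtype=self.dtype))
        dxs = []
        offset = 0
        for ch, length in zip(self.channels, self._channel_lengths):
            dxs.append(ch.backward(g[:, :, offset : offset + length]))
            offset += length
        return np.sum(dxs, axis=0)

    @property
    def flatten_activation_size(self) -> int:
        """Length of the flattened feature vector seen at runtime."""
        return int(self._flat.shape[1])

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> dict[str, np.ndarray]:
        return {name: layer.parameters()[key] for name, (layer, key) in self._named.items()}

    def gradients(self) -> dict[str, np.ndarray]:
        out = {}
        for name, (layer, key) in self._named.items():
            grads = layer.gradients()
            if key in grads:
                out[name] = grads[key]
        return out

    def _stateful_layers(self) -> list[tuple[str, nn.Layer]]:
        seen: list[tuple[str, nn.Layer]] = []
        for name, (layer, _) in self._named.items():
            prefix = name.rsplit(".", 1)[0]
            if not any(l is layer for _, l in seen):
                seen.append((prefix, layer))
        return seen

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for prefix, layer in self._stateful_layers():
            for key, arr in layer.state().items():
                out[f"{prefix}.{key}"] = arr.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for prefix, layer in self._stateful_layers():
            for key, arr in layer.state().items():
                arr[...] = state[f"{prefix}.{key}"]

    def set_trainable(self, trainable: bool) -> None:
        for _, layer in self._stateful_layers():
            layer.trainable = trainable


def build_network(spec: NetworkSpec, seed: int, dtype=np.float32) -> DeepSpectraNet:
    """Build a trainable network with seeded parameter initialization."""
    return DeepSpectraNet(spec, seed, dtype)


def count_parameters(net: DeepSpectraNet) -> int:
    """Total trainable scalar parameters (weights, biases, BN scale/shift)."""
    total = 0
    for name, (layer, key) in net._named.items():
        if layer.trainable:
            total += layer.parameters()[key].size
    return total
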