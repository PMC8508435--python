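"""Network architecture specifications and weight-free shape arithmetic.

The proposed classifier (MEL-CAP) replaces the single wide first
convolution of the original capsule network with an Inception-style stem:
a cascade of small convolutions, batch normalisations and max-poolings that
aggressively reduces 299x299x3 dermoscopy images before the feature maps
are reshaped into primary capsules.  This module describes both that
architecture and the single-conv baseline as plain data
(:class:`ArchitectureSpec`), and provides :func:`compute_layer_shapes`, a
deterministic shape engine that propagates an input shape through every
layer without allocating any weights — so the exact published geometry can
be verified in microseconds.

Convolution arithmetic: ``valid`` padding gives ``floor((in - k)/s) + 1``,
``same`` gives ``ceil(in / s)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Any

import yaml

__all__ = [
    "LayerSpec",
    "DecoderSpec",
    "ArchitectureSpec",
    "ShapeError",
    "default_melcap_spec",
    "reduced_melcap_spec",
    "baseline_capsnet_spec",
    "compute_layer_shapes",
]

_LAYER_KINDS = {
    "conv",
    "batchnorm",
    "activation",
    "maxpool",
    "reshape",
    "caps_squash",
    "capsule_layer",
    "length",
}


class ShapeError(ValueError):
    """A layer produced a non-positive spatial dimension."""


@dataclass
class LayerSpec:
    """One layer of the network, mirroring a row of the published table."""

    name: str
    kind: str
    kernel: tuple[int, int] | None = None
    stride: int = 1
    padding: str | None = None  # "valid" | "same"; conv/maxpool only
    width: int | None = None  # filters (conv) or capsule dim (reshape)
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _LAYER_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kernel is not None and min(self.kernel) < 1:
            raise ValueError(f"{self.name}: kernel must be positive")
        if self.stride < 1:
            raise ValueError(f"{self.name}: stride must be positive")
        if self.kind in ("conv", "maxpool"):
            if self.padding not in ("valid", "same"):
                raise ValueError(f"{self.name}: padding must be valid/same")
        elif self.padding is not None:
            raise ValueError(f"{self.name}: padding defined for conv/maxpool only")


@dataclass
class DecoderSpec:
    """Fully connected reconstruction head regularising the class capsules.

    The decoder reads the (masked) class-capsule vectors and reconstructs a
    downsampled copy of the input image; its summed squared error is added
    to the classification loss with weight ``reconstruction_loss_weight``.
    """

    hidden_widths: tuple[int, ...] = (512, 1024)
    reconstruction_target_size: tuple[int, int, int] = (56, 56, 3)
    reconstruction_loss_weight: float = 0.0005

    def __post_init__(self) -> None:
        if self.reconstruction_loss_weight < 0:
            raise ValueError("reconstruction_loss_weight must be >= 0")


@dataclass
class ArchitectureSpec:
    """Ordered layer list plus the capsule hyper-parameters.

    ``layers`` lists every trainable-graph row (the input layer is implied
    by ``input_shape``).  ``primary_caps_dim`` is the dimension D of the
    primary capsules formed by reshaping the stem output;
    ``class_caps_features`` the dimension of each class capsule.
    """

    layers: list[LayerSpec]
    primary_caps_dim: int = 16
    num_classes: int = 2
    class_caps_features: int = 64
    routing_iterations: int = 1
    input_shape: tuple[int, int, int] = (299, 299, 3)
    decoder: DecoderSpec | None = None
    name: str = "melcap"

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        for layer in d["layers"]:
            if layer["kernel"] is not None:
                layer["kernel"] = list(layer["kernel"])
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ArchitectureSpec":
        d = dict(d)
        d["layers"] = [
            LayerSpec(**{**ld, "kernel": tuple(ld["kernel"]) if ld.get("kernel") else None})
            for ld in d["layers"]
        ]
        if d.get("decoder"):
            dec = dict(d["decoder"])
            dec["hidden_widths"] = tuple(dec["hidden_widths"])
            dec["reconstruction_target_size"] = tuple(dec["reconstruction_target_size"])
            d["decoder"] = DecoderSpec(**dec)
        d["input_shape"] = tuple(d["input_shape"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ArchitectureSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _conv_bn_act(idx: int, filters: int, kernel: int, stride: int, padding: str) -> list[LayerSpec]:
    return [
        LayerSpec(f"conv2d_{idx}", "conv", (kernel, kernel), stride, padding, filters),
        LayerSpec(f"batch_normalization_{idx}", "batchnorm"),
        LayerSpec(f"activation_{idx}", "activation", params={"fn": "relu"}),
    ]


def _capsule_tail(primary_dim: int, num_classes: int, class_features: int, routing: int) -> list[LayerSpec]:
    return [
        LayerSpec("primary_capsule_reshape", "reshape", width=primary_dim),
        LayerSpec("primary_capsule_squash", "caps_squash"),
        LayerSpec(
            "digit_capsule",
            "capsule_layer",
            width=class_features,
            params={"num_classes": num_classes, "routing_iterations": routing},
        ),
        LayerSpec("output_capsule", "length"),
    ]


def default_melcap_spec(
    input_size: int = 299,
    *,
    primary_caps_dim: int = 16,
    class_caps_features: int = 64,
    routing_iterations: int = 1,
    decoder: DecoderSpec | None = None,
) -> ArchitectureSpec:
    """The published MEL-CAP architecture.

    Stem (Inception-style): conv 32/3x3/s2 -> conv 32/3x3 -> conv 64/3x3
    (same) -> maxpool 3x3/s2 -> conv 80/1x1 -> conv 192/3x3 -> maxpool
    3x3/s2 -> conv 512/9x9/s2 (linear), each convolution except the last
    followed by batch normalisation and ReLU.  The 14x14x512 stem output is
    reshaped into 6272 primary capsules of 16 dimensions, squashed, routed
    (one iteration) into two 64-D class capsules, whose norms are the class
    scores.
    """
    layers: list[LayerSpec] = []
    layers += _conv_bn_act(1, 32, 3, 2, "valid")
    layers += _conv_bn_act(2, 32, 3, 1, "valid")
    layers += _conv_bn_act(3, 64, 3, 1, "same")
    layers.append(LayerSpec("max_pooling2d_1", "maxpool", (3, 3), 2, "valid"))
    layers += _conv_bn_act(4, 80, 1, 1, "valid")
    layers += _conv_bn_act(5, 192, 3, 1, "valid")
    layers.append(LayerSpec("max_pooling2d_2", "maxpool", (3, 3), 2, "valid"))
    # final stem conv is linear (no BN/activation row) before the squash
    layers.append(LayerSpec("conv2d_6", "conv", (9, 9), 2, "valid", 512))
    layers += _capsule_tail(primary_caps_dim, 2, class_caps_features, routing_iterations)
    return ArchitectureSpec(
        layers=layers,
        primary_caps_dim=primary_caps_dim,
        class_caps_features=class_caps_features,
        routing_iterations=routing_iterations,
        input_shape=(input_size, input_size, 3),
        decoder=decoder,
        name="melcap",
    )


def reduced_melcap_spec(
    input_size: int = 48,
    *,
    primary_caps_dim: int = 16,
    class_caps_features: int = 64,
    routing_iterations: int = 1,
) -> ArchitectureSpec:
    """Width-reduced MEL-CAP for small inputs and CPU-scale experiments.

    Same stem structure with filter counts scaled down (8/8/16/20/48) and a
    3x3 final convolution (the full 9x9 stride-2 conv would underflow a
    48-px input under valid padding).  Keeps 16-D primary capsules and
    64-D class capsules with one routing iteration.
    """
    layers: list[LayerSpec] = []
    layers += _conv_bn_act(1, 8, 3, 2, "valid")
    layers += _conv_bn_act(2, 8, 3, 1, "valid")
    layers += _conv_bn_act(3, 16, 3, 1, "same")
    layers.append(LayerSpec("max_pooling2d_1", "maxpool", (3, 3), 2, "valid"))
    layers += _conv_bn_act(4, 20, 1, 1, "valid")
    layers += _conv_bn_act(5, 48, 3, 1, "valid")
    layers.append(LayerSpec("max_pooling2d_2", "maxpool", (3, 3), 2, "valid"))
    layers.append(LayerSpec("conv2d_6", "conv", (3, 3), 2, "valid", 256))
    layers += _capsule_tail(primary_caps_dim, 2, class_caps_features, routing_iterations)
    return ArchitectureSpec(
        layers=layers,
        primary_caps_dim=primary_caps_dim,
        class_caps_features=class_caps_features,
        routing_iterations=routing_iterations,
        input_shape=(input_size, input_size, 3),
        name="melcap-reduced",
    )


def baseline_capsnet_spec(
    primary_dim: int = 8,
    class_features: int = 16,
    *,
    input_size: int = 299,
    routing_iterations: int = 1,
) -> ArchitectureSpec:
    """The single-conv baseline capsule network.

    A simplistic 256-filter 9x9 stride-1 ReLU convolution feeds a
    convolutional primary-capsule layer (32 channels of ``primary_dim``-D
    capsules, 9x9 kernel, stride 2) and then the class capsules.  The
    (8, 16) configuration is the original-style network; (16, 64) is the
    tuned configuration selected by the rank analysis.
    """
    if primary_dim <= 0 or class_features <= 0:
        raise ValueError(
            f"primary_dim and class_features must be positive, got "
            f"({primary_dim}, {class_features})"
        )
    layers: list[LayerSpec] = [
        LayerSpec("conv2d_1", "conv", (9, 9), 1, "valid", 256),
        LayerSpec("activation_1", "activation", params={"fn": "relu"}),
        LayerSpec("primary_caps_conv", "conv", (9, 9), 2, "valid", 32 * primary_dim),
    ]
    layers += _capsule_tail(primary_dim, 2, class_features, routing_iterations)
    return ArchitectureSpec(
        layers=layers,
        primary_caps_dim=primary_dim,
        class_caps_features=class_features,
        routing_iterations=routing_iterations,
        input_shape=(input_size, input_size, 3),
        name="capsnet-baseline",
    )


def _conv_out(size: int, k: int, stride: int, padding: str, layer: str) -> int:
    if padding == "same":
        out = math.ceil(size / stride)
    else:
        if k > size:
            raise ShapeError(
                f"layer {layer!r}: kernel {k} exceeds input size {size} under valid padding"
            )
        out = (size - k) // stride + 1
    if out < 1:
        raise ShapeError(f"layer {layer!r}: output spatial size underflows ({out})")
    return out


def compute_layer_shapes(
    spec: ArchitectureSpec,
    input_shape: tuple[int, int, int] | None = None,
) -> list[tuple[str, tuple[int, ...]]]:
    """Propagate an input shape through every layer (batch dim excluded).

    Returns one ``(name, shape)`` pair per layer in order.  Raises
    :class:`ShapeError` naming the offending layer if any spatial dimension
    underflows, or if the stem output cannot be reshaped into whole
    primary capsules.
    """
    shape: tuple[int, ...] = tuple(input_shape or spec.input_shape)
    if any(s < 1 for s in shape):
        raise ShapeError(f"input shape {shape} has non-positive entries")
    out: list[tuple[str, tuple[int, ...]]] = []
    for layer in spec.layers:
        if layer.kind == "conv":
            h, w, _ = shape
            kh, kw = layer.kernel
            shape = (
                _conv_out(h, kh, layer.stride, layer.padding, layer.name),
                _conv_out(w, kw, layer.stride, layer.padding, layer.name),
                layer.width,
            )
        elif layer.kind == "maxpool":
            h, w, c = shape
            kh, kw = layer.kernel
            shape = (
                _conv_out(h, kh, layer.stride, layer.padding, layer.name),
                _conv_out(w, kw, layer.stride, layer.padding, layer.name),
                c,
            )
        elif layer.kind in ("batchnorm", "activation", "caps_squash"):
            pass  # shape preserved
        elif layer.kind == "reshape":
            total = 1
            for s in shape:
                total *= s
            dim = layer.width or spec.primary_caps_dim
            if total % dim != 0:
                raise ShapeError(
                    f"layer {layer.name!r}: stem output of {total} values is not "
                    f"divisible by the primary capsule dimension {dim}"
                )
            shape = (total // dim, dim)
        elif layer.kind == "capsule_layer":
            ncls = layer.params.get("num_classes", spec.num_classes)
            shape = (ncls, layer.width or spec.class_caps_features)
        elif layer.kind == "length":
            shape = (shape[0],)
        out.append((layer.name, shape))
    return out
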