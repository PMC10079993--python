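"""Compact convolutional ERP classifier in two variants.

The network follows the EEGNet-style compact design: a bias-free temporal
convolution learns band-pass-like filters, a max-norm-constrained depthwise
convolution over all 22 electrodes learns one spatial filter pair per
temporal filter, and a separable (depthwise temporal + pointwise) block
mixes feature maps cheaply before a 1x1 classification convolution with
log-softmax output.

Variants:

* ``eeg`` — input one 22 x 250 epoch (channels x samples at 250 Hz);
  pooling widths 4 then 8 with a trailing global average.
* ``pli`` — input one 22 x 22 phase-lag-index matrix; the first pooling
  kernel and stride are halved (2 instead of 4) so the narrow input
  survives to the classifier. Layer shapes and parameter counts of this
  variant are pinned row-for-row by the architecture table it implements
  (1000 / 16 / 352 / 32 / 352 / 256 / 32 / 51 trainable parameters).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..containers import ValidationError
from . import layers as L


@dataclass
class ArchitectureSpec:
    """Layer plan of the compact CNN."""

    variant: str = "pli"  # "eeg" | "pli"
    n_channels: int = 22
    input_width: int | None = None  # 22 for pli, 250 for eeg
    temporal_filters: int = 8  # F1
    depth_multiplier: int = 2  # D
    separable_filters: int = 16  # F2 = F1 * D
    temporal_kernel: int = 125
    separable_kernel: int = 22
    pool1_width: int | None = None  # 2 for pli, 4 for eeg
    pool2_width: int | None = None  # None: pool the full remaining width
    dropout_rate: float = 0.5
    n_classes: int = 3
    max_norm: float = 1.0

    def __post_init__(self) -> None:
        if self.variant not in ("eeg", "pli"):
            raise ValidationError(f"unknown variant {self.variant!r}")
        if self.input_width is None:
            self.input_width = 22 if self.variant == "pli" else 250
        if self.pool1_width is None:
            self.pool1_width = 2 if self.variant == "pli" else 4
        if self.pool2_width is None and self.variant == "eeg":
            self.pool2_width = 8  # trailing global pool handles the rest
        if self.separable_filters != self.temporal_filters * self.depth_multiplier:
            raise ValidationError(
                "separable_filters must equal temporal_filters * depth_multiplier")

    def widths(self) -> dict[str, int]:
        """Width of the feature trace after each stage; validates pooling."""
        w = self.input_width
        w1 = w // self.pool1_width
        if w1 < 1:
            raise ValidationError(
                f"pool1_width {self.pool1_width} leaves no samples from "
                f"width {w}")
        # even separable kernel with half-kernel padding widens by 1
        w2 = w1 + (1 if self.separable_kernel % 2 == 0 else 0)
        pool2 = self.pool2_width if self.pool2_width is not None else w2
        if pool2 > w2:
            raise ValidationError(
                f"pool2_width {pool2} exceeds remaining width {w2}")
        w3 = w2 // pool2
        return {"input": w, "pool1": w1, "separable": w2, "pool2": w3,
                "pool2_width": pool2}


class Sequential:
    """Minimal sequential container with parameter traversal."""

    def __init__(self, layer_list: list[L.Layer], spec: ArchitectureSpec):
        self.layers = layer_list
        self.spec = spec

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    __call__ = forward

    def backward(self, gout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout

    def named_params(self):
        for layer in self.layers:
            for pname in layer.params:
                yield layer, pname

    def apply_constraints(self) -> None:
        for layer in self.layers:
            layer.apply_constraints()

    def get_state(self) -> list:
        state = []
        for layer in self.layers:
            entry = {k: v.copy() for k, v in layer.params.items()}
            if isinstance(layer, L.BatchNorm):
                entry["_running_mean"] = layer.running_mean.copy()
                entry["_running_var"] = layer.running_var.copy()
            state.append(entry)
        return state

    def set_state(self, state: list) -> None:
        for layer, entry in zip(self.layers, state):
            for k in layer.params:
                layer.params[k] = entry[k].copy()
            if isinstance(layer, L.BatchNorm):
                layer.running_mean = entry["_running_mean"].copy()
                layer.running_var = entry["_running_var"].copy()


def build_model(spec: ArchitectureSpec, seed: int = 0) -> Sequential:
    """Instantiate the network with Glorot-uniform weights."""
    widths = spec.widths()  # validates pool plan before building
    rng = np.random.default_rng(seed)
    F1, D, F2 = spec.temporal_filters, spec.depth_multiplier, spec.separable_filters
    stack = [
        L.ConvWidth(1, F1, spec.temporal_kernel, pad=spec.temporal_kernel // 2,
                    bias=False, rng=rng, name="temporal_conv"),
        L.BatchNorm(F1, name="temporal_bn"),
        L.SpatialDepthwiseConv(F1, D, spec.n_channels, max_norm=spec.max_norm,
                               rng=rng, name="spatial_conv"),
        L.BatchNorm(F2, name="spatial_bn"),
        L.ELU(),
        L.AvgPoolWidth(spec.pool1_width, name="pool1"),
        L.Dropout(spec.dropout_rate),
        L.ConvWidth(F2, F2, spec.separable_kernel,
                    pad=spec.separable_kernel // 2, groups=F2, bias=False,
                    rng=rng, name="separable_depthwise"),
        L.ConvWidth(F2, F2, 1, bias=False, rng=rng, name="separable_pointwise"),
        L.BatchNorm(F2, name="separable_bn"),
        L.ELU(),
        L.AvgPoolWidth(widths["pool2_width"], name="pool2"),
        L.Dropout(spec.dropout_rate),
    ]
    if widths["pool2"] > 1:  # trailing global average (eeg variant)
        stack.append(L.AvgPoolWidth(widths["pool2"], name="global_pool"))
    stack += [
        L.ConvWidth(F2, spec.n_classes, 1, bias=True, rng=rng,
                    name="classifier"),
        L.Flatten(),
        L.LogSoftmax(),
    ]
    return Sequential(stack, spec)


def count_parameters(model: Sequential) -> dict[str, int]:
    """Trainable parameters per named layer, plus the total."""
    counts = {}
    for layer in model.layers:
        n = layer.n_params()
        if layer.params:
            counts[layer.name] = n
    counts["total"] = sum(counts.values())
    return counts


def shape_trace(model: Sequential, batch_size: int = 32) -> list[tuple[str, tuple]]:
    """Output shape after every layer for a given batch size."""
    spec = model.spec
    x = np.zeros((batch_size, 1, spec.n_channels, spec.input_width))
    trace = []
    for layer in model.layers:
        x = layer.forward(x, training=False)
        trace.append((layer.name, tuple(x.shape)))
    return trace
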