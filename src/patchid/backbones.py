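"""Frozen feature-extractor backbones.

Two backbones are provided behind one contract (a declared input side and
intensity range, a feature dimension F, and a frozen ``forward`` producing a
spatial feature map):

* ``TinyConvBackbone`` — a 4-layer strided convolution stack with seeded
  random frozen weights (input side 64, F = 64). It exercises the full twin
  network contract in seconds with no pretrained download.
* the reference configuration — EfficientNet-B4 without its classification
  top. Pretrained weights are not shipped; what this module implements is the
  exact architecture bookkeeping (compound width/depth scaling, MBConv block
  inventory, parameter counting) so the reference feature dimension and the
  published parameter count are computable offline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .exceptions import ConfigError

__all__ = [
    "BackboneSpec",
    "Backbone",
    "TinyConvBackbone",
    "FunctionBackbone",
    "efficientnet_scaling",
    "efficientnet_feature_dim",
    "efficientnet_feature_extractor_params",
    "EFFICIENTNET_B4_FEATURE_DIM",
    "EFFICIENTNET_B4_PARAMS",
]


@dataclass(frozen=True)
class BackboneSpec:
    """Declared contract of a frozen feature extractor."""

    name: str
    input_side: int
    input_range: tuple[float, float]
    feature_dim: int
    provenance: str  # "pretrained_reference" | "random_frozen_test"

    def __post_init__(self) -> None:
        if self.provenance not in ("pretrained_reference", "random_frozen_test"):
            raise ConfigError(f"unknown backbone provenance {self.provenance!r}")
        if self.feature_dim < 1 or self.input_side < 1:
            raise ConfigError("feature_dim and input_side must be positive")


class Backbone:
    """Base class: immutable weights + ``forward`` to a spatial feature map."""

    spec: BackboneSpec

    def forward(self, batch: np.ndarray) -> np.ndarray:
        """Map (N, side, side, 3) inputs to (N, Hf, Wf, F) feature maps."""
        raise NotImplementedError

    def weight_checksum(self) -> str:
        """Stable digest of all weights, for freeze auditing."""
        import hashlib

        h = hashlib.sha256()
        for w in self.weights():
            h.update(np.ascontiguousarray(w).tobytes())
        return h.hexdigest()

    def weights(self) -> list[np.ndarray]:
        return []


def _conv2d_strided(x: np.ndarray, kernel: np.ndarray, stride: int) -> np.ndarray:
    """Valid-mode strided convolution on (N, H, W, Cin) with (k, k, Cin, Cout)."""
    k = kernel.shape[0]
    win = sliding_window_view(x, (k, k), axis=(1, 2))[:, ::stride, ::stride]
    # win: (N, Ho, Wo, Cin, k, k) -> contract over (Cin, k, k)
    return np.einsum("nhwcij,ijco->nhwo", win, kernel, optimize=True)


class TinyConvBackbone(Backbone):
    """Seeded random frozen 4-layer strided conv stack (test backbone).

    Input 64x64x3 in [0, 1]; four 3x3 stride-2 ReLU convolutions with channel
    widths (8, 16, 32, 64) and He-scaled Gaussian weights; output feature map
    is 4x4x64, so F = 64 after average pooling.
    """

    CHANNELS = (8, 16, 32, 64)

    def __init__(self, seed: int = 0):
        self.seed = int(seed)
        self.spec = BackboneSpec(
            name=f"tiny-conv-{seed}",
            input_side=64,
            input_range=(0.0, 1.0),
            feature_dim=self.CHANNELS[-1],
            provenance="random_frozen_test",
        )
        rng = np.random.default_rng(self.seed)
        self._kernels: list[np.ndarray] = []
        self._biases: list[np.ndarray] = []
        cin = 3
        for cout in self.CHANNELS:
            fan_in = 3 * 3 * cin
            k = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(3, 3, cin, cout))
            b = rng.normal(0.0, 0.05, size=cout)
            k.setflags(write=False)
            b.setflags(write=False)
            self._kernels.append(k)
            self._biases.append(b)
            cin = cout

    def weights(self) -> list[np.ndarray]:
        return [*self._kernels, *self._biases]

    def forward(self, batch: np.ndarray) -> np.ndarray:
        x = np.asarray(batch, dtype=np.float64)
        if x.ndim != 4 or x.shape[1] != self.spec.input_side or x.shape[2] != self.spec.input_side:
            raise ConfigError(
                f"expected (N, {self.spec.input_side}, {self.spec.input_side}, 3) input, "
                f"got {x.shape}"
            )
        for kern, bias in zip(self._kernels, self._biases):
            x = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
            x = _conv2d_strided(x, kern, stride=2) + bias
            x = np.maximum(x, 0.0)
        return x


class FunctionBackbone(Backbone):
    """Wrap an arbitrary frozen function as a backbone (test stubs)."""

    def __init__(self, spec: BackboneSpec, fn: Callable[[np.ndarray], np.ndarray]):
        self.spec = spec
        self._fn = fn

    def forward(self, batch: np.ndarray) -> np.ndarray:
        return self._fn(np.asarray(batch, dtype=np.float64))


# ---------------------------------------------------------------------------
# Reference architecture bookkeeping (EfficientNet family)
# ---------------------------------------------------------------------------

#: Baseline (B0) MBConv stage inventory:
#: (kernel, repeats, filters_in, filters_out, expand_ratio, stride, se_ratio)
_MBCONV_STAGES = (
    (3, 1, 32, 16, 1, 1, 0.25),
    (3, 2, 16, 24, 6, 2, 0.25),
    (5, 2, 24, 40, 6, 2, 0.25),
    (3, 3, 40, 80, 6, 2, 0.25),
    (5, 3, 80, 112, 6, 1, 0.25),
    (5, 4, 112, 192, 6, 2, 0.25),
    (3, 1, 192, 320, 6, 1, 0.25),
)

#: Compound scaling coefficients: variant -> (width, depth, resolution).
_EFFICIENTNET_SCALING = {
    "b0": (1.0, 1.0, 224),
    "b1": (1.0, 1.1, 240),
    "b2": (1.1, 1.2, 260),
    "b3": (1.2, 1.4, 300),
    "b4": (1.4, 1.8, 380),
    "b5": (1.6, 2.2, 456),
    "b6": (1.8, 2.6, 528),
    "b7": (2.0, 3.1, 600),
}


def efficientnet_scaling(variant: str) -> tuple[float, float, int]:
    try:
        return _EFFICIENTNET_SCALING[variant.lower()]
    except KeyError:
        raise ConfigError(f"unknown EfficientNet variant {variant!r}") from None


def _round_filters(filters: float, width: float, divisor: int = 8) -> int:
    """Width-scale a channel count to the nearest multiple of the divisor."""
    filters *= width
    new = max(divisor, int(filters + divisor / 2) // divisor * divisor)
    if new < 0.9 * filters:
        new += divisor
    return int(new)


def _round_repeats(repeats: int, depth: float) -> int:
    return int(math.ceil(depth * repeats))


def efficientnet_feature_dim(variant: str = "b4") -> int:
    """Channel count of the final feature map (the pooled embedding length)."""
    width, _, _ = efficientnet_scaling(variant)
    return _round_filters(1280, width)


def efficientnet_feature_extractor_params(variant: str = "b4", in_channels: int = 3) -> int:
    """Parameter count of the feature extractor (no classification top).

    Counts every weight of the architecture as published: the input
    normalization statistics (mean, variance and their sample count), the
    stem convolution + batch norm, every MBConv block (expansion, depthwise,
    squeeze-excitation, projection, each with its batch norm), and the final
    1x1 convolution + batch norm. Batch-norm layers contribute 4 parameters
    per channel (scale, shift and the two non-trainable running statistics).
    """
    width, depth, _ = efficientnet_scaling(variant)
    total = 0

    # input normalization statistics: per-channel mean + variance, plus count
    total += 2 * in_channels + 1

    stem = _round_filters(32, width)
    total += 3 * 3 * in_channels * stem + 4 * stem

    for kernel, repeats, f_in, f_out, expand, _stride, se_ratio in _MBCONV_STAGES:
        cin0 = _round_filters(f_in, width)
        cout = _round_filters(f_out, width)
        for rep in range(_round_repeats(repeats, depth)):
            cin = cin0 if rep == 0 else cout
            cexp = cin * expand
            if expand != 1:
                total += cin * cexp + 4 * cexp  # 1x1 expansion conv + BN
            total += kernel * kernel * cexp + 4 * cexp  # depthwise conv + BN
            se = max(1, int(cin * se_ratio))
            total += cexp * se + se  # SE squeeze conv (with bias)
            total += se * cexp + cexp  # SE excite conv (with bias)
            total += cexp * cout + 4 * cout  # 1x1 projection conv + BN

    top = _round_filters(1280, width)
    total += _round_filters(_MBCONV_STAGES[-1][3], width) * top + 4 * top
    return total


EFFICIENTNET_B4_FEATURE_DIM = efficientnet_feature_dim("b4")
EFFICIENTNET_B4_PARAMS = efficientnet_feature_extractor_params("b4")
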