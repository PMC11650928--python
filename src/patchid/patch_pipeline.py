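"""Patch standardization: masking, rotated-box extraction, augmentation.

``extract_patch`` samples the axis-aligned w x h rectangle in the box's own
frame (rotating by -angle about the box center) on an ``out_size`` x
``out_size`` grid, with bilinear interpolation and out-of-image samples read
as 0. Rotations within 1e-9 of a 90-degree multiple are snapped to the exact
integer rotation matrix so that aligned geometry reproduces pixel values
bit-exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .annotations_io import PATCH_TYPES, RotatedBox
from .exceptions import ConfigError

__all__ = [
    "Patch",
    "AugmentParams",
    "DEFAULT_PATCH_SIZE",
    "apply_mask",
    "extract_patch",
    "augment",
    "preprocess_for_backbone",
]

#: Standard square patch side in pixels.
DEFAULT_PATCH_SIZE = 380


@dataclass(frozen=True)
class Patch:
    """A standardized square image patch for one body region."""

    patch_type: str
    pixels: np.ndarray  # (S, S, 3) float32, intensities in [0, 255]
    source_image_id: str = ""
    shark_id: str = ""
    time_marker: str = ""

    def __post_init__(self) -> None:
        if self.patch_type not in PATCH_TYPES:
            raise ConfigError(f"unknown patch type {self.patch_type!r}")
        px = self.pixels
        if px.ndim != 3 or px.shape[0] != px.shape[1] or px.shape[2] != 3:
            raise ConfigError(f"patch pixels must be square (S, S, 3), got {px.shape}")

    @property
    def size(self) -> int:
        return int(self.pixels.shape[0])


def apply_mask(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero out all channels wherever the mask is 0."""
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape[:2]:
        raise ConfigError(
            f"image {image.shape[:2]} and mask {mask.shape[:2]} sizes differ"
        )
    keep = mask != 0
    if image.ndim == 3:
        keep = keep[..., None]
    return np.where(keep, image, 0).astype(image.dtype, copy=False)


def _snapped_rotation(angle: float) -> np.ndarray:
    """Clockwise-positive rotation matrix; exact for 90-degree multiples."""
    c, s = math.cos(angle), math.sin(angle)
    quarter = angle / (math.pi / 2.0)
    if abs(quarter - round(quarter)) < 1e-9:
        c, s = round(c), round(s)
    return np.array([[c, -s], [s, c]], dtype=np.float64)


def extract_patch(
    image: np.ndarray,
    box: RotatedBox,
    out_size: int = DEFAULT_PATCH_SIZE,
    source_image_id: str = "",
    shark_id: str = "",
    time_marker: str = "",
) -> Patch:
    """Sample a rotated box from an image into a square patch."""
    if out_size <= 0:
        raise ConfigError(f"out_size must be positive, got {out_size}")
    image = np.asarray(image)
    squeeze = image.ndim == 2
    if squeeze:
        image = image[..., None]

    # output sample positions in the box's own frame, pixel-center convention
    j = (np.arange(out_size) + 0.5) * (box.w / out_size) - box.w / 2.0
    i = (np.arange(out_size) + 0.5) * (box.h / out_size) - box.h / 2.0
    xl, yl = np.meshgrid(j, i)

    R = _snapped_rotation(box.angle)
    sx = box.cx + R[0, 0] * xl + R[0, 1] * yl
    sy = box.cy + R[1, 0] * xl + R[1, 1] * yl

    coords = np.stack([sy.ravel(), sx.ravel()])
    channels = [
        map_coordinates(
            image[..., ch].astype(np.float64), coords, order=1, mode="constant", cval=0.0
        ).reshape(out_size, out_size)
        for ch in range(image.shape[2])
    ]
    px = np.stack(channels, axis=-1)
    if squeeze:
        px = np.repeat(px, 3, axis=-1) if px.shape[-1] == 1 else px
    if px.shape[-1] == 1:
        px = np.repeat(px, 3, axis=-1)
    return Patch(
        patch_type=box.patch_type,
        pixels=px.astype(np.float32),
        source_image_id=source_image_id,
        shark_id=shark_id,
        time_marker=time_marker,
    )


@dataclass(frozen=True)
class AugmentParams:
    """Ranges for the fixed augmentation chain.

    Order of application: x-flip, y-flip, 90-degree-multiple rotation,
    additive Gaussian noise, Gaussian blur, gamma contrast, linear contrast
    about the mean.
    """

    flip_x_prob: float = 0.5
    flip_y_prob: float = 0.5
    rotations: tuple[int, ...] = (0, 90, 180, 270)
    noise_max: float = 10.0
    blur_max: float = 2.0
    gamma_range: tuple[float, float] = (0.7, 1.4)
    contrast_range: tuple[float, float] = (0.8, 1.2)

    def __post_init__(self) -> None:
        for name in ("flip_x_prob", "flip_y_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.noise_max < 0 or self.blur_max < 0:
            raise ConfigError("noise_max and blur_max must be >= 0")
        for name in ("gamma_range", "contrast_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo <= 0:
                raise ConfigError(f"{name} must satisfy 0 < lo <= hi")
        if any(r % 90 != 0 for r in self.rotations) or not self.rotations:
            raise ConfigError("rotations must be a nonempty set of 90-degree multiples")


def augment(patch: Patch, params: AugmentParams, rng: np.random.Generator) -> Patch:
    """Apply the randomized augmentation chain; reproducible from rng state."""
    px = patch.pixels.astype(np.float64)
    if rng.random() < params.flip_x_prob:
        px = px[:, ::-1]
    if rng.random() < params.flip_y_prob:
        px = px[::-1, :]
    rot = int(params.rotations[rng.integers(len(params.rotations))])
    if rot % 360:
        px = np.rot90(px, k=(rot // 90) % 4)
    noise_sd = float(rng.uniform(0.0, params.noise_max))
    if noise_sd > 0:
        px = px + rng.normal(0.0, noise_sd, size=px.shape)
    blur = float(rng.uniform(0.0, params.blur_max))
    if blur > 0:
        px = gaussian_filter(px, sigma=(blur, blur, 0.0))
    gamma = float(rng.uniform(*params.gamma_range))
    if gamma != 1.0:
        px = np.clip(px, 0.0, 255.0)
        px = 255.0 * (px / 255.0) ** gamma
    alpha = float(rng.uniform(*params.contrast_range))
    if alpha != 1.0:
        mean = px.mean()
        px = mean + alpha * (px - mean)
    px = np.clip(px, 0.0, 255.0)
    return replace(patch, pixels=np.ascontiguousarray(px, dtype=np.float32))


def _resize_bilinear(px: np.ndarray, out_side: int) -> np.ndarray:
    """Pixel-center bilinear resize of a square (S, S, C) array."""
    side = px.shape[0]
    if out_side == side:
        return px
    pos = (np.arange(out_side) + 0.5) * (side / out_side) - 0.5
    xg, yg = np.meshgrid(pos, pos)
    coords = np.stack([yg.ravel(), xg.ravel()])
    out = [
        map_coordinates(px[..., c].astype(np.float64), coords, order=1, mode="nearest")
        .reshape(out_side, out_side)
        for c in range(px.shape[2])
    ]
    return np.stack(out, axis=-1)


def preprocess_for_backbone(patch: Patch, backbone_spec) -> np.ndarray:
    """Rescale intensities into the backbone's input range and resize.

    Returns a float64 array of shape (side, side, 3) where ``side`` is the
    backbone's declared input side.
    """
    side = getattr(backbone_spec, "input_side", None)
    rng_ = getattr(backbone_spec, "input_range", None)
    if side is None or rng_ is None:
        raise ConfigError("backbone declares no input spec (input_side / input_range)")
    lo, hi = rng_
    px = patch.pixels.astype(np.float64)
    px = _resize_bilinear(px, int(side))
    return px / 255.0 * (hi - lo) + lo
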