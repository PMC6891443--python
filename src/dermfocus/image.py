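"""Image ingestion and blur-reference preprocessing.

Every assessment starts from the same short pipeline: crop the frame to a
central square (the dermatoscope barrel leaves a dark circular vignette, so
only the centre carries signal), convert to luma, and build a *blur
reference* ``IBlur`` by mean-filtering the luma image with a kernel whose
size adapts to the image resolution.  Comparing focus metrics between the
original and its blur reference yields scale-adaptive relative features: a
sharp image changes a lot under the mean filter, an already-blurred one
barely changes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, ImageOps
from scipy.ndimage import uniform_filter

__all__ = [
    "SourceRole",
    "RawImage",
    "GrayImage",
    "ImagePair",
    "ImageTooSmallError",
    "InvalidFractionError",
    "load_image",
    "central_crop",
    "to_grayscale",
    "compute_kernel_size",
    "mean_filter",
    "make_pair",
    "preprocess",
    "MIN_CROP_SIDE",
    "KERNEL_DIVISOR",
    "DEFAULT_CROP_FRACTION",
]

#: Post-crop sides below this would give a degenerate (k < 3) blur kernel.
MIN_CROP_SIDE = 150
#: Divisor in the adaptive kernel-size rule.
KERNEL_DIVISOR = 75
DEFAULT_CROP_FRACTION = 0.7

# BT.601 luma weights.
_LUMA = np.array([0.299, 0.587, 0.114])


class ImageTooSmallError(ValueError):
    """Image (or its crop) is too small for the adaptive kernel rule."""


class InvalidFractionError(ValueError):
    """Crop fraction outside (0, 1]."""


class SourceRole(str, enum.Enum):
    PREVIEW = "preview"
    ACQUIRED = "acquired"
    UNSPECIFIED = "unspecified"


@dataclass
class RawImage:
    """8-bit RGB image, row-major, origin top-left.

    ``meta`` carries generator bookkeeping (e.g. speck counts for synthetic
    artifact scenes); it never affects processing.
    """

    pixels: np.ndarray
    source_role: SourceRole = SourceRole.UNSPECIFIED
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected H x W x 3 array, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("empty image")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            px = np.round(px).astype(np.uint8)
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class GrayImage:
    """Single-channel image stored as float64 for downstream arithmetic."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"expected H x W array, got shape {px.shape}")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class ImagePair:
    """The luma crop ``gray`` and its mean-filtered counterpart ``blur``."""

    gray: GrayImage
    blur: GrayImage
    kernel_size: int
    crop_fraction: float

    def __post_init__(self) -> None:
        if self.gray.pixels.shape != self.blur.pixels.shape:
            raise ValueError("gray and blur must have identical dimensions")
        if self.kernel_size < 3 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be an odd integer >= 3")


def load_image(path: str | Path, source_role: SourceRole = SourceRole.UNSPECIFIED) -> RawImage:
    """Read a PNG/JPEG file as 8-bit RGB, honouring EXIF orientation."""
    with Image.open(path) as im:
        im = ImageOps.exif_transpose(im)
        arr = np.asarray(im.convert("RGB"))
    return RawImage(arr, source_role=source_role)


def central_crop(image: RawImage, fraction: float = DEFAULT_CROP_FRACTION) -> RawImage:
    """Centered square crop of side ``floor(fraction * min(W, H))``.

    Raises :class:`ImageTooSmallError` when the resulting side would be below
    ``MIN_CROP_SIDE`` (the adaptive kernel rule degenerates there) and
    :class:`InvalidFractionError` for fractions outside (0, 1].
    """
    if not (0.0 < fraction <= 1.0):
        raise InvalidFractionError(f"crop fraction must be in (0, 1], got {fraction}")
    # epsilon guards against binary-float underestimates of decimal products
    # (0.7 * 720 is 503.999...94 in binary but means 504)
    side = int(np.floor(fraction * min(image.width, image.height) + 1e-9))
    if side < MIN_CROP_SIDE:
        raise ImageTooSmallError(
            f"crop side {side} px < {MIN_CROP_SIDE} px minimum "
            f"(input {image.width}x{image.height}, fraction {fraction})"
        )
    top = (image.height - side) // 2
    left = (image.width - side) // 2
    out = image.pixels[top : top + side, left : left + side].copy()
    return RawImage(out, source_role=image.source_role, meta=dict(image.meta))


def to_grayscale(image: RawImage) -> GrayImage:
    """BT.601 luma conversion Y = 0.299 R + 0.587 G + 0.114 B."""
    return GrayImage(image.pixels.astype(np.float64) @ _LUMA)


def compute_kernel_size(width: int, height: int) -> int:
    """Adaptive mean-filter kernel size: ``min(W, H) // 75``, bumped to odd.

    Defined for min dimension >= 150 px so the result is an odd integer >= 3.
    """
    m = min(width, height)
    if m < MIN_CROP_SIDE:
        raise ImageTooSmallError(f"min dimension {m} px < {MIN_CROP_SIDE} px")
    k = m // KERNEL_DIVISOR
    return k if k % 2 == 1 else k + 1


def mean_filter(gray: GrayImage, kernel_size: int) -> GrayImage:
    """k x k uniform mean filter with reflective border padding."""
    if kernel_size < 3 or kernel_size % 2 == 0:
        raise ValueError("kernel_size must be an odd integer >= 3")
    out = uniform_filter(gray.pixels, size=kernel_size, mode="reflect")
    # reflect-padded mean of values in [0,255] stays in range; clip rounding dust
    return GrayImage(np.clip(out, 0.0, 255.0))


def make_pair(image: RawImage, fraction: float = DEFAULT_CROP_FRACTION) -> ImagePair:
    """Crop -> luma -> adaptive kernel -> mean filter."""
    cropped = central_crop(image, fraction)
    gray = to_grayscale(cropped)
    k = compute_kernel_size(gray.width, gray.height)
    return ImagePair(gray=gray, blur=mean_filter(gray, k), kernel_size=k, crop_fraction=fraction)


def preprocess(
    image: RawImage, fraction: float = DEFAULT_CROP_FRACTION
) -> tuple[ImagePair, RawImage]:
    """Return the gray/blur pair together with the cropped RGB source.

    The colour crop is needed by the histogram metrics, which are computed
    per channel.
    """
    cropped = central_crop(image, fraction)
    gray = to_grayscale(cropped)
    k = compute_kernel_size(gray.width, gray.height)
    pair = ImagePair(gray=gray, blur=mean_filter(gray, k), kernel_size=k, crop_fraction=fraction)
    return pair, cropped
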