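"""RGB raster images and colour-space helpers.

Images are held as float arrays in [0, 1] with shape (H, W, 3).  All feature
computations in :mod:`artvalue.features` go through this container, so the
conversion conventions (luminance weights, HSV) are pinned in one place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from skimage import color as skcolor

#: ITU-R BT.601 luma weights (default grayscale convention).
LUMA_601 = (0.299, 0.587, 0.114)
#: ITU-R BT.709 luma weights (optional alternative).
LUMA_709 = (0.2126, 0.7152, 0.0722)


@dataclass(frozen=True)
class RasterImage:
    """An RGB image with channel values in [0, 1].

    Parameters
    ----------
    pixels
        Array of shape (H, W, 3), float, every value in [0, 1].
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) RGB pixels, got shape {px.shape}")
        if px.shape[0] < 8 or px.shape[1] < 8:
            raise ValueError("image must be at least 8x8 pixels")
        if not np.isfinite(px).all():
            raise ValueError("pixel values must be finite")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("pixel values must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @classmethod
    def from_uint8(cls, arr: np.ndarray) -> "RasterImage":
        """Build from an 8-bit (H, W, 3) array by dividing by 255."""
        arr = np.asarray(arr)
        return cls(arr.astype(float) / 255.0)

    @classmethod
    def from_file(cls, path) -> "RasterImage":
        """Read a PNG or JPEG file.  Alpha channels are rejected."""
        with Image.open(path) as im:
            if im.mode in ("RGBA", "LA", "PA"):
                raise ValueError(
                    f"{path}: image has an alpha channel; flatten it before loading"
                )
            rgb = im.convert("RGB")
            return cls.from_uint8(np.asarray(rgb))

    def luminance(self, weights: tuple[float, float, float] = LUMA_601) -> np.ndarray:
        """Grayscale image in [0, 1] using the given luma weights."""
        w = np.asarray(weights, dtype=float)
        return self.pixels @ w

    def grayscale_255(self, weights: tuple[float, float, float] = LUMA_601) -> np.ndarray:
        """Grayscale intensity on the 0-255 scale (float, not quantised)."""
        return self.luminance(weights) * 255.0

    def hsv(self) -> np.ndarray:
        """HSV representation, every channel in [0, 1] (hue wraps at 1)."""
        return skcolor.rgb2hsv(self.pixels)

    def lab(self) -> np.ndarray:
        """CIE LAB representation."""
        return skcolor.rgb2lab(self.pixels)
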