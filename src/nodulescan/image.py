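"""Core raster types shared by every pipeline stage.

Coordinate convention: row-major, 0-based, pixel centers. Masks are always
congruent (same shape) with the image they were derived from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GrayImage", "SpacingInfo", "window_to_uint8"]

#: Default HU display window applied before any gray-level operation.
DEFAULT_WINDOW_HU = (-1000.0, 400.0)


@dataclass(frozen=True)
class SpacingInfo:
    """Physical pixel spacing in millimetres."""

    row_mm: float
    col_mm: float
    slice_mm: float | None = None

    def __post_init__(self) -> None:
        if self.row_mm <= 0 or self.col_mm <= 0:
            raise ValueError("in-plane spacing must be positive")
        if self.slice_mm is not None and self.slice_mm <= 0:
            raise ValueError("slice spacing must be positive")


@dataclass
class GrayImage:
    """A 2D grayscale raster with a declared value domain and pixel spacing.

    Parameters
    ----------
    pixels : ndarray
        2D array of intensities.  ``float`` for HU-valued images, any
        integer/float dtype in [0, 255] for ``uint8``-domain images.
    value_domain : {"HU", "uint8", "linear"}
        Interpretation of the pixel values; "linear" marks unconstrained
        intermediate rasters (e.g. frequency-band components).
    spacing : SpacingInfo
        Physical pixel size.
    """

    pixels: np.ndarray
    value_domain: str = "HU"
    spacing: SpacingInfo = field(default_factory=lambda: SpacingInfo(1.0, 1.0))

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a nonempty 2D raster")
        if self.value_domain not in ("HU", "uint8", "linear"):
            raise ValueError(f"unknown value domain {self.value_domain!r}")
        if self.value_domain == "uint8":
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("uint8-domain pixels must lie in [0, 255]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray, value_domain: str | None = None) -> "GrayImage":
        """Copy of this image with new pixel data (same spacing)."""
        return GrayImage(
            pixels=pixels,
            value_domain=value_domain or self.value_domain,
            spacing=self.spacing,
        )


def window_to_uint8(image: GrayImage, window: tuple[float, float] = DEFAULT_WINDOW_HU) -> GrayImage:
    """Linearly map an HU window to [0, 255], clipping outside.

    The map is monotone; values at the window edges hit 0 and 255 exactly.
    Half-way values round up (floor(x + 0.5)).
    """
    if image.value_domain != "HU":
        raise ValueError("window_to_uint8 expects an HU-domain image")
    lo, hi = float(window[0]), float(window[1])
    if hi <= lo:
        raise ValueError("window must be a nonempty interval")
    scaled = (np.asarray(image.pixels, dtype=float) - lo) * (255.0 / (hi - lo))
    out = np.clip(np.floor(scaled + 0.5), 0, 255).astype(np.uint8)
    return image.with_pixels(out, value_domain="uint8")
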