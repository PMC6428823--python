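"""Weber Local Descriptor (WLD) texture features.

Two complementary maps are computed per patch: differential excitation
(arctan-compressed relative intensity difference of each pixel against its
8-neighbourhood — near zero on flat areas) and gradient orientation.  Each
map is divided into non-overlapping blocks, a normalized histogram is built
per block, and the excitation and orientation histograms are concatenated
into the fused feature vector.

Neighbour indexing: x_1..x_8 clockwise from North, so x_1/x_3/x_5/x_7 are
the N/E/S/W neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.transform import resize

from .candidates import CandidateRegion
from .image import GrayImage

__all__ = [
    "WldConfig",
    "FeatureVector",
    "differential_excitation",
    "gradient_orientation",
    "block_histograms",
    "extract_patch",
    "extract_features",
]

# Offsets of x_1..x_8, clockwise from North.
_NEIGHBOR_OFFSETS = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def differential_excitation(patch: np.ndarray, alpha: float = 3.0, p: int = 8) -> np.ndarray:
    """Excitation map: arctan(alpha * sum_i (x_i - x_c) / x_c) per pixel.

    The sum runs over the first ``p`` neighbours of the clockwise-from-North
    ring; borders are reflection-padded; a centre value below 1 is replaced
    by 1 (uint8-domain convention) to keep the ratio bounded.  Output lies
    strictly inside (-pi/2, pi/2).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 2 or min(patch.shape) < 3:
        raise ValueError("patch must be 2D and at least 3x3")
    padded = np.pad(patch, 1, mode="reflect")
    center = np.maximum(patch, 1.0)
    acc = np.zeros_like(patch)
    for dr, dc in _NEIGHBOR_OFFSETS[:p]:
        acc += padded[1 + dr : 1 + dr + patch.shape[0], 1 + dc : 1 + dc + patch.shape[1]] - patch
    return np.arctan(alpha * acc / center)


def gradient_orientation(patch: np.ndarray, mode: str = "cross") -> np.ndarray:
    """Orientation map in [0, 2*pi).

    ``cross`` (default): quadrant-corrected arctangent of the N-S intensity
    difference (x_1 - x_5) over the E-W difference (x_3 - x_7).  ``sobel``
    uses Sobel-kernel gradients with the same sign convention.  Pixels where
    both differences vanish map to 0.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 2 or min(patch.shape) < 3:
        raise ValueError("patch must be 2D and at least 3x3")
    if mode == "cross":
        padded = np.pad(patch, 1, mode="reflect")
        h, w = patch.shape
        north = padded[0:h, 1 : 1 + w]
        south = padded[2 : 2 + h, 1 : 1 + w]
        east = padded[1 : 1 + h, 2 : 2 + w]
        west = padded[1 : 1 + h, 0:w]
        vert, horiz = north - south, east - west
    elif mode == "sobel":
        # sobel along rows measures the S-N gradient; negate to match x_1 - x_5
        vert = -ndi.sobel(patch, axis=0, mode="reflect")
        horiz = ndi.sobel(patch, axis=1, mode="reflect")
    else:
        raise ValueError(f"unknown orientation mode {mode!r}")
    theta = np.arctan2(vert, horiz)  # (0, 0) -> 0 by arctan2 convention
    return np.mod(theta, 2.0 * np.pi)


def _as_grid(n_blocks: int | tuple[int, int]) -> tuple[int, int]:
    if isinstance(n_blocks, tuple):
        return n_blocks
    side = int(round(np.sqrt(n_blocks)))
    if side * side != n_blocks:
        raise ValueError(f"n_blocks={n_blocks} is not a realizable square grid; pass (rows, cols)")
    return side, side


def block_histograms(
    value_map: np.ndarray,
    n_blocks: int | tuple[int, int],
    n_bins: int,
    value_range: tuple[float, float],
) -> list[np.ndarray]:
    """One normalized ``n_bins`` histogram per grid block of the map."""
    value_map = np.asarray(value_map, dtype=float)
    gr, gc = _as_grid(n_blocks)
    if gr > value_map.shape[0] or gc > value_map.shape[1]:
        raise ValueError("block grid finer than the map")
    hists = []
    for rows in np.array_split(value_map, gr, axis=0):
        for tile in np.array_split(rows, gc, axis=1):
            h, _ = np.histogram(np.clip(tile, *value_range), bins=n_bins, range=value_range)
            hists.append(h / tile.size)
    return hists


@dataclass
class WldConfig:
    """FS-k configuration: k bins per histogram per component."""

    fs_bins: int = 14
    grid: tuple[int, int] = (2, 2)
    alpha: float = 3.0
    patch_size: int = 32
    margin_px: int = 4
    orientation_mode: str = "cross"

    @property
    def n_blocks(self) -> int:
        return self.grid[0] * self.grid[1]

    @property
    def vector_length(self) -> int:
        return self.n_blocks * 2 * self.fs_bins


@dataclass
class FeatureVector:
    values: np.ndarray
    layout: tuple[int, int, int]  # (n_blocks, bins_excitation, bins_orientation)
    degenerate: bool = False


def extract_patch(image: GrayImage, region: CandidateRegion, config: WldConfig | None = None) -> np.ndarray:
    """Standardized patch around a candidate: bounding box plus margin,
    clipped to the image, bilinearly resized to patch_size x patch_size."""
    config = config or WldConfig()
    r0, c0, r1, c1 = region.bbox
    m = config.margin_px
    h, w = image.shape
    r0, c0 = max(r0 - m, 0), max(c0 - m, 0)
    r1, c1 = min(r1 + m, h), min(c1 + m, w)
    crop = np.asarray(image.pixels, dtype=float)[r0:r1, c0:c1]
    return resize(crop, (config.patch_size, config.patch_size), order=1, mode="reflect", anti_aliasing=False)


def extract_features(patch: np.ndarray, config: WldConfig | None = None) -> FeatureVector:
    """Fused WLD feature vector [EHist_1..EHist_N, OHist_1..OHist_N].

    Deterministic for a fixed config.  An all-zero patch still produces a
    valid (all-spike) vector but is flagged degenerate.
    """
    config = config or WldConfig()
    patch = np.asarray(patch, dtype=float)
    excitation = differential_excitation(patch, alpha=config.alpha)
    orientation = gradient_orientation(patch, mode=config.orientation_mode)
    e_hists = block_histograms(excitation, config.grid, config.fs_bins, (-np.pi / 2, np.pi / 2))
    o_hists = block_histograms(orientation, config.grid, config.fs_bins, (0.0, 2.0 * np.pi))
    values = np.concatenate(e_hists + o_hists)
    return FeatureVector(
        values=values,
        layout=(config.n_blocks, config.fs_bins, config.fs_bins),
        degenerate=bool(np.all(patch == 0)),
    )
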