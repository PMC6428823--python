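"""Frequency-domain contrast enhancement.

The image is tiled into square blocks, each block is transformed with an
orthonormal 2D DCT, and the coefficients are classed low- or high-frequency
by zig-zag rank.  The low-frequency reconstruction is contrast-enhanced with
CLAHE; the high-frequency reconstruction is added back unchanged so edge and
texture detail (and noise) are never amplified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft

from .image import GrayImage

__all__ = [
    "dct2",
    "idct2",
    "power_spectrum",
    "zigzag_order",
    "split_frequency",
    "clahe",
    "enhance",
    "EnhanceParams",
    "FrequencyDecomposition",
]


def _check_block(block: np.ndarray) -> np.ndarray:
    block = np.asarray(block, dtype=float)
    if block.ndim != 2 or block.size == 0:
        raise ValueError("block must be a nonempty 2D raster")
    if block.shape[0] != block.shape[1]:
        raise ValueError(f"block must be square, got {block.shape}")
    return block


def dct2(block: np.ndarray) -> np.ndarray:
    """Orthonormal 2D type-II DCT of a square block.

    The top-left entry is the DC coefficient; for an n-by-n constant block of
    value c it equals n*c.
    """
    return scipy.fft.dctn(_check_block(block), type=2, norm="ortho")


def idct2(coeffs: np.ndarray) -> np.ndarray:
    """Exact inverse of :func:`dct2`."""
    return scipy.fft.idctn(_check_block(coeffs), type=2, norm="ortho")


def power_spectrum(coeffs: np.ndarray) -> np.ndarray:
    """P(u, v) = |D(u, v)|^2.  By orthonormality, sum(P) equals the
    squared-pixel energy of the spatial block (Parseval)."""
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.ndim != 2 or coeffs.size == 0:
        raise ValueError("coeffs must be a nonempty 2D raster")
    return np.abs(coeffs) ** 2


def zigzag_order(block_size: int) -> list[tuple[int, int]]:
    """JPEG-style zig-zag enumeration of all block_size**2 coefficient
    positions, from DC at (0, 0) towards increasing spatial frequency."""
    n = int(block_size)
    if n < 1:
        raise ValueError("block_size must be >= 1")
    order: list[tuple[int, int]] = []
    for s in range(2 * n - 1):
        lo, hi = max(0, s - n + 1), min(s, n - 1)
        rows = range(hi, lo - 1, -1) if s % 2 == 0 else range(lo, hi + 1)
        order.extend((u, s - u) for u in rows)
    return order


def _zigzag_mask(block_size: int, lf_cutoff: int) -> np.ndarray:
    """Boolean mask selecting the first lf_cutoff zig-zag coefficients."""
    mask = np.zeros((block_size, block_size), dtype=bool)
    for u, v in zigzag_order(block_size)[:lf_cutoff]:
        mask[u, v] = True
    return mask


@dataclass
class FrequencyDecomposition:
    """LF/HF split of an image; lf + hf reconstructs the original."""

    lf_image: GrayImage
    hf_image: GrayImage
    block_size: int
    lf_cutoff: int


def _blockwise(pixels: np.ndarray, block_size: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Reflect-pad to a block multiple and reshape to (bi, bj, b, b) tiles."""
    h, w = pixels.shape
    b = block_size
    pad_r, pad_c = (-h) % b, (-w) % b
    padded = np.pad(pixels, ((0, pad_r), (0, pad_c)), mode="symmetric")
    ph, pw = padded.shape
    tiles = padded.reshape(ph // b, b, pw // b, b).transpose(0, 2, 1, 3)
    return tiles, (h, w)


def _unblock(tiles: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    bi, bj, b, _ = tiles.shape
    out = tiles.transpose(0, 2, 1, 3).reshape(bi * b, bj * b)
    return out[: shape[0], : shape[1]]


def split_frequency(image: GrayImage, block_size: int = 8, lf_cutoff: int = 16) -> FrequencyDecomposition:
    """Per-block DCT split into low- and high-frequency images.

    The first ``lf_cutoff`` zig-zag coefficients of each block reconstruct
    the LF image, the remainder the HF image.  Additivity holds to transform
    round-trip tolerance: lf + hf == image.
    """
    if not 1 <= lf_cutoff <= block_size**2:
        raise ValueError(f"lf_cutoff must be in [1, {block_size**2}], got {lf_cutoff}")
    tiles, shape = _blockwise(np.asarray(image.pixels, dtype=float), block_size)
    coeffs = scipy.fft.dctn(tiles, type=2, norm="ortho", axes=(2, 3))
    mask = _zigzag_mask(block_size, lf_cutoff)
    lf = scipy.fft.idctn(np.where(mask, coeffs, 0.0), type=2, norm="ortho", axes=(2, 3))
    hf = scipy.fft.idctn(np.where(mask, 0.0, coeffs), type=2, norm="ortho", axes=(2, 3))
    return FrequencyDecomposition(
        lf_image=image.with_pixels(_unblock(lf, shape), value_domain="linear"),
        hf_image=image.with_pixels(_unblock(hf, shape), value_domain="linear"),
        block_size=block_size,
        lf_cutoff=lf_cutoff,
    )


def _tile_lut(tile_bins: np.ndarray, clip_limit: float, n_bins: int, j_min: float, j_max: float) -> np.ndarray:
    """Clipped-histogram equalization LUT for one tile (given binned values).

    New gray level J = (j_max - j_min) * P(f) + j_min with P(f) the clipped
    cumulative distribution over the image's occupied gray range.  Clipped
    excess is redistributed uniformly across the bins.
    """
    hist = np.bincount(tile_bins.ravel(), minlength=n_bins).astype(float)
    clip = max(clip_limit * tile_bins.size, 1.0)
    excess = np.sum(np.maximum(hist - clip, 0.0))
    hist = np.minimum(hist, clip) + excess / n_bins
    cdf = np.cumsum(hist) / hist.sum()
    return (j_max - j_min) * cdf + j_min


def clahe(
    image: GrayImage,
    clip_limit: float = 0.01,
    tile_grid: tuple[int, int] = (8, 8),
    n_bins: int = 256,
) -> GrayImage:
    """Contrast-limited adaptive histogram equalization on a uint8 image.

    Per-tile histograms are clipped at ``clip_limit`` (a fraction of the tile
    pixel count) before CDF mapping; pixel mappings are bilinearly blended
    between the four surrounding tile centres.  The output display range
    [j_min, j_max] is the global min/max of the input, so a constant image is
    a fixed point.
    """
    if image.value_domain != "uint8":
        raise ValueError("clahe expects a uint8-domain image (window HU inputs first)")
    if clip_limit <= 0:
        raise ValueError("clip_limit must be positive")
    px = np.asarray(image.pixels, dtype=float)
    h, w = px.shape
    j_min, j_max = float(px.min()), float(px.max())
    if j_min == j_max:
        return image.with_pixels(px.copy())

    gr, gc = tile_grid
    gr, gc = min(gr, h), min(gc, w)  # degenerate small images
    th, tw = int(np.ceil(h / gr)), int(np.ceil(w / gc))
    padded = np.pad(px, ((0, gr * th - h), (0, gc * tw - w)), mode="symmetric")

    # bins span the occupied gray range so clipped excess never leaks
    # outside it (which would compress instead of enhance)
    n_bins = min(n_bins, int(np.ceil(j_max - j_min)) + 1)
    bins = np.clip(
        ((padded - j_min) * (n_bins / (j_max - j_min + 1e-12))).astype(np.intp), 0, n_bins - 1
    )

    luts = np.empty((gr, gc, n_bins))
    for i in range(gr):
        for j in range(gc):
            tile = bins[i * th : (i + 1) * th, j * tw : (j + 1) * tw]
            luts[i, j] = _tile_lut(tile, clip_limit, n_bins, j_min, j_max)

    rows = np.arange(gr * th, dtype=float)
    cols = np.arange(gc * tw, dtype=float)
    fy = (rows - (th - 1) / 2.0) / th
    fx = (cols - (tw - 1) / 2.0) / tw
    y0 = np.clip(np.floor(fy).astype(int), 0, gr - 1)
    x0 = np.clip(np.floor(fx).astype(int), 0, gc - 1)
    y1 = np.minimum(y0 + 1, gr - 1)
    x1 = np.minimum(x0 + 1, gc - 1)
    wy = np.clip(fy - np.floor(fy), 0.0, 1.0)
    wx = np.clip(fx - np.floor(fx), 0.0, 1.0)
    wy[fy < 0] = 0.0  # replicate edge tiles outside the centre lattice
    wx[fx < 0] = 0.0

    Y0, X0 = y0[:, None], x0[None, :]
    Y1, X1 = y1[:, None], x1[None, :]
    m00 = luts[Y0, X0, bins]
    m01 = luts[Y0, X1, bins]
    m10 = luts[Y1, X0, bins]
    m11 = luts[Y1, X1, bins]
    WY, WX = wy[:, None], wx[None, :]
    out = (1 - WY) * ((1 - WX) * m00 + WX * m01) + WY * ((1 - WX) * m10 + WX * m11)
    return image.with_pixels(np.clip(out[:h, :w], j_min, j_max))


@dataclass
class EnhanceParams:
    block_size: int = 8
    lf_cutoff: int = 16
    clip_limit: float = 0.01
    tile_grid: tuple[int, int] = field(default=(8, 8))
    n_bins: int = 256


def enhance(image: GrayImage, params: EnhanceParams | None = None, return_parts: bool = False):
    """CLAHE on the low-frequency component; high-frequency added back
    unchanged; result clipped to the uint8 display range.

    With ``return_parts=True`` also returns (enhanced_lf, hf) where ``hf`` is
    the untouched high-frequency component of the input.
    """
    params = params or EnhanceParams()
    if image.value_domain != "uint8":
        raise ValueError("enhance expects a uint8-domain image (window HU inputs first)")
    decomp = split_frequency(image, params.block_size, params.lf_cutoff)
    lf_px = np.clip(decomp.lf_image.pixels, 0, 255)
    lf_enh = clahe(
        image.with_pixels(lf_px),
        clip_limit=params.clip_limit,
        tile_grid=params.tile_grid,
        n_bins=params.n_bins,
    )
    out = np.clip(lf_enh.pixels + decomp.hf_image.pixels, 0, 255)
    result = image.with_pixels(out)
    if return_parts:
        return result, lf_enh, decomp.hf_image
    return result
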