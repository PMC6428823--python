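"""Candidate nodule extraction and pruning.

Nodules and vessels are denser than lung parenchyma, so candidates are the
bright connected components inside the lung mask.  The threshold is computed
once, on the median slice of a stack, and reused for every slice.  Candidates
are then pruned by area-equivalent diameter (nodules are 3-30 mm) and by
elongation (tubular vessels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .image import GrayImage, SpacingInfo
from .segmentation import DeParams, ThresholdSet, compute_histogram, de_optimal_thresholds

__all__ = [
    "CandidateRegion",
    "median_slice_threshold",
    "extract_rois",
    "equivalent_diameter",
    "elongation",
    "prune",
]

LABELS = ("candidate", "pruned_small", "pruned_large", "pruned_vessel", "nodule", "non_nodule")


@dataclass
class CandidateRegion:
    """A connected bright region inside the lung mask."""

    coords: np.ndarray  # (n, 2) pixel coordinates, row/col
    centroid: tuple[float, float]
    area_px: int
    equiv_diameter_mm: float
    elongation: float
    source_slice: int = 0
    label: str = "candidate"

    def __post_init__(self) -> None:
        if self.area_px <= 0 or self.area_px != len(self.coords):
            raise ValueError("area_px must equal the pixel count and be positive")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """(min_row, min_col, max_row_exclusive, max_col_exclusive)."""
        return (
            int(self.coords[:, 0].min()),
            int(self.coords[:, 1].min()),
            int(self.coords[:, 0].max()) + 1,
            int(self.coords[:, 1].max()) + 1,
        )


def equivalent_diameter(area_px: int | "CandidateRegion", spacing: SpacingInfo) -> float:
    """Area-equivalent disc diameter in mm: 2*sqrt(area/pi)*row_mm.

    Isotropic in-plane spacing is assumed (row spacing used).
    """
    area = area_px.area_px if isinstance(area_px, CandidateRegion) else int(area_px)
    if area <= 0:
        raise ValueError("area must be positive")
    return 2.0 * np.sqrt(area / np.pi) * spacing.row_mm


def elongation(coords: np.ndarray | "CandidateRegion") -> float:
    """Major/minor axis ratio of the region's moment-equivalent ellipse.

    Axis lengths are 4*sqrt(eigenvalue) of the central second-moment matrix;
    the minor axis is floored at one pixel so lines stay finite.
    """
    if isinstance(coords, CandidateRegion):
        coords = coords.coords
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 1:
        raise ValueError("coords must be a nonempty (n, 2) array")
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / coords.shape[0]
    eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    major = max(4.0 * np.sqrt(max(eigvals[0], 0.0)), 1.0)
    minor = max(4.0 * np.sqrt(max(eigvals[1], 0.0)), 1.0)
    return major / minor


def median_slice_threshold(
    stack: list[GrayImage],
    lung_masks: list[np.ndarray],
    k: int = 2,
    de_params: DeParams | None = None,
    seed: int | None = 0,
) -> ThresholdSet:
    """DE optimal threshold(s) of the median slice's lung-interior histogram.

    The median-index slice is used when its mask is nonempty; otherwise the
    nearest slice with a nonempty mask stands in.  The result is reused for
    every slice of the stack.

    The lung interior is dominated by parenchyma, and on such unbalanced
    histograms the raw misclassification criterion degenerates (isolating an
    extreme tail drives the error to zero).  The DE search is therefore
    bracketed between the lower-cluster mean and the fixed point of the
    iterative mean-split threshold of the interior values.
    """
    if len(stack) != len(lung_masks) or not stack:
        raise ValueError("stack and lung_masks must be nonempty and congruent")
    nonempty = [i for i, m in enumerate(lung_masks) if np.asarray(m).any()]
    if not nonempty:
        raise ValueError("all lung masks are empty")
    mid = len(stack) // 2
    idx = min(nonempty, key=lambda i: abs(i - mid))
    px = np.asarray(stack[idx].pixels, dtype=float)
    interior = px[np.asarray(lung_masks[idx], dtype=bool)]
    t = float(interior.mean())
    for _ in range(100):  # mean-split fixed point of the interior values
        below = interior <= t
        if below.all() or not below.any():
            break
        t_new = 0.5 * (interior[below].mean() + interior[~below].mean())
        if abs(t_new - t) < 0.5:
            t = t_new
            break
        t = t_new
    lo = float(interior[interior <= t].mean()) if (interior <= t).any() else float(interior.min())
    hist = compute_histogram(interior)
    bounds = (lo, t) if t > lo else None
    return de_optimal_thresholds(hist, k=k, de_params=de_params, seed=seed, bounds=bounds)


def extract_rois(
    slice_image: GrayImage,
    lung_mask: np.ndarray,
    threshold: float | ThresholdSet,
    source_slice: int = 0,
) -> list[CandidateRegion]:
    """Connected components (8-connectivity) of lung pixels at or above the
    threshold, with geometry populated from the slice spacing."""
    if isinstance(threshold, ThresholdSet):
        threshold = float(threshold.thresholds[0])
    mask = np.asarray(lung_mask, dtype=bool)
    bright = mask & (np.asarray(slice_image.pixels, dtype=float) >= threshold)
    labels = measure.label(bright, connectivity=2)
    spacing = slice_image.spacing
    regions = []
    for rp in measure.regionprops(labels):
        coords = rp.coords
        regions.append(
            CandidateRegion(
                coords=coords,
                centroid=tuple(rp.centroid),
                area_px=int(rp.area),
                equiv_diameter_mm=equivalent_diameter(int(rp.area), spacing),
                elongation=elongation(coords),
                source_slice=source_slice,
            )
        )
    return regions


def prune(
    regions: list[CandidateRegion],
    d_min_mm: float = 3.0,
    d_max_mm: float = 30.0,
    elong_max: float = 3.0,
) -> list[CandidateRegion]:
    """Label every region; survivors keep the label ``candidate``.

    Regions under ``d_min_mm`` are noise (pruned_small), over ``d_max_mm``
    lesions or vessels (pruned_large), and more elongated than ``elong_max``
    tubular vessels (pruned_vessel).  Non-destructive: all regions are
    returned, each with exactly one label.
    """
    out = []
    for r in regions:
        if r.equiv_diameter_mm < d_min_mm:
            label = "pruned_small"
        elif r.equiv_diameter_mm > d_max_mm:
            label = "pruned_large"
        elif r.elongation > elong_max:
            label = "pruned_vessel"
        else:
            label = "candidate"
        out.append(
            CandidateRegion(
                coords=r.coords,
                centroid=r.centroid,
                area_px=r.area_px,
                equiv_diameter_mm=r.equiv_diameter_mm,
                elongation=r.elongation,
                source_slice=r.source_slice,
                label=label,
            )
        )
    return out
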