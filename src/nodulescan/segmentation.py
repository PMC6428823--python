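"""Lung-field segmentation.

Pipeline: corner-scan background removal, an iterative mean-split threshold
initialised at -950 HU (the lung parenchyma band is roughly -950..-500 HU),
differential-evolution optimal thresholding that minimises the total Gaussian
misclassification error of the histogram partition, corner-seeded removal of
outside air, and hole filling so dense structures inside the lung stay in the
lung mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from scipy.special import erf
from skimage import measure

from .image import GrayImage

__all__ = [
    "GrayHistogram",
    "GaussianMixtureModel",
    "ThresholdSet",
    "DeParams",
    "SegmentationParams",
    "DegeneratePartitionError",
    "compute_histogram",
    "fit_mixture_from_partition",
    "classification_error",
    "de_optimal_thresholds",
    "iterative_initial_threshold",
    "remove_background",
    "corner_seeded_region_growing",
    "fill_holes",
    "segment_lungs",
]

_SIGMA_FLOOR = 1e-6


class DegeneratePartitionError(ValueError):
    """A threshold partition produced an empty class interval."""


@dataclass
class GrayHistogram:
    """Normalized frequency of each gray level present in an image."""

    levels: np.ndarray  # strictly increasing
    probs: np.ndarray  # nonnegative, sums to 1

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if not np.all(np.diff(self.levels) > 0):
            raise ValueError("levels must be strictly increasing")
        if abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("probs must sum to 1")


@dataclass
class GaussianMixtureModel:
    """Per-class Gaussian description of a partitioned histogram."""

    weights: np.ndarray
    means: np.ndarray
    stds: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.stds = np.asarray(self.stds, dtype=float)
        if not (len(self.weights) == len(self.means) == len(self.stds)):
            raise ValueError("mismatched mixture component counts")
        if len(self.weights) < 2:
            raise ValueError("mixture needs K >= 2 components")
        if np.any(self.stds <= 0):
            raise ValueError("stds must be positive")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    @property
    def k(self) -> int:
        return len(self.weights)


@dataclass
class ThresholdSet:
    thresholds: np.ndarray  # strictly increasing gray values
    total_error: float

    def __post_init__(self) -> None:
        self.thresholds = np.atleast_1d(np.asarray(self.thresholds, dtype=float))
        if not np.all(np.diff(self.thresholds) > 0):
            raise ValueError("thresholds must be strictly increasing")
        if self.total_error < 0:
            raise ValueError("total_error must be nonnegative")


def compute_histogram(image: GrayImage | np.ndarray) -> GrayHistogram:
    """Histogram of present gray levels, normalized to total mass 1.

    HU-valued float rasters are rounded to integer gray levels first.
    """
    px = image.pixels if isinstance(image, GrayImage) else np.asarray(image)
    if px.size == 0:
        raise ValueError("empty image")
    vals = np.asarray(px, dtype=float).ravel()
    if not np.allclose(vals, np.round(vals)):
        vals = np.round(vals)
    levels, counts = np.unique(vals, return_counts=True)
    return GrayHistogram(levels=levels, probs=counts / counts.sum())


def fit_mixture_from_partition(hist: GrayHistogram, thresholds) -> GaussianMixtureModel:
    """Moment-match one Gaussian per class interval induced by the thresholds.

    Class i collects histogram mass on [T_{i-1}, T_i); weights are interval
    masses, means/stds are interval moments (std floored at a tiny epsilon so
    single-level classes stay well defined).
    """
    thresholds = np.atleast_1d(np.asarray(thresholds, dtype=float))
    if thresholds.size == 0 or not np.all(np.diff(thresholds) > 0):
        raise ValueError("thresholds must be nonempty and strictly increasing")
    edges = np.concatenate(([-np.inf], thresholds, [np.inf]))
    weights, means, stds = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (hist.levels >= lo) & (hist.levels < hi)
        mass = hist.probs[sel].sum()
        if mass <= 0:
            raise DegeneratePartitionError(f"empty class interval [{lo}, {hi})")
        p = hist.probs[sel] / mass
        mu = float(np.dot(p, hist.levels[sel]))
        var = float(np.dot(p, (hist.levels[sel] - mu) ** 2))
        weights.append(mass)
        means.append(mu)
        stds.append(max(np.sqrt(var), _SIGMA_FLOOR))
    return GaussianMixtureModel(np.array(weights), np.array(means), np.array(stds))


def _norm_cdf(x: np.ndarray | float, mu: np.ndarray | float, sigma: np.ndarray | float):
    return 0.5 * (1.0 + erf((np.asarray(x, dtype=float) - mu) / (np.sqrt(2.0) * sigma)))


def classification_error(model: GaussianMixtureModel, thresholds) -> float:
    """Total Gaussian misclassification probability of a threshold vector.

    For each threshold T_i between adjacent classes i and i+1:
        e(T_i) = P_i * Pr[X_i > T_i] + P_{i+1} * Pr[X_{i+1} < T_i]
    i.e. each class contributes its mass falling on the wrong side of T_i.
    Well-separated classes drive the total towards zero; two identical
    classes give e = 0.5 * (P_i + P_{i+1}) at any threshold.
    """
    thresholds = np.atleast_1d(np.asarray(thresholds, dtype=float))
    if thresholds.size != model.k - 1:
        raise ValueError(f"expected {model.k - 1} thresholds, got {thresholds.size}")
    if thresholds.size > 1 and not np.all(np.diff(thresholds) > 0):
        raise ValueError("thresholds must be strictly increasing")
    p, mu, sd = model.weights, model.means, model.stds
    wrong_hi = p[:-1] * (1.0 - _norm_cdf(thresholds, mu[:-1], sd[:-1]))
    wrong_lo = p[1:] * _norm_cdf(thresholds, mu[1:], sd[1:])
    return float(np.sum(wrong_hi + wrong_lo))


@dataclass
class DeParams:
    """DE/rand/1/bin hyperparameters."""

    pop_size: int = 20
    mutation: float = 0.5  # F
    crossover: float = 0.9  # CR
    generations: int = 100


def _threshold_objective(hist: GrayHistogram, tvec: np.ndarray) -> float:
    """Misclassification error of a (sorted, repaired) threshold vector;
    infeasible partitions score +inf."""
    tvec = np.sort(tvec)
    if tvec.size > 1 and np.any(np.diff(tvec) <= 0):
        return np.inf
    try:
        model = fit_mixture_from_partition(hist, tvec)
    except DegeneratePartitionError:
        return np.inf
    return classification_error(model, tvec)


def de_optimal_thresholds(
    hist: GrayHistogram,
    k: int = 2,
    de_params: DeParams | None = None,
    seed: int | None = 0,
    bounds: tuple[float, float] | None = None,
) -> ThresholdSet:
    """Minimise the Gaussian misclassification error over K-1 thresholds with
    differential evolution (DE/rand/1/bin, sort-repair before evaluation).

    Deterministic for a fixed seed.  ``bounds`` restricts the search interval
    (default: the full histogram range); callers use it to window out
    degenerate tail splits on heavily unbalanced histograms.  Raises if the
    histogram has fewer than K distinct levels (no feasible partition).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(hist.levels) < k:
        raise ValueError(f"histogram has {len(hist.levels)} distinct levels; need >= {k}")
    params = de_params or DeParams()
    rng = np.random.default_rng(seed)
    d = k - 1
    if bounds is None:
        lo, hi = float(hist.levels.min()), float(hist.levels.max())
    else:
        lo, hi = float(bounds[0]), float(bounds[1])
    npop = max(params.pop_size, 4)

    pop = rng.uniform(lo, hi, size=(npop, d))
    fitness = np.array([_threshold_objective(hist, x) for x in pop])

    for _ in range(params.generations):
        for i in range(npop):
            r1, r2, r3 = rng.choice(npop, size=3, replace=False)
            mutant = pop[r1] + params.mutation * (pop[r2] - pop[r3])
            cross = rng.random(d) < params.crossover
            cross[rng.integers(d)] = True
            trial = np.clip(np.where(cross, mutant, pop[i]), lo, hi)
            f = _threshold_objective(hist, trial)
            if f <= fitness[i]:
                pop[i], fitness[i] = trial, f

    best = np.sort(pop[np.argmin(fitness)])
    err = fitness.min()
    if not np.isfinite(err):
        raise ValueError("differential evolution found no feasible partition")
    return ThresholdSet(thresholds=best, total_error=float(err))


def iterative_initial_threshold(image: GrayImage, t0_hu: float = -950.0) -> float:
    """Fixed point of T <- (mean[pixels <= T] + mean[pixels > T]) / 2,
    starting at -950 HU; converges when |dT| < 0.5 HU or after 100 rounds.

    If every pixel falls on one side of the start value, the start value is
    returned with a warning.
    """
    if image.value_domain != "HU":
        raise ValueError("iterative_initial_threshold expects an HU-domain image")
    px = np.asarray(image.pixels, dtype=float).ravel()
    t = float(t0_hu)
    below = px <= t
    if below.all() or not below.any():
        warnings.warn(f"all pixels on one side of {t0_hu} HU; returning the start value")
        return t
    for _ in range(100):
        below = px <= t
        if below.all() or not below.any():
            break
        t_new = 0.5 * (px[below].mean() + px[~below].mean())
        if abs(t_new - t) < 0.5:
            return float(t_new)
        t = float(t_new)
    return t


def _default_bg_range(image: GrayImage) -> tuple[float, float]:
    if image.value_domain == "HU":
        return (-1024.0, -1000.0)
    mn = float(np.min(image.pixels))
    return (mn, mn + 24.0)


def remove_background(image: GrayImage, bg_range: tuple[float, float] | None = None) -> np.ndarray:
    """Foreground mask after stripping corner-connected background.

    Pixels whose value lies in ``bg_range`` and that are reachable from the
    four image corners (or from the top/bottom runs of the middle column)
    through in-range pixels are background; the returned boolean mask marks
    everything else as foreground.
    """
    if bg_range is None:
        bg_range = _default_bg_range(image)
    px = np.asarray(image.pixels, dtype=float)
    in_range = (px >= bg_range[0]) & (px <= bg_range[1])
    labels = measure.label(in_range, connectivity=2)
    h, w = px.shape
    seeds = {labels[r, c] for r, c in ((0, 0), (0, w - 1), (h - 1, 0), (h - 1, w - 1))}
    mid = w // 2
    col = in_range[:, mid]
    r = 0
    while r < h and col[r]:
        seeds.add(labels[r, mid])
        r += 1
    r = h - 1
    while r >= 0 and col[r]:
        seeds.add(labels[r, mid])
        r -= 1
    seeds.discard(0)
    background = np.isin(labels, sorted(seeds)) if seeds else np.zeros_like(in_range)
    return ~background


def corner_seeded_region_growing(mask: np.ndarray) -> np.ndarray:
    """Remove mask components connected to any image corner (flood fill from
    the corners), isolating interior structures."""
    mask = np.asarray(mask, dtype=bool)
    labels = measure.label(mask, connectivity=2)
    h, w = mask.shape
    corner_labels = {labels[r, c] for r, c in ((0, 0), (0, w - 1), (h - 1, 0), (h - 1, w - 1))}
    corner_labels.discard(0)
    if not corner_labels:
        return mask.copy()
    return mask & ~np.isin(labels, sorted(corner_labels))


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill interior background holes (idempotent)."""
    return ndi.binary_fill_holes(np.asarray(mask, dtype=bool))


@dataclass
class SegmentationParams:
    k: int = 2
    de: DeParams = field(default_factory=DeParams)
    bg_range: tuple[float, float] | None = None
    t0_hu: float = -950.0
    min_area_px: int = 32  # specks below this are not lung tissue


def segment_lungs(
    image: GrayImage,
    params: SegmentationParams | None = None,
    seed: int | None = 0,
) -> np.ndarray:
    """Full lung-field segmentation of one HU slice; returns a boolean mask.

    Composition: background removal -> iterative -950 HU initial threshold
    (windows the body interior) -> DE optimal threshold (K classes on the
    interior histogram) -> corner-seeded removal of outside air -> hole fill.
    An empty result is returned with a warning rather than raising.
    """
    params = params or SegmentationParams()
    if image.value_domain != "HU":
        raise ValueError("segment_lungs expects an HU-domain image")
    px = np.asarray(image.pixels, dtype=float)

    fg = remove_background(image, params.bg_range)
    t_init = iterative_initial_threshold(image, params.t0_hu)

    interior = px[fg]
    empty = np.zeros_like(fg)
    if interior.size == 0:
        warnings.warn("background removal left no body interior; empty lung mask")
        return empty
    hist = compute_histogram(interior)
    try:
        tset = de_optimal_thresholds(hist, k=params.k, de_params=params.de, seed=seed)
        threshold = float(tset.thresholds[0])
    except ValueError:
        threshold = t_init  # degenerate interior; fall back on the HU prior

    below = px < threshold
    interior_air = corner_seeded_region_growing(below)
    lung = fill_holes(interior_air & fg)
    if params.min_area_px > 1:
        lung = measure.label(lung, connectivity=2)
        lung = np.isin(lung, [r.label for r in measure.regionprops(lung) if r.area >= params.min_area_px])
    if not lung.any():
        warnings.warn("lung segmentation produced an empty mask")
    return lung
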