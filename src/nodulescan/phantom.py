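"""Synthetic thorax CT phantom with ground truth.

Each slice is built in HU: air background at -1000, a soft-tissue body
ellipse around 40, two elliptical lung fields filled with smooth parenchyma
texture inside the -950..-500 HU band, tubular vessels and compact vessel
cross-section blobs near -50 HU, and implanted nodules with smooth-tapered
profiles.  Ground truth (lung mask, nodule records/mask, vessel mask) is
returned alongside, so every pipeline stage can be validated without any
external dataset.

Everything is driven by one seeded generator: a fixed seed reproduces the
image and truth bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from .candidates import extract_rois, median_slice_threshold, prune
from .classify import NEGATIVE_LABEL, POSITIVE_LABEL, LabeledDataset
from .image import GrayImage, SpacingInfo, window_to_uint8
from .segmentation import SegmentationParams, segment_lungs
from .wld import WldConfig, extract_features, extract_patch

__all__ = ["PhantomSpec", "PhantomTruth", "generate_slice", "generate_dataset", "DatasetResult"]


@dataclass
class PhantomSpec:
    image_size: int = 256
    spacing_mm: float = 0.7
    n_nodules: int = 2
    nodule_diameter_range_mm: tuple[float, float] = (5.0, 20.0)
    nodule_hu_range: tuple[float, float] = (0.0, 120.0)
    n_vessels: int = 3
    n_vessel_blobs: int = 3  # compact vessel cross-sections (non-nodule candidates)
    n_tiny_blobs: int = 0  # sub-3 mm distractors for the pruning rule
    noise_sigma_hu: float = 12.0
    contrast_degradation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        if self.spacing_mm <= 0:
            raise ValueError("spacing_mm must be positive")
        lo, hi = self.nodule_diameter_range_mm
        if not 0 < lo <= hi:
            raise ValueError("invalid nodule diameter range")
        if self.noise_sigma_hu < 0 or not 0 <= self.contrast_degradation <= 1:
            raise ValueError("invalid noise/contrast parameters")


@dataclass
class PhantomTruth:
    lung_mask: np.ndarray
    nodule_records: list[dict]  # center (row, col), diameter_mm, hu
    nodule_mask: np.ndarray
    vessel_mask: np.ndarray
    distractor_records: list[dict] = field(default_factory=list)


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float], semi: tuple[float, float]) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((rr - center[0]) / semi[0]) ** 2 + ((cc - center[1]) / semi[1]) ** 2 <= 1.0


def _lung_geometry(s: int):
    body = ((s / 2, s / 2), (0.40 * s, 0.46 * s))
    left = ((s / 2, 0.31 * s), (0.28 * s, 0.155 * s))
    right = ((s / 2, 0.69 * s), (0.28 * s, 0.155 * s))
    return body, left, right


def _paint_disc(px: np.ndarray, center: tuple[float, float], radius: float, hu: float, edge_px: float = 1.5) -> np.ndarray:
    """Blend a smooth-profile disc into the raster; returns its core mask."""
    r0, c0 = center
    rr, cc = np.mgrid[0 : px.shape[0], 0 : px.shape[1]]
    dist = np.sqrt((rr - r0) ** 2 + (cc - c0) ** 2)
    w = np.clip((radius - dist) / edge_px, 0.0, 1.0)
    px[:] = (1 - w) * px + w * hu
    return dist <= radius


def _random_point(rng: np.random.Generator, allowed: np.ndarray) -> tuple[int, int] | None:
    idx = np.flatnonzero(allowed.ravel())
    if idx.size == 0:
        return None
    flat = rng.choice(idx)
    return np.unravel_index(flat, allowed.shape)  # type: ignore[return-value]


def generate_slice(spec: PhantomSpec) -> tuple[GrayImage, PhantomTruth]:
    """One thorax-like HU slice plus its ground truth."""
    rng = np.random.default_rng(spec.seed)
    s = spec.image_size
    px = np.full((s, s), -1000.0)

    body, left, right = _lung_geometry(s)
    px[_ellipse_mask((s, s), *body)] = 40.0
    lung_mask = _ellipse_mask((s, s), *left) | _ellipse_mask((s, s), *right)

    # parenchyma: smooth random texture clipped into the -950..-500 band
    texture = ndi.gaussian_filter(rng.normal(0.0, 1.0, (s, s)), sigma=4.0)
    scale = max(np.abs(texture).max(), 1e-9)
    px[lung_mask] = np.clip(-780.0 + 120.0 * texture[lung_mask] / scale, -950.0, -500.0)

    vessel_mask = np.zeros((s, s), dtype=bool)
    vessel_hu = -50.0
    safe_lung = ndi.distance_transform_edt(lung_mask)

    for _ in range(spec.n_vessels):
        start = _random_point(rng, safe_lung > 6)
        if start is None:
            break
        r, c = float(start[0]), float(start[1])
        angle = rng.uniform(0, 2 * np.pi)
        width = rng.integers(1, 5)
        for _ in range(int(rng.integers(25, 60))):
            rr, cc = int(round(r)), int(round(c))
            if not (0 <= rr < s and 0 <= cc < s) or not lung_mask[rr, cc]:
                break
            rr0, rr1 = max(rr - width, 0), min(rr + width + 1, s)
            cc0, cc1 = max(cc - width, 0), min(cc + width + 1, s)
            stamp = np.zeros((s, s), dtype=bool)
            yy, xx = np.mgrid[rr0:rr1, cc0:cc1]
            stamp[rr0:rr1, cc0:cc1] = (yy - r) ** 2 + (xx - c) ** 2 <= (width / 2.0 + 0.5) ** 2
            stamp &= lung_mask
            px[stamp] = vessel_hu
            vessel_mask |= stamp
            angle += rng.normal(0.0, 0.25)
            r += np.sin(angle)
            c += np.cos(angle)

    truth = PhantomTruth(
        lung_mask=lung_mask,
        nodule_records=[],
        nodule_mask=np.zeros((s, s), dtype=bool),
        vessel_mask=vessel_mask,
    )

    def _place_blob(radius_px: float, keep_clear: np.ndarray, margin: float) -> tuple | None:
        """Centre where a disc of radius_px fits inside the lung, clear of
        already-placed structures; None when no such centre exists."""
        fits = ndi.distance_transform_edt(lung_mask & ~keep_clear) > (radius_px + margin)
        return _random_point(rng, fits)

    occupied = vessel_mask.copy()
    for i in range(spec.n_vessel_blobs):
        d_mm = rng.uniform(3.5, 6.5)
        radius = d_mm / 2.0 / spec.spacing_mm
        at = _place_blob(radius, occupied, margin=3.0)
        if at is None:
            continue
        core = _paint_disc(px, at, radius, vessel_hu, edge_px=0.8)
        truth.vessel_mask |= core
        occupied |= ndi.binary_dilation(core, iterations=3)

    for i in range(spec.n_tiny_blobs):
        d_mm = 2.0
        radius = max(d_mm / 2.0 / spec.spacing_mm, 1.0)
        at = _place_blob(radius, occupied, margin=2.0)
        if at is None:
            continue
        core = _paint_disc(px, at, radius, 60.0, edge_px=0.8)
        truth.distractor_records.append({"center": at, "diameter_mm": d_mm, "hu": 60.0})
        occupied |= ndi.binary_dilation(core, iterations=3)

    placed = 0
    for i in range(spec.n_nodules):
        d_mm = rng.uniform(*spec.nodule_diameter_range_mm)
        hu = rng.uniform(*spec.nodule_hu_range)
        radius = d_mm / 2.0 / spec.spacing_mm
        at = _place_blob(radius, occupied, margin=4.0)
        if at is None:
            raise RuntimeError(
                f"could not place nodule {i + 1}/{spec.n_nodules} without overlap; placed {placed}"
            )
        core = _paint_disc(px, at, radius, hu, edge_px=max(1.5, 0.45 * radius))
        truth.nodule_mask |= core
        truth.nodule_records.append({"center": at, "diameter_mm": d_mm, "hu": hu})
        occupied |= ndi.binary_dilation(core, iterations=4)
        placed += 1

    if spec.noise_sigma_hu > 0:
        px += rng.normal(0.0, spec.noise_sigma_hu, (s, s))
    if spec.contrast_degradation > 0:
        px = px.mean() + (px - px.mean()) * (1.0 - spec.contrast_degradation)

    image = GrayImage(px, value_domain="HU", spacing=SpacingInfo(spec.spacing_mm, spec.spacing_mm))
    return image, truth


@dataclass
class DatasetResult:
    dataset: LabeledDataset
    slices: list[GrayImage]
    truths: list[PhantomTruth]
    regions: list[list]  # pruned regions per slice
    n_implanted: int
    n_detected: int

    @property
    def detection_sensitivity(self) -> float:
        return self.n_detected / self.n_implanted if self.n_implanted else float("nan")


def generate_dataset(
    spec: PhantomSpec | None = None,
    n_slices: int = 20,
    seed: int = 0,
    seg_params: SegmentationParams | None = None,
    wld_config: WldConfig | None = None,
    d_min_mm: float = 3.0,
    d_max_mm: float = 30.0,
    elong_max: float = 3.0,
    balance: bool = True,
) -> DatasetResult:
    """Generate slices, run segmentation + candidate extraction on them, and
    return a labeled WLD feature dataset.

    A surviving candidate is labeled nodule when its centroid falls inside a
    ground-truth nodule disc, non-nodule otherwise.  Each dataset implants
    one sub-3 mm distractor (exercising the small-diameter pruning rule) and
    tubular vessels (the elongation rule).  With ``balance`` the majority
    class is subsampled with the seed.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    base = spec or PhantomSpec()
    wld_config = wld_config or WldConfig()
    rng = np.random.default_rng(seed)

    slices, truths, masks = [], [], []
    for i in range(n_slices):
        slice_spec = PhantomSpec(
            **{
                **base.__dict__,
                "seed": int(np.random.default_rng([seed, i]).integers(2**31)),
                "n_tiny_blobs": base.n_tiny_blobs or (1 if i == 0 else 0),
            }
        )
        img, truth = generate_slice(slice_spec)
        slices.append(img)
        truths.append(truth)
        masks.append(segment_lungs(img, seg_params, seed=seed))

    tset = median_slice_threshold(slices, masks, seed=seed)

    feats, labels, ids, regions_per_slice = [], [], [], []
    n_implanted = n_detected = 0
    for i, (img, truth, mask) in enumerate(zip(slices, truths, masks)):
        regions = prune(extract_rois(img, mask, tset, source_slice=i), d_min_mm, d_max_mm, elong_max)
        regions_per_slice.append(regions)
        survivors = [r for r in regions if r.label == "candidate"]
        win = window_to_uint8(img)
        for j, r in enumerate(survivors):
            rr, cc = int(round(r.centroid[0])), int(round(r.centroid[1]))
            inside = truth.nodule_mask[rr, cc]
            fv = extract_features(extract_patch(win, r, wld_config), wld_config)
            feats.append(fv.values)
            labels.append(POSITIVE_LABEL if inside else NEGATIVE_LABEL)
            ids.append(f"s{i}r{j}")
        n_implanted += len(truth.nodule_records)
        for rec in truth.nodule_records:
            r0, c0 = rec["center"]
            rad = rec["diameter_mm"] / 2.0 / base.spacing_mm
            hit = any(
                (s.centroid[0] - r0) ** 2 + (s.centroid[1] - c0) ** 2 <= rad**2 for s in survivors
            )
            n_detected += int(hit)

    if not feats:
        raise ValueError("pipeline produced zero surviving candidates")
    dataset = LabeledDataset(np.array(feats), np.array(labels), np.array(ids))

    if balance:
        pos = np.flatnonzero(dataset.labels == POSITIVE_LABEL)
        neg = np.flatnonzero(dataset.labels == NEGATIVE_LABEL)
        n = min(len(pos), len(neg))
        if n > 0:
            keep = np.sort(
                np.concatenate(
                    [rng.choice(pos, n, replace=False), rng.choice(neg, n, replace=False)]
                )
            )
            dataset = dataset.subset(keep)

    return DatasetResult(
        dataset=dataset,
        slices=slices,
        truths=truths,
        regions=regions_per_slice,
        n_implanted=n_implanted,
        n_detected=n_detected,
    )
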