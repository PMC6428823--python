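"""End-to-end driver: enhance -> segment -> detect -> features -> predict.

Every stage records its parameters and output counts in a JSON-serializable
run report, so a rerun with the same seed and config reproduces the report
exactly.
"""

from __future__ import annotations

import logging

import numpy as np

from .candidates import extract_rois, median_slice_threshold, prune
from .classify import SvmModel, confusion, metrics, predict
from .config import PipelineConfig, _to_dict
from .enhancement import enhance
from .image import GrayImage, window_to_uint8
from .segmentation import segment_lungs
from .wld import extract_features, extract_patch

__all__ = ["run_pipeline"]

log = logging.getLogger("nodulescan")


def run_pipeline(
    config: PipelineConfig,
    slices: list[GrayImage],
    model: SvmModel | None = None,
    true_labels: list[str] | None = None,
) -> dict:
    """Run the full pipeline over HU slices.

    Returns a report with per-stage counts, the pruned candidate table, the
    fused feature matrix, and (when a trained model is given) predictions —
    plus metrics when ground-truth labels for the surviving candidates are
    supplied as well.
    """
    if not slices:
        raise ValueError("no input slices")
    report: dict = {"config": _to_dict(config), "stages": {}}

    enhanced, masks = [], []
    for img in slices:
        win = window_to_uint8(img, config.window_hu) if img.value_domain == "HU" else img
        enhanced.append(enhance(win, config.enhancement))
        masks.append(segment_lungs(img, config.segmentation, seed=config.seed))
    report["stages"]["enhance"] = {"n_slices": len(slices)}
    report["stages"]["segment"] = {"lung_px": [int(m.sum()) for m in masks]}

    try:
        tset = median_slice_threshold(
            slices, masks, k=config.candidates.k, de_params=config.segmentation.de, seed=config.seed
        )
    except ValueError as exc:
        raise RuntimeError(f"detect stage failed: {exc}") from exc

    all_regions, survivors = [], []
    for i, (img, mask) in enumerate(zip(slices, masks)):
        regions = prune(
            extract_rois(img, mask, tset, source_slice=i),
            config.candidates.d_min_mm,
            config.candidates.d_max_mm,
            config.candidates.elong_max,
        )
        all_regions.append(regions)
        survivors.extend(r for r in regions if r.label == "candidate")
    label_counts: dict[str, int] = {}
    for regions in all_regions:
        for r in regions:
            label_counts[r.label] = label_counts.get(r.label, 0) + 1
    report["stages"]["detect"] = {
        "threshold": [float(t) for t in tset.thresholds],
        "labels": label_counts,
        "n_candidates": len(survivors),
    }

    features = []
    for r in survivors:
        patch = extract_patch(enhanced[r.source_slice], r, config.features)
        features.append(extract_features(patch, config.features).values)
    feature_matrix = np.array(features) if features else np.empty((0, config.features.vector_length))
    report["stages"]["features"] = {"n_vectors": len(features), "dim": int(feature_matrix.shape[1])}
    report["candidates"] = [
        {
            "slice": r.source_slice,
            "centroid_row": float(r.centroid[0]),
            "centroid_col": float(r.centroid[1]),
            "area_px": r.area_px,
            "diameter_mm": float(r.equiv_diameter_mm),
            "elongation": float(r.elongation),
            "label": r.label,
        }
        for regions in all_regions
        for r in regions
    ]
    report["feature_matrix"] = feature_matrix

    if model is not None and len(features) > 0:
        pred, scores = predict(model, feature_matrix)
        report["predictions"] = {"labels": pred.tolist(), "scores": scores.tolist()}
        if true_labels is not None:
            cm = confusion(pred, np.asarray(true_labels))
            report["metrics"] = {
                "tp": cm.tp,
                "fp": cm.fp,
                "fn": cm.fn,
                "tn": cm.tn,
                **metrics(cm),
            }
    log.info("pipeline: %s", report["stages"])
    return report
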