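"""Per-ROI discriminability: repeat the classification per atlas region.

Each ROI is cropped to its bounding box (voxels outside the mask
zeroed), padded symmetrically to at least 8 voxels per dimension, and
the full nested-CV pipeline is rerun on the crops with the same fold
plan for every ROI so accuracies are directly comparable.  Regions too
small for three poolings use two (third hidden layer unpooled).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import evaluation as ev
from . import model as pcnn
from .errors import DomainError
from .prep import PreparedDataset
from .synthetic import LabelVolume

MIN_DIM = 8  # model floor after padding
THREE_POOL_MIN = 16  # below this, drop the third pooling


@dataclass
class ROIResult:
    roi_id: int
    roi_name: str
    tissue: str
    mean_accuracy: float
    fold_accuracies: list

    def __post_init__(self):
        if len(self.fold_accuracies) != ev.N_FOLDS:
            raise DomainError(f"expected {ev.N_FOLDS} fold accuracies")
        if abs(self.mean_accuracy - float(np.mean(self.fold_accuracies))) > 1e-9:
            raise DomainError("mean_accuracy must equal the mean of fold_accuracies")


def roi_bounding_box(labels: LabelVolume, roi_id: int):
    mask = labels.labels == roi_id
    if not mask.any():
        raise DomainError(f"unknown roi_id {roi_id}")
    coords = np.argwhere(mask)
    lo = coords.min(axis=0)
    hi = coords.max(axis=0) + 1
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def extract_roi_volume(volume: np.ndarray, labels: LabelVolume, roi_id: int) -> np.ndarray:
    """Masked bounding-box crop, zero-padded symmetrically up to 8^3."""
    volume = np.asarray(volume)
    if volume.shape != labels.labels.shape:
        raise DomainError("volume and atlas shapes differ")
    box = roi_bounding_box(labels, roi_id)
    crop = np.where((labels.labels == roi_id)[box], volume[box], 0.0)
    pads = []
    for s in crop.shape:
        extra = max(0, MIN_DIM - s)
        pads.append((extra // 2, extra - extra // 2))
    return np.pad(crop, pads)


def per_roi_accuracy(
    store: PreparedDataset,
    labels: LabelVolume,
    roi_id: int,
    config: pcnn.TrainingConfig,
    plan: ev.FoldPlan,
) -> ROIResult:
    """Nested CV on ROI crops of every subject (same folds as whole-brain)."""
    if roi_id not in labels.roi_table:
        raise DomainError(f"unknown roi_id {roi_id}")
    crops = np.stack([extract_roi_volume(v, labels, roi_id) for v in store.volumes])
    roi_store = PreparedDataset(crops, store.labels, store.subject_ids)
    n_pools = 2 if min(crops.shape[1:]) < THREE_POOL_MIN else 3
    try:
        result = ev.run_nested_cv(roi_store, config, plan, n_pools=n_pools, keep_best_model=False)
    except Exception as exc:
        raise type(exc)(f"roi {roi_id}: {exc}") from exc
    info = labels.roi_table[roi_id]
    return ROIResult(
        roi_id=roi_id,
        roi_name=info["name"],
        tissue=info["tissue"],
        mean_accuracy=result.mean_accuracy,
        fold_accuracies=result.fold_accuracies,
    )


def map_all_rois(store, labels, config, plan, progress=None) -> list:
    results = []
    for rid in labels.roi_ids:
        results.append(per_roi_accuracy(store, labels, rid, config, plan))
        if progress:
            progress(results[-1])
    return results


def build_accuracy_map(labels: LabelVolume, results: list) -> np.ndarray:
    """Recolor each ROI with its mean accuracy; background stays 0."""
    by_id = {r.roi_id: r for r in results}
    missing = set(labels.roi_table) - set(by_id)
    if missing:
        raise DomainError(f"missing ROI results for ids {sorted(missing)}")
    out = np.zeros(labels.labels.shape)
    for rid, res in by_id.items():
        out[labels.labels == rid] = res.mean_accuracy
    return out


def rank_rois(results: list, k: int) -> dict:
    """Top-k table per tissue class, ties broken by ascending roi_id."""
    if k < 1:
        raise DomainError("k must be >= 1")
    if not results:
        raise DomainError("no ROI results to rank")
    tables = {}
    for tissue in ("gray", "white"):
        rows = [r for r in results if r.tissue == tissue]
        rows.sort(key=lambda r: (-r.mean_accuracy, r.roi_id))
        tables[tissue] = pd.DataFrame(
            [
                {
                    "rank": i + 1,
                    "roi_id": r.roi_id,
                    "name": r.roi_name,
                    "tissue": r.tissue,
                    "mean_accuracy": r.mean_accuracy,
                }
                for i, r in enumerate(rows[:k])
            ]
        )
    return tables
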