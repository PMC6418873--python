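"""Statistics of the 32 first-hidden-layer feature maps.

Per subject and feature: the mean voxel value of the map and the Shannon
entropy H = -sum p_i ln p_i of its 256-level quantized histogram.  Group
differences are tested per feature with Welch two-sample t-tests and
flagged at the Bonferroni threshold 0.05/32.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import model as pcnn
from .errors import DomainError
from .prep import PreparedDataset

N_LEVELS = 256
N_FEATURES = 32
ALPHA = 0.05


@dataclass
class QuantizedMap:
    values: np.ndarray  # integer grid in 0..255
    source_feature: int = 0
    subject_id: str = ""

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.min() < 0 or v.max() > N_LEVELS - 1:
            raise DomainError("quantized values must lie in 0..255")
        self.values = v.astype(np.int16)


def quantize_map(values: np.ndarray, source_feature: int = 0, subject_id: str = "") -> QuantizedMap:
    """Per-map min-max scaling to 0..255, rounded; constant maps -> all zeros."""
    values = np.asarray(values, dtype=np.float64)
    if not np.isfinite(values).all():
        raise DomainError("map contains non-finite values")
    lo, hi = values.min(), values.max()
    if hi == lo:
        q = np.zeros(values.shape, np.int16)
    else:
        q = np.rint((values - lo) / (hi - lo) * (N_LEVELS - 1)).astype(np.int16)
    return QuantizedMap(q, source_feature, subject_id)


def entropy(qmap: QuantizedMap) -> float:
    """Shannon entropy (natural log) of the 256-bin frequency distribution."""
    v = qmap.values
    if v.size == 0:
        raise DomainError("empty grid")
    p = np.bincount(v.reshape(-1), minlength=N_LEVELS) / v.size
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def two_sample_ttest(values_a, values_b):
    """Welch two-sided t-test; returns (t, p)."""
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise DomainError("each group needs at least 2 values")
    if a.var(ddof=1) + b.var(ddof=1) == 0:
        raise DomainError("degenerate (zero) variance in both groups")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def bonferroni_threshold(alpha: float, m: int) -> float:
    if not 0 < alpha < 1:
        raise DomainError(f"alpha must be in (0, 1); got {alpha}")
    if m < 1:
        raise DomainError(f"m must be >= 1; got {m}")
    return alpha / m


def _layer1_maps_batched(model: pcnn.PCNNModel, volumes: np.ndarray, batch_size: int = 45):
    """(n, d2, w2, h2, 32) stack of first-hidden-layer maps, inference mode."""
    out = []
    v = volumes[..., None].astype(np.float32) if volumes.ndim == 4 else volumes
    for start in range(0, len(v), batch_size):
        x = v[start : start + batch_size]
        for layer in model.layers[: model._hidden_ends[0]]:
            x = layer.forward(x, training=False)
        out.append(x)
    return np.concatenate(out)


def feature_group_analysis(
    model: pcnn.PCNNModel, store: PreparedDataset, alpha: float = ALPHA
) -> pd.DataFrame:
    """Per-feature group statistics table (32 rows).

    Columns: feature, mean_A, mean_B, t_mean, p_mean, sig_mean,
    H_A, H_B, t_H, p_H, sig_H.  Dead features (identical values in both
    groups) get t = 0, p = 1 rather than an error.
    """
    groups = np.asarray(store.groups)
    if set(groups) != {"A", "B"}:
        raise DomainError("both groups must be present in the dataset")
    maps = _layer1_maps_batched(model, store.volumes)
    n_feat = maps.shape[-1]
    mean_vals = maps.reshape(len(store), -1, n_feat).mean(axis=1)  # (n, 32)
    ent_vals = np.empty_like(mean_vals)
    for i in range(len(store)):
        for f in range(n_feat):
            ent_vals[i, f] = entropy(quantize_map(maps[i, ..., f]))
    thresh = bonferroni_threshold(alpha, n_feat)
    is_a = groups == "A"
    rows = []
    for f in range(n_feat):
        row = {"feature": f + 1}
        for stat_name, vals in (("mean", mean_vals[:, f]), ("H", ent_vals[:, f])):
            a, b = vals[is_a], vals[~is_a]
            try:
                t, p = two_sample_ttest(a, b)
            except DomainError:
                t, p = 0.0, 1.0
            prefix = {"mean": "mean", "H": "H"}[stat_name]
            row[f"{prefix}_A"] = float(a.mean())
            row[f"{prefix}_B"] = float(b.mean())
            row[f"t_{stat_name}"] = t
            row[f"p_{stat_name}"] = p
            row[f"sig_{stat_name}"] = bool(p < thresh)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["bonferroni_threshold"] = thresh
    df.attrs["entropy_log_base"] = "e"
    df.attrs["maps"] = "layer 1, post-activation, post-pooling"
    return df[
        ["feature", "mean_A", "mean_B", "t_mean", "p_mean", "sig_mean",
         "H_A", "H_B", "t_H", "p_H", "sig_H"]
    ]
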