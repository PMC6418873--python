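"""Volume loading, rescaling to the model grid, labels and record store.

The record store is a single HDF5 container with datasets ``volumes``
(n, d, w, h float32), ``labels`` (n, 2 int8 one-hot) and ``subject_ids``
(UTF-8), replacing the framework-specific record format with something
portable and seekable.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DomainError

#: reference model input grid; configurable downward for desk-scale runs
DEFAULT_TARGET_SHAPE = (58, 70, 58)

LABEL_MAP = {"A": (1, 0), "B": (0, 1)}  # A = man -> [1 0], B = woman -> [0 1]
_GROUP_ALIASES = {"man": "A", "woman": "B", "A": "A", "B": "B"}


def load_volume(path):
    """A 3D NIfTI as ``(values, voxel_size)``; values unchanged."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such volume: {p}")
    img = nib.load(str(p))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise DomainError(f"expected a 3D volume, got shape {data.shape} in {p}")
    return np.asarray(data, dtype=np.float64), tuple(float(z) for z in img.header.get_zooms()[:3])


def rescale_volume(volume: np.ndarray, target_shape, order: int = 3) -> np.ndarray:
    """Spline-resample onto ``target_shape``; overshoot clipped to input range."""
    volume = np.asarray(volume, dtype=np.float64)
    target_shape = tuple(int(t) for t in target_shape)
    if any(t < 1 for t in target_shape):
        raise DomainError(f"target dims must be positive; got {target_shape}")
    if any(s < 2 for s in volume.shape):
        raise DomainError(f"input dims must all be >= 2; got {volume.shape}")
    if volume.shape == target_shape:
        return volume.copy()
    factors = [t / s for t, s in zip(target_shape, volume.shape)]
    out = ndimage.zoom(volume, factors, order=order, mode="mirror", grid_mode=True)
    if out.shape != target_shape:  # zoom rounds the output size; enforce exactly
        out = out[tuple(slice(0, t) for t in target_shape)]
    return np.clip(out, volume.min(), volume.max())


def encode_label(group: str):
    """One-hot pair: man/A -> [1, 0]; woman/B -> [0, 1]."""
    if group not in _GROUP_ALIASES:
        raise DomainError(f"unknown group {group!r}")
    return np.array(LABEL_MAP[_GROUP_ALIASES[group]], dtype=np.int8)


def decode_label(onehot) -> str:
    pair = tuple(int(v) for v in onehot)
    for group, enc in LABEL_MAP.items():
        if enc == pair:
            return group
    raise DomainError(f"not a valid one-hot pair: {pair}")


class PreparedDataset:
    """In-memory view of a record store: volumes, one-hot labels, ids."""

    def __init__(self, volumes: np.ndarray, labels: np.ndarray, subject_ids):
        volumes = np.asarray(volumes, dtype=np.float32)
        labels = np.asarray(labels, dtype=np.int8)
        if volumes.ndim != 4:
            raise DomainError(f"volumes must be (n, d, w, h); got {volumes.shape}")
        if labels.shape != (len(volumes), 2):
            raise DomainError("labels must be one-hot pairs, one per volume")
        if not np.all(labels.sum(axis=1) == 1):
            raise DomainError("every label must be exactly one-hot")
        self.volumes = volumes
        self.labels = labels
        self.subject_ids = [str(s) for s in subject_ids]
        if len(self.subject_ids) != len(volumes):
            raise DomainError("subject_ids length mismatch")

    def __len__(self):
        return len(self.volumes)

    @property
    def target_shape(self):
        return self.volumes.shape[1:]

    @property
    def groups(self):
        return [decode_label(lbl) for lbl in self.labels]

    def index_of(self, subject_id: str) -> int:
        return self.subject_ids.index(subject_id)

    def subset(self, subject_ids) -> "PreparedDataset":
        idx = [self.index_of(s) for s in subject_ids]
        return PreparedDataset(self.volumes[idx], self.labels[idx], [self.subject_ids[i] for i in idx])

    def iter_records(self, shuffle_seed: int | None = None):
        """Yield (volume, label, subject_id); optionally in seeded shuffled order."""
        order = np.arange(len(self))
        if shuffle_seed is not None:
            order = np.random.default_rng(shuffle_seed).permutation(order)
        for i in order:
            yield self.volumes[i], self.labels[i], self.subject_ids[i]

    @classmethod
    def from_groups(cls, volumes, groups, subject_ids=None) -> "PreparedDataset":
        labels = np.stack([encode_label(g) for g in groups])
        if subject_ids is None:
            subject_ids = [f"s{i + 1:04d}" for i in range(len(volumes))]
        return cls(volumes, labels, subject_ids)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"subject_id", "group", "path"}
    if not required.issubset(df.columns):
        raise DomainError(f"manifest must have columns {sorted(required)}; got {list(df.columns)}")
    return df


def build_record_store(manifest_path, target_shape, out_path) -> "PreparedDataset":
    """Rescale every manifest volume, one-hot its label, write the store."""
    df = read_manifest(manifest_path)
    target_shape = tuple(int(t) for t in target_shape)
    volumes = np.empty((len(df), *target_shape), np.float32)
    labels = np.empty((len(df), 2), np.int8)
    for i, row in df.iterrows():
        try:
            vol, _ = load_volume(row["path"])
            volumes[i] = rescale_volume(vol, target_shape)
        except Exception as exc:
            raise type(exc)(f"subject {row['subject_id']}: {exc}") from exc
        labels[i] = encode_label(row["group"])
    ds = PreparedDataset(volumes, labels, df["subject_id"].tolist())
    save_record_store(ds, out_path)
    return ds


def save_record_store(ds: PreparedDataset, path):
    with h5py.File(path, "w") as f:
        f.create_dataset("volumes", data=ds.volumes, chunks=(1, *ds.target_shape))
        f.create_dataset("labels", data=ds.labels)
        f.create_dataset("subject_ids", data=np.array(ds.subject_ids, dtype="S"))
        f.attrs["label_map"] = "A=man=[1,0]; B=woman=[0,1]"


def load_record_store(path) -> PreparedDataset:
    with h5py.File(path, "r") as f:
        return PreparedDataset(
            f["volumes"][...],
            f["labels"][...],
            [s.decode() for s in f["subject_ids"][...]],
        )
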