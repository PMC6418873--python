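"""Synthetic diffusion-tensor cohorts with controllable group differences.

Generates, for each subject, a grid of axially symmetric diffusion
tensors whose noiseless FA hits a per-tissue target, inside an
ellipsoidal "brain" mask parcellated into connected gray- and
white-matter ROIs.  Two kinds of group effect can be injected:

``mean_shift``
    Group FA means inside target ROIs differ by a stated Cohen's d.
    Each subject carries a global FA deviation with standard deviation
    ``subject_sd``; the shift is ±d·subject_sd/2 applied to the FA
    target before eigenvalue construction, so the between-subject SD of
    ROI-mean FA is the pooled denominator the effect size refers to.

``texture_complexity``
    One group's scalar maps are smoothed with a wider Gaussian kernel
    (width difference = magnitude, in voxels), lowering the entropy of
    their quantized maps.  ``direction = +1`` means group A keeps the
    higher entropy (group B gets the extra smoothing).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage

from . import scalars as sc
from .errors import DomainError

GROUPS = ("A", "B")  # A <-> "man", B <-> "woman" downstream

EFFECT_KINDS = ("mean_shift", "texture_complexity")


@dataclass
class GroupEffect:
    kind: str
    target_roi_ids: frozenset = frozenset()
    magnitude: float = 0.0
    direction: int = +1  # +1: group A larger (mean or entropy)

    def __post_init__(self):
        if self.kind not in EFFECT_KINDS:
            raise DomainError(f"unknown effect kind {self.kind!r}")
        if self.magnitude < 0:
            raise DomainError("effect magnitude must be >= 0")
        if self.direction not in (+1, -1):
            raise DomainError("direction must be +1 or -1")
        self.target_roi_ids = frozenset(int(r) for r in self.target_roi_ids)
        if self.kind == "mean_shift" and self.magnitude > 0 and not self.target_roi_ids:
            raise DomainError("mean_shift requires nonempty target_roi_ids")


@dataclass
class CohortSpec:
    n_subjects: int
    volume_shape: tuple
    group_fraction: float = 0.5
    effects: list = field(default_factory=list)
    noise_sd: float = 0.02
    subject_sd: float = 0.03
    base_fa: dict = field(default_factory=lambda: {"gray": 0.25, "white": 0.65})
    mean_diffusivity: float = 0.8
    n_gray_rois: int = 6
    n_white_rois: int = 4
    texture_base_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise DomainError("n_subjects must be >= 2")
        if not 0.0 <= self.group_fraction <= 1.0:
            raise DomainError("group_fraction must be in [0, 1]")
        self.volume_shape = tuple(int(s) for s in self.volume_shape)
        if len(self.volume_shape) != 3 or min(self.volume_shape) < 8:
            raise DomainError(f"volume_shape must be a triple with dims >= 8; got {self.volume_shape}")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be >= 0")
        if self.subject_sd < 0:
            raise DomainError("subject_sd must be >= 0")
        for fa in self.base_fa.values():
            if not 0.0 <= fa < 1.0:
                raise DomainError("base FA targets must lie in [0, 1)")

    @property
    def n_group_a(self) -> int:
        return int(np.floor(self.n_subjects * self.group_fraction))


@dataclass
class LabelVolume:
    labels: np.ndarray  # int grid, 0 = background
    roi_table: dict  # roi_id -> {"name": str, "tissue": "gray"|"white"}
    voxel_size: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int32)
        present = set(np.unique(self.labels)) - {0}
        table = set(self.roi_table)
        if present - table:
            raise DomainError(f"labels contain ids absent from roi_table: {sorted(present - table)}")
        if table - present:
            raise DomainError(f"roi_table ids absent from labels: {sorted(table - present)}")

    @property
    def roi_ids(self):
        return sorted(self.roi_table)

    def mask(self) -> np.ndarray:
        return self.labels > 0

    def tissue_masks(self) -> dict:
        out = {"gray": np.zeros(self.labels.shape, bool), "white": np.zeros(self.labels.shape, bool)}
        for rid, info in self.roi_table.items():
            out[info["tissue"]] |= self.labels == rid
        return out


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    scalar_volume_path: str | None = None
    # generation parameters, filled by effect injection
    fa_roi_shift: dict = field(default_factory=dict)  # roi_id -> FA delta
    smooth_sigma: float = 0.0  # whole-mask extra smoothing width
    smooth_roi_sigma: dict = field(default_factory=dict)  # roi_id -> extra width

    def __post_init__(self):
        if self.group not in GROUPS:
            raise DomainError(f"group must be one of {GROUPS}; got {self.group!r}")


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed derived by hashing (seed, stage)."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "little") % (2**63)


# -- atlas -----------------------------------------------------------------

def brain_mask(shape) -> np.ndarray:
    """Central ellipsoid occupying ~60% of each dimension."""
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    r2 = sum(((g - (s - 1) / 2.0) / (0.3 * s)) ** 2 for g, s in zip(grids, shape))
    return r2 <= 1.0


def generate_atlas(shape, n_gray: int, n_white: int, seed: int) -> LabelVolume:
    """Seeded region growth inside an ellipsoidal mask.

    White-matter ROIs tile an inner core ellipsoid, gray-matter ROIs the
    surrounding shell; each ROI is grown from a single random seed voxel
    by 6-connected dilation, so every ROI is nonempty and connected.
    """
    shape = tuple(int(s) for s in shape)
    if n_gray < 1 or n_white < 0:
        raise DomainError("need n_gray >= 1 and n_white >= 0")
    mask = brain_mask(shape)
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    r2_core = sum(((g - (s - 1) / 2.0) / (0.18 * s)) ** 2 for g, s in zip(grids, shape))
    core = (r2_core <= 1.0) & mask
    shell = mask & ~core
    if n_white > int(core.sum()) or n_gray > int(shell.sum()):
        raise DomainError(
            f"shape {shape} too small for {n_gray} gray + {n_white} white ROIs "
            f"(shell {int(shell.sum())}, core {int(core.sum())} voxels)"
        )
    rng = np.random.default_rng(seed)
    labels = np.zeros(shape, np.int32)
    roi_table = {}
    next_id = 1
    for tissue, region, count in (("gray", shell, n_gray), ("white", core, n_white)):
        if count == 0:
            continue
        coords = np.argwhere(region)
        picks = coords[rng.choice(len(coords), size=count, replace=False)]
        ids = list(range(next_id, next_id + count))
        for rid, (i, j, k) in zip(ids, picks):
            labels[i, j, k] = rid
            roi_table[rid] = {"name": f"{tissue}_{rid:03d}", "tissue": tissue}
        _grow(labels, region, ids, rng)
        next_id += count
    return LabelVolume(labels, roi_table)


def _grow(labels, region, ids, rng):
    """Round-robin 6-connected dilation of each label into free region voxels."""
    struct = ndimage.generate_binary_structure(3, 1)
    free = region & (labels == 0)
    while free.any():
        progress = False
        order = rng.permutation(ids)
        for rid in order:
            frontier = ndimage.binary_dilation(labels == rid, structure=struct) & free
            if frontier.any():
                labels[frontier] = rid
                free &= ~frontier
                progress = True
        if not progress:
            # disconnected free pockets: assign to nearest label by EDT
            idx = ndimage.distance_transform_edt(
                labels == 0, return_distances=False, return_indices=True
            )
            labels[free] = labels[tuple(c[free] for c in idx)]
            break


# -- tensors ---------------------------------------------------------------

def _anisotropy_factor(fa):
    """f such that (l1, l2, l3) = lbar(1+2f, 1-f, 1-f) has the given FA."""
    fa = np.asarray(fa, dtype=np.float64)
    return fa * np.sqrt(3.0 / (9.0 - 6.0 * np.clip(fa, 0, 1) ** 2))


def _random_rotations(rng, n):
    """Uniform random rotation matrices via normalized quaternions."""
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    R = np.empty((n, 3, 3))
    R[:, 0, 0] = 1 - 2 * (y * y + z * z)
    R[:, 0, 1] = 2 * (x * y - w * z)
    R[:, 0, 2] = 2 * (x * z + w * y)
    R[:, 1, 0] = 2 * (x * y + w * z)
    R[:, 1, 1] = 1 - 2 * (x * x + z * z)
    R[:, 1, 2] = 2 * (y * z - w * x)
    R[:, 2, 0] = 2 * (x * z - w * y)
    R[:, 2, 1] = 2 * (y * z + w * x)
    R[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return R


def generate_tensor_field(
    shape,
    labels: LabelVolume,
    base_fa_by_tissue: dict,
    noise_sd: float,
    seed: int,
    fa_offset: np.ndarray | None = None,
    mean_diffusivity: float = 0.8,
) -> sc.TensorField:
    """Axially symmetric tensors hitting per-voxel FA targets before noise.

    ``fa_offset`` is an optional per-voxel additive FA adjustment
    (subject deviations and injected shifts).  Eigenvalue noise is added
    after construction and clipped to nonnegative, so tensors remain PSD.
    """
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    shape = tuple(int(s) for s in shape)
    if labels.labels.shape != shape:
        raise DomainError("atlas shape does not match requested shape")
    for fa in base_fa_by_tissue.values():
        if not 0.0 <= fa < 1.0:
            raise DomainError("base FA targets must lie in [0, 1)")
    fa_target = np.zeros(shape)
    for tissue, m in labels.tissue_masks().items():
        fa_target[m] = base_fa_by_tissue.get(tissue, 0.0)
    mask = labels.mask()
    if fa_offset is not None:
        fa_target = np.where(mask, fa_target + fa_offset, 0.0)
    fa_target = np.clip(fa_target, 0.0, 0.95)

    rng = np.random.default_rng(seed)
    flat_mask = mask.reshape(-1)
    n_fg = int(flat_mask.sum())
    f = _anisotropy_factor(fa_target.reshape(-1)[flat_mask])
    lbar = mean_diffusivity
    lams = np.empty((n_fg, 3))
    lams[:, 0] = lbar * (1 + 2 * f)
    lams[:, 1] = lams[:, 2] = lbar * (1 - f)
    if noise_sd > 0:
        lams = np.clip(lams + rng.normal(0.0, noise_sd, size=lams.shape), 0.0, None)
    R = _random_rotations(rng, n_fg)
    t_fg = np.einsum("nij,nj,nkj->nik", R, lams, R)
    tensors = np.zeros((*shape, 3, 3))
    tensors.reshape(-1, 3, 3)[flat_mask] = t_fg
    return sc.TensorField(tensors)


# -- effects ---------------------------------------------------------------

def inject_group_effect(
    records: list, effect: GroupEffect, atlas: LabelVolume, spec: CohortSpec
) -> list:
    """Return records with generation parameters carrying the effect.

    The cohort volumes themselves are (re)rendered by
    :func:`generate_cohort`; this operation only sets per-subject FA
    shifts and smoothing widths.
    """
    missing = effect.target_roi_ids - set(atlas.roi_table)
    if missing:
        raise DomainError(f"effect ROIs absent from atlas: {sorted(missing)}")
    out = []
    for rec in records:
        rec = replace(rec)
        sign = +0.5 if rec.group == "A" else -0.5
        if effect.kind == "mean_shift":
            delta = effect.direction * sign * effect.magnitude * spec.subject_sd
            shifts = dict(rec.fa_roi_shift)
            for rid in effect.target_roi_ids:
                shifts[rid] = shifts.get(rid, 0.0) + delta
            rec.fa_roi_shift = shifts
        elif effect.kind == "texture_complexity":
            # the lower-entropy group gets the wider kernel
            smoothed_group = "B" if effect.direction == +1 else "A"
            if rec.group == smoothed_group:
                if effect.target_roi_ids:
                    sig = dict(rec.smooth_roi_sigma)
                    for rid in effect.target_roi_ids:
                        sig[rid] = max(sig.get(rid, 0.0), effect.magnitude)
                    rec.smooth_roi_sigma = sig
                else:
                    rec.smooth_sigma = max(rec.smooth_sigma, effect.magnitude)
        out.append(rec)
    return out


def _smooth_in_mask(values: np.ndarray, mask: np.ndarray, sigma: float) -> np.ndarray:
    """Mask-normalized Gaussian smoothing: no attenuation at the mask edge,
    so smoothing changes texture, not regional means."""
    if sigma <= 0:
        return values
    num = ndimage.gaussian_filter(np.where(mask, values, 0.0), sigma=sigma)
    den = ndimage.gaussian_filter(mask.astype(np.float64), sigma=sigma)
    with np.errstate(divide="ignore", invalid="ignore"):
        sm = num / den
    return np.where(mask, sm, values)


# -- cohort ----------------------------------------------------------------

def render_subject(rec: SubjectRecord, atlas: LabelVolume, spec: CohortSpec, subject_seed: int) -> dict:
    """All four scalar volumes for one subject, effects applied."""
    rng = np.random.default_rng(subject_seed)
    subject_dev = rng.normal(0.0, spec.subject_sd)
    fa_offset = np.full(spec.volume_shape, subject_dev)
    for rid, delta in rec.fa_roi_shift.items():
        fa_offset[atlas.labels == rid] += delta
    fld = generate_tensor_field(
        spec.volume_shape,
        atlas,
        spec.base_fa,
        spec.noise_sd,
        seed=int(rng.integers(2**63)),
        fa_offset=fa_offset,
        mean_diffusivity=spec.mean_diffusivity,
    )
    maps = sc.scalar_maps_from_field(fld)
    sigma = spec.texture_base_sigma + rec.smooth_sigma
    tissue_masks = atlas.tissue_masks()
    for vol in maps.values():
        if sigma > 0:
            # smooth each tissue class separately to avoid cross-tissue
            # mean blending at interfaces
            for m in tissue_masks.values():
                vol.values = _smooth_in_mask(vol.values, m, sigma)
        for rid, extra in rec.smooth_roi_sigma.items():
            vol.values = _smooth_in_mask(vol.values, atlas.labels == rid, extra)
    return maps


def make_records(spec: CohortSpec) -> list:
    """Subject records with groups split by the floor rounding rule."""
    n_a = spec.n_group_a
    recs = [
        SubjectRecord(subject_id=f"s{i + 1:04d}", group="A" if i < n_a else "B")
        for i in range(spec.n_subjects)
    ]
    return recs


def generate_cohort(spec: CohortSpec, output_dir) -> tuple:
    """Write per-subject scalar maps, the atlas and a manifest.

    Returns ``(records, atlas, manifest_path)``.  Fully deterministic in
    ``(spec, spec.seed)``.
    """
    from pathlib import Path

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas = generate_atlas(
        spec.volume_shape, spec.n_gray_rois, spec.n_white_rois, derive_seed(spec.seed, "atlas")
    )
    records = make_records(spec)
    for effect in spec.effects:
        records = inject_group_effect(records, effect, atlas, spec)

    nib.save(
        nib.Nifti1Image(atlas.labels.astype(np.int16), np.eye(4)), str(out / "atlas.nii.gz")
    )
    manifest_path = out / "manifest.tsv"
    lines = ["subject_id\tgroup\tpath"]
    for i, rec in enumerate(records):
        maps = render_subject(rec, atlas, spec, derive_seed(spec.seed, f"subject:{rec.subject_id}"))
        for kind, vol in maps.items():
            sc.save_scalar_volume(vol, out / f"{rec.subject_id}_{kind.lower()}.nii.gz")
        rec.scalar_volume_path = str(out / f"{rec.subject_id}_fa.nii.gz")
        lines.append(f"{rec.subject_id}\t{rec.group}\t{rec.scalar_volume_path}")
    manifest_path.write_text("\n".join(lines) + "\n")
    return records, atlas, manifest_path


def render_cohort_volumes(spec: CohortSpec) -> tuple:
    """In-memory variant of :func:`generate_cohort` (no file I/O).

    Returns ``(fa_volumes, groups, atlas)`` with FA volumes stacked as a
    float32 array (n, d, w, h).
    """
    atlas = generate_atlas(
        spec.volume_shape, spec.n_gray_rois, spec.n_white_rois, derive_seed(spec.seed, "atlas")
    )
    records = make_records(spec)
    for effect in spec.effects:
        records = inject_group_effect(records, effect, atlas, spec)
    vols = np.empty((spec.n_subjects, *spec.volume_shape), np.float32)
    for i, rec in enumerate(records):
        maps = render_subject(rec, atlas, spec, derive_seed(spec.seed, f"subject:{rec.subject_id}"))
        vols[i] = maps["FA"].values.astype(np.float32)
    groups = [r.group for r in records]
    return vols, groups, atlas
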