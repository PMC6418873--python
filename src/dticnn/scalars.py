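"""Tensor-derived scalar maps: FA, MD, AD and RD.

A diffusion tensor is a symmetric positive-semidefinite 3x3 matrix per
voxel.  With eigenvalues sorted descending (l1 >= l2 >= l3):

    FA = sqrt(3/2) * ||l - mean(l)|| / ||l||
    MD = (l1 + l2 + l3) / 3
    AD = l1
    RD = (l2 + l3) / 2

Background voxels (all-zero tensors) map to 0 in all four volumes so
they cannot poison downstream training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .errors import DomainError

SCALAR_KINDS = ("FA", "MD", "AD", "RD")

#: relative eigenvalue tolerance: values below -EIG_TOL * l_max are errors,
#: values within are clipped to zero (numerical eigensolver slop)
EIG_TOL = 1e-9

_SYM_TOL = 1e-9


@dataclass
class TensorField:
    """Per-voxel symmetric 3x3 diffusion tensors on a 3D grid."""

    tensors: np.ndarray  # (d, w, h, 3, 3)
    voxel_size: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        t = np.asarray(self.tensors, dtype=np.float64)
        if t.ndim != 5 or t.shape[3:] != (3, 3):
            raise DomainError(f"tensor grid must have shape (d, w, h, 3, 3); got {t.shape}")
        self.tensors = t

    @property
    def shape(self):
        return self.tensors.shape[:3]

    def validate_symmetry(self):
        asym = np.abs(self.tensors - self.tensors.transpose(0, 1, 2, 4, 3)).max()
        scale = max(1.0, float(np.abs(self.tensors).max()))
        if asym > _SYM_TOL * scale:
            raise DomainError(f"tensor field asymmetric: max |T - T^t| = {asym:.3e}")


@dataclass
class ScalarVolume:
    """A 3D grid of one tensor-derived scalar."""

    values: np.ndarray
    kind: str
    voxel_size: tuple = (1.0, 1.0, 1.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in SCALAR_KINDS:
            raise DomainError(f"kind must be one of {SCALAR_KINDS}; got {self.kind!r}")
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 3:
            raise DomainError(f"scalar grid must be 3D; got shape {v.shape}")
        self.values = v

    @property
    def shape(self):
        return self.values.shape


def eigendecompose_voxel(tensor: np.ndarray) -> np.ndarray:
    """Descending-sorted real eigenvalues of one symmetric 3x3 tensor."""
    t = np.asarray(tensor, dtype=np.float64)
    if t.shape != (3, 3):
        raise DomainError(f"expected a 3x3 matrix, got shape {t.shape}")
    scale = max(1.0, float(np.abs(t).max()))
    if np.abs(t - t.T).max() > _SYM_TOL * scale:
        raise DomainError("matrix is asymmetric beyond tolerance")
    return np.linalg.eigvalsh(t)[::-1]


def fa_from_eigenvalues(lams) -> float:
    """Fractional anisotropy in [0, 1]; all-zero eigenvalues map to 0."""
    lams = np.asarray(lams, dtype=np.float64)
    if lams.shape != (3,):
        raise DomainError("expected an eigenvalue triple")
    lmax = max(float(lams.max()), 0.0)
    if (lams < -EIG_TOL * max(lmax, 1.0)).any():
        raise DomainError(f"negative eigenvalues beyond tolerance: {lams}")
    lams = np.clip(lams, 0.0, None)
    norm2 = float((lams**2).sum())
    if norm2 == 0.0:
        return 0.0
    dev = lams - lams.mean()
    return float(min(1.0, np.sqrt(1.5 * float((dev**2).sum()) / norm2)))


def md_ad_rd_from_eigenvalues(lams):
    """(MD, AD, RD) from a descending-sorted eigenvalue triple."""
    lams = np.asarray(lams, dtype=np.float64)
    if lams.shape != (3,):
        raise DomainError("expected an eigenvalue triple")
    if not (lams[0] >= lams[1] >= lams[2]):
        raise DomainError(f"eigenvalues must be sorted descending; got {lams}")
    md = float(lams.mean())
    ad = float(lams[0])
    rd = float((lams[1] + lams[2]) / 2.0)
    return md, ad, rd


def scalar_maps_from_field(fld: TensorField) -> dict:
    """All four scalar volumes from a tensor field, vectorized over voxels.

    Raises with voxel coordinates if any voxel has eigenvalues below the
    PSD tolerance.
    """
    fld.validate_symmetry()
    t = fld.tensors
    lams = np.linalg.eigvalsh(t)[..., ::-1]  # descending (d, w, h, 3)
    lmax = lams[..., 0]
    bad = lams[..., 2] < -EIG_TOL * np.maximum(np.abs(lmax), 1.0)
    if bad.any():
        coord = tuple(int(c) for c in np.argwhere(bad)[0])
        raise DomainError(f"non-PSD tensor at voxel {coord}: eigenvalues {lams[coord]}")
    lams = np.clip(lams, 0.0, None)
    norm2 = (lams**2).sum(axis=-1)
    dev2 = ((lams - lams.mean(axis=-1, keepdims=True)) ** 2).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.sqrt(1.5 * dev2 / norm2)
    fa = np.where(norm2 > 0, np.clip(fa, 0.0, 1.0), 0.0)
    md = lams.mean(axis=-1)
    ad = lams[..., 0]
    rd = lams[..., 1:].mean(axis=-1)
    vs = fld.voxel_size
    return {
        "FA": ScalarVolume(fa, "FA", vs),
        "MD": ScalarVolume(md, "MD", vs),
        "AD": ScalarVolume(ad, "AD", vs),
        "RD": ScalarVolume(rd, "RD", vs),
    }


# -- NIfTI I/O -------------------------------------------------------------

_UPPER = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]  # Dxx Dxy Dxz Dyy Dyz Dzz


def _affine(voxel_size):
    return np.diag([*voxel_size, 1.0])


def save_scalar_volume(vol: ScalarVolume, path):
    nib.save(nib.Nifti1Image(vol.values.astype(np.float32), _affine(vol.voxel_size)), str(path))


def save_tensor_field(fld: TensorField, path):
    """Upper-triangle 6-component 4D NIfTI (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz)."""
    comps = np.stack([fld.tensors[..., i, j] for i, j in _UPPER], axis=-1)
    nib.save(nib.Nifti1Image(comps.astype(np.float32), _affine(fld.voxel_size)), str(path))


def load_tensor_field(path) -> TensorField:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4 or data.shape[3] != 6:
        raise DomainError(f"tensor NIfTI must be 4D with 6 components; got {data.shape}")
    t = np.zeros((*data.shape[:3], 3, 3))
    for k, (i, j) in enumerate(_UPPER):
        t[..., i, j] = data[..., k]
        t[..., j, i] = data[..., k]
    vs = tuple(float(z) for z in img.header.get_zooms()[:3])
    return TensorField(t, vs)
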