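"""Diffusion tensor fit and scalar metrics: FA, MD, and PSMD.

The tensor is estimated by weighted log-linear least squares (weights are the
squared observed signals, the standard first-order variance stabilization for
log-transformed Rician data). FA and MD come from the eigenvalues; PSMD is
the 95th-minus-5th percentile of MD over a white-matter skeleton mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gradients import GradientScheme
from .volume import DWIVolume

__all__ = [
    "TensorField",
    "fit_tensor",
    "fa_from_eigenvalues",
    "fa_map",
    "md_map",
    "skeleton_summary",
    "psmd",
]

#: tensor element order in design matrix and storage
TENSOR_ELEMENTS = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")

MIN_PSMD_VOXELS = 20


@dataclass
class TensorField:
    """Per-voxel symmetric tensors with eigendecomposition.

    ``tensors`` holds the 6 unique elements (mm^2/s) in TENSOR_ELEMENTS order;
    ``eigenvalues`` are sorted descending. Voxels with any negative eigenvalue
    keep their values but are flagged invalid — not silently clamped.
    """

    tensors: np.ndarray          # (X, Y, Z, 6)
    eigenvalues: np.ndarray      # (X, Y, Z, 3), descending
    eigenvectors: np.ndarray     # (X, Y, Z, 3, 3), columns match eigenvalues
    mask: np.ndarray
    valid: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))


def _design_matrix(scheme: GradientScheme) -> np.ndarray:
    b = scheme.bvals
    g = scheme.bvecs
    return np.column_stack([
        np.ones_like(b),
        -b * g[:, 0] ** 2,
        -b * g[:, 1] ** 2,
        -b * g[:, 2] ** 2,
        -2 * b * g[:, 0] * g[:, 1],
        -2 * b * g[:, 0] * g[:, 2],
        -2 * b * g[:, 1] * g[:, 2],
    ])


def fit_tensor(dwi: DWIVolume, mask: np.ndarray | None = None) -> TensorField:
    """Weighted log-linear LS tensor fit inside the mask.

    Voxels with any non-positive signal are flagged invalid and skipped.
    Requires at least 6 non-collinear directions plus a b0 (rank check on the
    design matrix).
    """
    scheme = dwi.scheme
    X = _design_matrix(scheme)
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError("rank-deficient gradient design: need >= 6 non-collinear directions and a b0")
    if mask is None:
        mask = dwi.mask
    shape = dwi.shape
    flat = dwi.data.reshape(-1, scheme.n_volumes)
    vox = np.flatnonzero(mask.ravel())
    sig = flat[vox]
    positive = np.all(sig > 0, axis=1)
    sig = sig[positive]
    vox = vox[positive]

    y = np.log(sig)
    w = sig ** 2
    # batched (X' W X) beta = X' W y
    xtwx = np.einsum("ni,vn,nj->vij", X, w, X, optimize=True)
    xtwy = np.einsum("ni,vn,vn->vi", X, w, y, optimize=True)
    beta = np.linalg.solve(xtwx, xtwy[..., None])[..., 0]

    d6 = beta[:, 1:]
    dmat = np.empty((d6.shape[0], 3, 3))
    dmat[:, 0, 0] = d6[:, 0]
    dmat[:, 1, 1] = d6[:, 1]
    dmat[:, 2, 2] = d6[:, 2]
    dmat[:, 0, 1] = dmat[:, 1, 0] = d6[:, 3]
    dmat[:, 0, 2] = dmat[:, 2, 0] = d6[:, 4]
    dmat[:, 1, 2] = dmat[:, 2, 1] = d6[:, 5]
    evals, evecs = np.linalg.eigh(dmat)   # ascending
    evals = evals[:, ::-1]
    evecs = evecs[:, :, ::-1]

    tensors = np.zeros(shape + (6,))
    eigenvalues = np.zeros(shape + (3,))
    eigenvectors = np.zeros(shape + (3, 3))
    valid = np.zeros(shape, dtype=bool)
    tensors.reshape(-1, 6)[vox] = d6
    eigenvalues.reshape(-1, 3)[vox] = evals
    eigenvectors.reshape(-1, 3, 3)[vox] = evecs
    valid.reshape(-1)[vox] = np.all(evals >= 0, axis=1)
    out_mask = np.zeros(shape, dtype=bool)
    out_mask.reshape(-1)[vox] = True
    return TensorField(tensors, eigenvalues, eigenvectors, out_mask, valid, dwi.affine)


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """Closed-form FA = sqrt(3/2) * ||lambda - mean|| / ||lambda||."""
    evals = np.asarray(evals, dtype=float)
    mean = evals.mean(axis=-1, keepdims=True)
    num = np.sum((evals - mean) ** 2, axis=-1)
    den = np.sum(evals ** 2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    return np.where(den > 0, fa, 0.0)


def fa_map(tensors: TensorField) -> np.ndarray:
    """FA per voxel; NaN where the fit is missing or invalid."""
    fa = fa_from_eigenvalues(tensors.eigenvalues)
    fa = np.clip(fa, 0.0, 1.0)
    return np.where(tensors.mask & tensors.valid, fa, np.nan)


def md_map(tensors: TensorField) -> np.ndarray:
    """MD = (l1 + l2 + l3)/3 per voxel; NaN where missing or invalid."""
    md = tensors.eigenvalues.mean(axis=-1)
    return np.where(tensors.mask & tensors.valid, md, np.nan)


def skeleton_summary(scalar_map: np.ndarray, skeleton_mask: np.ndarray) -> float:
    """Mean of a scalar map over the valid (non-NaN) skeleton voxels."""
    skeleton_mask = np.asarray(skeleton_mask, dtype=bool)
    if not skeleton_mask.any():
        raise ValueError("skeleton mask is empty")
    vals = np.asarray(scalar_map)[skeleton_mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no valid voxels inside the skeleton")
    return float(vals.mean())


def psmd(md: np.ndarray, skeleton_mask: np.ndarray, min_voxels: int = MIN_PSMD_VOXELS) -> float:
    """Peak width of skeletonized MD: p95 - p5 over the skeleton.

    Percentiles use linear interpolation between order statistics
    (numpy's default), pinned here because PSMD is sensitive to the rule.
    """
    skeleton_mask = np.asarray(skeleton_mask, dtype=bool)
    vals = np.asarray(md)[skeleton_mask]
    vals = vals[np.isfinite(vals)]
    if vals.size < min_voxels:
        raise ValueError(f"PSMD needs >= {min_voxels} valid skeleton voxels, have {vals.size}")
    p5, p95 = np.percentile(vals, [5.0, 95.0], method="linear")
    return float(p95 - p5)
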