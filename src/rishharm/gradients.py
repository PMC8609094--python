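"""Gradient tables: b-values, unit direction vectors, and FSL-style I/O.

A :class:`GradientScheme` describes the acquisition geometry of a single-shell
diffusion-weighted series: one b-value and one gradient direction per volume,
with b ~ 0 volumes identified by a configurable threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "GradientScheme",
    "read_bval_bvec",
    "write_bval_bvec",
    "fibonacci_directions",
    "rotate_scheme",
]

#: b-values below this (s/mm^2) count as non-diffusion-weighted by default.
DEFAULT_B0_THRESHOLD = 50.0

#: relative spread tolerated among the non-b0 b-values of a single shell.
SHELL_TOLERANCE = 0.05


@dataclass(frozen=True)
class GradientScheme:
    """Per-volume b-values (s/mm^2) and unit gradient directions.

    Parameters
    ----------
    bvals : (N,) array
        Diffusion weighting per volume.
    bvecs : (N, 3) array
        Gradient directions; rows for non-b0 volumes must be unit vectors.
    b0_threshold : float
        Volumes with ``bval < b0_threshold`` are treated as b0.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    b0_threshold: float = DEFAULT_B0_THRESHOLD

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise ValueError(f"bvecs must be (N, 3); got {bvecs.shape}")
        if bvals.shape[0] != bvecs.shape[0]:
            raise ValueError("bvals and bvecs describe different numbers of volumes")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        if not np.any(self.b0_mask):
            raise ValueError("scheme contains no b0 volume")
        dw = bvecs[~self.b0_mask]
        norms = np.linalg.norm(dw, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("non-b0 gradient directions must be unit vectors (|norm-1| <= 1e-6)")
        b_dw = bvals[~self.b0_mask]
        if b_dw.size and (b_dw.max() - b_dw.min()) > SHELL_TOLERANCE * b_dw.mean():
            raise ValueError(
                "multi-shell scheme not supported: non-b0 b-values spread "
                f"{b_dw.min():.1f}..{b_dw.max():.1f} s/mm^2"
            )

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals < self.b0_threshold

    @property
    def b0_indices(self) -> np.ndarray:
        return np.flatnonzero(self.b0_mask)

    @property
    def dwi_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.b0_mask)

    @property
    def n_volumes(self) -> int:
        return int(self.bvals.shape[0])

    @property
    def n_directions(self) -> int:
        return int(np.count_nonzero(~self.b0_mask))

    @property
    def shell_bvalue(self) -> float:
        """Mean b-value of the diffusion-weighted volumes."""
        return float(self.bvals[~self.b0_mask].mean())

    @property
    def directions(self) -> np.ndarray:
        """Unit directions of the diffusion-weighted volumes, (n_directions, 3)."""
        return self.bvecs[~self.b0_mask]

    def with_bvalue(self, b_new: float) -> "GradientScheme":
        """Return a copy with every non-b0 b-value replaced by ``b_new``."""
        bvals = self.bvals.copy()
        bvals[~self.b0_mask] = float(b_new)
        return GradientScheme(bvals, self.bvecs.copy(), self.b0_threshold)


def read_bval_bvec(bval_path: str | Path, bvec_path: str | Path,
                   b0_threshold: float = DEFAULT_B0_THRESHOLD) -> GradientScheme:
    """Read FSL-style whitespace-separated .bval (1 row) / .bvec (3 rows)."""
    bvals = np.loadtxt(bval_path, ndmin=1).ravel()
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        # ambiguous 3x3: FSL convention is rows = x/y/z components
        bvecs = bvecs.T
    # renormalize almost-unit rows (text round-off)
    norms = np.linalg.norm(bvecs, axis=1)
    dw = bvals >= b0_threshold
    fix = dw & (norms > 0) & (np.abs(norms - 1.0) < 1e-3)
    bvecs[fix] /= norms[fix, None]
    return GradientScheme(bvals, bvecs, b0_threshold)


def write_bval_bvec(scheme: GradientScheme, bval_path: str | Path, bvec_path: str | Path) -> None:
    """Write FSL-style .bval/.bvec text files."""
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%.1f")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.8f")


def fibonacci_directions(n: int) -> np.ndarray:
    """``n`` roughly uniform unit vectors on the sphere (golden-angle spiral).

    Deterministic; adequate for gradient-scheme emulation and quadrature checks.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def rotate_scheme(scheme: GradientScheme, rotation: np.ndarray) -> GradientScheme:
    """Apply a 3x3 rotation matrix to every gradient direction."""
    R = np.asarray(rotation, dtype=float)
    if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
        raise ValueError("rotation must be a 3x3 orthogonal matrix")
    return GradientScheme(scheme.bvals.copy(), scheme.bvecs @ R.T, scheme.b0_threshold)
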