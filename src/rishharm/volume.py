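"""In-memory containers for diffusion-weighted volumes and NIfTI I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .gradients import GradientScheme, read_bval_bvec, write_bval_bvec

__all__ = ["DWIVolume", "load_dwi", "save_dwi", "load_mask", "save_map"]


@dataclass
class DWIVolume:
    """A 4-D diffusion-weighted series with its brain mask and gradient scheme.

    ``data`` has shape (X, Y, Z, N) with one 3-D volume per scheme entry.
    ``affine`` is the voxel-to-world matrix; all subjects of a synthetic study
    share one grid, so harmonization never resamples.
    """

    data: np.ndarray
    scheme: GradientScheme
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4-D; got shape {self.data.shape}")
        if self.data.shape[3] != self.scheme.n_volumes:
            raise ValueError(
                f"data has {self.data.shape[3]} volumes, scheme {self.scheme.n_volumes}"
            )
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask grid does not match data grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def mean_b0(self) -> np.ndarray:
        """Voxelwise average of the b0 volumes."""
        return self.data[..., self.scheme.b0_mask].mean(axis=3)

    def dw_data(self) -> np.ndarray:
        """The diffusion-weighted volumes only, (X, Y, Z, n_directions)."""
        return self.data[..., ~self.scheme.b0_mask]


def load_dwi(nifti_path: str | Path, bval_path: str | Path, bvec_path: str | Path,
             mask_path: str | Path | None = None) -> DWIVolume:
    img = nib.load(str(nifti_path))
    data = np.asarray(img.get_fdata(), dtype=float)
    scheme = read_bval_bvec(bval_path, bvec_path)
    if mask_path is not None:
        mask = load_mask(mask_path)
    else:
        mask = np.ones(data.shape[:3], dtype=bool)
    return DWIVolume(data, scheme, mask, np.asarray(img.affine))


def save_dwi(dwi: DWIVolume, nifti_path: str | Path, bval_path: str | Path,
             bvec_path: str | Path) -> None:
    nib.save(nib.Nifti1Image(dwi.data.astype(np.float32), dwi.affine), str(nifti_path))
    write_bval_bvec(dwi.scheme, bval_path, bvec_path)


def load_mask(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata()) > 0.5


def save_map(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))
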