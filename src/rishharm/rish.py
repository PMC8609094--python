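"""Rotation-invariant SH (RISH) features and inter-site scale maps.

The order-l RISH feature E_l = sum_m c_lm^2 is the signal energy at angular
frequency l; it is invariant to rotations of the gradient frame. Site effects
that multiply the per-order energy can therefore be learned from matched
control groups as voxelwise scale maps

    Delta_l(v) = sqrt( (E_ref,l(v) + eps) / (E_target,l(v) + eps) )

and removed by scaling every order-l coefficient of a target-site subject by
Delta_l(v): the harmonized energy is exactly Delta_l^2 E_l. The mapping is
linear in the SH domain but nonlinear in the signal domain.

Hard precondition: all subjects and the scale maps share one voxel grid; no
registration is performed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .sh import SHCoefficientField, fit_sh, reconstruct_signal, DEFAULT_REG_LAMBDA
from .volume import DWIVolume

__all__ = [
    "RISHFeatureMap",
    "ScaleMapSet",
    "compute_rish",
    "group_mean_rish",
    "learn_scale_maps",
    "apply_scale_maps",
    "harmonize_subject",
    "MIN_TRAINING_CONTROLS",
]

#: below this many training controls, group-mean RISH features may capture
#: individual anatomy instead of site properties.
MIN_TRAINING_CONTROLS = 15

DEFAULT_EPS = 1e-8
DEFAULT_CLIP = (0.1, 10.0)
DEFAULT_SMOOTHING_FWHM = 4.0  # mm

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class RISHFeatureMap:
    """Per-order energy maps, shape (X, Y, Z, n_orders) for orders 0,2,..,L.

    ``noise_energy``, when present, is the expected contribution of
    coefficient noise to each order's energy (same shape as ``data``): the
    measured energy is E[signal energy] + noise energy, so subtracting it
    gives an approximately unbiased estimate of the signal energy.
    """

    data: np.ndarray
    l_max: int
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    noise_energy: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.shape[3] != self.l_max // 2 + 1:
            raise ValueError("order count does not match l_max")

    @property
    def orders(self) -> list[int]:
        return list(range(0, self.l_max + 1, 2))


@dataclass
class ScaleMapSet:
    """Voxelwise per-order scale maps Delta_l with provenance metadata.

    Delta_l is 1 outside the mask, so application is the identity there.
    """

    data: np.ndarray                        # (X, Y, Z, n_orders)
    l_max: int
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.shape[3] != self.l_max // 2 + 1:
            raise ValueError("order count does not match l_max")
        inside = self.data[self.mask]
        if inside.size and (not np.all(np.isfinite(inside)) or np.any(inside <= 0)):
            raise ValueError("scale maps must be finite and > 0 inside the mask")

    @property
    def orders(self) -> list[int]:
        return list(range(0, self.l_max + 1, 2))


def compute_rish(coeffs: SHCoefficientField) -> RISHFeatureMap:
    """E_l(v) = sum_m c_lm(v)^2 for each even order."""
    orders = coeffs.orders
    out = np.empty(coeffs.data.shape[:3] + (len(orders),), dtype=float)
    for i, l in enumerate(orders):
        block = coeffs.data[..., coeffs.order_slice(l)]
        out[..., i] = np.sum(block * block, axis=3)
    noise = None
    if coeffs.sigma2 is not None and coeffs.noise_trace is not None:
        noise = coeffs.sigma2[..., None] * coeffs.noise_trace[None, None, None, :]
    return RISHFeatureMap(out, coeffs.l_max, coeffs.mask, coeffs.affine, noise)


def _masked_smooth(data: np.ndarray, mask: np.ndarray, sigma_vox: float) -> np.ndarray:
    """Gaussian smoothing renormalized so the mask boundary does not bleed."""
    m = mask.astype(float)
    num = gaussian_filter(data * m, sigma_vox)
    den = gaussian_filter(m, sigma_vox)
    out = np.zeros_like(data)
    np.divide(num, den, out=out, where=den > 1e-8)
    return np.where(mask, out, 0.0)


def group_mean_rish(maps: list[RISHFeatureMap], smoothing_fwhm: float = DEFAULT_SMOOTHING_FWHM,
                    voxel_size: float = 2.0) -> RISHFeatureMap:
    """Expected per-order energies: the voxelwise sample mean over subjects.

    Optionally Gaussian-smoothed inside the common mask (FWHM in mm) so the
    mean captures group-level site properties rather than residual
    single-subject anatomy.
    """
    if not maps:
        raise ValueError("need at least one RISH map")
    first = maps[0]
    for m in maps[1:]:
        if m.data.shape != first.data.shape or m.l_max != first.l_max:
            raise ValueError("RISH maps on different grids or orders")
    if len(maps) < MIN_TRAINING_CONTROLS:
        warnings.warn(
            f"only {len(maps)} training subjects; group-mean RISH features are "
            f"recommended to use at least {MIN_TRAINING_CONTROLS}-20 controls",
            stacklevel=2,
        )
    mask = np.logical_and.reduce([m.mask for m in maps])

    def _mean(arrays):
        out = np.mean(arrays, axis=0)
        out = np.where(mask[..., None], out, 0.0)
        if smoothing_fwhm and smoothing_fwhm > 0:
            sigma = smoothing_fwhm * _FWHM_TO_SIGMA / voxel_size
            for i in range(out.shape[3]):
                out[..., i] = _masked_smooth(out[..., i], mask, sigma)
        return out

    mean = _mean([m.data for m in maps])
    noise = None
    if all(m.noise_energy is not None for m in maps):
        noise = _mean([m.noise_energy for m in maps])
    return RISHFeatureMap(mean, first.l_max, mask, first.affine, noise)


def learn_scale_maps(ref_mean: RISHFeatureMap, target_mean: RISHFeatureMap,
                     eps: float = DEFAULT_EPS,
                     clip: tuple[float, float] = DEFAULT_CLIP,
                     noise_correct: bool = True,
                     provenance: dict | None = None) -> ScaleMapSet:
    """Estimate Delta_l = sqrt((E_ref + eps) / (E_target + eps)), clipped.

    ``eps`` regularizes near-zero-energy voxels (background, CSF at high
    orders); ``clip`` bounds the ratio so noise in low-energy voxels cannot be
    amplified without limit. Assumes the two group means come from age- and
    sex-matched controls, so residual differences are scanner-related.

    With ``noise_correct`` (and noise-energy estimates attached to both
    maps), the expected coefficient-noise energy is subtracted from each
    side before the ratio. Measured per-order energy is the signal energy
    plus a noise term that grows as direction count shrinks; without the
    correction the ratio maps one site's noise energy onto the other's,
    leaving a small systematic shift in reconstructed anisotropy whenever
    the sites' direction counts differ.
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if ref_mean.data.shape != target_mean.data.shape or ref_mean.l_max != target_mean.l_max:
        raise ValueError("reference and target RISH maps on different grids or orders")
    lo, hi = clip
    if not (0 < lo < hi):
        raise ValueError("clip bounds must satisfy 0 < low < high")
    mask = ref_mean.mask & target_mean.mask
    e_ref, e_tar = ref_mean.data, target_mean.data
    corrected = (noise_correct and ref_mean.noise_energy is not None
                 and target_mean.noise_energy is not None)
    if corrected:
        e_ref = np.clip(e_ref - ref_mean.noise_energy, 0.0, None)
        e_tar = np.clip(e_tar - target_mean.noise_energy, 0.0, None)
    ratio = np.sqrt((e_ref + eps) / (e_tar + eps))
    ratio = np.clip(ratio, lo, hi)
    delta = np.where(mask[..., None], ratio, 1.0)
    prov = dict(provenance or {})
    prov.update({"eps": eps, "clip": [lo, hi], "noise_corrected": bool(corrected)})
    return ScaleMapSet(delta, ref_mean.l_max, mask, ref_mean.affine, prov)


def apply_scale_maps(coeffs: SHCoefficientField, scales: ScaleMapSet) -> SHCoefficientField:
    """Scale every order-l coefficient by Delta_l(v): c'_lm = Delta_l c_lm."""
    if scales.l_max != coeffs.l_max:
        raise ValueError("scale maps and coefficients have different maximum orders")
    if scales.data.shape[:3] != coeffs.data.shape[:3]:
        raise ValueError("scale maps and coefficients on different grids")
    out = coeffs.data.copy()
    for i, l in enumerate(coeffs.orders):
        out[..., coeffs.order_slice(l)] *= scales.data[..., i:i + 1]
    return SHCoefficientField(out, coeffs.l_max, coeffs.mask, coeffs.s0, coeffs.affine)


def harmonize_subject(dwi: DWIVolume, scales: ScaleMapSet | None, l_max: int | None = None,
                      reg_lambda: float = DEFAULT_REG_LAMBDA) -> DWIVolume:
    """Harmonize one subject: fit SH, apply scale maps, reconstruct.

    The input must already be b-value-mapped to the common shell and on the
    scale maps' grid. The signal is reconstructed at the subject's own
    gradient directions; b0 volumes pass through unchanged. With
    ``scales=None`` the subject is projected onto the band-limited SH
    representation without scaling (the identity harmonization, used to put
    reference-site scans on the same representation as harmonized ones).
    """
    coeffs = fit_sh(dwi, l_max=l_max, reg_lambda=reg_lambda)
    if scales is None:
        scaled = coeffs
    else:
        if scales.l_max != coeffs.l_max:
            raise ValueError(
                f"scale maps are order {scales.l_max} but subject fit is order {coeffs.l_max}"
            )
        scaled = apply_scale_maps(coeffs, scales)
    recon = reconstruct_signal(scaled, dwi.scheme.directions)
    data = dwi.data.copy()
    data[..., ~dwi.scheme.b0_mask] = np.where(
        coeffs.mask[..., None], recon, dwi.dw_data()
    )
    return DWIVolume(data, dwi.scheme, dwi.mask, dwi.affine)
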