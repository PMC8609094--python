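"""Map single-shell diffusion signals to a common b-value.

Under monoexponential (Gaussian) decay, S/S0 = exp(-b g'Dg), so moving from
b_source to b_target is a power law on the attenuation:

    (S/S0)_target = (S/S0)_source ** (b_target / b_source)

i.e. a linear scaling of the log-attenuation. This is exact for tensor-like
signals and well validated only for closely spaced b-values around
1000 s/mm^2, where non-Gaussian weighting is mild.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .volume import DWIVolume

__all__ = ["BValueMapSpec", "map_bvalue", "map_volume", "DEFAULT_COMMON_BVALUE"]

DEFAULT_COMMON_BVALUE = 1000.0

#: b-ratios outside this range are outside the validated regime.
VALIDATED_RATIO = (0.5, 2.0)


@dataclass(frozen=True)
class BValueMapSpec:
    """Source and target b-values (s/mm^2) plus the attenuation floor.

    The floor (default 1e-6) bounds S/S0 away from zero before the power law
    so log-domain scaling cannot produce infinities.
    """

    b_source: float
    b_target: float = DEFAULT_COMMON_BVALUE
    attenuation_floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.b_source <= 0 or self.b_target <= 0:
            raise ValueError("b-values must be > 0")
        if not (0 < self.attenuation_floor < 1):
            raise ValueError("attenuation floor must be in (0, 1)")
        ratio = self.b_target / self.b_source
        if not (VALIDATED_RATIO[0] <= ratio <= VALIDATED_RATIO[1]):
            warnings.warn(
                f"b-value ratio {ratio:.2f} outside validated range {VALIDATED_RATIO}",
                stacklevel=3,
            )

    @property
    def exponent(self) -> float:
        return self.b_target / self.b_source


def map_bvalue(signal: np.ndarray, s0: np.ndarray, spec: BValueMapSpec) -> np.ndarray:
    """Map diffusion-weighted values to the target b-value, voxelwise.

    Attenuations are clamped to [floor, 1] before exponentiation (values above
    1 arise from noise and are capped rather than rejected). Voxels with
    ``s0 <= 0`` are returned as NaN — excluded and flaggable by the caller.
    """
    signal = np.asarray(signal, dtype=float)
    s0 = np.asarray(s0, dtype=float)
    if np.any(signal < 0):
        raise ValueError("diffusion-weighted signal must be >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        atten = signal / s0
    atten = np.clip(atten, spec.attenuation_floor, 1.0)
    out = s0 * atten ** spec.exponent
    return np.where(s0 > 0, out, np.nan)


def map_volume(dwi: DWIVolume, b_target: float = DEFAULT_COMMON_BVALUE,
               attenuation_floor: float = 1e-6) -> DWIVolume:
    """Map every non-b0 volume of a single-shell series to ``b_target``.

    b0 volumes pass through untouched; the scheme's b-values are rewritten.
    Multi-shell input is rejected by the GradientScheme invariant itself.
    """
    scheme = dwi.scheme
    spec = BValueMapSpec(scheme.shell_bvalue, b_target, attenuation_floor)
    data = dwi.data.copy()
    s0 = dwi.mean_b0()
    dw = ~scheme.b0_mask
    data[..., dw] = map_bvalue(dwi.data[..., dw], s0[..., None], spec)
    data[..., dw] = np.nan_to_num(data[..., dw], nan=0.0)
    return DWIVolume(data, scheme.with_bvalue(b_target), dwi.mask, dwi.affine)
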