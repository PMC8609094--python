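"""Real symmetric spherical-harmonics representation of the diffusion signal.

The antipodally symmetric single-shell dMRI signal is expanded in the real,
even-order SH basis (modified Descoteaux-style convention). The attenuation
S/S0 — not the raw signal — is what gets expanded, so multiplicative edits in
the SH domain commute with b-value mapping and with reconstruction.

Column ordering (the single place it is defined)
------------------------------------------------
Columns are sorted by order ``l`` (even, ascending) then degree ``m`` from
``-l`` to ``+l``::

    j(l, m) = l * (l + 1) / 2 + m      for even l, -l <= m <= +l

i.e. (0,0), (2,-2), (2,-1), (2,0), (2,1), (2,2), (4,-4), ... For a complex
harmonic Y_l^m with Condon-Shortley phase, the real basis function is

    m < 0:  sqrt(2) * (-1)^m * Im(Y_l^|m|)
    m = 0:  Y_l^0  (real)
    m > 0:  sqrt(2) * (-1)^m * Re(Y_l^m)

which is orthonormal on the sphere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import sph_harm_y

from .gradients import GradientScheme
from .volume import DWIVolume

__all__ = [
    "sh_index_list",
    "n_coefficients",
    "max_order_for",
    "build_sh_basis",
    "laplace_beltrami_weights",
    "fit_sh",
    "fit_sh_signal",
    "reconstruct_signal",
    "SHCoefficientField",
]

DEFAULT_REG_LAMBDA = 0.0
DEFAULT_LMAX_CAP = 4


def sh_index_list(l_max: int) -> list[tuple[int, int]]:
    """The (l, m) pair for each basis column, in column order."""
    _check_order(l_max)
    return [(l, m) for l in range(0, l_max + 1, 2) for m in range(-l, l + 1)]


def n_coefficients(l_max: int) -> int:
    """Number of even-order basis functions up to ``l_max``: (L+1)(L+2)/2."""
    _check_order(l_max)
    return (l_max + 1) * (l_max + 2) // 2


def max_order_for(n_directions: int, cap: int = DEFAULT_LMAX_CAP) -> int:
    """Largest even order whose basis is not under-determined by ``n_directions``.

    Capped (default 4) because higher orders mostly fit noise at 30-60
    directions and the harmonization operates on orders 0, 2 and 4.
    """
    l = 0
    while l + 2 <= cap and n_coefficients(l + 2) <= n_directions:
        l += 2
    return l


def _check_order(l_max: int) -> None:
    if l_max < 0 or l_max % 2 != 0:
        raise ValueError(f"l_max must be an even integer >= 0; got {l_max}")


def build_sh_basis(directions: np.ndarray, l_max: int) -> np.ndarray:
    """Evaluate the real symmetric SH basis at unit ``directions``.

    Returns a (n_directions, n_coefficients) matrix; rows for antipodal
    directions are identical because only even orders appear.
    """
    _check_order(l_max)
    dirs = np.atleast_2d(np.asarray(directions, dtype=float))
    if dirs.ndim != 2 or dirs.shape[1] != 3 or dirs.shape[0] == 0:
        raise ValueError("directions must be a non-empty (N, 3) array")
    norms = np.linalg.norm(dirs, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("zero-norm direction in basis evaluation")
    dirs = dirs / norms[:, None]
    theta = np.arccos(np.clip(dirs[:, 2], -1.0, 1.0))  # polar angle
    phi = np.arctan2(dirs[:, 1], dirs[:, 0])           # azimuth

    cols = []
    for l, m in sh_index_list(l_max):
        y = sph_harm_y(l, abs(m), theta, phi)
        if m < 0:
            col = np.sqrt(2.0) * (-1.0) ** m * y.imag
        elif m == 0:
            col = y.real
        else:
            col = np.sqrt(2.0) * (-1.0) ** m * y.real
        cols.append(col)
    return np.column_stack(cols)


def laplace_beltrami_weights(l_max: int) -> np.ndarray:
    """Diagonal of the Laplace-Beltrami penalty: (l(l+1))^2 per column."""
    return np.array([(l * (l + 1)) ** 2 for l, _ in sh_index_list(l_max)], dtype=float)


def _fit_matrix(basis: np.ndarray, l_max: int, reg_lambda: float) -> np.ndarray:
    """(B'B + lambda*L)^-1 B' — maps signals to coefficients."""
    if reg_lambda < 0:
        raise ValueError("reg_lambda must be >= 0")
    btb = basis.T @ basis
    if reg_lambda > 0:
        btb = btb + reg_lambda * np.diag(laplace_beltrami_weights(l_max))
    return np.linalg.solve(btb, basis.T)


def fit_sh_signal(signals: np.ndarray, directions: np.ndarray, l_max: int,
                  reg_lambda: float = DEFAULT_REG_LAMBDA) -> np.ndarray:
    """Least-squares SH coefficients of per-row signals sampled at ``directions``.

    ``signals`` is (..., n_directions); returns (..., n_coefficients).
    """
    n_dir = np.atleast_2d(directions).shape[0]
    if n_coefficients(l_max) > n_dir:
        raise ValueError(
            f"l_max={l_max} needs {n_coefficients(l_max)} directions, have {n_dir}; "
            "lower l_max (see max_order_for)"
        )
    basis = build_sh_basis(directions, l_max)
    fit = _fit_matrix(basis, l_max, reg_lambda)
    return np.asarray(signals) @ fit.T


@dataclass
class SHCoefficientField:
    """Per-voxel even-order SH coefficients of the normalized signal S/S0.

    ``data`` is (X, Y, Z, n_coefficients) in the documented column order;
    values are zero outside ``mask``. ``s0`` carries the voxelwise mean b0 so
    the raw signal can be reconstructed.
    """

    data: np.ndarray
    l_max: int
    mask: np.ndarray
    s0: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    #: per-voxel residual variance of the LS fit (None if not estimable)
    sigma2: np.ndarray | None = None
    #: per-order trace of the coefficient covariance per unit sigma^2, so the
    #: expected noise energy at order l is sigma2 * noise_trace[l//2]
    noise_trace: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.shape[3] != n_coefficients(self.l_max):
            raise ValueError("coefficient count does not match l_max")
        if not np.all(np.isfinite(self.data[self.mask])):
            raise ValueError("non-finite coefficients inside mask")

    @property
    def orders(self) -> list[int]:
        return list(range(0, self.l_max + 1, 2))

    def order_slice(self, l: int) -> slice:
        """Column slice holding the 2l+1 degree-m coefficients of order ``l``."""
        start = l * (l - 1) // 2  # = n_coefficients(l - 2)
        return slice(start, start + 2 * l + 1)


def fit_sh(dwi: DWIVolume, l_max: int | None = None,
           reg_lambda: float = DEFAULT_REG_LAMBDA,
           attenuation_ceiling: float = 1.0) -> SHCoefficientField:
    """Fit per-voxel SH coefficients of the attenuation S/S0 inside the mask.

    The signal is normalized by the voxelwise mean b0; attenuations above
    ``attenuation_ceiling`` (noise pushing S above S0) are clamped before the
    fit. Voxels whose mean b0 is not strictly positive are dropped from the
    output mask.
    """
    scheme = dwi.scheme
    if l_max is None:
        l_max = max_order_for(scheme.n_directions)
    s0 = dwi.mean_b0()
    good = dwi.mask & (s0 > 0)
    vox = np.flatnonzero(good.ravel())
    atten = dwi.dw_data().reshape(-1, scheme.n_directions)[vox]
    atten = atten / s0.ravel()[vox, None]
    np.clip(atten, 0.0, attenuation_ceiling, out=atten)
    basis = build_sh_basis(scheme.directions, l_max)
    fit = _fit_matrix(basis, l_max, reg_lambda)
    coeffs = atten @ fit.T
    out = np.zeros(dwi.shape + (n_coefficients(l_max),), dtype=float)
    out.reshape(-1, out.shape[-1])[vox] = coeffs

    # residual variance and per-order coefficient-covariance trace: the
    # expected noise energy E[sum_m n_lm^2] = sigma2 * tr[(M M')_ll], used to
    # debias group-mean RISH features before scale-map ratios
    sigma2 = None
    noise_trace = None
    dof = scheme.n_directions - n_coefficients(l_max)
    if dof > 0:
        resid = atten - coeffs @ basis.T
        s2 = np.einsum("vn,vn->v", resid, resid) / dof
        sigma2 = np.zeros(dwi.shape, dtype=float)
        sigma2.reshape(-1)[vox] = s2
        cov_unit = np.diag(fit @ fit.T)
        orders = range(0, l_max + 1, 2)
        idx = np.array([l for l, _ in sh_index_list(l_max)])
        noise_trace = np.array([cov_unit[idx == l].sum() for l in orders])
    return SHCoefficientField(out, l_max, good, s0, dwi.affine,
                              sigma2=sigma2, noise_trace=noise_trace)


def reconstruct_signal(coeffs: SHCoefficientField, directions: np.ndarray,
                       s0: np.ndarray | None = None,
                       attenuation_floor: float = 0.0) -> np.ndarray:
    """Evaluate the SH expansion at ``directions`` and rescale by ``s0``.

    Returns (X, Y, Z, n_directions). Negative reconstructed attenuations are
    clamped to ``attenuation_floor``.
    """
    basis = build_sh_basis(directions, coeffs.l_max)
    if basis.shape[1] != coeffs.data.shape[3]:
        raise ValueError("basis order does not match coefficient field")
    atten = coeffs.data @ basis.T
    np.clip(atten, attenuation_floor, None, out=atten)
    if s0 is None:
        s0 = coeffs.s0
    return atten * np.asarray(s0)[..., None]
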