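"""Synthetic multi-site dMRI cohorts with known ground truth.

Emulates the structure of a retrospective multi-site small-vessel-disease
study: several sites with different single-shell gradient schemes (b-values
1000-1200 s/mm^2, 30-61 directions), elderly controls and patients, per-site
multiplicative site effects injected on the even-order SH coefficients
(smooth gamma_l fields), Rician noise at a configurable b0 SNR, and
WMH-like lesions whose total volume tracks a per-subject WMH burden drawn
from a heavy-tailed (log-normal) distribution in patients.

The digital phantom is a small 3-D grid holding a single-fiber bundle along
x, a second bundle along y (a crossing region where they meet), isotropic
grey-matter and CSF compartments, and a ground-truth white-matter skeleton
at the bundle cores. Patients additionally carry (a) focal lesions with
raised MD / lowered FA and (b) a diffuse radial-diffusivity increase whose
size is linear in the standardized log WMH burden, calibrated so the
population R^2 between Box-Cox WMH volume and skeleton MD equals a
configured target.

Everything is deterministic under a master seed: the per-subject generator
seed is ``SeedSequence([master_seed, site_index, subject_index])`` and site
effect fields use ``SeedSequence([master_seed, 777, site_index])``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .gradients import GradientScheme, fibonacci_directions
from .sh import fit_sh, reconstruct_signal, n_coefficients
from .volume import DWIVolume, save_dwi, save_map

__all__ = [
    "PhantomConfig",
    "SiteSpec",
    "SubjectSpec",
    "PhantomTruth",
    "SyntheticStudy",
    "Cohort",
    "default_sites",
    "generate_phantom",
    "apply_site_effect",
    "site_gamma_fields",
    "generate_cohort",
    "estimate_b0_snr",
]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and tissue parameters of the digital phantom.

    Diffusivities in mm^2/s; the 32x32x16 grid at 2 mm isotropic is large
    enough for skeleton statistics while keeping whole-study runs desk-scale.
    """

    shape: tuple[int, int, int] = (32, 32, 16)
    voxel_size: float = 2.0
    d_axial: float = 1.7e-3
    d_radial: float = 0.3e-3
    d_gm: float = 0.8e-3
    d_csf: float = 3.0e-3
    lesion_axial: float = 1.3e-3
    lesion_radial: float = 0.9e-3
    s0: float = 100.0
    # subject-level biological variation
    control_radial_sd: float = 0.085   # mean-skeleton FA SD ~ 0.018, MD SD ~ 2.3%
    age_slope: float = 0.004            # radial multiplier per year from age 70
    patient_radial_shift: float = 0.18  # diffuse disease effect (drives d ~ 1)
    severity_slope: float = 0.15        # radial multiplier per unit severity
    target_r2: float = 0.6              # population R^2 of skeleton MD on severity
    # WMH burden (% of intracranial volume)
    wmh_lognormal_mu: float = 0.0
    wmh_lognormal_sigma: float = 1.0
    wmh_clip: tuple[float, float] = (0.05, 8.0)
    control_wmh_range: tuple[float, float] = (0.01, 0.3)


@dataclass(frozen=True)
class SiteSpec:
    """Acquisition and site-effect description of one scanner site."""

    site_id: str
    bvalue: float
    n_directions: int
    snr: float = 30.0
    n_b0: int = 3
    gamma: tuple[float, float, float] = (1.0, 1.0, 1.0)  # per order 0, 2, 4
    gamma_field_amp: float = 0.05   # relative amplitude of the smooth field
    n_training: int = 20
    n_validation: int = 0
    n_patients: int = 0

    def __post_init__(self) -> None:
        if self.n_directions < 6:
            raise ValueError("need at least 6 gradient directions")
        if self.snr <= 0:
            raise ValueError("SNR must be > 0 (use np.inf for noise-free)")
        if any(g <= 0 for g in self.gamma):
            raise ValueError("site-effect factors gamma_l must be > 0")

    def scheme(self) -> GradientScheme:
        bvals = np.concatenate([np.zeros(self.n_b0), np.full(self.n_directions, self.bvalue)])
        bvecs = np.vstack([np.zeros((self.n_b0, 3)), fibonacci_directions(self.n_directions)])
        return GradientScheme(bvals, bvecs)


@dataclass(frozen=True)
class SubjectSpec:
    """One subject's demographic and disease description."""

    subject_id: str
    site: str
    group: str                 # "patient" | "control"
    age: float
    sex: str                   # "M" | "F"
    wmh_volume: float          # % of intracranial volume
    lesion_seed: int
    role: str = "training"     # "training" | "validation" | "patient"
    #: pre-drawn latent severity noise (cohort-level stratified draw);
    #: None lets the phantom generator draw it itself
    severity_noise: float | None = None


def default_sites(n_training: int = 20, n_validation: int = 15,
                  n_patients: int = 20, snr: float = 30.0) -> list[SiteSpec]:
    """Five site presets mirroring a 1000-1200 s/mm^2, 30-61-direction study.

    The first site is the reference (no injected effect); the second-to-last
    is a near-duplicate of the reference with only mild effects, as happens
    for two cohorts scanned on the same system years apart.
    """
    mk = lambda *a, **k: SiteSpec(*a, snr=snr, n_training=n_training,
                                  n_validation=n_validation, n_patients=n_patients, **k)
    return [
        mk("siteA", 1200.0, 45, gamma=(1.00, 1.00, 1.00)),
        mk("siteB", 1000.0, 32, gamma=(1.06, 0.85, 0.90)),
        mk("siteC", 1000.0, 30, gamma=(0.95, 0.80, 0.85)),
        mk("siteD", 1200.0, 45, gamma=(1.01, 0.96, 0.97)),
        mk("siteE", 1150.0, 61, gamma=(1.07, 0.88, 0.92)),
    ]


# --------------------------------------------------------------------------
# phantom geometry
# --------------------------------------------------------------------------

@dataclass
class PhantomMasks:
    brain: np.ndarray
    wm: np.ndarray
    gm: np.ndarray
    csf: np.ndarray
    bundle_x: np.ndarray
    bundle_y: np.ndarray
    crossing: np.ndarray
    skeleton: np.ndarray
    severity_weight: np.ndarray   # spatial profile of the diffuse disease effect
    radial_profile: np.ndarray    # static anatomical modulation of radial diffusivity


def phantom_masks(config: PhantomConfig) -> PhantomMasks:
    """Deterministic tissue layout shared by every subject of a study."""
    nx, ny, nz = config.shape
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")

    brain = ((x - cx) / (0.47 * nx)) ** 2 + ((y - cy) / (0.47 * ny)) ** 2 \
        + ((z - cz) / (0.47 * nz)) ** 2 <= 1.0

    def blob(c, r):
        return ((x - c[0]) / r[0]) ** 2 + ((y - c[1]) / r[1]) ** 2 + ((z - c[2]) / r[2]) ** 2 <= 1.0

    csf = blob((cx - 5, cy - 5, cz), (2.0, 2.0, 1.5)) | blob((cx + 5, cy + 5, cz), (2.0, 2.0, 1.5))
    csf &= brain

    bundle_x = brain & (np.abs(y - cy) <= 4) & (np.abs(z - cz) <= 3) & ~csf
    bundle_y = brain & (np.abs(x - cx) <= 4) & (np.abs(z - cz) <= 3) & ~csf
    wm = bundle_x | bundle_y
    crossing = bundle_x & bundle_y
    gm = brain & ~wm & ~csf

    # single-fiber bundle cores only: PSMD-style analyses mask the skeleton
    # conservatively, and in the crossing the tensor model itself is biased,
    # which would add a severity-tracking mode to the skeleton MD histogram
    skeleton = (
        (bundle_x & (np.abs(y - cy) <= 1) & (np.abs(z - cz) <= 1))
        | (bundle_y & (np.abs(x - cx) <= 1) & (np.abs(z - cz) <= 1))
    ) & ~crossing
    from scipy.ndimage import gaussian_filter

    def _smooth_unit_field(seed, sigma=2.5):
        f = gaussian_filter(np.random.default_rng(seed).normal(size=(nx, ny, nz)), sigma)
        return f / max(f.std(), 1e-12)

    # diffuse-effect spatial profile in [0.5, 1.5]: a fixed smooth field over
    # the whole white matter, so the disease effect broadens the skeleton MD
    # distribution (what PSMD measures) in every bundle
    severity_weight = 1.0 + 0.5 * np.clip(_smooth_unit_field(3141) / 1.1, -1.0, 1.0)

    # static anatomical heterogeneity of radial diffusivity (+-10%, smooth),
    # identical for every subject and site: real skeletons carry substantial
    # along-tract MD variation, which keeps PSMD from being noise-dominated
    radial_profile = 1.0 + 0.10 * np.clip(_smooth_unit_field(2718), -2.0, 2.0)
    return PhantomMasks(brain, wm, gm, csf, bundle_x, bundle_y, crossing,
                        skeleton, severity_weight, radial_profile)


# --------------------------------------------------------------------------
# per-subject ground truth
# --------------------------------------------------------------------------

def _tensor6(d_axial: float, d_radial: float, axis: int) -> np.ndarray:
    d = np.full(3, d_radial)
    d[axis] = d_axial
    return np.array([d[0], d[1], d[2], 0.0, 0.0, 0.0])


@dataclass
class PhantomTruth:
    """Ground-truth two-compartment tensor mixture plus masks for one subject."""

    fractions: np.ndarray      # (X, Y, Z, 2)
    tensors6: np.ndarray       # (X, Y, Z, 2, 6) in (xx, yy, zz, xy, xz, yz) order
    lesion: np.ndarray
    masks: PhantomMasks
    config: PhantomConfig
    radial_multiplier: float

    def attenuation(self, scheme: GradientScheme) -> np.ndarray:
        """Noise-free S/S0 at the scheme's diffusion-weighted directions."""
        g = scheme.directions
        b = scheme.shell_bvalue
        G6 = np.column_stack([
            g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2],
        ])
        brain = self.masks.brain
        f = self.fractions[brain]                     # (V, 2)
        d6 = self.tensors6[brain]                     # (V, 2, 6)
        q = np.einsum("vkd,nd->vkn", d6, G6, optimize=True)
        att = np.einsum("vk,vkn->vn", f, np.exp(-b * q), optimize=True)
        out = np.zeros(self.config.shape + (g.shape[0],))
        out[brain] = att
        return out

    def signal(self, scheme: GradientScheme) -> DWIVolume:
        """Noise-free DWI series (b0 volumes = s0 inside the brain)."""
        cfg = self.config
        data = np.zeros(cfg.shape + (scheme.n_volumes,))
        data[..., scheme.b0_mask] = np.where(self.masks.brain, cfg.s0, 0.0)[..., None]
        data[..., ~scheme.b0_mask] = cfg.s0 * self.attenuation(scheme)
        return DWIVolume(data, scheme, self.masks.brain)


def _severity(subject: SubjectSpec, config: PhantomConfig) -> float:
    """Standardized log WMH burden (the latent disease severity)."""
    return (np.log(subject.wmh_volume) - config.wmh_lognormal_mu) / config.wmh_lognormal_sigma


def _lesion_mask(target_voxels: int, masks: PhantomMasks, rng: np.random.Generator) -> np.ndarray:
    """Grow spherical lesions in WM, sparing the skeleton core, until exactly
    ``target_voxels`` are set.

    The thin core of the phantom's bundles stands in for the compact tract
    centers the skeleton represents; lesions occupy the surrounding WM, so
    the skeleton-mean association with WMH burden is the calibrated diffuse
    effect rather than an uncontrolled focal-overlap term.
    """
    allowed = masks.wm & ~masks.skeleton
    wm_idx = np.argwhere(allowed)
    if target_voxels > len(wm_idx):
        raise ValueError(
            f"requested lesion volume ({target_voxels} voxels) exceeds available "
            f"white matter ({len(wm_idx)} voxels)"
        )
    lesion = np.zeros(masks.wm.shape, dtype=bool)
    count = 0
    while count < target_voxels:
        center = wm_idx[rng.integers(len(wm_idx))]
        radius = rng.uniform(1.0, 2.2)
        lo = np.maximum(center - 3, 0)
        hi = np.minimum(center + 4, masks.wm.shape)
        sub = tuple(slice(l, h) for l, h in zip(lo, hi))
        xx, yy, zz = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
        dist = np.sqrt((xx - center[0]) ** 2 + (yy - center[1]) ** 2 + (zz - center[2]) ** 2)
        candidates = np.argwhere((dist <= radius) & allowed[sub] & ~lesion[sub])
        order = np.argsort(dist[tuple(candidates.T)], kind="stable")
        for idx in candidates[order]:
            lesion[tuple(idx + lo)] = True
            count += 1
            if count == target_voxels:
                break
    return lesion


def generate_phantom(config: PhantomConfig, subject: SubjectSpec,
                     seed: int | np.random.SeedSequence | None = None) -> PhantomTruth:
    """Build the ground-truth tensor field for one subject.

    Deterministic for a fixed ``subject.lesion_seed`` (the ``seed`` argument
    overrides it). The lesion mask volume matches the subject's WMH burden
    (as a fraction of intracranial volume) to the voxel, by construction.
    """
    if seed is None:
        seed = subject.lesion_seed
    rng = np.random.default_rng(seed)
    masks = phantom_masks(config)
    shape = config.shape

    # diffuse radial-diffusivity multiplier: disease + age + biology
    noise_sd = np.sqrt(1.0 / config.target_r2 - 1.0)
    if subject.group == "patient":
        noise = subject.severity_noise
        if noise is None:
            noise = rng.normal(0.0, noise_sd)
        sev = _severity(subject, config) + noise
        r = 1.0 + config.patient_radial_shift + config.severity_slope * sev
    else:
        r = 1.0 + config.control_radial_sd * rng.normal()
    r += config.age_slope * (subject.age - 70.0)
    r = float(np.clip(r, 0.5, 1.9))

    fractions = np.zeros(shape + (2,))
    tensors6 = np.zeros(shape + (2, 6))

    iso = lambda d: np.array([d, d, d, 0.0, 0.0, 0.0])
    fractions[masks.gm, 0] = 1.0
    tensors6[masks.gm, 0] = iso(config.d_gm)
    fractions[masks.csf, 0] = 1.0
    tensors6[masks.csf, 0] = iso(config.d_csf)

    # spatially weighted radial multiplier in WM, on top of the fixed
    # anatomical profile shared by all subjects
    w = masks.severity_weight
    r_field = masks.radial_profile * (1.0 + (r - 1.0) * w)
    only_x = masks.bundle_x & ~masks.crossing
    only_y = masks.bundle_y & ~masks.crossing
    for region, axis in ((only_x, 0), (only_y, 1)):
        fractions[region, 0] = 1.0
        n = int(region.sum())
        t = np.tile(_tensor6(config.d_axial, config.d_radial, axis), (n, 1))
        t[:, [i for i in range(3) if i != axis]] *= r_field[region][:, None]
        tensors6[region, 0] = t
    cross = masks.crossing
    ncr = int(cross.sum())
    t_cross = np.zeros((ncr, 2, 6))
    for k, axis in ((0, 0), (1, 1)):
        fractions[cross, k] = 0.5
        t = np.tile(_tensor6(config.d_axial, config.d_radial, axis), (ncr, 1))
        t[:, [i for i in range(3) if i != axis]] *= r_field[cross][:, None]
        t_cross[:, k, :] = t
    tensors6[cross] = t_cross

    # focal lesions: volume = WMH% of intracranial volume, rounded to voxels
    n_brain = int(masks.brain.sum())
    target = int(round(subject.wmh_volume / 100.0 * n_brain)) if subject.group == "patient" else 0
    lesion = _lesion_mask(target, masks, rng) if target > 0 else np.zeros(shape, dtype=bool)
    if target > 0:
        fractions[lesion, 0] = 1.0
        fractions[lesion, 1] = 0.0
        t = np.tile(_tensor6(config.lesion_axial, config.lesion_radial, 0), (int(lesion.sum()), 1))
        tensors6[lesion, 0] = t
        tensors6[lesion, 1] = 0.0

    return PhantomTruth(fractions, tensors6, lesion, masks, config, r)


# --------------------------------------------------------------------------
# site effects and noise
# --------------------------------------------------------------------------

def site_gamma_fields(site: SiteSpec, config: PhantomConfig, master_seed: int,
                      site_index: int) -> np.ndarray:
    """Smooth per-order multiplicative fields gamma_l(v), shape (X, Y, Z, 3).

    gamma_l = base_l * (1 + amp * f(v)) with f a unit-variance Gaussian random
    field (smoothed white noise, clipped to +-2 so the product stays > 0).
    Fixed per site: identical for every subject of the site.
    """
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(np.random.SeedSequence([master_seed, 777, site_index]))
    shape = config.shape
    out = np.empty(shape + (3,))
    for i, base in enumerate(site.gamma):
        f = gaussian_filter(rng.normal(size=shape), sigma=3.0)
        sd = f.std()
        f = np.clip(f / sd, -2.0, 2.0) if sd > 0 else f
        out[..., i] = base * (1.0 + site.gamma_field_amp * f)
    if np.any(out <= 0):
        raise ValueError("gamma field non-positive; lower gamma_field_amp")
    return out


def _add_rician(data: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return data
    n1 = rng.normal(0.0, sigma, data.shape)
    n2 = rng.normal(0.0, sigma, data.shape)
    return np.sqrt((data + n1) ** 2 + n2 ** 2)


def apply_site_effect(dwi_truth: DWIVolume, site: SiteSpec,
                      gamma_fields: np.ndarray,
                      seed: int | np.random.SeedSequence | np.random.Generator = 0,
                      l_max: int = 4) -> DWIVolume:
    """Inject the site's multiplicative SH-domain effect and Rician noise.

    The noise-free signal is projected onto the even-order SH basis (exact
    least squares, no regularization), order-l coefficients are multiplied by
    gamma_l(v), the signal is reconstructed at the site's own directions, and
    Rician noise at the site's b0 SNR is added (sigma = s0 / SNR).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    coeffs = fit_sh(dwi_truth, l_max=l_max, reg_lambda=0.0)
    scaled = coeffs.data.copy()
    for i, l in enumerate(coeffs.orders):
        scaled[..., coeffs.order_slice(l)] *= gamma_fields[..., i:i + 1]
    coeffs.data = scaled
    recon = reconstruct_signal(coeffs, dwi_truth.scheme.directions)
    data = dwi_truth.data.copy()
    data[..., ~dwi_truth.scheme.b0_mask] = recon
    if np.isfinite(site.snr):
        s0_nominal = float(dwi_truth.mean_b0()[dwi_truth.mask].mean())
        data = _add_rician(data, s0_nominal / site.snr, rng)
    return DWIVolume(data.astype(np.float32), dwi_truth.scheme, dwi_truth.mask,
                     dwi_truth.affine)


def estimate_b0_snr(dwi: DWIVolume, mask: np.ndarray | None = None) -> float:
    """SNR estimate from repeated b0 volumes: mean / pooled across-repeat SD."""
    b0 = dwi.data[..., dwi.scheme.b0_mask]
    if b0.shape[-1] < 2:
        raise ValueError("need at least 2 b0 volumes to estimate SNR")
    m = dwi.mask if mask is None else np.asarray(mask, dtype=bool)
    vals = b0[m]
    pooled_sd = np.sqrt(vals.var(axis=1, ddof=1).mean())
    return float(vals.mean() / pooled_sd)


# --------------------------------------------------------------------------
# whole cohorts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticStudy:
    """Study design: site list plus phantom configuration."""

    sites: list[SiteSpec]
    phantom: PhantomConfig = field(default_factory=PhantomConfig)

    def __post_init__(self) -> None:
        if len(self.sites) < 2:
            raise ValueError("a harmonization study needs at least 2 sites")
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate site ids")


@dataclass
class Cohort:
    """A generated multi-site cohort; subject data is rebuilt on demand.

    Volumes are deterministic functions of (master seed, site index, subject
    index), so nothing needs to stay in memory between pipeline passes.
    """

    study: SyntheticStudy
    seed: int
    table: pd.DataFrame
    masks: PhantomMasks
    gamma_fields: dict[str, np.ndarray]

    def site(self, site_id: str) -> SiteSpec:
        for s in self.study.sites:
            if s.site_id == site_id:
                return s
        raise KeyError(site_id)

    def subject(self, subject_id: str) -> SubjectSpec:
        row = self.table.loc[self.table.subject_id == subject_id]
        if row.empty:
            raise KeyError(subject_id)
        r = row.iloc[0]
        noise = getattr(r, "severity_noise", None)
        noise = None if noise is None or pd.isna(noise) else float(noise)
        return SubjectSpec(r.subject_id, r.site, r.group, float(r.age), r.sex,
                           float(r.wmh_volume), int(r.lesion_seed), r.role,
                           severity_noise=noise)

    def truth(self, subject_id: str) -> PhantomTruth:
        return generate_phantom(self.study.phantom, self.subject(subject_id))

    def dwi(self, subject_id: str, noise_free: bool = False) -> DWIVolume:
        """The subject's acquired series: truth -> site effect -> noise."""
        spec = self.subject(subject_id)
        site = self.site(spec.site)
        truth = self.truth(subject_id)
        clean = truth.signal(site.scheme())
        if noise_free:
            site = SiteSpec(**{**asdict(site), "snr": np.inf})
        row = self.table.loc[self.table.subject_id == subject_id].iloc[0]
        noise_ss = np.random.SeedSequence([self.seed, int(row.site_index), int(row.subject_index), 1])
        return apply_site_effect(clean, site, self.gamma_fields[spec.site], noise_ss)

    def subject_ids(self, site: str | None = None, group: str | None = None,
                    role: str | None = None) -> list[str]:
        t = self.table
        if site is not None:
            t = t[t.site == site]
        if group is not None:
            t = t[t.group == group]
        if role is not None:
            t = t[t.role == role]
        return t.subject_id.tolist()

    def write(self, out_dir: str | Path) -> None:
        """Dump the cohort as NIfTI/bval/bvec trees plus cohort.csv and truth."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        affine = np.diag([self.study.phantom.voxel_size] * 3 + [1.0])
        save_map(self.masks.skeleton.astype(np.uint8), affine, out / "skeleton.nii.gz")
        save_map(self.masks.wm.astype(np.uint8), affine, out / "wm_mask.nii.gz")
        self.table.to_csv(out / "cohort.csv", index=False)
        truth_dir = out / "truth"
        truth_dir.mkdir(exist_ok=True)
        for s in self.study.sites:
            save_map(self.gamma_fields[s.site_id], affine, truth_dir / f"gamma_{s.site_id}.nii.gz")
        (truth_dir / "truth.json").write_text(json.dumps({
            "seed": self.seed,
            "phantom": asdict(self.study.phantom),
            "sites": [asdict(s) for s in self.study.sites],
        }, indent=2, default=str))
        for sid in self.table.subject_id:
            spec = self.subject(sid)
            sdir = out / spec.site / sid
            sdir.mkdir(parents=True, exist_ok=True)
            dwi = self.dwi(sid)
            dwi = DWIVolume(dwi.data, dwi.scheme, dwi.mask, affine)
            save_dwi(dwi, sdir / "dwi.nii.gz", sdir / "dwi.bval", sdir / "dwi.bvec")
            save_map(dwi.mask.astype(np.uint8), affine, sdir / "mask.nii.gz")


def _stratified_normal(n: int, rng: np.random.Generator) -> np.ndarray:
    """Latin-hypercube draw of n standard normals (one per quantile stratum).

    Small designed cohorts then realize the population variance almost
    exactly, so the generator's declared association strengths are what a
    cohort of 60 actually carries; iid draws at that size would fluctuate by
    far more than the calibration being tested.
    """
    from scipy.stats import norm

    u = (np.arange(n) + rng.uniform(0.0, 1.0, n)) / n
    return rng.permutation(norm.ppf(u))


def _draw_wmh(group: str, config: PhantomConfig, rng: np.random.Generator) -> float:
    if group == "patient":
        w = float(np.exp(rng.normal(config.wmh_lognormal_mu, config.wmh_lognormal_sigma)))
        return float(np.clip(w, *config.wmh_clip))
    return float(rng.uniform(*config.control_wmh_range))


def generate_cohort(study: SyntheticStudy, seed: int) -> Cohort:
    """Build the cohort table and site-effect fields for a study.

    Training controls share one age/sex vector across sites (matched by
    construction, as a real study would match training controls to the
    reference); validation controls and patients get site-specific draws.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    masks = phantom_masks(study.phantom)
    n_train_max = max(s.n_training for s in study.sites)
    n_val_max = max(s.n_validation for s in study.sites)
    shared_train_ages = np.clip(rng.normal(70.0, 4.0, n_train_max), 55.0, 85.0)
    shared_val_ages = np.clip(rng.normal(70.0, 4.0, max(n_val_max, 1)), 55.0, 85.0)
    sexes = np.array(["M", "F"])

    phantom = study.phantom
    noise_sd = np.sqrt(1.0 / phantom.target_r2 - 1.0)
    rows = []
    for i_site, site in enumerate(study.sites):
        # designed patient cohort: stratified draws of log-burden and of the
        # latent severity noise, so each site realizes the declared
        # population association strength
        site_rng = np.random.default_rng(np.random.SeedSequence([seed, 5000 + i_site]))
        if site.n_patients > 0:
            z = _stratified_normal(site.n_patients, site_rng)
            patient_wmh = np.clip(
                np.exp(phantom.wmh_lognormal_mu + phantom.wmh_lognormal_sigma * z),
                *phantom.wmh_clip,
            )
            patient_noise = noise_sd * _stratified_normal(site.n_patients, site_rng)
            if site.n_patients >= 3:
                # orthogonalize the noise against the design variable and pin
                # its sample SD, so the cohort carries the declared R^2
                zt = np.log(patient_wmh)
                zc = zt - zt.mean()
                patient_noise = patient_noise - patient_noise.mean()
                patient_noise -= (patient_noise @ zc) / (zc @ zc) * zc
                patient_noise *= noise_sd / patient_noise.std(ddof=1)
        i_patient = 0
        subj_index = 0
        roster = (
            [("control", "training")] * site.n_training
            + [("control", "validation")] * site.n_validation
            + [("patient", "patient")] * site.n_patients
        )
        for group, role in roster:
            sid = f"{site.site_id}_{role[:3]}{subj_index:03d}"
            ss = np.random.SeedSequence([seed, i_site, subj_index])
            srng = np.random.default_rng(ss)
            severity_noise = None
            if role == "training":
                age = shared_train_ages[subj_index]
                sex = sexes[subj_index % 2]
                wmh = _draw_wmh(group, phantom, srng)
            elif role == "validation":
                age = shared_val_ages[subj_index - site.n_training]
                sex = sexes[subj_index % 2]
                wmh = _draw_wmh(group, phantom, srng)
            else:
                age = float(np.clip(srng.normal(73.0, 6.0), 50.0, 90.0))
                sex = sexes[srng.integers(2)]
                wmh = float(patient_wmh[i_patient])
                severity_noise = float(patient_noise[i_patient])
                i_patient += 1
            lesion_seed = int(srng.integers(0, 2 ** 31 - 1))
            rows.append({
                "subject_id": sid, "site": site.site_id, "group": group, "role": role,
                "age": float(age), "sex": sex, "wmh_volume": wmh,
                "lesion_seed": lesion_seed, "site_index": i_site,
                "subject_index": subj_index, "severity_noise": severity_noise,
            })
            subj_index += 1
    table = pd.DataFrame(rows)
    gamma = {
        s.site_id: site_gamma_fields(s, study.phantom, seed, i)
        for i, s in enumerate(study.sites)
    }
    return Cohort(study, seed, table, masks, gamma)
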