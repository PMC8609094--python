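"""Canonical synthetic study scenarios.

One place defines the study conditions used by the validation experiments,
the analysis drivers and the acceptance script: site presets (b-values,
direction counts, injected per-order effects), cohort sizes, SNR and the
pipeline configuration. Group-mean RISH smoothing is off in these scenarios
because synthetic subjects share one voxel-aligned grid, so there is no
misregistration-driven anatomy leakage for smoothing to suppress.
"""

from __future__ import annotations

from .pipeline import StudyConfig
from .simulate import PhantomConfig, SiteSpec, SyntheticStudy, default_sites

__all__ = [
    "site_effect_study",
    "transitivity_study",
    "preservation_study",
    "disease_study",
    "five_site_study",
]


def _config(reference: str, targets: list[str], **overrides) -> StudyConfig:
    base = dict(
        reference_site=reference,
        target_sites=targets,
        common_bvalue=1000.0,
        l_max=4,
        smoothing_fwhm=0.0,
        n_permutations=1000,
        alpha=0.05,
    )
    base.update(overrides)
    return StudyConfig(**base)


def site_effect_study(n_controls: int = 20, snr: float = 30.0,
                      **config_overrides) -> tuple[SyntheticStudy, StudyConfig]:
    """Two matched control groups with an injected order-2 site effect.

    Reference at b=1200 s/mm^2 with 45 directions; target at b=1000 with 32
    directions and gamma_2 = 0.8 (anisotropy energy suppressed by the
    scanner), the canonical site-difference-removal experiment.
    """
    study = SyntheticStudy(sites=[
        SiteSpec("siteA", 1200.0, 45, snr=snr, n_training=n_controls),
        SiteSpec("siteB", 1000.0, 32, snr=snr, gamma=(1.0, 0.8, 1.0),
                 n_training=n_controls),
    ])
    return study, _config("siteA", ["siteB"], **config_overrides)


def transitivity_study(n_controls: int = 15, snr: float = 30.0,
                       **config_overrides) -> tuple[SyntheticStudy, StudyConfig]:
    """Three sites: two targets independently harmonized to one reference.

    Checks that harmonizing B and C to A also harmonizes B against C.
    """
    study = SyntheticStudy(sites=[
        SiteSpec("siteA", 1200.0, 45, snr=snr, n_training=n_controls),
        SiteSpec("siteB", 1000.0, 32, snr=snr, gamma=(1.06, 0.85, 0.90),
                 n_training=n_controls),
        SiteSpec("siteC", 1000.0, 30, snr=snr, gamma=(0.95, 0.80, 0.85),
                 n_training=n_controls),
    ])
    return study, _config("siteA", ["siteB", "siteC"], **config_overrides)


def disease_study(n_controls: int = 20, n_patients: int = 60, snr: float = 30.0,
                  **config_overrides) -> tuple[SyntheticStudy, StudyConfig]:
    """Patients with WMH-driven diffusion change and a strong site effect.

    Used for WMH-volume association recovery per site and the pooled-patient
    regression: the injected gamma_2 = 0.8 produces clearly separated FA
    clusters across sites before harmonization.
    """
    study = SyntheticStudy(sites=[
        SiteSpec("siteA", 1200.0, 45, snr=snr, n_training=n_controls,
                 n_patients=n_patients),
        SiteSpec("siteB", 1000.0, 32, snr=snr, gamma=(1.0, 0.8, 1.0),
                 n_training=n_controls, n_patients=n_patients),
    ])
    return study, _config("siteA", ["siteB"], **config_overrides)


def preservation_study(n_controls: int = 40, n_patients: int = 60, snr: float = 30.0,
                       **config_overrides) -> tuple[SyntheticStudy, StudyConfig]:
    """Effect-size preservation under a realistic mild site effect.

    The target mirrors a same-scanner, software-updates-apart site: small,
    spatially uniform per-order effects (a pure gain/protocol difference).
    Strong or
    strongly spatially structured injected effects interact with
    disease-driven diffusion change (through the tensor fit and the PSMD
    percentiles), so removing them legitimately moves within-site contrasts
    — preservation is a statement about what harmonization does to contrasts
    when the site effect itself is modest. Expected RISH maps are smoothed
    heavily (12 mm FWHM) here: for a near-uniform effect spatial pooling
    suppresses training-sample noise in the scale maps without biasing them.
    """
    kw = dict(snr=snr, gamma_field_amp=0.0, n_training=n_controls,
              n_patients=n_patients)
    study = SyntheticStudy(sites=[
        SiteSpec("siteA", 1200.0, 45, **kw),
        SiteSpec("siteD", 1200.0, 45, gamma=(1.01, 0.96, 0.97), **kw),
    ])
    return study, _config("siteA", ["siteD"], smoothing_fwhm=12.0, **config_overrides)


def five_site_study(n_training: int = 20, n_validation: int = 15,
                    n_patients: int = 20, snr: float = 30.0,
                    **config_overrides) -> tuple[SyntheticStudy, StudyConfig]:
    """The full five-site layout (b 1000-1200 s/mm^2, 30-61 directions)."""
    sites = default_sites(n_training, n_validation, n_patients, snr)
    study = SyntheticStudy(sites=sites)
    ref = sites[0].site_id
    return study, _config(ref, [s.site_id for s in sites[1:]], **config_overrides)
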