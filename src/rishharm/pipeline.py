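"""Study orchestration: learn scale maps, harmonize, compute metrics, evaluate.

The pipeline runs over a :class:`~rishharm.simulate.Cohort` (subjects are
regenerated deterministically on demand) or over a written data tree via
:class:`FileCohort`. Pre- vs post-harmonization comparisons are realized by
computing metrics on both arms, never by mutating data in place.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

import nibabel as nib

from . import stats
from .bmap import map_volume
from .dti import fa_map, fit_tensor, md_map, psmd, skeleton_summary
from .rish import (
    DEFAULT_CLIP,
    DEFAULT_EPS,
    DEFAULT_SMOOTHING_FWHM,
    MIN_TRAINING_CONTROLS,
    ScaleMapSet,
    apply_scale_maps,
    compute_rish,
    group_mean_rish,
    harmonize_subject,
    learn_scale_maps,
)
from .sh import DEFAULT_REG_LAMBDA, fit_sh
from .volume import DWIVolume, load_dwi, load_mask, save_map

__all__ = [
    "StudyConfig",
    "FileCohort",
    "learn_study_scale_maps",
    "harmonized_dwi",
    "compute_metrics",
    "run_voxelwise_site_test",
    "evaluate",
    "save_scale_maps",
    "load_scale_maps",
]

METRICS = ("fa", "md", "psmd")


class StudyConfig(BaseModel):
    """Validated harmonization-study configuration."""

    reference_site: str
    target_sites: list[str]
    common_bvalue: float = 1000.0
    l_max: int = 4
    reg_lambda: float = Field(default=DEFAULT_REG_LAMBDA, ge=0)
    eps: float = Field(default=DEFAULT_EPS, gt=0)
    clip: tuple[float, float] = DEFAULT_CLIP
    smoothing_fwhm: float = Field(default=DEFAULT_SMOOTHING_FWHM, ge=0)
    #: debias expected RISH features by each site's estimated coefficient
    #: noise energy before taking the scale-map ratio (see rish module).
    noise_correct: bool = True
    voxel_size: float = Field(default=2.0, gt=0)
    n_permutations: int = Field(default=1000, ge=1)
    alpha: float = Field(default=0.05, gt=0, lt=1)
    seed: int = 0
    #: project reference scans onto the same band-limited SH representation
    #: (identity scaling) in the harmonized arm, so pre/post comparisons
    #: measure the site effect rather than the representation; set False to
    #: copy reference data through raw.
    project_reference: bool = True
    #: evaluate the pre-harmonization arm in the same representation
    #: (identity projection, no scaling), so before/after comparisons of
    #: disease contrasts isolate the learned inter-site transformation;
    #: set False to evaluate the raw b-value-mapped data instead.
    project_before: bool = True
    max_age_gap_years: float = 3.0
    max_sex_ratio_gap: float = 0.35

    @model_validator(mode="after")
    def _check_sites(self):
        if self.reference_site in self.target_sites:
            raise ValueError("reference site must not be among the target sites")
        if self.l_max < 0 or self.l_max % 2:
            raise ValueError("l_max must be an even integer >= 0")
        return self

    @property
    def all_sites(self) -> list[str]:
        return [self.reference_site] + list(self.target_sites)


@dataclass
class _Masks:
    skeleton: np.ndarray
    wm: np.ndarray


class FileCohort:
    """Adapter exposing a written cohort tree through the Cohort interface."""

    def __init__(self, root: str | Path):
        self.root = Path(root)
        if not (self.root / "cohort.csv").exists():
            raise FileNotFoundError(f"no cohort.csv under {self.root}")
        self.table = pd.read_csv(self.root / "cohort.csv")
        self.masks = _Masks(
            skeleton=load_mask(self.root / "skeleton.nii.gz"),
            wm=load_mask(self.root / "wm_mask.nii.gz"),
        )

    def dwi(self, subject_id: str) -> DWIVolume:
        row = self.table.loc[self.table.subject_id == subject_id].iloc[0]
        d = self.root / row.site / subject_id
        return load_dwi(d / "dwi.nii.gz", d / "dwi.bval", d / "dwi.bvec", d / "mask.nii.gz")

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


def _check_matching(cohort, config: StudyConfig, site: str) -> None:
    t = cohort.table
    ref = t[(t.site == config.reference_site) & (t.role == "training")]
    tar = t[(t.site == site) & (t.role == "training")]
    if len(tar) < MIN_TRAINING_CONTROLS:
        warnings.warn(
            f"{site}: {len(tar)} training controls; at least "
            f"{MIN_TRAINING_CONTROLS}-20 are recommended for stable scale maps",
            stacklevel=3,
        )
    if len(ref) and len(tar):
        age_gap = abs(ref.age.mean() - tar.age.mean())
        if age_gap > config.max_age_gap_years:
            warnings.warn(f"{site}: mean training-control age differs from reference by "
                          f"{age_gap:.1f} y (limit {config.max_age_gap_years})", stacklevel=3)
        sex_gap = abs((ref.sex == "M").mean() - (tar.sex == "M").mean())
        if sex_gap > config.max_sex_ratio_gap:
            warnings.warn(f"{site}: training-control sex ratio differs from reference by "
                          f"{sex_gap:.2f}", stacklevel=3)


def _mean_training_rish(cohort, config: StudyConfig, site: str):
    maps = []
    ids = cohort.subject_ids(site=site, role="training")
    if not ids:
        raise ValueError(f"site {site} has no training controls")
    for sid in ids:
        dwi = map_volume(cohort.dwi(sid), config.common_bvalue)
        coeffs = fit_sh(dwi, l_max=config.l_max, reg_lambda=config.reg_lambda)
        maps.append(compute_rish(coeffs))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # training-count warning issued by _check_matching
        return group_mean_rish(maps, config.smoothing_fwhm, config.voxel_size)


def learn_study_scale_maps(cohort, config: StudyConfig) -> dict[str, ScaleMapSet]:
    """One ScaleMapSet per (reference, target) pair, from training controls."""
    ref_mean = _mean_training_rish(cohort, config, config.reference_site)
    out: dict[str, ScaleMapSet] = {}
    for site in config.target_sites:
        _check_matching(cohort, config, site)
        tar_mean = _mean_training_rish(cohort, config, site)
        out[site] = learn_scale_maps(
            ref_mean, tar_mean, eps=config.eps, clip=config.clip,
            noise_correct=config.noise_correct,
            provenance={
                "reference_site": config.reference_site,
                "target_site": site,
                "n_training_reference": len(cohort.subject_ids(site=config.reference_site,
                                                               role="training")),
                "n_training_target": len(cohort.subject_ids(site=site, role="training")),
                "smoothing_fwhm_mm": config.smoothing_fwhm,
                "l_max": config.l_max,
            },
        )
    return out


def harmonized_dwi(cohort, subject_id: str, scale_maps: dict[str, ScaleMapSet],
                   config: StudyConfig) -> DWIVolume:
    """B-value-map a subject and, if it belongs to a target site, harmonize it.

    Reference-site subjects pass through (b-value mapping only).
    """
    row = cohort.table.loc[cohort.table.subject_id == subject_id].iloc[0]
    dwi = map_volume(cohort.dwi(subject_id), config.common_bvalue)
    if row.site == config.reference_site:
        if not config.project_reference:
            return dwi
        return harmonize_subject(dwi, None, l_max=config.l_max,
                                 reg_lambda=config.reg_lambda)
    if row.site not in scale_maps:
        raise KeyError(f"no scale maps learned for site {row.site}")
    return harmonize_subject(dwi, scale_maps[row.site], l_max=config.l_max,
                             reg_lambda=config.reg_lambda)


def _subject_maps(dwi: DWIVolume) -> dict[str, np.ndarray]:
    tensors = fit_tensor(dwi)
    return {"fa": fa_map(tensors), "md": md_map(tensors)}


def compute_metrics(cohort, config: StudyConfig,
                    scale_maps: dict[str, ScaleMapSet] | None = None,
                    subject_ids: list[str] | None = None,
                    collect_maps: tuple[str, ...] = ()) -> tuple[pd.DataFrame, dict]:
    """Per-subject skeleton summaries (mean FA, mean MD, PSMD).

    With ``scale_maps`` given, subjects are harmonized first (the "after"
    arm); with ``scale_maps=None`` metrics describe the pre-harmonization
    arm — b-value-mapped and, under ``config.project_before``, projected
    onto the common SH representation without scaling, so that the two arms
    differ only by the learned transformation. ``collect_maps`` optionally
    retains the listed scalar maps per subject for voxelwise tests.
    """
    skeleton = cohort.masks.skeleton
    ids = subject_ids if subject_ids is not None else cohort.table.subject_id.tolist()
    rows, kept = [], {m: {} for m in collect_maps}
    for sid in ids:
        if scale_maps is None:
            dwi = map_volume(cohort.dwi(sid), config.common_bvalue)
            if config.project_before:
                dwi = harmonize_subject(dwi, None, l_max=config.l_max,
                                        reg_lambda=config.reg_lambda)
        else:
            dwi = harmonized_dwi(cohort, sid, scale_maps, config)
        maps = _subject_maps(dwi)
        row = cohort.table.loc[cohort.table.subject_id == sid].iloc[0].to_dict()
        row.update({
            "fa": skeleton_summary(maps["fa"], skeleton),
            "md": skeleton_summary(maps["md"], skeleton),
            "psmd": psmd(maps["md"], skeleton),
        })
        rows.append(row)
        for m in collect_maps:
            kept[m][sid] = maps[m]
    return pd.DataFrame(rows), kept


def run_voxelwise_site_test(cohort, config: StudyConfig, target_site: str,
                            scale_maps: dict[str, ScaleMapSet] | None = None,
                            metric: str = "fa", role: str = "training",
                            mask: np.ndarray | None = None) -> stats.VoxelwiseTestResult:
    """Voxelwise reference-vs-target control comparison of FA or MD maps.

    Permutation max-statistic FWER control at ``config.alpha``; deterministic
    for ``config.seed``.
    """
    ids_ref = cohort.subject_ids(site=config.reference_site, role=role)
    ids_tar = cohort.subject_ids(site=target_site, role=role)
    ids = ids_ref + ids_tar
    _, kept = compute_metrics(cohort, config, scale_maps, subject_ids=ids,
                              collect_maps=(metric,))
    maps = np.stack([kept[metric][sid] for sid in ids])
    labels = ["ref"] * len(ids_ref) + ["target"] * len(ids_tar)
    if mask is None:
        mask = cohort.masks.wm
    mask = mask & np.all(np.isfinite(maps), axis=0)
    return stats.voxelwise_group_test(maps, labels, mask,
                                      n_permutations=config.n_permutations,
                                      alpha=config.alpha, seed=config.seed)


# --------------------------------------------------------------------------
# evaluation report
# --------------------------------------------------------------------------

def _es(result: stats.EffectSizeResult) -> dict:
    return {"d": result.d, "ci": [result.ci_low, result.ci_high],
            "p": result.p_value, "n": [result.n1, result.n2]}


def evaluate(metrics_before: pd.DataFrame, metrics_after: pd.DataFrame,
             config: StudyConfig) -> dict:
    """The study report: site differences, effect sizes, WMH associations.

    Mirrors a multi-site harmonization evaluation: control-vs-reference
    effect sizes per target site, patient-vs-control effect sizes with their
    relative pre/post change, one-way ANOVA of control skeleton means across
    sites, WMH-volume regressions per site, pooled-patient regressions, and
    internal- vs external-control contrasts.
    """
    report: dict = {"config": {"reference_site": config.reference_site,
                               "target_sites": list(config.target_sites)},
                    "sites": {}, "anova": {}, "pooled_regression": {}}
    arms = {"before": metrics_before, "after": metrics_after}

    for site in config.target_sites:
        entry: dict = {"control_vs_reference": {}, "patient_vs_control": {},
                       "wmh_regression": {}}
        for metric in METRICS:
            cvr = {}
            for arm, df in arms.items():
                ctrl = df[(df.group == "control") & (df.role == "training")
                          & df.site.isin([config.reference_site, site])]
                res = stats.adjusted_cohens_d(ctrl[metric], ctrl.site, ctrl.age, ctrl.sex,
                                              positive_label=site)
                cvr[arm] = _es(res)
            entry["control_vs_reference"][metric] = cvr

            pvc = {}
            for arm, df in arms.items():
                sub = df[df.site == site]
                if (sub.group == "patient").sum() >= 2 and (sub.group == "control").sum() >= 2:
                    res = stats.adjusted_cohens_d(sub[metric], sub.group, sub.age, sub.sex,
                                                  positive_label="patient")
                    pvc[arm] = _es(res)
            if {"before", "after"} <= pvc.keys():
                pvc["relative_change_pct"] = stats.relative_effect_change(
                    pvc["before"]["d"], pvc["after"]["d"])
            entry["patient_vs_control"][metric] = pvc

            wmh = {}
            for arm, df in arms.items():
                pats = df[(df.site == site) & (df.group == "patient")]
                if len(pats) >= 6:
                    reg = stats.wmh_metric_regression(pats[metric], pats.wmh_volume,
                                                      pats.age, pats.sex)
                    wmh[arm] = {"r2": reg.r_squared, "beta_wmh": reg.beta["wmh"],
                                "p_wmh": reg.p_values["wmh"], "n": reg.n}
            entry["wmh_regression"][metric] = wmh
        report["sites"][site] = entry

    # reference-site patient-vs-control effects (single arm: untouched data)
    ref_entry = {}
    for metric in METRICS:
        sub = metrics_before[metrics_before.site == config.reference_site]
        if (sub.group == "patient").sum() >= 2 and (sub.group == "control").sum() >= 2:
            res = stats.adjusted_cohens_d(sub[metric], sub.group, sub.age, sub.sex,
                                          positive_label="patient")
            ref_entry[metric] = _es(res)
    report["reference_patient_vs_control"] = ref_entry

    # one-way ANOVA across sites on held-out (validation) controls if present
    role = "validation" if (metrics_before.role == "validation").any() else "training"
    for metric in METRICS:
        report["anova"][metric] = {}
        for arm, df in arms.items():
            ctrl = df[(df.group == "control") & (df.role == role)
                      & df.site.isin(config.all_sites)]
            if ctrl.site.nunique() >= 2:
                F, dof, p = stats.site_anova(ctrl[metric], ctrl.site)
                report["anova"][metric][arm] = {"F": F, "df": list(dof), "p": p,
                                                "controls": role}

    # pooled-patient WMH regressions
    for metric in METRICS:
        pooled = {}
        for arm, df in arms.items():
            pats = df[(df.group == "patient") & df.site.isin(config.all_sites)]
            if len(pats) >= 6:
                reg = stats.wmh_metric_regression(pats[metric], pats.wmh_volume,
                                                  pats.age, pats.sex)
                pooled[arm] = {"r2": reg.r_squared, "beta_wmh": reg.beta["wmh"],
                               "p_wmh": reg.p_values["wmh"], "n": reg.n}
        report["pooled_regression"][metric] = pooled

    # internal vs external controls
    report["external_controls"] = {}
    for site in config.all_sites:
        entry = {}
        for metric in METRICS:
            per_metric = {}
            for arm, df in arms.items():
                pats = df[(df.site == site) & (df.group == "patient")]
                internal = df[(df.site == site) & (df.group == "control")]
                external = df[(df.site != site) & df.site.isin(config.all_sites)
                              & (df.group == "control")]
                if len(pats) < 2 or len(internal) < 2 or len(external) < 2:
                    continue
                combo_int = pd.concat([pats, internal])
                combo_ext = pd.concat([pats, external])
                d_int = stats.adjusted_cohens_d(combo_int[metric], combo_int.group,
                                                combo_int.age, combo_int.sex,
                                                positive_label="patient")
                d_ext = stats.adjusted_cohens_d(combo_ext[metric], combo_ext.group,
                                                combo_ext.age, combo_ext.sex,
                                                positive_label="patient")
                per_metric[arm] = {"internal_d": d_int.d, "external_d": d_ext.d}
            if per_metric:
                entry[metric] = per_metric
        if entry:
            report["external_controls"][site] = entry
    return report


# --------------------------------------------------------------------------
# scale-map persistence
# --------------------------------------------------------------------------

def save_scale_maps(scales: ScaleMapSet, nifti_path: str | Path) -> None:
    """One 4-D NIfTI (one volume per order) + JSON sidecar with provenance."""
    path = Path(nifti_path)
    save_map(scales.data, scales.affine, path)
    sidecar = {
        "l_max": scales.l_max,
        "orders": scales.orders,
        "provenance": scales.provenance,
    }
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_scale_maps(nifti_path: str | Path) -> ScaleMapSet:
    path = Path(nifti_path)
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    sidecar = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    mask = ~np.all(np.isclose(data, 1.0), axis=3)
    return ScaleMapSet(data, int(sidecar["l_max"]), mask, np.asarray(img.affine),
                       sidecar.get("provenance", {}))
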