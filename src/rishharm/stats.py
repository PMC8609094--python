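"""Evaluation statistics for harmonization studies.

Covers the study's readouts: site-difference tests in matched controls
(skeleton-mean comparisons, one-way ANOVA, voxelwise permutation tests),
age/sex-adjusted Cohen's d for patients vs controls, and WMH-volume
regressions with a Box-Cox transformed predictor.

The voxelwise test controls family-wise error with a max-statistic
permutation null (a permutation-based alternative to cluster-enhancement
pipelines; the readout — are site differences present? — is the same).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "EffectSizeResult",
    "RegressionResult",
    "VoxelwiseTestResult",
    "adjusted_cohens_d",
    "relative_effect_change",
    "boxcox_transform",
    "wmh_metric_regression",
    "site_anova",
    "voxelwise_group_test",
]


@dataclass(frozen=True)
class EffectSizeResult:
    d: float
    ci_low: float
    ci_high: float
    p_value: float
    n1: int
    n2: int
    adjusted_for: tuple[str, ...]


@dataclass(frozen=True)
class RegressionResult:
    r_squared: float
    beta: dict[str, float]
    p_values: dict[str, float]
    n: int


@dataclass(frozen=True)
class VoxelwiseTestResult:
    t_map: np.ndarray
    p_corrected: np.ndarray
    n_significant: int
    alpha: float
    n_permutations: int


def _encode_sex(sex) -> np.ndarray:
    s = pd.Series(sex)
    if s.dtype == object or str(s.dtype) == "category":
        return (s.astype(str).str.upper().isin(["M", "MALE", "1"])).to_numpy(dtype=float)
    return s.to_numpy(dtype=float)


def adjusted_cohens_d(values, group, age=None, sex=None,
                      positive_label=None) -> EffectSizeResult:
    """Age/sex-adjusted Cohen's d from a linear model.

    Fits ``metric ~ group + age + sex`` (age centered, sex as a 0/1
    indicator); d is the group coefficient divided by the residual standard
    deviation, so with no covariates it reduces to classical pooled-SD
    Cohen's d. The 95% CI uses the large-sample formula
    d +- 1.96 * sqrt((n1+n2)/(n1 n2) + d^2 / (2(n1+n2))).

    ``group`` may be any two-level labelling; the coefficient is the mean of
    ``positive_label`` (default: the label sorting last, so patient > control)
    minus the other level, in residual-SD units.
    """
    y = np.asarray(values, dtype=float)
    glabels = pd.Series(group)
    levels = sorted(glabels.unique())
    if len(levels) != 2:
        raise ValueError(f"group must have exactly 2 levels, got {levels}")
    pos = positive_label if positive_label is not None else levels[-1]
    g = (glabels == pos).to_numpy(dtype=float)
    n1 = int(g.sum())
    n2 = int(len(g) - n1)
    if min(n1, n2) < 2:
        raise ValueError("need at least 2 subjects per group")

    cols: dict[str, np.ndarray] = {"group": g}
    adjusted: list[str] = []
    if age is not None:
        a = np.asarray(age, dtype=float)
        cols["age"] = a - a.mean()
        adjusted.append("age")
    if sex is not None:
        cols["sex"] = _encode_sex(sex)
        adjusted.append("sex")
    X = sm.add_constant(pd.DataFrame(cols), has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = X.drop(columns="const").corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.max().idxmax()
        raise ValueError(f"singular design matrix; collinear column: {worst}")
    fit = sm.OLS(y, X).fit()
    resid_sd = float(np.sqrt(fit.mse_resid))
    d = float(fit.params["group"] / resid_sd)
    n = n1 + n2
    se_d = np.sqrt((n1 + n2) / (n1 * n2) + d * d / (2 * n))
    z = sps.norm.ppf(0.975)
    return EffectSizeResult(
        d=d, ci_low=d - z * se_d, ci_high=d + z * se_d,
        p_value=float(fit.pvalues["group"]), n1=n1, n2=n2,
        adjusted_for=tuple(adjusted),
    )


def relative_effect_change(d_before: float, d_after: float) -> float:
    """Percent change in effect-size magnitude: 100*|d_after - d_before|/|d_before|.

    Undefined (NaN) when the pre-harmonization effect is exactly zero.
    """
    if d_before == 0:
        return float("nan")
    return 100.0 * abs(d_after - d_before) / abs(d_before)


def boxcox_transform(x, offset: float = 0.0,
                     lmbda: float | None = None) -> tuple[np.ndarray, float]:
    """Box-Cox transform with lambda chosen by profile ML on a grid.

    lambda is scanned over [-2, 2] in steps of 0.01 (profile log-likelihood);
    the transform is (x^l - 1)/l, or log x at l = 0. Non-positive values must
    be handled by the caller-supplied ``offset`` added to x first.
    """
    x = np.asarray(x, dtype=float) + offset
    if np.any(x <= 0):
        raise ValueError("Box-Cox requires strictly positive values (use offset)")
    if lmbda is None:
        grid = np.arange(-2.0, 2.0 + 1e-9, 0.01)
        llf = np.array([sps.boxcox_llf(l, x) for l in grid])
        lmbda = float(grid[np.argmax(llf)])
    transformed = sps.boxcox(x, lmbda=lmbda)
    return np.asarray(transformed), float(lmbda)


def wmh_metric_regression(metric, wmh_volume, age, sex,
                          wmh_offset: float = 1e-3) -> RegressionResult:
    """Regress a dMRI metric on Box-Cox WMH volume, adjusted for age and sex.

    Outcome and predictors are z-scored, so the WMH coefficient is a
    standardized beta; R^2 is for the full model. Intended for patients
    (controls have near-zero WMH by selection).
    """
    y = np.asarray(metric, dtype=float)
    wmh_t, _ = boxcox_transform(wmh_volume, offset=wmh_offset)
    X = pd.DataFrame({
        "wmh": wmh_t,
        "age": np.asarray(age, dtype=float),
        "sex": _encode_sex(sex),
    })
    n = len(y)
    if n < X.shape[1] + 2:
        raise ValueError(f"need at least {X.shape[1] + 2} subjects, have {n}")

    def _z(v):
        sd = v.std(ddof=1)
        return (v - v.mean()) / sd if sd > 0 else v - v.mean()

    yz = _z(y)
    Xz = X.apply(_z)
    fit = sm.OLS(yz, sm.add_constant(Xz, has_constant="add")).fit()
    beta = {k: float(fit.params[k]) for k in X.columns}
    pvals = {k: float(fit.pvalues[k]) for k in X.columns}
    return RegressionResult(r_squared=float(fit.rsquared), beta=beta, p_values=pvals, n=n)


def site_anova(metric, site) -> tuple[float, tuple[int, int], float]:
    """One-way ANOVA of per-subject summaries across sites: (F, (df1, df2), p)."""
    df = pd.DataFrame({"y": np.asarray(metric, dtype=float), "site": pd.Series(site)})
    groups = [g["y"].to_numpy() for _, g in df.groupby("site")]
    if len(groups) < 2:
        raise ValueError("need at least 2 sites")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every site needs at least 2 subjects")
    F, p = sps.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = len(df) - len(groups)
    return float(F), (df1, df2), float(p)


def _two_sample_t(data: np.ndarray, g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per column of ``data`` (subjects x voxels)."""
    x1, x2 = data[g1], data[g2]
    n1, n2 = len(x1), len(x2)
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    v1 = x1.var(axis=0, ddof=1)
    v2 = x2.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return np.where(sp2 > 0, t, 0.0)


def voxelwise_group_test(maps: np.ndarray, group, mask: np.ndarray,
                         n_permutations: int = 1000, alpha: float = 0.05,
                         seed: int | np.random.Generator = 0) -> VoxelwiseTestResult:
    """Two-sample t per voxel with max-statistic permutation FWER control.

    ``maps`` is (n_subjects, X, Y, Z) (or (n_subjects, n_voxels) with a 1-D
    mask). Corrected p for voxel v is the fraction of permutations whose
    maximum |t| over the mask reaches |t_v|. Deterministic for a fixed seed.
    """
    if n_permutations < 100:
        warnings.warn(f"{n_permutations} permutations is too few for stable FWER control",
                      stacklevel=2)
    mask = np.asarray(mask, dtype=bool)
    maps = np.asarray(maps, dtype=float)
    data = maps.reshape(maps.shape[0], -1)[:, mask.ravel()]
    labels = pd.Series(group)
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ValueError("voxelwise test needs exactly 2 groups")
    g1 = (labels == levels[0]).to_numpy()
    g2 = ~g1
    if min(g1.sum(), g2.sum()) < 5:
        raise ValueError("need at least 5 subjects per group")

    t_obs = _two_sample_t(data, g1, g2)
    abs_obs = np.abs(t_obs)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = data.shape[0]
    exceed = np.ones_like(abs_obs)  # observed labelling counts once
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        p1 = np.zeros(n, dtype=bool)
        p1[perm[: g1.sum()]] = True
        t_perm = _two_sample_t(data, p1, ~p1)
        exceed += np.max(np.abs(t_perm)) >= abs_obs
    p_corr_vals = exceed / (n_permutations + 1)

    t_map = np.full(mask.shape, np.nan)
    p_map = np.full(mask.shape, np.nan)
    t_map[mask] = t_obs
    p_map[mask] = p_corr_vals
    return VoxelwiseTestResult(
        t_map=t_map, p_corrected=p_map,
        n_significant=int(np.sum(p_corr_vals < alpha)),
        alpha=alpha, n_permutations=n_permutations,
    )
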