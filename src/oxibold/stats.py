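"""ROI summaries and the cohort statistical battery.

Implements the analysis pipeline applied to regional oxygenation metrics in
an aging cohort: within-ROI plausibility filtering and 5th-95th percentile
trimming, normality-gated group comparisons (Student t vs Mann-Whitney U),
paired region-vs-global contrasts (paired t vs Wilcoxon signed-rank),
Benjamini-Hochberg FDR adjustment within metric families, multiple linear
regression of each metric on age with sex and ICV-normalized volume as
covariates, Pearson age correlations, ICV-normalized volumetrics, laterality
indices, and the 2x2 chi-square for sex balance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .regions import REPORT_REGIONS

__all__ = [
    "RoiSummary",
    "TestResult",
    "RegressionResult",
    "LateralityResult",
    "roi_summary",
    "prepare_masks",
    "compare_groups",
    "compare_region_to_global",
    "bh_adjust",
    "fit_age_model",
    "pearson_age_corr",
    "laterality",
    "volumetrics",
    "chi_square_2x2",
    "run_stats_battery",
]

ALPHA_NORMALITY = 0.05


# ---------------------------------------------------------------------------
# masks and ROI summaries
# ---------------------------------------------------------------------------

def prepare_masks(
    labels: np.ndarray,
    target_shape: tuple[int, ...] | None = None,
    erode_wm: bool = True,
    composites: dict[str, list[int]] | None = None,
    known_labels: set[int] | None = None,
):
    """Per-region boolean masks from an integer label volume.

    Labels are resampled to ``target_shape`` by nearest neighbor if needed;
    the white-matter mask is eroded with a 3x3x3 structuring element when
    ``erode_wm`` (removing boundary voxels contaminated by gray matter).
    Composite regions (whole brain, gray matter, medial temporal lobe) are
    unions of label codes. Unknown label codes are reported, not fatal.

    Returns (masks dict, warnings list).
    """
    from scipy import ndimage

    from .regions import COMPOSITES, LABEL_NAMES

    if not np.issubdtype(labels.dtype, np.integer):
        raise ValueError("labels must be integer-valued")
    if composites is None:
        composites = COMPOSITES
    if known_labels is None:
        known_labels = set(LABEL_NAMES)
    warnings = []
    unknown = sorted(set(np.unique(labels).tolist()) - known_labels)
    if unknown:
        warnings.append(f"unknown label codes ignored: {unknown}")

    if target_shape is not None and tuple(target_shape) != labels.shape:
        zoom = [t / s for t, s in zip(target_shape, labels.shape)]
        labels = ndimage.zoom(labels, zoom, order=0, grid_mode=True, mode="nearest")

    masks = {name: np.isin(labels, codes) for name, codes in composites.items()}
    if erode_wm and "wm" in masks:
        masks["wm"] = ndimage.binary_erosion(masks["wm"], structure=np.ones((3, 3, 3)))
    return masks, warnings


@dataclass
class RoiSummary:
    region: str
    n_total: int
    n_kept: int
    mean: float
    sd: float
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.n_kept > self.n_total:
            raise ValueError("kept count cannot exceed total count")


def roi_summary(values: np.ndarray, mask: np.ndarray, region: str = "") -> RoiSummary:
    """Trimmed ROI summary of a parameter map.

    Voxels are restricted to the mask, then to physiologically plausible
    values (finite and strictly positive), then trimmed to the within-ROI
    [P5, P95] interval (linear-interpolation percentiles, inclusive at both
    bounds). Mean and SD are computed over the retained voxels.
    """
    if mask.sum() == 0:
        raise ValueError("mask is empty")
    v = np.asarray(values)[mask]
    plausible = v[np.isfinite(v) & (v > 0)]
    n_total = int(mask.sum())
    if plausible.size < 2:
        if plausible.size == 1:
            return RoiSummary(region, n_total, 1, float(plausible[0]), 0.0, True)
        return RoiSummary(region, n_total, 0, np.nan, np.nan, True)
    p5, p95 = np.percentile(plausible, [5, 95])
    kept = plausible[(plausible >= p5) & (plausible <= p95)]
    return RoiSummary(
        region, n_total, int(kept.size),
        float(np.mean(kept)), float(np.std(kept, ddof=1)),
        low_confidence=kept.size < 2,
    )


# ---------------------------------------------------------------------------
# hypothesis tests
# ---------------------------------------------------------------------------

@dataclass
class TestResult:
    test: str
    statistic: float
    p: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    effect_size: float = np.nan
    normal_gate: tuple = ()
    mean_diff: float = np.nan
    flag: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.p) and not 0.0 <= self.p <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _shapiro_normal(x: np.ndarray) -> bool:
    if len(x) < 3 or np.ptp(x) == 0:
        return True
    return bool(sps.shapiro(x).pvalue >= ALPHA_NORMALITY)


def compare_groups(a, b) -> TestResult:
    """Two-group comparison with a Shapiro-Wilk normality gate.

    Both groups normal at alpha 0.05: two-sided equal-variance Student t-test
    with a 95% CI on the mean difference; otherwise a two-sided Mann-Whitney
    U test (normal approximation with tie correction). Zero variance in both
    groups with equal means returns p = 1 by convention, flagged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 observations per group")
    gate = (_shapiro_normal(a), _shapiro_normal(b))
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return TestResult("t", 0.0, 1.0, 0.0, 0.0, 0.0, gate, 0.0,
                          flag="degenerate: zero variance, equal means")
    if all(gate):
        res = sps.ttest_ind(a, b, equal_var=True)
        n1, n2 = len(a), len(b)
        df = n1 + n2 - 2
        sp2 = (((n1 - 1) * np.var(a, ddof=1) + (n2 - 1) * np.var(b, ddof=1)) / df)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        diff = float(np.mean(a) - np.mean(b))
        tcrit = sps.t.ppf(0.975, df)
        return TestResult("t", float(res.statistic), float(res.pvalue),
                          diff - tcrit * se, diff + tcrit * se,
                          normal_gate=gate, mean_diff=diff)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return TestResult("mann-whitney", float(res.statistic), float(res.pvalue),
                      normal_gate=gate,
                      mean_diff=float(np.mean(a) - np.mean(b)))


def compare_region_to_global(region_vals, global_vals) -> TestResult:
    """Paired within-subject contrast of a region against the global mean.

    Differences d = region - global are gated by Shapiro-Wilk: paired t-test
    (95% CI from the t distribution) or Wilcoxon signed-rank (zeros dropped).
    Cohen's dz = mean(d) / sd(d). All-zero differences give p = 1.
    """
    r = np.asarray(region_vals, dtype=float)
    g = np.asarray(global_vals, dtype=float)
    if r.shape != g.shape:
        raise ValueError("paired samples must have equal length")
    d = r - g
    n = len(d)
    mean_d = float(np.mean(d))
    sd_d = float(np.std(d, ddof=1)) if n > 1 else 0.0
    dz = mean_d / sd_d if sd_d > 0 else (0.0 if mean_d == 0 else np.inf)
    if np.all(d == 0):
        return TestResult("paired-t", 0.0, 1.0, 0.0, 0.0, 0.0, (True,), 0.0,
                          flag="degenerate: all differences zero")
    if _shapiro_normal(d):
        res = sps.ttest_rel(r, g)
        se = sd_d / np.sqrt(n)
        tcrit = sps.t.ppf(0.975, n - 1)
        return TestResult("paired-t", float(res.statistic), float(res.pvalue),
                          mean_d - tcrit * se, mean_d + tcrit * se,
                          effect_size=dz, normal_gate=(True,), mean_diff=mean_d)
    nz = d[d != 0]
    res = sps.wilcoxon(nz)
    return TestResult("wilcoxon", float(res.statistic), float(res.pvalue),
                      effect_size=dz, normal_gate=(False,), mean_diff=mean_d)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values.

    q(i) = min_{j >= i} p(j) * m / j over the ascending-sorted p-values,
    mapped back to input order and capped at 1. Preserves the order of the
    input p-values and satisfies q >= p elementwise.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class RegressionResult:
    """OLS fit of metric = b0 + b1 age + b2 sex + b3 normalized volume."""

    params: dict
    se: dict
    ci: dict
    p: dict
    std_beta: dict
    r_squared: float
    n: int
    resid_normality_p: float
    heteroscedastic: bool

    def __post_init__(self) -> None:
        for k in self.params:
            lo, hi = self.ci[k]
            if not lo <= self.params[k] <= hi:
                raise ValueError("CI must contain the point estimate")


def fit_age_model(
    df: pd.DataFrame,
    metric: str,
    covariates: tuple[str, ...] = ("age_years", "sex", "norm_volume"),
) -> RegressionResult:
    """Multiple linear regression of a metric on age, sex, normalized volume.

    Ordinary least squares with an intercept; SEs from the unbiased residual
    variance; 95% CIs from the t distribution with n - k - 1 df; standardized
    coefficients from z-scored variables. Residual-normality (Shapiro-Wilk)
    and a Breusch-Pagan heteroscedasticity flag are attached as diagnostics.
    """
    import statsmodels.api as sm
    from statsmodels.stats.diagnostic import het_breuschpagan

    cols = [metric, *covariates]
    data = df[cols].dropna()
    n = len(data)
    if n < len(covariates) + 2:
        raise ValueError(f"need at least {len(covariates) + 2} complete rows")
    y = data[metric].to_numpy(float)
    x = sm.add_constant(data[list(covariates)].to_numpy(float))
    if np.linalg.cond(x) > 1e8:
        raise ValueError(f"collinear design among covariates {covariates}")
    fit = sm.OLS(y, x).fit()
    names = ["intercept", *covariates]
    params = dict(zip(names, fit.params))
    se = dict(zip(names, fit.bse))
    ci_arr = fit.conf_int(alpha=0.05)
    ci = {nm: (float(ci_arr[i][0]), float(ci_arr[i][1])) for i, nm in enumerate(names)}
    pvals = dict(zip(names, fit.pvalues))
    sd_y = np.std(y, ddof=1)
    std_beta = {}
    for i, nm in enumerate(names):
        if nm == "intercept":
            continue
        sd_x = np.std(x[:, i], ddof=1)
        std_beta[nm] = float(fit.params[i] * sd_x / sd_y) if sd_y > 0 else np.nan
    resid = fit.resid
    resid_p = float(sps.shapiro(resid).pvalue) if n >= 3 and np.ptp(resid) > 0 else 1.0
    try:
        bp_p = het_breuschpagan(resid, x)[1]
    except Exception:
        bp_p = 1.0
    return RegressionResult(
        params={k: float(v) for k, v in params.items()},
        se={k: float(v) for k, v in se.items()},
        ci=ci,
        p={k: float(v) for k, v in pvals.items()},
        std_beta=std_beta,
        r_squared=float(fit.rsquared),
        n=n,
        resid_normality_p=resid_p,
        heteroscedastic=bool(bp_p < 0.05),
    )


def pearson_age_corr(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with the two-tailed p-value from
    the exact t transform t = r sqrt((n-2)/(1-r^2))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class LateralityResult:
    mean_li: float
    sd_li: float
    ci_low: float
    ci_high: float
    p: float
    effect_size: float
    test: str
    n_excluded: int = 0


def laterality(right, left) -> LateralityResult:
    """Laterality index LI = (Right - Left)/(Right + Left) per subject,
    tested against zero (one-sample t or Wilcoxon signed-rank per the
    Shapiro-Wilk gate). Positive LI = rightward asymmetry. Subjects with
    right + left = 0 are excluded and counted."""
    r = np.asarray(right, dtype=float)
    l = np.asarray(left, dtype=float)
    if r.shape != l.shape:
        raise ValueError("paired samples must have equal length")
    denom = r + l
    keep = denom != 0
    n_excluded = int(np.sum(~keep))
    li = (r[keep] - l[keep]) / denom[keep]
    n = li.size
    mean_li = float(np.mean(li))
    sd_li = float(np.std(li, ddof=1)) if n > 1 else 0.0
    dz = mean_li / sd_li if sd_li > 0 else 0.0
    se = sd_li / np.sqrt(n) if n else np.nan
    tcrit = sps.t.ppf(0.975, n - 1) if n > 1 else np.nan
    if np.all(li == 0):
        return LateralityResult(0.0, 0.0, 0.0, 0.0, 1.0, 0.0, "one-sample-t",
                                n_excluded)
    if _shapiro_normal(li):
        res = sps.ttest_1samp(li, 0.0)
        return LateralityResult(mean_li, sd_li, mean_li - tcrit * se,
                                mean_li + tcrit * se, float(res.pvalue), dz,
                                "one-sample-t", n_excluded)
    nz = li[li != 0]
    res = sps.wilcoxon(nz)
    return LateralityResult(mean_li, sd_li, mean_li - tcrit * se,
                            mean_li + tcrit * se, float(res.pvalue), dz,
                            "wilcoxon", n_excluded)


def volumetrics(gm: float, wm: float, csf: float,
                regional: dict[str, float] | None = None) -> dict:
    """ICV normalization: ICV = GM + WM + CSF; every volume expressed as
    percent of ICV; gray/whole-brain and white/whole-brain ratios with
    WB = GM + WM."""
    for name, v in (("gm", gm), ("wm", wm), ("csf", csf)):
        if v < 0:
            raise ValueError(f"{name} volume must be >= 0")
    icv = gm + wm + csf
    if icv <= 0:
        raise ValueError("ICV must be > 0")
    wb = gm + wm
    out = {
        "icv_ml": icv,
        "wb_ml": wb,
        "gm_pct_icv": 100.0 * gm / icv,
        "wm_pct_icv": 100.0 * wm / icv,
        "csf_pct_icv": 100.0 * csf / icv,
        "wb_pct_icv": 100.0 * wb / icv,
        "gm_over_wb": gm / wb if wb > 0 else np.nan,
        "wm_over_wb": wm / wb if wb > 0 else np.nan,
    }
    if regional:
        for name, v in regional.items():
            if v < 0:
                raise ValueError(f"{name} volume must be >= 0")
            out[f"{name}_pct_icv"] = 100.0 * v / icv
    return out


def chi_square_2x2(counts) -> TestResult:
    """Pearson chi-square on a 2x2 contingency table, no continuity
    correction, df = 1, two-sided p."""
    tab = np.asarray(counts)
    if tab.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(tab < 0) or not np.issubdtype(tab.dtype, np.integer):
        raise ValueError("counts must be nonnegative integers")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("all margins must be > 0")
    chi2, p, dof, _ = sps.chi2_contingency(tab, correction=False)
    return TestResult("chi-square", float(chi2), float(p))


# ---------------------------------------------------------------------------
# full battery
# ---------------------------------------------------------------------------

METRICS = ("oef", "cbf", "cmro2")
LATERAL_METRIC_REGIONS = ("hc", "ag")
LATERAL_VOLUME_REGIONS = ("hc", "ag", "thl")
VOLUME_REGIONS = ("hc", "ag", "thl")


def run_stats_battery(
    cohort: pd.DataFrame,
    regions: list[str] | None = None,
    regression_family: list[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Run the full cohort analysis battery on a per-subject table.

    Emits one DataFrame per analysis family:

    * ``group`` — young vs old comparison per metric and region, BH-adjusted
      within each metric family (m = number of regions);
    * ``region_vs_global`` — paired region-minus-whole-brain contrasts per
      group and metric, BH within each (metric, group) family;
    * ``regression`` — age model per metric and region, BH on the age
      coefficient within each metric family (family size configurable via
      ``regression_family``);
    * ``correlation`` — Pearson age correlations per metric and region;
    * ``volumes`` — group comparisons of raw and ICV-normalized volumes;
    * ``laterality`` — LI tests per group for the lateralized structures;
    * ``sex`` — the 2x2 group-by-sex chi-square.
    """
    if regions is None:
        regions = list(REPORT_REGIONS)
    missing = [f"{r}_{m}" for r in regions for m in METRICS
               if f"{r}_{m}" not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing[:6]}")
    if not {"young", "old"} <= set(cohort["group"].unique()):
        raise ValueError("cohort must contain both 'young' and 'old' groups")
    young = cohort[cohort["group"] == "young"]
    old = cohort[cohort["group"] == "old"]

    # group comparisons, BH within metric family
    rows = []
    for metric in METRICS:
        for region in regions:
            col = f"{region}_{metric}"
            res = compare_groups(young[col], old[col])
            rows.append({
                "family": metric, "region": region, "test": res.test,
                "statistic": res.statistic, "p": res.p,
                "mean_young": float(young[col].mean()),
                "mean_old": float(old[col].mean()),
                "ci_low": res.ci_low, "ci_high": res.ci_high,
            })
    group_df = pd.DataFrame(rows)
    group_df["q"] = np.concatenate([
        bh_adjust(group_df.loc[group_df.family == m, "p"].to_numpy())
        for m in METRICS
    ])

    # region vs global, per group and metric, BH within each family
    rows = []
    for metric in METRICS:
        for gname, gdf in (("young", young), ("old", old)):
            for region in [r for r in regions if r != "wb"]:
                res = compare_region_to_global(
                    gdf[f"{region}_{metric}"], gdf[f"wb_{metric}"]
                )
                rows.append({
                    "family": metric, "group": gname, "region": region,
                    "test": res.test, "statistic": res.statistic, "p": res.p,
                    "mean_diff": res.mean_diff, "ci_low": res.ci_low,
                    "ci_high": res.ci_high, "cohen_dz": res.effect_size,
                })
    paired_df = pd.DataFrame(rows)
    qcols = []
    for metric in METRICS:
        for gname in ("young", "old"):
            sel = (paired_df.family == metric) & (paired_df.group == gname)
            qcols.append(bh_adjust(paired_df.loc[sel, "p"].to_numpy()))
    paired_df["q"] = np.concatenate(qcols)

    # regressions: metric ~ age + sex + normalized volume
    reg_regions = regression_family if regression_family is not None else regions
    work = cohort.copy()
    icv = work["gm_volume_ml"] + work["wm_volume_ml"] + work["csf_volume_ml"]
    rows = []
    for metric in METRICS:
        for region in reg_regions:
            vol_col = f"{region}_volume_ml"
            if vol_col in work.columns:
                work["norm_volume"] = 100.0 * work[vol_col] / icv
            else:
                wb = work["gm_volume_ml"] + work["wm_volume_ml"]
                work["norm_volume"] = 100.0 * wb / icv
            res = fit_age_model(work, f"{region}_{metric}")
            rows.append({
                "family": metric, "region": region,
                "coef_age": res.params["age_years"],
                "se_age": res.se["age_years"],
                "p_age": res.p["age_years"],
                "ci_age_low": res.ci["age_years"][0],
                "ci_age_high": res.ci["age_years"][1],
                "std_beta_age": res.std_beta["age_years"],
                "coef_sex": res.params["sex"], "p_sex": res.p["sex"],
                "coef_volume": res.params["norm_volume"],
                "p_volume": res.p["norm_volume"],
                "r_squared": res.r_squared,
            })
    reg_df = pd.DataFrame(rows)
    reg_df["q_age"] = np.concatenate([
        bh_adjust(reg_df.loc[reg_df.family == m, "p_age"].to_numpy())
        for m in METRICS
    ])

    # Pearson age correlations
    rows = []
    for metric in METRICS:
        for region in regions:
            r, p = pearson_age_corr(cohort["age_years"],
                                    cohort[f"{region}_{metric}"])
            rows.append({"family": metric, "region": region, "r": r, "p": p})
    corr_df = pd.DataFrame(rows)

    # volumetrics: group comparisons of raw volumes and derived ratios
    rows = []
    vol_frames = {}
    for gname, gdf in (("young", young), ("old", old)):
        wb = gdf["gm_volume_ml"] + gdf["wm_volume_ml"]
        vol_frames[gname] = pd.DataFrame({
            "wb": wb,
            "gm": gdf["gm_volume_ml"],
            "wm": gdf["wm_volume_ml"],
            "gm_over_wb": gdf["gm_volume_ml"] / wb,
            "wm_over_wb": gdf["wm_volume_ml"] / wb,
            **{r: gdf[f"{r}_volume_ml"] for r in VOLUME_REGIONS
               if f"{r}_volume_ml" in gdf.columns},
        })
    for col in vol_frames["young"].columns:
        res = compare_groups(vol_frames["young"][col], vol_frames["old"][col])
        rows.append({
            "measure": col, "test": res.test, "statistic": res.statistic,
            "p": res.p,
            "mean_young": float(vol_frames["young"][col].mean()),
            "mean_old": float(vol_frames["old"][col].mean()),
        })
    vol_df = pd.DataFrame(rows)
    vol_df["q"] = bh_adjust(vol_df["p"].to_numpy())

    # laterality: metrics for hippocampus/amygdala, volumes + thalamus
    rows = []
    for gname, gdf in (("young", young), ("old", old)):
        for metric in METRICS:
            for region in LATERAL_METRIC_REGIONS:
                rc, lc = f"{region}_right_{metric}", f"{region}_left_{metric}"
                if rc not in gdf.columns:
                    continue
                res = laterality(gdf[rc], gdf[lc])
                rows.append({
                    "group": gname, "measure": metric, "region": region,
                    "mean_li": res.mean_li, "sd_li": res.sd_li,
                    "ci_low": res.ci_low, "ci_high": res.ci_high,
                    "p": res.p, "cohen_dz": res.effect_size, "test": res.test,
                })
        for region in LATERAL_VOLUME_REGIONS:
            rc = f"{region}_right_volume_ml"
            lc = f"{region}_left_volume_ml"
            if rc not in gdf.columns:
                continue
            res = laterality(gdf[rc], gdf[lc])
            rows.append({
                "group": gname, "measure": "volume", "region": region,
                "mean_li": res.mean_li, "sd_li": res.sd_li,
                "ci_low": res.ci_low, "ci_high": res.ci_high,
                "p": res.p, "cohen_dz": res.effect_size, "test": res.test,
            })
    lat_df = pd.DataFrame(rows)

    # sex balance chi-square
    tab = np.array([
        [int((young["sex"] == 1).sum()), int((young["sex"] == 0).sum())],
        [int((old["sex"] == 1).sum()), int((old["sex"] == 0).sum())],
    ])
    sex_res = chi_square_2x2(tab)
    sex_df = pd.DataFrame([{
        "young_male": tab[0, 0], "young_female": tab[0, 1],
        "old_male": tab[1, 0], "old_female": tab[1, 1],
        "chi2": sex_res.statistic, "p": sex_res.p,
    }])

    return {
        "group": group_df,
        "region_vs_global": paired_df,
        "regression": reg_df,
        "correlation": corr_df,
        "volumes": vol_df,
        "laterality": lat_df,
        "sex": sex_df,
    }
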