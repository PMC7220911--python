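"""Group-level inference for two-group repeated-measures retinal cohorts.

Each eye contributes one metric value per sampled retinal location, and the
locations within an eye are correlated. Under compound symmetry (equal
correlation rho between any two locations of the same eye) the exact
between-groups test in the balanced design is the nested ANOVA F ratio

    F = MS_group / MS_eye(group),   df = (1, n_eyes - 2)

with the compound-symmetry correlation estimated from the variance
components as

    rho_hat = (MS_eye - MS_within) / (MS_eye + (k - 1) * MS_within)

which is allowed to go negative (a small negative rho is what real retinal
designs show). Unbalanced designs fall back to a Welch two-sample test on
eye means. Normality of residuals is screened with Shapiro-Wilk at a
Bonferroni-corrected level, and homogeneity of eye-level variances with the
Brown-Forsythe (median-centered Levene) test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import QUADRANTS

__all__ = [
    "MixedModelResult",
    "AssumptionCheck",
    "validate_cohort_table",
    "rm_anova_between",
    "check_normality",
    "check_variance_homogeneity",
    "quadrant_analysis",
]


@dataclass(frozen=True)
class MixedModelResult:
    """Between-groups test for one (metric, layer) under repeated measures."""

    metric: str
    layer: str
    effect: float  # AD mean - WT mean (eye-level)
    f_statistic: float
    p_value: float
    rho_hat: float
    n_wt: int
    n_ad: int
    k_locations: int
    balanced: bool
    degenerate: bool = False

    def summary(self) -> str:
        kind = "balanced RM-ANOVA" if self.balanced else "Welch on eye means"
        rho = f"{self.rho_hat:+.4f}" if np.isfinite(self.rho_hat) else "n/a"
        return (
            f"{self.metric}/{self.layer} [{kind}]: effect(AD-WT) = {self.effect:+.5g}, "
            f"F = {self.f_statistic:.4g}, p = {self.p_value:.4g}, rho_hat = {rho} "
            f"(n_WT={self.n_wt}, n_AD={self.n_ad}, k={self.k_locations})"
        )


@dataclass(frozen=True)
class AssumptionCheck:
    name: str
    statistic: float
    p_value: float
    alpha: float
    passed: bool
    degenerate: bool = False


def validate_cohort_table(table: pd.DataFrame) -> None:
    """Check the long-format cohort table invariants."""
    required = {"eye", "group", "location", "layer", "metric", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    if table.duplicated(subset=["eye", "location", "layer", "metric"]).any():
        raise ValueError("(eye, location, layer, metric) must be unique")
    per_eye = table.groupby("eye")["group"].nunique()
    if (per_eye > 1).any():
        bad = per_eye[per_eye > 1].index.tolist()
        raise ValueError(f"group must be constant within eye; offending eyes: {bad}")


def _subset(table: pd.DataFrame, metric: str, layer: str) -> pd.DataFrame:
    sub = table[(table["metric"] == metric) & (table["layer"] == layer)]
    if sub.empty:
        raise ValueError(f"no rows for metric={metric!r}, layer={layer!r}")
    return sub


def rm_anova_between(table: pd.DataFrame, metric: str, layer: str) -> MixedModelResult:
    """Between-groups mixed repeated-measures ANOVA for one metric and layer.

    Balanced designs (every eye measured at the same number of locations)
    use the exact nested-ANOVA F against the eye(group) stratum; unbalanced
    designs collapse to eye means and use a Welch two-sample test.
    """
    sub = _subset(table, metric, layer)
    groups = sub.groupby("eye")["group"].first()
    eyes_by_group = {g: groups[groups == g].index.tolist() for g in ("WT", "AD")}
    n_wt, n_ad = len(eyes_by_group["WT"]), len(eyes_by_group["AD"])
    if n_wt < 2 or n_ad < 2:
        raise ValueError(f"need >= 2 eyes per group, got WT={n_wt}, AD={n_ad}")
    counts = sub.groupby("eye")["value"].count()
    balanced = counts.nunique() == 1
    eye_means = sub.groupby("eye")["value"].mean()
    wt_mean = eye_means[eyes_by_group["WT"]].mean()
    ad_mean = eye_means[eyes_by_group["AD"]].mean()
    effect = float(ad_mean - wt_mean)
    n_eyes = n_wt + n_ad

    if not balanced:
        wt = eye_means[eyes_by_group["WT"]].to_numpy()
        ad = eye_means[eyes_by_group["AD"]].to_numpy()
        t, p = sps.ttest_ind(ad, wt, equal_var=False)
        return MixedModelResult(
            metric=metric, layer=layer, effect=effect,
            f_statistic=float(t**2), p_value=float(p), rho_hat=float("nan"),
            n_wt=n_wt, n_ad=n_ad, k_locations=int(counts.max()), balanced=False,
        )

    k = int(counts.iloc[0])
    grand = float(sub["value"].mean())
    group_means = {g: float(sub[sub["group"] == g]["value"].mean()) for g in ("WT", "AD")}
    ss_group = k * sum(
        len(eyes_by_group[g]) * (group_means[g] - grand) ** 2 for g in ("WT", "AD")
    )
    ss_eye = k * sum(
        (eye_means[e] - group_means[g]) ** 2
        for g in ("WT", "AD")
        for e in eyes_by_group[g]
    )
    resid = sub["value"].to_numpy() - eye_means[sub["eye"]].to_numpy()
    ss_within = float(np.sum(resid**2))

    ms_group = ss_group / 1.0
    df_eye = n_eyes - 2
    ms_eye = ss_eye / df_eye
    degenerate = ms_eye <= 0
    if k > 1:
        ms_within = ss_within / (n_eyes * (k - 1))
        denom_rho = ms_eye + (k - 1) * ms_within
        rho_hat = (ms_eye - ms_within) / denom_rho if denom_rho > 0 else float("nan")
    else:
        rho_hat = float("nan")
    if degenerate:
        f = float("nan") if ms_group == 0 else float("inf")
        p = 1.0 if ms_group == 0 else 0.0
    else:
        f = ms_group / ms_eye
        p = float(sps.f.sf(f, 1, df_eye))
    return MixedModelResult(
        metric=metric, layer=layer, effect=effect,
        f_statistic=float(f), p_value=float(p), rho_hat=float(rho_hat),
        n_wt=n_wt, n_ad=n_ad, k_locations=k, balanced=True, degenerate=degenerate,
    )


def check_normality(
    table: pd.DataFrame, metric: str, layer: str, alpha: float = 0.003
) -> AssumptionCheck:
    """Shapiro-Wilk on within-eye residuals at a Bonferroni-corrected level."""
    sub = _subset(table, metric, layer)
    eye_means = sub.groupby("eye")["value"].transform("mean")
    resid = (sub["value"] - eye_means).to_numpy()
    if resid.size < 3:
        raise ValueError(f"need >= 3 residuals for Shapiro-Wilk, got {resid.size}")
    if np.ptp(resid) == 0:
        return AssumptionCheck("shapiro-wilk", float("nan"), float("nan"), alpha,
                               passed=True, degenerate=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        w, p = sps.shapiro(resid)
    return AssumptionCheck("shapiro-wilk", float(w), float(p), alpha, passed=p > alpha)


def check_variance_homogeneity(
    table: pd.DataFrame, metric: str, layer: str, alpha: float = 0.05
) -> AssumptionCheck:
    """Brown-Forsythe (median-centered Levene) test on eye-level means."""
    sub = _subset(table, metric, layer)
    eye_means = sub.groupby("eye").agg(group=("group", "first"), value=("value", "mean"))
    wt = eye_means[eye_means["group"] == "WT"]["value"].to_numpy()
    ad = eye_means[eye_means["group"] == "AD"]["value"].to_numpy()
    if len(wt) < 2 or len(ad) < 2:
        raise ValueError("need >= 2 eyes per group for Levene's test")
    if np.ptp(wt) == 0 and np.ptp(ad) == 0:
        return AssumptionCheck("levene-median", float("nan"), float("nan"), alpha,
                               passed=True, degenerate=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat, p = sps.levene(wt, ad, center="median")
    return AssumptionCheck("levene-median", float(stat), float(p), alpha, passed=p > alpha)


def quadrant_analysis(
    table: pd.DataFrame, metric: str, layer: str, quadrants: tuple[str, ...]
) -> MixedModelResult:
    """Between-groups test restricted to locations in the named quadrants."""
    if not quadrants:
        raise ValueError("quadrant subset must be non-empty")
    unknown = set(quadrants) - set(QUADRANTS)
    if unknown:
        raise ValueError(f"unknown quadrants: {sorted(unknown)}")
    if "quadrant" not in table.columns:
        raise ValueError("cohort table has no quadrant column")
    sub = table[table["quadrant"].isin(quadrants)]
    if sub.empty:
        raise ValueError(f"no records in quadrants {quadrants}")
    return rm_anova_between(sub, metric, layer)
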