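"""Cohort-level statistics for the gait parameters.

The battery applied per gait parameter across the three frailty
stages:

* one-way ANOVA with the eta-squared effect size, computed from group
  summary statistics (mean, SD, n are sufficient for one-way ANOVA);
* Games-Howell pairwise post-hoc tests (studentized-range based,
  robust to unequal group sizes and variances) with mean-difference
  confidence intervals;
* Cohen's d (pooled-SD standardised mean difference) per pair;
* percent differences between group means;
* ANCOVA: the group effect on a parameter after adjusting for age,
  sex and BMI (partial F on the group indicators, adjusted means at
  the covariate means);
* Spearman rank correlation between gait parameters and phenotype
  measures;
* Pearson chi-squared (no continuity correction) for 2x2 tables of
  categorical characteristics.

Summary-statistic entry points are first class: every test that can
run from printed group summaries does, so published tables can be
re-analysed without raw data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "PairwiseResult",
    "AncovaResult",
    "anova_eta2",
    "cohens_d",
    "games_howell",
    "percent_difference",
    "ancova_group_effect",
    "spearman",
    "chi2_pairwise",
    "eta_squared_label",
    "cohens_d_label",
    "stat_report",
]

#: Conventional interpretation bands for eta-squared.
ETA2_BANDS = {"small": 0.01, "medium": 0.06, "large": 0.14}
#: Conventional interpretation bands for Cohen's d.
COHEN_D_BANDS = {"small": 0.2, "medium": 0.5, "large": 0.8}


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics for one group: label, n, mean, sd."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be at least 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    @staticmethod
    def from_data(label: str, values: Sequence[float]) -> "GroupSummary":
        v = np.asarray(values, dtype=float)
        return GroupSummary(label, v.size, float(v.mean()), float(v.std(ddof=1)))


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    eta_squared: float
    df_between: int
    df_within: int


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple
    p: float
    cohen_d: float
    mean_difference: float
    ci_lower: float
    ci_upper: float
    df: float


@dataclass(frozen=True)
class AncovaResult:
    F: float
    p: float
    df_group: int
    df_resid: int
    adjusted_means: dict


def anova_eta2(groups: Sequence[GroupSummary]) -> AnovaResult:
    """One-way ANOVA and eta-squared from group summaries.

    eta^2 = SS_between / (SS_between + SS_within); F and p follow from
    the same sums of squares, so the result equals a raw-data ANOVA on
    any sample having exactly these summaries.  Zero total variance
    returns F = 0, p = 1, eta^2 = 0 by convention.
    """
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups])
    sds = np.array([g.sd for g in groups])
    grand = float(np.sum(ns * means) / ns.sum())
    ss_b = float(np.sum(ns * (means - grand) ** 2))
    ss_w = float(np.sum((ns - 1) * sds**2))
    df_b = len(groups) - 1
    df_w = int(ns.sum()) - len(groups)
    if ss_b + ss_w <= 0:
        return AnovaResult(0.0, 1.0, 0.0, df_b, df_w)
    if ss_w == 0:
        return AnovaResult(float("inf"), 0.0, 1.0, df_b, df_w)
    F = (ss_b / df_b) / (ss_w / df_w)
    p = float(sps.f.sf(F, df_b, df_w))
    return AnovaResult(float(F), p, ss_b / (ss_b + ss_w), df_b, df_w)


def cohens_d(m1: float, s1: float, n1: int, m2: float, s2: float, n2: int) -> float:
    """Pooled-SD standardised mean difference (magnitude).

    d = |m1 - m2| / s_pooled with
    s_pooled = sqrt(((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2)).
    Equal means give d = 0 even when the pooled SD vanishes; a zero
    pooled SD with unequal means is an infinite effect and raises.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two observations")
    diff = abs(m1 - m2)
    pooled = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    if pooled == 0:
        if diff == 0:
            return 0.0
        raise ZeroDivisionError(
            "zero pooled SD with unequal means: effect size is unbounded"
        )
    return float(diff / pooled)


def _welch_df(s1: float, n1: int, s2: float, n2: int) -> float:
    v1, v2 = s1**2 / n1, s2**2 / n2
    if v1 + v2 == 0:
        return float(n1 + n2 - 2)
    return (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))


def games_howell(
    groups: Sequence[GroupSummary], alpha: float = 0.05
) -> list[PairwiseResult]:
    """Games-Howell pairwise comparisons from group summaries.

    Per pair: SE = sqrt(s1^2/n1 + s2^2/n2), Welch-Satterthwaite df,
    q = |dm| * sqrt(2) / SE referred to the studentized-range
    distribution with k groups, and the mean-difference CI
    dm -/+ q_crit(alpha, k, df) * SE / sqrt(2).  Cohen's d is attached
    to each pair for reporting.
    """
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    k = len(groups)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = groups[i], groups[j]
            se = np.sqrt(a.sd**2 / a.n + b.sd**2 / b.n)
            df = _welch_df(a.sd, a.n, b.sd, b.n)
            if df < 1:
                raise ValueError(
                    f"Welch df < 1 for pair ({a.label}, {b.label}); "
                    "comparison undefined"
                )
            dm = a.mean - b.mean
            if se == 0:
                p = 1.0 if dm == 0 else 0.0
                half = 0.0
            else:
                q = abs(dm) * np.sqrt(2) / se
                p = float(sps.studentized_range.sf(q, k, df))
                q_crit = float(sps.studentized_range.ppf(1 - alpha, k, df))
                half = q_crit * se / np.sqrt(2)
            out.append(
                PairwiseResult(
                    pair=(a.label, b.label),
                    p=p,
                    cohen_d=cohens_d(a.mean, a.sd, a.n, b.mean, b.sd, b.n),
                    mean_difference=float(dm),
                    ci_lower=float(dm - half),
                    ci_upper=float(dm + half),
                    df=float(df),
                )
            )
    return out


def percent_difference(a: float, ref: float) -> float:
    """Percent difference of ``a`` relative to ``ref``: 100 (a - ref)/ref."""
    if ref == 0:
        raise ZeroDivisionError("reference mean is zero")
    return 100.0 * (a - ref) / ref


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with tie-averaged ranks.

    rho is the Pearson correlation of average ranks; p follows the
    usual t approximation.  Constant input has no defined rank
    correlation and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("rank correlation undefined for constant input")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def chi2_pairwise(counts) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 table, df = 1, no continuity correction."""
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("counts must form a 2x2 table")
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("counts must be non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("table has a zero margin")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def ancova_group_effect(
    table: pd.DataFrame,
    outcome: str,
    group: str = "stage",
    covariates: Sequence[str] = ("age", "sex", "bmi"),
) -> AncovaResult:
    """Group effect on an outcome adjusting for covariates.

    Fits the linear model outcome ~ group indicators + covariates
    (categorical covariates are dummy-coded) and tests the group
    factor with a partial F — the Type III test for a main effect in
    an additive model.  Adjusted group means are the model predictions
    at the covariate means.
    """
    df = table.dropna(subset=[outcome, group, *covariates])
    y = df[outcome].to_numpy(dtype=float)
    n = y.size
    levels = pd.unique(df[group])
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    G = pd.get_dummies(df[group], drop_first=True).to_numpy(dtype=float)
    cov_blocks = []
    for c in covariates:
        col = df[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            cov_blocks.append(pd.get_dummies(col, drop_first=True).to_numpy(dtype=float))
        else:
            cov_blocks.append(col.to_numpy(dtype=float)[:, None])
    C = np.hstack(cov_blocks) if cov_blocks else np.empty((n, 0))
    X_full = np.hstack([np.ones((n, 1)), G, C])
    X_red = np.hstack([np.ones((n, 1)), C])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("rank-deficient design matrix")

    def _rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r), beta

    rss_full, beta = _rss(X_full)
    rss_red, _ = _rss(X_red)
    df_group = G.shape[1]
    df_resid = n - X_full.shape[1]
    if df_resid < 1:
        raise ValueError("not enough residual degrees of freedom")
    F = ((rss_red - rss_full) / df_group) / (rss_full / df_resid)
    p = float(sps.f.sf(F, df_group, df_resid))

    cbar = C.mean(axis=0) if C.size else np.empty(0)
    adjusted = {}
    dummy_levels = list(pd.get_dummies(df[group], drop_first=True).columns)
    base = [lv for lv in levels if lv not in dummy_levels][0]
    for lv in levels:
        g_row = np.array([1.0 if lv == d else 0.0 for d in dummy_levels])
        x = np.concatenate([[1.0], g_row, cbar])
        adjusted[lv] = float(x @ beta)
    adjusted[base] = float(np.concatenate([[1.0], np.zeros(df_group), cbar]) @ beta)
    return AncovaResult(float(F), p, df_group, df_resid, adjusted)


def eta_squared_label(eta2: float) -> str:
    """Interpretation band for eta-squared (small/medium/large)."""
    if eta2 >= ETA2_BANDS["large"]:
        return "large"
    if eta2 >= ETA2_BANDS["medium"]:
        return "medium"
    if eta2 >= ETA2_BANDS["small"]:
        return "small"
    return "negligible"


def cohens_d_label(d: float) -> str:
    """Interpretation band for Cohen's d (small/medium/large)."""
    if d >= COHEN_D_BANDS["large"]:
        return "large"
    if d >= COHEN_D_BANDS["medium"]:
        return "medium"
    if d >= COHEN_D_BANDS["small"]:
        return "small"
    return "negligible"


def stat_report(
    summaries: dict, alpha: float = 0.05
) -> dict:
    """Full per-parameter report from group summaries.

    ``summaries`` maps parameter name -> list of GroupSummary.
    Returns a JSON-serialisable dict mirroring the per-parameter
    layout of a published gait-parameter table: ANOVA p and
    eta-squared plus the three pairwise blocks with p, d and CI.
    """
    report = {}
    for param, groups in summaries.items():
        an = anova_eta2(groups)
        pairs = games_howell(groups, alpha)
        report[param] = {
            "anova": {
                "F": an.F,
                "p": an.p,
                "eta_squared": an.eta_squared,
                "effect_band": eta_squared_label(an.eta_squared),
            },
            "pairwise": [
                {
                    "pair": list(pr.pair),
                    "p": pr.p,
                    "cohen_d": pr.cohen_d,
                    "effect_band": cohens_d_label(pr.cohen_d),
                    "mean_difference": pr.mean_difference,
                    "ci": [pr.ci_lower, pr.ci_upper],
                }
                for pr in pairs
            ],
        }
    return report
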