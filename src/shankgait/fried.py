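"""Fried frailty-phenotype flags and three-stage classification.

The five phenotypes and their operationalisation:

* **shrinking** — unintentional weight loss of at least 4.54 kg
  (10 lbs) in the past year;
* **weakness** — grip strength in the lowest quintile (20%),
  stratified by sex and BMI;
* **slowness** — walking speed over a 4.57 m (15 ft) course in the
  slowest quintile, stratified by sex and height (equivalently, walk
  time in the highest quintile);
* **exhaustion** — depression-questionnaire-derived exhaustion score
  in the worst quintile;
* **low activity** — self-reported activity (kcal-equivalent) in the
  lowest quintile.

Staging by flag count: 0 -> non-frail, 1-2 -> pre-frail,
3 or more -> frail.

Quintile cut-offs use inclusive linear interpolation and ties at the
cut-off are all flagged (the conservative convention); continuous
strata (BMI, height) are binned into within-sex quartiles, since
published operationalisations leave the bin edges open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .reference import SHRINKING_THRESHOLD_KG

__all__ = [
    "PhenotypeMeasures",
    "FriedResult",
    "stratified_lowest_quintile",
    "phenotype_flags",
    "frailty_stage",
    "stage_cohort",
]

PHENOTYPES = ("shrinking", "weakness", "exhaustion", "slowness", "low_activity")
STAGE_BY_COUNT = {0: "non-frail", 1: "pre-frail", 2: "pre-frail"}


@dataclass(frozen=True)
class PhenotypeMeasures:
    """Raw measures needed to score the five phenotypes for one person."""

    weight_loss_kg: float
    grip_kg: float
    walk_time_s: float
    exhaustion_score: float
    activity_score: float
    sex: str
    bmi: float
    height: float


@dataclass(frozen=True)
class FriedResult:
    flags: dict
    count: int
    stage: str


def frailty_stage(flags: Sequence[bool]) -> str:
    """Stage from the five phenotype flags: 0 / 1-2 / >=3 true."""
    flags = list(flags)
    if len(flags) != 5:
        raise ValueError("exactly five phenotype flags are required")
    count = int(sum(bool(f) for f in flags))
    return STAGE_BY_COUNT.get(count, "frail")


def stratified_lowest_quintile(
    values: Sequence[float],
    strata: Sequence | None = None,
    *,
    quantile: float = 0.20,
    higher_is_worse: bool = False,
) -> np.ndarray:
    """Flag the worst quintile within each stratum.

    By default the *lowest* 20% of each stratum is flagged (lower is
    worse, e.g. grip strength or activity); with
    ``higher_is_worse=True`` the highest 20% is flagged (e.g. walk
    time).  The cut-off is the within-stratum 20th (or 80th)
    percentile with inclusive linear interpolation; values tied with
    the cut-off are flagged.

    NaN values are never flagged (missing measure).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("values must be non-empty")
    if strata is None:
        strata = np.zeros(values.size)
    strata = np.asarray(strata)
    if strata.size != values.size:
        raise ValueError("values and strata must have the same length")
    flags = np.zeros(values.size, dtype=bool)
    for s in pd.unique(strata):
        mask = strata == s
        v = values[mask]
        ok = np.isfinite(v)
        if not ok.any():
            continue
        if higher_is_worse:
            cut = np.quantile(v[ok], 1 - quantile)
            flags[mask] = np.where(ok, v >= cut - 1e-12, False)
        else:
            cut = np.quantile(v[ok], quantile)
            flags[mask] = np.where(ok, v <= cut + 1e-12, False)
    return flags


def _sex_by_quartile_strata(sex: np.ndarray, cont: np.ndarray, n_bins: int = 4):
    """Sex x quartile-bin strata labels for a continuous covariate."""
    labels = np.empty(len(sex), dtype=object)
    for s in pd.unique(sex):
        m = sex == s
        x = cont[m]
        if np.unique(x[np.isfinite(x)]).size < n_bins:
            labels[m] = [f"{s}:0"] * int(m.sum())
            continue
        bins = pd.qcut(x, n_bins, labels=False, duplicates="drop")
        labels[m] = [f"{s}:{b}" for b in np.asarray(bins)]
    return labels


def phenotype_flags(
    measures: PhenotypeMeasures,
    cohort: Sequence[PhenotypeMeasures],
) -> dict:
    """Score one person's five flags against a reference cohort.

    The quintile criteria are cohort-relative, so the person is scored
    jointly with the cohort.  A missing (NaN) measure yields ``None``
    for that flag — undetermined, surfaced explicitly rather than
    silently false.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be non-empty (quintiles are cohort-relative)")
    everyone = [measures, *cohort]
    df = pd.DataFrame([vars(m) for m in everyone])
    flags = cohort_flags(df)
    out = {}
    for p in PHENOTYPES:
        val = flags[p].iloc[0]
        out[p] = None if pd.isna(val) else bool(val)
    return out


def cohort_flags(df: pd.DataFrame) -> pd.DataFrame:
    """Five phenotype flag columns for a whole cohort table.

    Expects columns ``weight_loss_kg, grip_kg, walk_time_s,
    exhaustion_score, activity_score, sex, bmi`` and ``height`` (or
    ``height_m``).  Returns a DataFrame of nullable booleans (pd.NA
    where the measure is missing).
    """
    height = df["height"] if "height" in df else df["height_m"]
    sex = df["sex"].to_numpy()
    out = pd.DataFrame(index=df.index)

    def _nullable(raw_flags, series):
        return pd.array(
            [pd.NA if not np.isfinite(v) else bool(f)
             for f, v in zip(raw_flags, series.astype(float))],
            dtype="boolean",
        )

    wl = df["weight_loss_kg"].astype(float)
    out["shrinking"] = _nullable((wl >= SHRINKING_THRESHOLD_KG).to_numpy(), wl)
    grip_strata = _sex_by_quartile_strata(sex, df["bmi"].to_numpy(dtype=float))
    out["weakness"] = _nullable(
        stratified_lowest_quintile(df["grip_kg"], grip_strata), df["grip_kg"]
    )
    out["exhaustion"] = _nullable(
        stratified_lowest_quintile(
            df["exhaustion_score"], higher_is_worse=True
        ),
        df["exhaustion_score"],
    )
    walk_strata = _sex_by_quartile_strata(sex, np.asarray(height, dtype=float))
    out["slowness"] = _nullable(
        stratified_lowest_quintile(
            df["walk_time_s"], walk_strata, higher_is_worse=True
        ),
        df["walk_time_s"],
    )
    out["low_activity"] = _nullable(
        stratified_lowest_quintile(df["activity_score"]), df["activity_score"]
    )
    return out


def stage_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Append flags, phenotype count and Fried stage to a cohort table.

    Undetermined flags count as absent for staging but remain NA in
    the flag columns.
    """
    flags = cohort_flags(df)
    out = df.copy()
    for p in PHENOTYPES:
        out[f"flag_{p}"] = flags[p]
    counts = flags.fillna(False).astype(bool).sum(axis=1)
    out["phenotype_count"] = counts
    out["fried_stage"] = [
        STAGE_BY_COUNT.get(int(c), "frail") for c in counts
    ]
    return out


def fried_result(flags: dict) -> FriedResult:
    determined = {p: bool(flags[p]) for p in PHENOTYPES if flags[p] is not None}
    count = sum(determined.values())
    return FriedResult(flags=dict(flags), count=count,
                       stage=STAGE_BY_COUNT.get(count, "frail"))
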