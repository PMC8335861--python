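"""Analysis covariate construction.

Codes the raw panel into the variables the growth model consumes: a birth
cohort score 1–4 (treated as continuous downstream), age centered at the
cohort median (separating age from cohort variation) and its square,
education indicators with middle-school-or-higher as reference fixed at the
baseline-wave value, rural hukou, base-10 log per-capita household income,
median-split expenditure dummies (ties assigned upward), out-of-pocket
ratios, and a died/lost-to-follow-up attrition indicator.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import CohortRangeError, DataError
from .panel import PanelDataset, as_frame

log = logging.getLogger(__name__)

#: Default cohort bands (inclusive birth-year intervals), coded 1..4.
DEFAULT_BOUNDARIES = ((1942, 1947), (1948, 1953), (1954, 1959), (1960, 1964))
#: Alternative bands supported by configuration.
ALT_BOUNDARIES = ((1942, 1946), (1947, 1953), (1954, 1959), (1960, 1964))

EDUCATION_LEVELS = ("illiterate", "elementary", "middle_or_higher")

#: Expenditure amounts that get pooled median-split dummies (Q2 = 1).
EXPENDITURE_COLUMNS = ("hosp_oop", "hosp_fee", "doctor_oop", "doctor_fee")


def assign_cohort(birth_year: int, boundaries=DEFAULT_BOUNDARIES) -> int:
    """Map a birth year to its cohort score 1..4; raise if out of span."""
    for k, (lo, hi) in enumerate(boundaries, start=1):
        if lo <= birth_year <= hi:
            return k
    span = (boundaries[0][0], boundaries[-1][1])
    raise CohortRangeError(
        f"birth year {birth_year} outside cohort span {span[0]}–{span[1]}"
    )


def assign_cohorts(birth_years: pd.Series, boundaries=DEFAULT_BOUNDARIES) -> pd.Series:
    """Vectorised cohort assignment; out-of-span years become <NA> (logged)."""
    out = pd.Series(pd.NA, index=birth_years.index, dtype="Int64")
    for k, (lo, hi) in enumerate(boundaries, start=1):
        out[(birth_years >= lo) & (birth_years <= hi)] = k
    n_excluded = int(out.isna().sum())
    if n_excluded:
        log.info("excluded %d records with birth year outside cohort span", n_excluded)
    return out


def lower_median(values) -> float:
    """Median taking the lower of the two central order statistics on even n."""
    arr = np.sort(np.asarray(values, dtype=float))
    if arr.size == 0:
        raise DataError("median of empty set")
    return float(arr[(arr.size - 1) // 2])


def center_age(df: pd.DataFrame, medians: dict | None = None):
    """Center age at the cohort median over all observed person-waves.

    Returns ``(age_c, medians)`` where ``medians`` maps cohort -> median age
    (lower-median convention on even counts).
    """
    if medians is None:
        medians = {
            int(c): lower_median(g["age"]) for c, g in df.groupby("cohort")
        }
    med = df["cohort"].map(medians)
    if med.isna().any():
        missing = sorted(df.loc[med.isna(), "cohort"].unique())
        raise DataError(f"no age median available for cohorts {missing}")
    return (df["age"] - med).astype(float), medians


def code_panel(
    panel,
    boundaries=DEFAULT_BOUNDARIES,
    income_floor: float = 1.0,
    income_log_base: float = 10.0,
    median_split: str = "pooled",
    attrition_dummy: str = "combined",
    age_medians: dict | None = None,
) -> PanelDataset:
    """Produce the fully coded analysis panel.

    Coding is idempotent: all derived columns are recomputed from the raw
    fields, so recoding a coded panel reproduces it.  The applied rules are
    recorded in ``meta['codebook']``.
    """
    if median_split not in ("pooled", "per_wave"):
        raise DataError(f"median_split must be 'pooled' or 'per_wave': {median_split}")
    if attrition_dummy not in ("combined", "split"):
        raise DataError(f"attrition_dummy must be 'combined' or 'split'")
    df = as_frame(panel).copy()

    # Birth cohort 1..4; out-of-span records are excluded with a logged count.
    df["cohort"] = assign_cohorts(df["birth_year"], boundaries)
    df = df[df["cohort"].notna()].copy()
    df["cohort"] = df["cohort"].astype(int)

    # Education fixed at the baseline-wave (first observed) value per person.
    df = df.sort_values(["person_id", "wave_year"]).reset_index(drop=True)
    baseline_edu = df.groupby("person_id")["education"].transform("first")
    n_vary = int((df["education"] != baseline_edu).sum())
    if n_vary:
        log.info("collapsed %d within-person education changes to baseline", n_vary)
    df["education_baseline"] = baseline_edu
    df["edu_illiterate"] = (baseline_edu == "illiterate").astype(int)
    df["edu_elementary"] = (baseline_edu == "elementary").astype(int)

    # Log per-capita household income with a positive floor for zero incomes.
    income = df["income_pc"].astype(float)
    n_floored = int((income < income_floor).sum())
    if n_floored:
        log.info("floored %d nonpositive/low incomes at %s", n_floored, income_floor)
    df["log_income"] = np.log(income.clip(lower=income_floor)) / np.log(income_log_base)

    # Cohort-median age centering.
    df["age_c"], medians = center_age(df, age_medians)
    df["age_c2"] = df["age_c"] ** 2

    # Expenditure median splits: second quartile, ties assigned upward (>= Q2 -> 1).
    split_medians = {}
    for col in EXPENDITURE_COLUMNS:
        if col not in df.columns:
            continue
        if median_split == "pooled":
            med = float(np.median(df[col].dropna()))
            df[f"{col}_q2"] = (df[col] >= med).astype(int)
            split_medians[col] = med
        else:
            med = df.groupby("wave_year")[col].transform("median")
            df[f"{col}_q2"] = (df[col] >= med).astype(int)
            split_medians[col] = "per_wave"

    # Attrition indicator: 1 for every record of a person who died or was
    # lost to follow-up before the final wave.
    exited = df["exit_type"].isin(("died", "lost"))
    person_exit = exited.groupby(df["person_id"]).transform("max")
    if attrition_dummy == "combined":
        df["died_or_lost"] = person_exit.astype(int)
    else:
        for kind in ("died", "lost"):
            flag = (df["exit_type"] == kind).groupby(df["person_id"]).transform("max")
            df[kind] = flag.astype(int)
        df["died_or_lost"] = person_exit.astype(int)

    codebook = {
        "cohort_boundaries": [list(b) for b in boundaries],
        "cohort_scale": "continuous 1-4",
        "age_centering": {
            "statistic": "lower median per cohort over observed person-waves",
            "medians": {str(k): v for k, v in medians.items()},
        },
        "education": "baseline-wave value; indicators for illiterate/elementary, "
        "middle-or-higher reference",
        "income": {"log_base": income_log_base, "floor": income_floor},
        "expenditure_split": {"mode": median_split, "ties": "upward (>= Q2 -> 1)",
                              "medians": split_medians},
        "attrition_dummy": attrition_dummy,
    }
    meta = dict(panel.meta) if isinstance(panel, PanelDataset) else {}
    meta["codebook"] = codebook
    return PanelDataset(data=df, meta=meta)
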