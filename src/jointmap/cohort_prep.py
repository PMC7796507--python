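"""Individual-level cohort ingestion and derived variables.

The cohort is a person-level table (one row per adult) carrying district
membership, the two binary outcomes, and the demographic / socioeconomic /
anthropometric / behavioural covariates.  In memory it is a plain pandas
DataFrame with canonical column names; :func:`read_individuals` maps a CSV
with arbitrary headers onto those names through a schema dictionary.

Outcome definitions
-------------------
Hypertension: mean systolic BP >= 140 mmHg, or mean diastolic >= 90 mmHg
(averaging up to three sequential readings), or self-reported hypertension
with current antihypertensive medication use.  Below 120/80 is
normotensive; systolic 120-139 or diastolic 80-89 (without meeting the
hypertension rule) is prehypertensive.  Diabetes is self-report only
("ever told by a health professional").  Comorbidity is having both.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "read_individuals",
    "classify_bp_status",
    "classify_bp_table",
    "derive_anthropometrics",
    "add_anthropometrics",
    "wealth_index",
    "comorbidity_flag",
    "prevalence_by_group",
]

#: canonical roles; only person_id and district_id are always required
CORE_ROLES = ("person_id", "district_id")

_NUMERIC_ROLES = {
    "age", "schooling_years", "weight_kg", "height_cm", "waist_cm",
    "sbp1", "sbp2", "sbp3", "dbp1", "dbp2", "dbp3",
}
_BINARY_ROLES = {
    "y_htn", "y_dm", "self_report_htn", "on_antihypertensives", "employed",
    "salt_at_table", "vigorous_pa", "ever_alcohol", "ever_tobacco",
    "govt_support",
}


def read_individuals(path, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a cohort CSV and rename columns to canonical roles.

    ``schema`` maps role -> CSV column name; roles already matching the CSV
    header may be omitted.  Rows whose typed fields fail coercion (e.g. sex
    outside {male, female}, non-numeric blood pressure) are dropped and the
    count is logged.
    """
    df = pd.read_csv(
        path,
        dtype={"person_id": str, "district_id": str},
        float_precision="round_trip",
    )
    if df.empty:
        raise ValueError(f"cohort file {path} contains no rows")
    schema = dict(schema or {})
    rename = {col: role for role, col in schema.items() if col in df.columns}
    df = df.rename(columns=rename)
    missing = [r for r in CORE_ROLES if r not in df.columns]
    if missing:
        raise ValueError(f"required roles missing from cohort: {missing}")
    df["person_id"] = df["person_id"].astype(str)
    df["district_id"] = df["district_id"].astype(str)

    n0 = len(df)
    bad = pd.Series(False, index=df.index)
    if "sex" in df.columns:
        sex = df["sex"].astype(str).str.lower()
        ok = sex.isin(["male", "female"])
        df["sex"] = sex
        bad |= ~ok
    for role in _NUMERIC_ROLES & set(df.columns):
        coerced = pd.to_numeric(df[role], errors="coerce")
        bad |= coerced.isna() & df[role].notna()
        df[role] = coerced
    for role in _BINARY_ROLES & set(df.columns):
        coerced = pd.to_numeric(df[role], errors="coerce")
        bad |= df[role].notna() & ~coerced.isin([0, 1])
        df[role] = coerced
    if bad.any():
        logger.warning("dropping %d rows failing type coercion", int(bad.sum()))
        df = df.loc[~bad]
    if df.empty:
        raise ValueError("no rows survived type coercion")
    logger.info("read %d of %d cohort rows", len(df), n0)
    return df.reset_index(drop=True)


def classify_bp_status(
    sbp: Sequence[float],
    dbp: Sequence[float],
    self_report: int | None = 0,
    on_meds: int | None = 0,
) -> tuple[str, float]:
    """Classify one person's blood-pressure status.

    Returns ``(category, hypertension_flag)`` where category is one of
    ``normotensive``, ``prehypertensive``, ``hypertensive`` or ``missing``.
    Hypertensive if mean SBP >= 140 or mean DBP >= 90 or (self-reported
    hypertension with current medication use); normotensive if below
    120/80; otherwise prehypertensive.
    """
    sbp_vals = [v for v in np.atleast_1d(sbp) if v is not None and np.isfinite(v)]
    dbp_vals = [v for v in np.atleast_1d(dbp) if v is not None and np.isfinite(v)]
    self_report = 0 if self_report is None or (isinstance(self_report, float) and math.isnan(self_report)) else int(self_report)
    on_meds = 0 if on_meds is None or (isinstance(on_meds, float) and math.isnan(on_meds)) else int(on_meds)
    if not sbp_vals or not dbp_vals:
        if self_report and on_meds:
            return "hypertensive", 1.0
        return "missing", float("nan")
    ms, md = float(np.mean(sbp_vals)), float(np.mean(dbp_vals))
    if ms >= 140.0 or md >= 90.0 or (self_report and on_meds):
        return "hypertensive", 1.0
    if ms < 120.0 and md < 80.0:
        return "normotensive", 0.0
    return "prehypertensive", 0.0


def classify_bp_table(table: pd.DataFrame) -> pd.DataFrame:
    """Vectorised wrapper adding ``bp_category`` and ``y_htn_measured``."""
    sbp_cols = [c for c in ("sbp1", "sbp2", "sbp3") if c in table.columns]
    dbp_cols = [c for c in ("dbp1", "dbp2", "dbp3") if c in table.columns]
    cats, flags = [], []
    for _, row in table.iterrows():
        cat, flag = classify_bp_status(
            row[sbp_cols].to_numpy(dtype=float) if sbp_cols else [],
            row[dbp_cols].to_numpy(dtype=float) if dbp_cols else [],
            row.get("self_report_htn", 0),
            row.get("on_antihypertensives", 0),
        )
        cats.append(cat)
        flags.append(flag)
    out = table.copy()
    out["bp_category"] = cats
    out["y_htn_measured"] = flags
    return out


_BMI_BINS = [
    (-np.inf, 18.5, "underweight"),
    (18.5, 25.0, "normal"),
    (25.0, 30.0, "overweight"),
    (30.0, np.inf, "obese"),
]


def derive_anthropometrics(
    weight_kg: float, height_cm: float, waist_cm: float
) -> tuple[float, float, str]:
    """BMI (kg/m^2), waist-to-height ratio, and BMI category.

    Bins are left-closed and disjoint: [18.5, 25), [25, 30), [30, inf);
    heights outside the 100-250 cm plausibility window yield missing values.
    """
    if weight_kg <= 0 or height_cm <= 0 or waist_cm <= 0:
        raise ValueError("anthropometric inputs must be positive")
    if not (100.0 <= height_cm <= 250.0):
        return float("nan"), float("nan"), "missing"
    h_m = height_cm / 100.0
    bmi = weight_kg / (h_m * h_m)
    whtr = waist_cm / height_cm
    for lo, hi, label in _BMI_BINS:
        if lo <= bmi < hi:
            return bmi, whtr, label
    raise AssertionError("BMI bins should partition the positive line")


def add_anthropometrics(table: pd.DataFrame) -> pd.DataFrame:
    """Add bmi / whtr / bmi_category columns derived from raw measurements."""
    out = table.copy()
    vals = [
        derive_anthropometrics(w, h, wc)
        for w, h, wc in zip(out["weight_kg"], out["height_cm"], out["waist_cm"])
    ]
    out["bmi"] = [v[0] for v in vals]
    out["whtr"] = [v[1] for v in vals]
    out["bmi_category"] = [v[2] for v in vals]
    return out


def wealth_index(asset_matrix) -> tuple[np.ndarray, np.ndarray]:
    """Household SES index: first principal component of standardised assets.

    Columns are standardised to mean 0 / sd 1 (constant columns dropped with
    a warning), the score is the projection on the first PC with its sign
    fixed so the asset with the largest absolute loading loads positively,
    and tertiles are cut at the empirical 33.33 / 66.67 percentiles.

    Returns ``(score, tertile)`` with tertile in {1, 2, 3}.
    """
    X = np.asarray(asset_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("asset matrix must be n x p with p >= 2")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 households")
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all asset columns are constant")
    if not keep.all():
        logger.warning("dropping %d constant asset columns", int((~keep).sum()))
        X = X[:, keep]
        sd = sd[keep]
    Z = (X - X.mean(axis=0)) / sd
    # first right-singular vector of Z = leading eigenvector of correlation matrix
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    loading = vt[0]
    if loading[np.argmax(np.abs(loading))] < 0:
        loading = -loading
    score = Z @ loading
    q1, q2 = np.percentile(score, [100 / 3.0, 200 / 3.0])
    tertile = np.where(score <= q1, 1, np.where(score <= q2, 2, 3)).astype(int)
    return score, tertile


def comorbidity_flag(table: pd.DataFrame) -> pd.Series:
    """1 if the person has both hypertension and diabetes, else 0."""
    for col in ("y_htn", "y_dm"):
        if col not in table.columns:
            raise KeyError(f"column {col!r} required for comorbidity")
    return (
        (table["y_htn"].astype(int) & table["y_dm"].astype(int))
        .astype(int)
        .rename("comorbidity")
    )


def _round_half_up(x: float, decimals: int = 1) -> float:
    factor = 10.0 ** decimals
    return math.floor(x * factor + 0.5) / factor


def prevalence_by_group(
    table: pd.DataFrame, outcome: str, group: str
) -> pd.DataFrame:
    """Per-group prevalence table: group, total, count, percent (1 decimal).

    Percentages are 100*count/total rounded half-up to one decimal; an
    overall row labelled ``All`` is appended.  Empty groups are omitted.
    """
    if outcome not in table.columns or group not in table.columns:
        raise KeyError(f"columns {outcome!r} and {group!r} must exist")
    y = table[outcome]
    if not y.dropna().isin([0, 1]).all():
        raise ValueError(f"outcome column {outcome!r} is not binary")
    sub = table.loc[y.notna(), [group, outcome]]
    rows = []
    for g, grp in sub.groupby(group, sort=True, observed=True):
        total = len(grp)
        if total == 0:
            logger.warning("group %r is empty; omitted", g)
            continue
        count = int(grp[outcome].sum())
        rows.append(
            {"group": g, "total": total, "count": count,
             "percent": _round_half_up(100.0 * count / total)}
        )
    total = len(sub)
    count = int(sub[outcome].sum())
    rows.append(
        {"group": "All", "total": total, "count": count,
         "percent": _round_half_up(100.0 * count / total)}
    )
    return pd.DataFrame(rows, columns=["group", "total", "count", "percent"])
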