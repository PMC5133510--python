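"""Phenotype pre-processing for longitudinal blood-pressure data.

Mirrors the standard epidemiological pipeline for analysing blood
pressure in treated cohorts: (1) add back the expected medication effect
(+10 mmHg systolic, +5 mmHg diastolic for medicated exams), (2) derive
mean arterial pressure MAP = 2/3 DBP + 1/3 SBP, (3) collapse the exams
to per-person means, with smoking reduced to an ever-smoked indicator.
The order is fixed: adjust, then MAP, then collapse.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["MED_SBP_ADJUST", "MED_DBP_ADJUST", "adjust_for_medication",
           "compute_map", "collapse_longitudinal", "prepare_analysis_table"]

MED_SBP_ADJUST = 10.0   # mmHg added to SBP for medicated exams
MED_DBP_ADJUST = 5.0    # mmHg added to DBP for medicated exams


def adjust_for_medication(exams: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with +10/+5 mmHg added to medicated exams' SBP/DBP.

    Not idempotent: applying it twice double-adjusts.  Rows where the
    medication flag is missing are a validation error.
    """
    for col in ("SBP", "DBP", "med"):
        if col not in exams.columns:
            raise ValueError(f"exam table lacks required column {col!r}")
    med = exams["med"]
    if med.isna().any():
        bad = exams.index[med.isna()].tolist()
        raise ValueError(f"medication flag missing for rows {bad}")
    out = exams.copy()
    on_med = med.astype(float) == 1.0
    out.loc[on_med, "SBP"] = out.loc[on_med, "SBP"] + MED_SBP_ADJUST
    out.loc[on_med, "DBP"] = out.loc[on_med, "DBP"] + MED_DBP_ADJUST
    return out


def compute_map(sbp, dbp):
    """Mean arterial pressure, MAP = (2*DBP + SBP) / 3, in mmHg."""
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(sbp[~np.isnan(sbp)] <= 0) or np.any(dbp[~np.isnan(dbp)] <= 0):
            raise ValueError("blood pressures must be positive")
    out = (2.0 * dbp + sbp) / 3.0
    return float(out) if out.ndim == 0 else out


def collapse_longitudinal(exams: pd.DataFrame) -> pd.DataFrame:
    """Collapse an exam-level table to one row per individual.

    Means of age/SBP/DBP/MAP are taken over non-missing exams only;
    ever_smoked is 1 iff the individual smoked at any exam.  Individuals
    with zero exams (or all-missing MAP) are dropped with a warning.

    Expects columns: individual_id, exam, age, sex, smoke, SBP, DBP
    (and MAP, computed here if absent).
    """
    df = exams.copy()
    if "MAP" not in df.columns:
        df["MAP"] = compute_map(df["SBP"], df["DBP"])
    grouped = df.groupby("individual_id", sort=False)
    out = grouped.agg(
        mean_age=("age", "mean"),
        mean_SBP=("SBP", "mean"),
        mean_DBP=("DBP", "mean"),
        mean_MAP=("MAP", "mean"),
        ever_smoked=("smoke", "max"),
        sex=("sex", "first"),
        n_exams=("exam", "count"),
    ).reset_index()
    dropped = out["mean_MAP"].isna() | (out["n_exams"] == 0)
    if dropped.any():
        warnings.warn(f"dropping {int(dropped.sum())} individual(s) with no "
                      "usable exams", stacklevel=2)
        out = out[~dropped]
    out["ever_smoked"] = (out["ever_smoked"].astype(float) > 0).astype(int)
    return out.drop(columns="n_exams").reset_index(drop=True)


def prepare_analysis_table(exams: pd.DataFrame) -> pd.DataFrame:
    """Full pipeline: medication adjustment -> MAP -> collapse."""
    adj = adjust_for_medication(exams)
    adj["MAP"] = compute_map(adj["SBP"], adj["DBP"])
    return collapse_longitudinal(adj)
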