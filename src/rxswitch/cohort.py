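"""Cohort construction: depression identification, exclusions, and strata.

The analysis cohort is every participant with at least one prescription
record. A participant with any bipolar, psychosis or substance-abuse
diagnosis — at any date, before or after the index prescription — is
excluded outright. The remaining participants are placed in three nested
strata by their count of depression diagnostic records: ALL (no requirement),
GE1_MDD (at least one record) and GE2_MDD (at least two). Two depression
codes on the same day count separately when the codes differ; identical
(date, code) duplicates count once.
"""

from __future__ import annotations

import pandas as pd

from .model import DxCategory, EXCLUSION_CATEGORIES

__all__ = ["STRATA", "build_cohort", "stratum_ids", "diagnosis_precedes_index"]

STRATA = ("ALL", "GE1_MDD", "GE2_MDD")


def build_cohort(diagnoses: pd.DataFrame, participants: set[str] | pd.Series) -> pd.DataFrame:
    """One membership row per participant with a prescription record.

    Returns columns: participant_id, n_depression_records, excluded,
    exclusion_reason, in_all, in_ge1_mdd, in_ge2_mdd. Exclusion empties all
    strata. ``exclusion_reason`` is the category of the earliest excluding
    record (alphabetical on ties).
    """
    ids = sorted(set(map(str, participants)))
    out = pd.DataFrame({"participant_id": ids})

    if len(diagnoses):
        dx = diagnoses[diagnoses["participant_id"].isin(out["participant_id"])]
    else:
        dx = pd.DataFrame(columns=["participant_id", "event_date", "code_raw", "category"])

    dep = dx[dx["category"] == DxCategory.DEPRESSION.value]
    # distinct (date, code) pairs per participant
    n_dep = (
        dep.drop_duplicates(subset=["participant_id", "event_date", "code_raw"])
        .groupby("participant_id")
        .size()
    )
    out["n_depression_records"] = (
        out["participant_id"].map(n_dep).fillna(0).astype(int)
    )

    excl = dx[dx["category"].isin(EXCLUSION_CATEGORIES)]
    if len(excl):
        first = (
            excl.sort_values(["participant_id", "event_date", "category"], kind="mergesort")
            .groupby("participant_id")
            .first()["category"]
        )
    else:
        first = pd.Series(dtype=object)
    out["exclusion_reason"] = out["participant_id"].map(first)
    out["excluded"] = out["exclusion_reason"].notna()
    out["exclusion_reason"] = out["exclusion_reason"].where(out["excluded"], None)

    ok = ~out["excluded"]
    out["in_all"] = ok
    out["in_ge1_mdd"] = ok & (out["n_depression_records"] >= 1)
    out["in_ge2_mdd"] = ok & (out["n_depression_records"] >= 2)
    return out


_STRATUM_COL = {"ALL": "in_all", "GE1_MDD": "in_ge1_mdd", "GE2_MDD": "in_ge2_mdd"}


def stratum_ids(memberships: pd.DataFrame, stratum: str) -> set[str]:
    col = _STRATUM_COL[stratum]
    return set(memberships.loc[memberships[col], "participant_id"])


def diagnosis_precedes_index(
    memberships: pd.DataFrame,
    diagnoses: pd.DataFrame,
    phenotypes: pd.DataFrame,
) -> pd.DataFrame:
    """Fraction of classified participants whose first depression record is on
    or before the index date, per stratum.

    Eligible participants are switchers/nonswitchers with at least one
    depression record. A stratum with zero eligible participants reports a
    missing proportion (``NaN``), never 0.
    """
    dep = diagnoses[diagnoses["category"] == DxCategory.DEPRESSION.value]
    first_dep = dep.groupby("participant_id")["event_date"].min()

    classified = phenotypes[phenotypes["status"].isin(["SWITCHER", "NONSWITCHER"])]
    merged = classified.merge(memberships, on="participant_id")
    merged = merged[merged["participant_id"].isin(first_dep.index)]
    merged = merged.assign(first_dep=merged["participant_id"].map(first_dep))
    merged = merged.assign(precedes=merged["first_dep"] <= merged["index_date"])

    rows = []
    for stratum, col in _STRATUM_COL.items():
        sub = merged[merged[col]]
        n = len(sub)
        rows.append(
            {
                "stratum": stratum,
                "n_eligible": n,
                "n_preceding": int(sub["precedes"].sum()),
                "proportion": (sub["precedes"].mean() if n else float("nan")),
            }
        )
    return pd.DataFrame(rows)
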