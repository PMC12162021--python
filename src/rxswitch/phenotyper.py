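"""SSRI-switching phenotype: event detection and participant classification.

A switching event is a prescription of a *different* antidepressant (any
antidepressant class, including another SSRI) issued 5–95 days after the
first prescription of an index SSRI. Four criteria qualify an event:

1. the gap lies in the 5–95-day window (the 5-day minimum avoids counting
   overlapping prescriptions — augmentation — as switches);
2. the index SSRI is prescribed at most 3 times over the entire prescribing
   history, so it was not resumed in later treatment episodes;
3. the index SSRI is prescribed at most 2 times strictly before the switch
   date (early switchers);
4. the index SSRI is prescribed at most 2 times strictly after the switch
   date (a brief cross-tapering allowance while still excluding
   augmentation). A same-day index-SSRI issue on the switch date counts as
   "after" under the strict-inequality convention used here.

A participant is a SWITCHER if any valid event exists, else a NONSWITCHER if
some SSRI was issued on at least 3 distinct dates, else UNCLASSIFIED. The
index date is the first prescription date of the index SSRI for both
switchers and nonswitchers.

All thresholds live in :class:`PhenotypeCriteria`. The window may be
anchored on the first index-SSRI prescription (default, matching the index
date definition) or on the most recent index-SSRI prescription before the
candidate switch.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import DrugClass

__all__ = [
    "PhenotypeCriteria",
    "SwitchEvent",
    "find_candidate_switches",
    "classify_participant",
    "phenotype_cohort",
]

_STATUSES = ("SWITCHER", "NONSWITCHER", "UNCLASSIFIED")


@dataclass(frozen=True)
class PhenotypeCriteria:
    """Tunable thresholds of the switching phenotype (defaults per the published algorithm)."""

    min_gap_days: int = 5
    max_gap_days: int = 95
    max_index_rx_total: int = 3
    max_index_rx_before: int = 2
    max_index_rx_after: int = 2
    min_nonswitcher_rx: int = 3
    #: "first" anchors the window on the first index-SSRI prescription;
    #: "last_before" on the most recent one before the candidate switch.
    anchor: str = "first"
    #: optional cap on the gap between consecutive nonswitcher issues; None
    #: imposes no maximum (the default reading of "consecutive").
    max_refill_gap_days: int | None = None

    def __post_init__(self) -> None:
        if self.min_gap_days < 1:
            raise ValueError("min_gap_days must be >= 1")
        if self.max_gap_days <= self.min_gap_days:
            raise ValueError("max_gap_days must exceed min_gap_days")
        for name in ("max_index_rx_total", "max_index_rx_before", "max_index_rx_after", "min_nonswitcher_rx"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.anchor not in ("first", "last_before"):
            raise ValueError("anchor must be 'first' or 'last_before'")


@dataclass(frozen=True)
class SwitchEvent:
    """One candidate index-SSRI → other-antidepressant transition."""

    participant_id: str
    index_ssri: str
    index_date: int  # epoch days
    switch_date: int
    gap_days: int
    post_switch_drug: str
    post_switch_class: str
    criteria_pass: dict = field(compare=False, default_factory=dict)
    valid: bool = False


def _participant_arrays(rx: pd.DataFrame):
    dates = (rx["issue_date"].values.astype("datetime64[D]")).astype(np.int64)
    return dates, rx["drug_canonical"].to_numpy(), rx["drug_class"].to_numpy()


def _find_events(
    pid: str,
    dates: np.ndarray,
    drugs: np.ndarray,
    classes: np.ndarray,
    criteria: PhenotypeCriteria,
) -> list[SwitchEvent]:
    """Events on sorted, deduplicated per-participant arrays (epoch-day ints)."""
    is_ad = classes != DrugClass.NON_AD.value
    ssri_mask = classes == DrugClass.SSRI.value
    if not ssri_mask.any():
        return []
    events: list[SwitchEvent] = []
    for s in np.unique(drugs[ssri_mask]):
        s_dates = np.sort(dates[drugs == s])
        d0 = int(s_dates[0])
        other = is_ad & (drugs != s)
        if not other.any():
            continue
        o_dates = dates[other]
        o_drugs = drugs[other]
        o_classes = classes[other]
        order = np.lexsort((o_drugs, o_dates))
        sl = s_dates.tolist()
        hit = None
        for i in order:
            t = int(o_dates[i])
            if criteria.anchor == "first":
                a = d0
            else:
                j = bisect_left(sl, t)
                a = sl[j - 1] if j > 0 else d0
            gap = t - a
            if criteria.min_gap_days <= gap <= criteria.max_gap_days:
                hit = (t, gap, str(o_drugs[i]), str(o_classes[i]))
                break
        if hit is None:
            continue
        t, gap, post_drug, post_class = hit
        n_total = len(sl)
        n_before = bisect_left(sl, t)
        n_after = n_total - bisect_right(sl, t)
        crit = {
            "gap_in_window": True,
            "total_le_3": n_total <= criteria.max_index_rx_total,
            "before_le_2": n_before <= criteria.max_index_rx_before,
            "after_le_2": n_after <= criteria.max_index_rx_after,
        }
        events.append(
            SwitchEvent(
                participant_id=pid,
                index_ssri=str(s),
                index_date=d0,
                switch_date=t,
                gap_days=gap,
                post_switch_drug=post_drug,
                post_switch_class=post_class,
                criteria_pass=crit,
                valid=all(crit.values()),
            )
        )
    return events


def find_candidate_switches(rx: pd.DataFrame, criteria: PhenotypeCriteria | None = None) -> list[SwitchEvent]:
    """Candidate switching events for one participant's prescription table.

    ``rx`` must be the sorted, deduplicated output of
    :func:`rxswitch.model.read_prescriptions` restricted to one participant.
    For each SSRI ever prescribed, the earliest other-antidepressant
    prescription inside the gap window yields one event, with the four
    criteria evaluated on it. Participants with no SSRI yield no events.
    """
    criteria = criteria or PhenotypeCriteria()
    if rx.empty:
        return []
    pid = str(rx["participant_id"].iloc[0])
    dates, drugs, classes = _participant_arrays(rx)
    return _find_events(pid, dates, drugs, classes, criteria)


def _classify_arrays(
    pid: str,
    dates: np.ndarray,
    drugs: np.ndarray,
    classes: np.ndarray,
    criteria: PhenotypeCriteria,
) -> dict:
    # fast path: a single-drug history can never contain a switch event
    if len(drugs) and (drugs == drugs[0]).all():
        if classes[0] == DrugClass.SSRI.value and criteria.max_refill_gap_days is None:
            count = len(drugs)
            if count >= criteria.min_nonswitcher_rx:
                return {
                    "participant_id": pid,
                    "status": "NONSWITCHER",
                    "index_ssri": str(drugs[0]),
                    "index_date": int(dates.min()),
                    "time_to_switch_days": None,
                    "post_switch_drug": None,
                    "post_switch_class": None,
                    "n_index_ssri_rx": count,
                    "had_invalid_candidate": False,
                }
            return {
                "participant_id": pid,
                "status": "UNCLASSIFIED",
                "index_ssri": None,
                "index_date": None,
                "time_to_switch_days": None,
                "post_switch_drug": None,
                "post_switch_class": None,
                "n_index_ssri_rx": count,
                "had_invalid_candidate": False,
            }
    events = _find_events(pid, dates, drugs, classes, criteria)
    valid = [e for e in events if e.valid]
    if valid:
        winner = min(
            valid,
            key=lambda e: (e.switch_date, e.gap_days, e.post_switch_drug, e.index_ssri),
        )
        n_idx = int((drugs == winner.index_ssri).sum())
        return {
            "participant_id": pid,
            "status": "SWITCHER",
            "index_ssri": winner.index_ssri,
            "index_date": winner.index_date,
            "time_to_switch_days": winner.gap_days,
            "post_switch_drug": winner.post_switch_drug,
            "post_switch_class": winner.post_switch_class,
            "n_index_ssri_rx": n_idx,
            "had_invalid_candidate": len(valid) < len(events),
        }
    # nonswitcher: some SSRI with enough distinct-date issues
    ssri_mask = classes == DrugClass.SSRI.value
    best = None  # (count, name, first_date)
    for s in np.unique(drugs[ssri_mask]):
        s_dates = np.sort(dates[drugs == s])
        if criteria.max_refill_gap_days is not None and len(s_dates) > 1:
            # longest run of consecutive issues within the allowed refill gap
            gaps = np.diff(s_dates)
            run, best_run = 1, 1
            for g in gaps:
                run = run + 1 if g <= criteria.max_refill_gap_days else 1
                best_run = max(best_run, run)
            count = int(best_run)
        else:
            count = len(s_dates)
        if best is None or count > best[0] or (count == best[0] and str(s) < best[1]):
            best = (count, str(s), int(s_dates[0]), len(s_dates))
    if best is not None and best[0] >= criteria.min_nonswitcher_rx:
        return {
            "participant_id": pid,
            "status": "NONSWITCHER",
            "index_ssri": best[1],
            "index_date": best[2],
            "time_to_switch_days": None,
            "post_switch_drug": None,
            "post_switch_class": None,
            "n_index_ssri_rx": best[3],
            "had_invalid_candidate": bool(events),
        }
    return {
        "participant_id": pid,
        "status": "UNCLASSIFIED",
        "index_ssri": None,
        "index_date": None,
        "time_to_switch_days": None,
        "post_switch_drug": None,
        "post_switch_class": None,
        "n_index_ssri_rx": best[3] if best is not None else 0,
        "had_invalid_candidate": bool(events),
    }


def classify_participant(rx: pd.DataFrame, criteria: PhenotypeCriteria | None = None) -> dict:
    """Classify one participant; returns a phenotype-record dict.

    Keys: participant_id, status, index_ssri, index_date (Timestamp or None),
    time_to_switch_days, post_switch_drug, post_switch_class,
    n_index_ssri_rx, had_invalid_candidate.
    """
    criteria = criteria or PhenotypeCriteria()
    pid = str(rx["participant_id"].iloc[0])
    dates, drugs, classes = _participant_arrays(rx)
    rec = _classify_arrays(pid, dates, drugs, classes, criteria)
    if rec["index_date"] is not None:
        rec["index_date"] = pd.Timestamp(np.datetime64(int(rec["index_date"]), "D"))
    return rec


def phenotype_cohort(
    rx: pd.DataFrame,
    memberships: pd.DataFrame | None = None,
    criteria: PhenotypeCriteria | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every non-excluded participant; return (phenotypes, stratum counts).

    ``rx`` is the full sorted prescription table. Excluded participants (per
    ``memberships``) are dropped before classification. The counts table has
    one row per (stratum, status) with the number of participants.
    """
    criteria = criteria or PhenotypeCriteria()
    from .cohort import STRATA  # local import to avoid cycle at module load

    rx_use = rx
    if memberships is not None and len(memberships):
        keep = set(memberships.loc[~memberships["excluded"], "participant_id"])
        rx_use = rx[rx["participant_id"].isin(keep)]

    records: list[dict] = []
    if len(rx_use):
        pids = rx_use["participant_id"].to_numpy()
        dates = rx_use["issue_date"].values.astype("datetime64[D]").astype(np.int64)
        drugs = rx_use["drug_canonical"].to_numpy()
        classes = rx_use["drug_class"].to_numpy()
        # participant boundaries in the (already sorted) table
        change = np.flatnonzero(pids[1:] != pids[:-1]) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(pids)]))
        for a, b in zip(starts, ends):
            records.append(
                _classify_arrays(str(pids[a]), dates[a:b], drugs[a:b], classes[a:b], criteria)
            )

    pheno = pd.DataFrame(
        records,
        columns=[
            "participant_id",
            "status",
            "index_ssri",
            "index_date",
            "time_to_switch_days",
            "post_switch_drug",
            "post_switch_class",
            "n_index_ssri_rx",
            "had_invalid_candidate",
        ],
    )
    if len(pheno):
        pheno["index_date"] = pd.to_datetime(
            pheno["index_date"].map(
                lambda d: np.datetime64(int(d), "D") if pd.notna(d) else np.datetime64("NaT")
            )
        )

    counts_rows = []
    if memberships is not None and len(memberships):
        merged = pheno.merge(memberships, on="participant_id", how="left")
        flags = {"ALL": "in_all", "GE1_MDD": "in_ge1_mdd", "GE2_MDD": "in_ge2_mdd"}
        for stratum in STRATA:
            sub = merged[merged[flags[stratum]].fillna(False).astype(bool)]
            for status in _STATUSES:
                counts_rows.append(
                    {"stratum": stratum, "status": status, "n": int((sub["status"] == status).sum())}
                )
    else:
        for status in _STATUSES:
            counts_rows.append(
                {"stratum": "ALL", "status": status, "n": int((pheno["status"] == status).sum())}
            )
    return pheno, pd.DataFrame(counts_rows)
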