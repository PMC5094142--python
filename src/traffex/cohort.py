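"""Asthma case definition and exacerbation-event detection.

Visits carry a care setting (inpatient, emergency department, outpatient) and
up to three ordered ICD-9-CM diagnosis codes; any code with prefix ``493`` is
asthma.  Two rules operate on them:

* Case definition — a person is an asthma case if they have at least two
  visits, in any setting, with asthma as the *first-listed* diagnosis whose
  dates differ by at most 548 days (an 18-month period).

* Exacerbation events — three kinds: an inpatient hospitalization with
  first-listed asthma; an emergency-department (ED) visit with first-listed
  asthma; or a cluster of three or more outpatient visits with asthma in any
  of the first three diagnosis positions within a two-week window (dates
  spanning fewer than 14 days).  Outpatient clusters are found by a greedy
  left-to-right scan; a same-day ED + inpatient pair collapses into a single
  hospitalization event.

All date arithmetic is in whole days; the input visit order never affects the
result (visits are sorted defensively).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("traffex")

__all__ = [
    "ASTHMA_PREFIX",
    "CASE_WINDOW_DAYS",
    "CLUSTER_WINDOW_DAYS",
    "ExacerbationEvent",
    "identify_cases",
    "detect_exacerbations",
    "detect_all_events",
    "person_outcomes",
]

ASTHMA_PREFIX = "493"
CASE_WINDOW_DAYS = 548      # "18 month period"
CLUSTER_WINDOW_DAYS = 14    # "2-week time period": dates span < 14 days
DX_COLS = ("dx1", "dx2", "dx3")
SETTINGS = ("inpatient", "ed", "outpatient")


@dataclass(frozen=True)
class ExacerbationEvent:
    """One asthma exacerbation.

    ``date`` is the first visit of an outpatient cluster, or the admission
    date otherwise.  ``member_visits`` holds the row indices of the visits
    that make up the event; an outpatient cluster has >= 3 members spanning
    < 14 days, the other kinds have >= 1 (a same-day ED + inpatient pair
    collapses into one hospitalization).
    """

    person_id: str
    date: pd.Timestamp
    kind: str  # hospitalization | ed_visit | outpatient_cluster
    member_visits: tuple[int, ...]


def _is_asthma(code: object) -> bool:
    return isinstance(code, str) and code.strip().startswith(ASTHMA_PREFIX)


def _first_dx_asthma(df: pd.DataFrame) -> pd.Series:
    return df["dx1"].map(_is_asthma)


def _any_dx3_asthma(df: pd.DataFrame) -> pd.Series:
    out = pd.Series(False, index=df.index)
    for c in DX_COLS:
        if c in df.columns:
            out |= df[c].map(_is_asthma)
    return out


def identify_cases(visits: pd.DataFrame) -> set[str]:
    """Person ids meeting the asthma case definition.

    A person qualifies iff at least two visits (any setting) have a
    first-listed diagnosis with prefix 493 and dates at most 548 days apart.
    Visits with a malformed (missing/non-string) first diagnosis are skipped
    and counted in a rejects log.
    """
    dx1 = visits["dx1"]
    malformed = ~dx1.map(lambda c: isinstance(c, str) and c.strip() != "")
    if malformed.any():
        logger.warning(
            "identify_cases: skipped %d visits with malformed first diagnosis",
            int(malformed.sum()),
        )
    ok = visits.loc[~malformed]
    asthma = ok.loc[_first_dx_asthma(ok)]
    cases: set[str] = set()
    for pid, grp in asthma.groupby("person_id", sort=False):
        days = np.sort(grp["date"].to_numpy(dtype="datetime64[D]").astype(int))
        if len(days) >= 2 and np.any(np.diff(days) <= CASE_WINDOW_DAYS):
            cases.add(pid)
    return cases


def _collapse_acute(visits: pd.DataFrame, pid: str) -> list[ExacerbationEvent]:
    """Hospitalization and ED events, with the same-day ED+inpatient collapse."""
    acute = visits.loc[
        visits["setting"].isin(["inpatient", "ed"]) & _first_dx_asthma(visits)
    ]
    events: list[ExacerbationEvent] = []
    for date, day_grp in acute.groupby("date", sort=True):
        has_inpatient = (day_grp["setting"] == "inpatient").any()
        if has_inpatient:
            # all qualifying acute visits that day become one hospitalization
            events.append(
                ExacerbationEvent(pid, date, "hospitalization", tuple(day_grp.index))
            )
        else:
            for idx in day_grp.index:
                events.append(ExacerbationEvent(pid, date, "ed_visit", (idx,)))
    return events


def _outpatient_clusters(visits: pd.DataFrame, pid: str) -> list[ExacerbationEvent]:
    """Greedy left-to-right scan for >= 3 outpatient asthma visits in < 14 days.

    When visit i and the next two qualifying visits fall within the window,
    one event is emitted consuming every qualifying outpatient visit dated
    before date_i + 14 days; the scan resumes after the consumed visits, so no
    visit belongs to two events.
    """
    qual = visits.loc[(visits["setting"] == "outpatient") & _any_dx3_asthma(visits)]
    qual = qual.sort_values("date", kind="stable")
    dates = qual["date"].to_numpy(dtype="datetime64[D]").astype(int)
    idx = qual.index.to_numpy()
    events: list[ExacerbationEvent] = []
    i = 0
    n = len(dates)
    while i + 2 < n:
        if dates[i + 2] - dates[i] < CLUSTER_WINDOW_DAYS:
            end = i + 3
            while end < n and dates[end] - dates[i] < CLUSTER_WINDOW_DAYS:
                end += 1
            events.append(
                ExacerbationEvent(
                    pid,
                    qual["date"].iloc[i],
                    "outpatient_cluster",
                    tuple(idx[i:end]),
                )
            )
            i = end
        else:
            i += 1
    return events


def detect_exacerbations(visits: pd.DataFrame) -> list[ExacerbationEvent]:
    """Exacerbation events for a single person's visits.

    Accepts the person's visit table in any row order (sorted defensively);
    returns events sorted by date.  An empty input yields an empty list.
    """
    if visits.empty:
        return []
    pids = visits["person_id"].unique()
    if len(pids) != 1:
        raise ValueError("detect_exacerbations expects visits of a single person")
    pid = pids[0]
    v = visits.sort_values(["date", "setting"], kind="stable")
    events = _collapse_acute(v, pid) + _outpatient_clusters(v, pid)
    events.sort(key=lambda e: (e.date, e.kind))
    return events


def _person_event_days(
    day: np.ndarray, setting: np.ndarray, first: np.ndarray, any3: np.ndarray
) -> list[tuple[int, str]]:
    """Event (day, kind) pairs for one person, on integer-day arrays.

    Mirrors :func:`detect_exacerbations` exactly (the two paths are
    cross-checked in the test suite); operating on plain arrays keeps the
    whole-cohort scan fast.
    """
    events: list[tuple[int, str]] = []
    acute = first & ((setting == "inpatient") | (setting == "ed"))
    a_day = day[acute]
    a_set = setting[acute]
    for ud in np.unique(a_day):
        m = a_day == ud
        if (a_set[m] == "inpatient").any():
            events.append((int(ud), "hospitalization"))
        else:
            events.extend([(int(ud), "ed_visit")] * int(m.sum()))
    q = np.sort(day[(setting == "outpatient") & any3])
    i, n = 0, len(q)
    while i + 2 < n:
        if q[i + 2] - q[i] < CLUSTER_WINDOW_DAYS:
            end = i + 3
            while end < n and q[end] - q[i] < CLUSTER_WINDOW_DAYS:
                end += 1
            events.append((int(q[i]), "outpatient_cluster"))
            i = end
        else:
            i += 1
    events.sort()
    return events


def detect_all_events(visits: pd.DataFrame) -> pd.DataFrame:
    """Run the event detector over every person in a visit table.

    Returns a DataFrame with columns ``person_id``, ``date``, ``kind``,
    sorted by person then date; equivalent to calling
    :func:`detect_exacerbations` per person.
    """
    if visits.empty:
        return pd.DataFrame(columns=["person_id", "date", "kind"])
    day = visits["date"].to_numpy(dtype="datetime64[D]").astype(int)
    setting = visits["setting"].to_numpy()
    first = visits["dx1"].map(_is_asthma).to_numpy()
    any3 = _any_dx3_asthma(visits).to_numpy()
    pids, codes = np.unique(visits["person_id"].to_numpy(), return_inverse=True)
    order = np.argsort(codes, kind="stable")
    bounds = np.searchsorted(codes[order], np.arange(len(pids) + 1))
    out_pid: list[str] = []
    out_day: list[int] = []
    out_kind: list[str] = []
    for k, pid in enumerate(pids):
        idx = order[bounds[k]: bounds[k + 1]]
        for d, kind in _person_event_days(day[idx], setting[idx], first[idx], any3[idx]):
            out_pid.append(pid)
            out_day.append(d)
            out_kind.append(kind)
    dates = pd.to_datetime(np.asarray(out_day, dtype="int64").astype("datetime64[D]"))
    return pd.DataFrame({"person_id": out_pid, "date": dates, "kind": out_kind})


def person_outcomes(events: pd.DataFrame, persons: pd.DataFrame) -> pd.DataFrame:
    """Per-person outcome measures.

    ``rate`` is the number of exacerbation events divided by the person-years
    of residence in the study window; ``any_event`` flags a nonzero count.
    Persons with non-positive person-years are excluded with an error log.

    Returns a DataFrame with columns person_id, n_events, person_years, rate,
    any_event covering every person (zero counts included).
    """
    bad = persons["person_years"] <= 0
    if bad.any():
        for pid in persons.loc[bad, "person_id"]:
            logger.error("person %s excluded: non-positive person-years", pid)
    kept = persons.loc[~bad, ["person_id", "person_years"]].copy()
    if not events.empty:
        unknown = set(events["person_id"]) - set(persons["person_id"])
        if unknown:
            raise KeyError(f"events reference unknown persons: {sorted(unknown)[:5]}")
    counts = (
        events.groupby("person_id").size() if not events.empty else pd.Series(dtype=int)
    )
    kept["n_events"] = kept["person_id"].map(counts).fillna(0).astype(int)
    kept["rate"] = kept["n_events"] / kept["person_years"]
    kept["any_event"] = kept["n_events"] > 0
    return kept[["person_id", "n_events", "person_years", "rate", "any_event"]].reset_index(
        drop=True
    )
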