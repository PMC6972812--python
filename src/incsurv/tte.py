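"""Time-to-event construction and sample-size bookkeeping.

Each analyzed individual contributes an interval from first observation
(capture or release) to its last week observed.  Animals alive at their last
observation are right-censored; for observed deaths the unknown death date is
estimated as the midpoint of the last-alive and first-dead observation dates
(the Mayfield convention).  Individuals seen only once carry no elapsed time
and are excluded, with the exclusion counted.

Durations are fractional weeks (days / 7).  The exponential hazard model is
continuous and memoryless, so each animal's clock starts at its own entry
with no left-truncation adjustment needed for staggered release cohorts.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .records import (
    AGE_CLASSES,
    METHODS,
    N_GROUPS,
    RESIDENCIES,
    SITES,
    EncounterRecord,
    ValidationError,
    group_index,
    group_label,
)

DEATH = "death"
RIGHT_CENSORED = "right_censored"


def mayfield_death_date(
    last_alive: dt.date, first_dead: dt.date, individual_id: str = "?"
) -> dt.date:
    """Midpoint of the last-alive and first-dead dates.

    For an odd day gap the midpoint falls between two calendar days; we round
    toward ``last_alive``, dating deaths conservatively early.
    """
    if last_alive > first_dead:
        raise ValidationError(
            f"{individual_id}: last_alive {last_alive} after first_dead {first_dead}"
        )
    return last_alive + dt.timedelta(days=(first_dead - last_alive).days // 2)


@dataclass(frozen=True)
class TimeToEventRecord:
    """One likelihood contribution: duration in weeks plus the event flag."""

    individual_id: str
    group: int  # residency x age class x site index, 0..7
    duration_weeks: float
    event: str  # DEATH or RIGHT_CENSORED
    method: str  # carried for censoring bookkeeping, not used by the model


@dataclass
class TimeToEventData:
    """Built time-to-event records plus the single-encounter exclusions."""

    records: list[TimeToEventRecord]
    excluded_single_encounter: list[str]
    sources: list[EncounterRecord]

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded_single_encounter)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "individual_id": r.individual_id,
                    "group": r.group,
                    "group_label": group_label(r.group),
                    "duration_weeks": r.duration_weeks,
                    "event": r.event,
                    "method": r.method,
                }
                for r in self.records
            ],
            columns=[
                "individual_id",
                "group",
                "group_label",
                "duration_weeks",
                "event",
                "method",
            ],
        )


def build_time_to_event(
    records: Sequence[EncounterRecord], study_end: dt.date
) -> TimeToEventData:
    """Convert encounter records to analysis-ready durations.

    Deaths are dated by the Mayfield midpoint; censored animals end at their
    last-alive date.  A record whose first and last observation coincide (a
    single encounter) contributes zero elapsed time and is excluded but
    counted, so retained + excluded always equals the input count.
    """
    if not records:
        raise ValidationError("no encounter records supplied")
    out: list[TimeToEventRecord] = []
    excluded: list[str] = []
    retained_sources: list[EncounterRecord] = []
    for r in records:
        for d in (r.last_alive, r.first_dead):
            if d is not None and d > study_end:
                raise ValidationError(
                    f"{r.individual_id}: observation {d} after study end {study_end}"
                )
        if r.first_dead is not None:
            # first_observed is itself an alive observation, so a missing
            # last_alive collapses to the marking date.
            last_alive = r.last_alive if r.last_alive is not None else r.first_observed
            event_date = mayfield_death_date(last_alive, r.first_dead, r.individual_id)
            event = DEATH
        else:
            event_date = r.last_alive
            event = RIGHT_CENSORED
        duration = (event_date - r.first_observed).days / 7.0
        if duration <= 0.0:
            excluded.append(r.individual_id)
            continue
        out.append(
            TimeToEventRecord(
                individual_id=r.individual_id,
                group=r.group,
                duration_weeks=duration,
                event=event,
                method=r.method,
            )
        )
        retained_sources.append(r)
    return TimeToEventData(out, excluded, retained_sources)


def sufficient_statistics(
    data: TimeToEventData | Iterable[TimeToEventRecord],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-group death counts D_j and total exposure T_j (weeks).

    Under the constant-hazard exponential likelihood these two vectors carry
    all the information the data hold about the eight hazards.
    """
    records = data.records if isinstance(data, TimeToEventData) else list(data)
    deaths = np.zeros(N_GROUPS)
    exposure = np.zeros(N_GROUPS)
    for r in records:
        if r.duration_weeks <= 0:
            raise ValidationError(f"{r.individual_id}: nonpositive duration")
        exposure[r.group] += r.duration_weeks
        if r.event == DEATH:
            deaths[r.group] += 1
    return deaths, exposure


# --- bookkeeping -----------------------------------------------------------

GROUP_TABLE_INDEX = ["site", "residency", "age_class"]


def summarize_groups(records: Sequence[EncounterRecord]) -> pd.DataFrame:
    """Sample-size table: individuals per cell and method, deaths pooled.

    One row per site x residency x age-class cell, with a column per
    monitoring method and a pooled mortality count (deaths are tallied
    across methods within the cell).
    """
    if not records:
        raise ValidationError("no records to summarize")
    rows = []
    for site in SITES:
        for residency in RESIDENCIES:
            for age_class in AGE_CLASSES:
                cell = [
                    r
                    for r in records
                    if (r.site, r.residency, r.age_class)
                    == (site, residency, age_class)
                ]
                row = {"site": site, "residency": residency, "age_class": age_class}
                for method in METHODS:
                    row[method] = sum(1 for r in cell if r.method == method)
                row["mortalities"] = sum(1 for r in cell if r.died)
                rows.append(row)
    return pd.DataFrame(rows).set_index(GROUP_TABLE_INDEX)


def group_table_totals(table: pd.DataFrame) -> dict[str, int]:
    """Aggregate a sample-size table to the headline totals."""
    totals = {
        "individuals": int(table[list(METHODS)].to_numpy().sum()),
        "radiotelemetry": int(table["radiotelemetry"].sum()),
        "mark_encounter": int(table["mark_encounter"].sum()),
        "mortalities": int(table["mortalities"].sum()),
    }
    by_res = table.groupby(level="residency")[list(METHODS)].sum().sum(axis=1)
    for residency in RESIDENCIES:
        totals[residency] = int(by_res.get(residency, 0))
    return totals


def censoring_proportions(
    data: TimeToEventData,
) -> pd.DataFrame:
    """Right-censoring proportion per method x residency stratum.

    proportion = 1 - deaths / individuals.  An empty stratum is flagged
    undefined (NaN) rather than silently 0 or 1.
    """
    rows = []
    by_key: dict[tuple[str, str], list[TimeToEventRecord]] = {}
    for rec, src in zip(data.records, data.sources):
        by_key.setdefault((rec.method, src.residency), []).append(rec)
    for method in METHODS:
        for residency in RESIDENCIES:
            recs = by_key.get((method, residency), [])
            n = len(recs)
            deaths = sum(1 for r in recs if r.event == DEATH)
            rows.append(
                {
                    "method": method,
                    "residency": residency,
                    "individuals": n,
                    "deaths": deaths,
                    "proportion_censored": (1.0 - deaths / n) if n else np.nan,
                    "defined": n > 0,
                }
            )
    return pd.DataFrame(rows).set_index(["method", "residency"])


def censoring_from_counts(
    individuals: dict[tuple[str, str], int], deaths: dict[tuple[str, str], int]
) -> pd.DataFrame:
    """Censoring proportions straight from stratum counts.

    ``individuals`` and ``deaths`` are keyed by (method, residency); used
    when only a published count table, not record-level data, is available.
    """
    rows = []
    for method in METHODS:
        for residency in RESIDENCIES:
            n = individuals.get((method, residency), 0)
            d = deaths.get((method, residency), 0)
            rows.append(
                {
                    "method": method,
                    "residency": residency,
                    "individuals": n,
                    "deaths": d,
                    "proportion_censored": (1.0 - d / n) if n else np.nan,
                    "defined": n > 0,
                }
            )
    return pd.DataFrame(rows).set_index(["method", "residency"])


# --- interchange -----------------------------------------------------------

TTE_COLUMNS = ["individual_id", "group", "duration_weeks", "event", "method"]


def write_tte_csv(
    records: Sequence[TimeToEventRecord], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "individual_id": r.individual_id,
                "group": r.group,
                "duration_weeks": repr(r.duration_weeks),
                "event": r.event,
                "method": r.method,
            }
            for r in records
        ],
        columns=TTE_COLUMNS,
    ).to_csv(path, index=False)


def read_tte_csv(path: str | Path) -> list[TimeToEventRecord]:
    frame = pd.read_csv(path, dtype={"individual_id": str})
    missing = set(TTE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValidationError(f"time-to-event CSV missing columns: {sorted(missing)}")
    return [
        TimeToEventRecord(
            individual_id=str(row.individual_id),
            group=int(row.group),
            duration_weeks=float(row.duration_weeks),
            event=str(row.event),
            method=str(row.method),
        )
        for row in frame.itertuples(index=False)
    ]
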