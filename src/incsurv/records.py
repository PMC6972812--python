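"""Encounter records and demographic grouping.

Raw data are one row per marked individual: who it is, where it lives
(north/south study site), whether it is an adult or juvenile, whether it is
a resident or a translocatee, how it was monitored (scheduled radiotelemetry
relocations vs. ad hoc incidental re-encounters), and the three dates that
carry all the survival information — first observed (capture for residents,
release for translocatees), last seen alive, and first found dead.

The eight analysis groups are the cells of residency x age class x site.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

SITES = ("north", "south")
AGE_CLASSES = ("adult", "juvenile")
RESIDENCIES = ("resident", "translocated")
METHODS = ("radiotelemetry", "mark_encounter")

#: Midline carapace length (mm) at or above which a tortoise is an adult.
ADULT_MCL_MM = 180.0

N_GROUPS = 8


def group_index(residency: str, age_class: str, site: str) -> int:
    """Map a residency x age-class x site cell to its index in 0..7."""
    return (
        RESIDENCIES.index(residency) * 4
        + AGE_CLASSES.index(age_class) * 2
        + SITES.index(site)
    )


def group_label(j: int) -> str:
    """Human-readable label ('translocated.adult.north') for group j."""
    residency, age_class, site = group_fields(j)
    return f"{residency}.{age_class}.{site}"


def group_fields(j: int) -> tuple[str, str, str]:
    """Inverse of :func:`group_index`: (residency, age_class, site)."""
    if not 0 <= j < N_GROUPS:
        raise ValueError(f"group index {j} out of range 0..{N_GROUPS - 1}")
    return RESIDENCIES[j // 4], AGE_CLASSES[(j // 2) % 2], SITES[j % 2]


GROUP_LABELS = tuple(group_label(j) for j in range(N_GROUPS))


def reference_group(site: str) -> int:
    """The contrast baseline for a site: its resident adults."""
    return group_index("resident", "adult", site)


class ValidationError(ValueError):
    """A record violated an invariant; the message names the individual."""


@dataclass(frozen=True)
class EncounterRecord:
    """Per-individual observation summary.

    ``first_observed`` is the capture date for residents and the release
    date for translocatees; it counts as an "alive" observation.  At least
    one of ``last_alive`` / ``first_dead`` must be present.
    """

    individual_id: str
    site: str
    age_class: str
    residency: str
    method: str
    first_observed: dt.date
    last_alive: dt.date | None = None
    first_dead: dt.date | None = None
    midline_carapace_length: float | None = None

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValidationError(f"{self.individual_id}: unknown site {self.site!r}")
        if self.age_class not in AGE_CLASSES:
            raise ValidationError(
                f"{self.individual_id}: unknown age class {self.age_class!r}"
            )
        if self.residency not in RESIDENCIES:
            raise ValidationError(
                f"{self.individual_id}: unknown residency {self.residency!r}"
            )
        if self.method not in METHODS:
            raise ValidationError(
                f"{self.individual_id}: unknown method {self.method!r}"
            )
        if self.last_alive is None and self.first_dead is None:
            raise ValidationError(
                f"{self.individual_id}: needs at least one of last_alive/first_dead"
            )
        if self.last_alive is not None and self.first_observed > self.last_alive:
            raise ValidationError(
                f"{self.individual_id}: first_observed {self.first_observed} after "
                f"last_alive {self.last_alive}"
            )
        if (
            self.last_alive is not None
            and self.first_dead is not None
            and self.last_alive > self.first_dead
        ):
            raise ValidationError(
                f"{self.individual_id}: last_alive {self.last_alive} after "
                f"first_dead {self.first_dead}"
            )
        if self.midline_carapace_length is not None:
            derived = (
                "adult"
                if self.midline_carapace_length >= ADULT_MCL_MM
                else "juvenile"
            )
            if derived != self.age_class:
                raise ValidationError(
                    f"{self.individual_id}: age class {self.age_class!r} inconsistent "
                    f"with carapace length {self.midline_carapace_length} mm"
                )

    @property
    def group(self) -> int:
        return group_index(self.residency, self.age_class, self.site)

    @property
    def died(self) -> bool:
        return self.first_dead is not None


ENCOUNTER_COLUMNS = [
    "individual_id",
    "site",
    "age_class",
    "residency",
    "method",
    "first_observed",
    "last_alive",
    "first_dead",
    "midline_carapace_length",
]

_DATE_COLS = ("first_observed", "last_alive", "first_dead")


def _parse_date(value) -> dt.date | None:
    if value is None or value == "" or pd.isna(value):
        return None
    if isinstance(value, dt.date) and not isinstance(value, dt.datetime):
        return value
    return pd.Timestamp(value).date()


def records_to_frame(records: Iterable[EncounterRecord]) -> pd.DataFrame:
    """Tabulate records with ISO-8601 date strings (interchange form)."""
    rows = []
    for r in records:
        rows.append(
            {
                "individual_id": r.individual_id,
                "site": r.site,
                "age_class": r.age_class,
                "residency": r.residency,
                "method": r.method,
                "first_observed": r.first_observed.isoformat(),
                "last_alive": r.last_alive.isoformat() if r.last_alive else "",
                "first_dead": r.first_dead.isoformat() if r.first_dead else "",
                "midline_carapace_length": r.midline_carapace_length,
            }
        )
    return pd.DataFrame(rows, columns=ENCOUNTER_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[EncounterRecord]:
    records = []
    for row in frame.itertuples(index=False):
        mcl = getattr(row, "midline_carapace_length", None)
        if mcl is not None and pd.isna(mcl):
            mcl = None
        records.append(
            EncounterRecord(
                individual_id=str(row.individual_id),
                site=row.site,
                age_class=row.age_class,
                residency=row.residency,
                method=row.method,
                first_observed=_parse_date(row.first_observed),
                last_alive=_parse_date(row.last_alive),
                first_dead=_parse_date(row.first_dead),
                midline_carapace_length=float(mcl) if mcl is not None else None,
            )
        )
    return records


def write_encounters_csv(records: Sequence[EncounterRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_encounters_csv(path: str | Path) -> list[EncounterRecord]:
    frame = pd.read_csv(path, dtype={"individual_id": str}, keep_default_na=True)
    missing = set(ENCOUNTER_COLUMNS) - {"midline_carapace_length"} - set(frame.columns)
    if missing:
        raise ValidationError(f"encounter CSV missing columns: {sorted(missing)}")
    if "midline_carapace_length" not in frame.columns:
        frame["midline_carapace_length"] = None
    return frame_to_records(frame)


def validate_records(records: Sequence[EncounterRecord]) -> list[str]:
    """Line-oriented validation report; empty list means clean.

    Construction already enforces per-record invariants, so this checks the
    cross-record ones (duplicate identifiers).
    """
    report: list[str] = []
    seen: dict[str, int] = {}
    for r in records:
        seen[r.individual_id] = seen.get(r.individual_id, 0) + 1
    for ind, n in seen.items():
        if n > 1:
            report.append(f"duplicate individual_id {ind!r} appears {n} times")
    return report
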