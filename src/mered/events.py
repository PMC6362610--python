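"""Resight records, composite events, and encounter histories.

Field observations are made in three annual capture periods:

* ``U`` -- the "uneven" weekly breeding-season surveys (weeks 1, 3, 5, 7),
* ``E`` -- the "even" weekly breeding-season surveys (weeks 2, 4, 6, 8),
* ``M`` -- any sighting outside the breeding season (moult or winter).

All sightings of one animal within a seal year (September of year *t*
through August of *t + 1*) collapse to a single composite event coded 0-7
by which subset of the three capture periods contained at least one
sighting:

===== ======= =========================================
code  label   capture periods with >= 1 sighting
===== ======= =========================================
0     NS      none
1     MUE     M, U and E
2     MU      M and U
3     ME      M and E
4     M       M only
5     UE      U and E
6     U       U only
7     E       E only
===== ======= =========================================

Encounter histories are conditioned on the first breeding-season capture:
the first event of every history involves a U or E sighting (codes
1, 2, 3, 5, 6, 7).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Event code -> short label (capture-period subset).
EVENT_LABELS = {0: "NS", 1: "MUE", 2: "MU", 3: "ME", 4: "M", 5: "UE", 6: "U", 7: "E"}

#: Capture-period subset -> event code.
_PERIODS_TO_EVENT = {
    frozenset(): 0,
    frozenset("MUE"): 1,
    frozenset("MU"): 2,
    frozenset("ME"): 3,
    frozenset("M"): 4,
    frozenset("UE"): 5,
    frozenset("U"): 6,
    frozenset("E"): 7,
}

#: Events that include a breeding-season (U or E) sighting.
BREEDING_EVENTS = frozenset({1, 2, 3, 5, 6, 7})

_VALID_CONTEXTS = tuple(f"breed_week_{k}" for k in range(1, 9)) + ("moult", "winter")


@dataclass(frozen=True)
class ResightRecord:
    """One sighting of one animal in one survey context.

    ``year`` labels the seal year by the September that starts it; ``context``
    is ``breed_week_1`` .. ``breed_week_8``, ``moult`` or ``winter``.
    """

    animal_id: str
    year: int
    context: str

    def __post_init__(self):
        if self.context not in _VALID_CONTEXTS:
            raise ValidationError(
                f"unknown survey context {self.context!r} for animal "
                f"{self.animal_id!r} in year {self.year}; expected one of "
                f"{', '.join(_VALID_CONTEXTS)}"
            )


def classify_capture_period(context: str) -> str:
    """Map a survey context to its capture period ``U``, ``E`` or ``M``.

    Odd breeding weeks collapse to U, even weeks to E, and moult or winter
    sightings to M.
    """
    if context in ("moult", "winter"):
        return "M"
    if context.startswith("breed_week_"):
        try:
            week = int(context[len("breed_week_"):])
        except ValueError:
            week = -1
        if 1 <= week <= 8:
            return "U" if week % 2 == 1 else "E"
    raise ValidationError(
        f"unknown survey context {context!r}; expected one of "
        f"{', '.join(_VALID_CONTEXTS)}"
    )


def event_from_periods(periods: Iterable[str]) -> int:
    """Composite event code for a set of capture periods with sightings."""
    key = frozenset(periods)
    if not key <= frozenset("MUE"):
        raise ValidationError(f"capture periods must be within {{M,U,E}}, got {set(key)}")
    return _PERIODS_TO_EVENT[key]


def collapse_to_event(records: Iterable[ResightRecord]) -> int:
    """Collapse all sightings of one animal-year into its composite event.

    Pure function of the *set* of capture periods touched; duplicates and
    record order are irrelevant.  An empty collection gives event 0.
    """
    records = list(records)
    if records:
        ids = {(r.animal_id, r.year) for r in records}
        if len(ids) > 1:
            raise ValidationError(
                f"records span multiple animal-years: {sorted(ids)}"
            )
    return event_from_periods(classify_capture_period(r.context) for r in records)


@dataclass(frozen=True)
class EncounterHistory:
    """Composite-event history of one animal from its first breeding capture.

    ``events`` holds one code per occasion from ``first_occasion`` (inclusive)
    to the end of the study axis; storage is sparse in the leading occasions.
    """

    animal_id: str
    first_occasion: int
    events: tuple[int, ...]

    def __post_init__(self):
        if self.first_occasion < 0:
            raise ValidationError(f"{self.animal_id}: negative first occasion")
        if not self.events:
            raise ValidationError(f"{self.animal_id}: empty event vector")
        if any(e not in EVENT_LABELS for e in self.events):
            raise ValidationError(f"{self.animal_id}: event codes must be 0-7")
        if self.events[0] not in BREEDING_EVENTS:
            raise ValidationError(
                f"{self.animal_id}: history must start with a breeding-season "
                f"event (codes {sorted(BREEDING_EVENTS)}), got {self.events[0]}"
            )

    def __len__(self) -> int:
        return len(self.events)

    def dense(self, n_occasions: int) -> np.ndarray:
        """Events on the full occasion axis, zero-padded before first capture."""
        out = np.zeros(n_occasions, dtype=np.int8)
        out[self.first_occasion:self.first_occasion + len(self.events)] = self.events
        return out


@dataclass
class BuildReport:
    """Bookkeeping from encoding raw records into histories."""

    n_individuals_in: int = 0
    n_individuals_kept: int = 0
    excluded_ids: list = field(default_factory=list)
    truncated_prefix_occasions: int = 0

    @property
    def n_excluded(self) -> int:
        return len(self.excluded_ids)


class Dataset:
    """A collection of encounter histories on a common year axis.

    ``counts`` are per-history multiplicities (identical histories may be
    pooled to speed the likelihood).
    """

    def __init__(self, years: Sequence[int], histories: Sequence[EncounterHistory],
                 counts: Sequence[int] | None = None):
        self.years = list(years)
        self.histories = list(histories)
        if counts is None:
            counts = [1] * len(self.histories)
        self.counts = np.asarray(counts, dtype=np.int64)
        if len(self.counts) != len(self.histories):
            raise ValidationError("counts length must match number of histories")
        if np.any(self.counts < 1):
            raise ValidationError("history multiplicities must be >= 1")
        T = len(self.years)
        for h in self.histories:
            if h.first_occasion + len(h.events) != T:
                raise ValidationError(
                    f"{h.animal_id}: history does not span to the last occasion "
                    f"(first {h.first_occasion}, length {len(h.events)}, axis {T})"
                )

    @property
    def n_occasions(self) -> int:
        return len(self.years)

    @property
    def n_individuals(self) -> int:
        return int(self.counts.sum())

    def __len__(self) -> int:
        return len(self.histories)

    def dense_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(first_occasion, events (n, T), counts) as numpy arrays."""
        T = self.n_occasions
        first = np.array([h.first_occasion for h in self.histories], dtype=np.int64)
        events = np.zeros((len(self.histories), T), dtype=np.int8)
        for i, h in enumerate(self.histories):
            events[i, h.first_occasion:] = h.events
        return first, events, self.counts.copy()

    def aggregated(self) -> "Dataset":
        """Pool identical histories, summing multiplicities.

        Pooled histories keep the id of their first representative.
        """
        seen: dict[tuple[int, tuple[int, ...]], int] = {}
        hists: list[EncounterHistory] = []
        counts: list[int] = []
        for h, c in zip(self.histories, self.counts):
            key = (h.first_occasion, h.events)
            if key in seen:
                counts[seen[key]] += int(c)
            else:
                seen[key] = len(hists)
                hists.append(h)
                counts.append(int(c))
        return Dataset(self.years, hists, counts)


def build_histories(records: Iterable[ResightRecord],
                    years: Sequence[int]) -> tuple[Dataset, BuildReport]:
    """Encode raw resight records into conditioned encounter histories.

    Each individual gets one composite event per year on the ``years`` axis.
    Occasions before the first breeding-season event (the first capture) are
    discarded; individuals never seen during any breeding season are excluded
    and listed in the report.
    """
    year_index = {y: i for i, y in enumerate(years)}
    T = len(years)
    per_animal: dict[str, dict[int, set[str]]] = {}
    for r in records:
        if r.year not in year_index:
            raise ValidationError(
                f"record for {r.animal_id!r} in year {r.year} lies outside the "
                f"occasion axis {years[0]}..{years[-1]}"
            )
        per_animal.setdefault(r.animal_id, {}).setdefault(
            year_index[r.year], set()).add(classify_capture_period(r.context))

    report = BuildReport(n_individuals_in=len(per_animal))
    histories = []
    for animal_id in sorted(per_animal):
        ev = np.zeros(T, dtype=np.int8)
        for occ, periods in per_animal[animal_id].items():
            ev[occ] = event_from_periods(periods)
        first = next((t for t in range(T) if ev[t] in BREEDING_EVENTS), None)
        if first is None:
            report.excluded_ids.append(animal_id)
            continue
        report.truncated_prefix_occasions += first
        histories.append(EncounterHistory(animal_id, first, tuple(int(e) for e in ev[first:])))
    report.n_individuals_kept = len(histories)
    return Dataset(years, histories), report


def condition_event_matrix(animal_ids: Sequence[str], events: np.ndarray,
                           years: Sequence[int]) -> tuple[Dataset, BuildReport]:
    """Apply first-capture conditioning to a dense (n, T) event-code matrix."""
    events = np.asarray(events, dtype=np.int8)
    if events.ndim != 2 or events.shape[1] != len(years):
        raise ValidationError("event matrix must be (n_individuals, n_years)")
    report = BuildReport(n_individuals_in=events.shape[0])
    histories = []
    breeding = np.isin(events, sorted(BREEDING_EVENTS))
    for i, animal_id in enumerate(animal_ids):
        hit = np.flatnonzero(breeding[i])
        if hit.size == 0:
            report.excluded_ids.append(animal_id)
            continue
        first = int(hit[0])
        report.truncated_prefix_occasions += first
        histories.append(EncounterHistory(str(animal_id), first,
                                          tuple(int(e) for e in events[i, first:])))
    report.n_individuals_kept = len(histories)
    return Dataset(years, histories), report


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def read_resights_csv(path) -> list[ResightRecord]:
    """Read a headed ``animal_id,year,context`` CSV of resight records.

    Rejects unknown contexts with the offending line numbers in the message.
    """
    df = pd.read_csv(path, dtype={"animal_id": str})
    required = {"animal_id", "year", "context"}
    if not required <= set(df.columns):
        raise ValidationError(
            f"resight CSV needs columns {sorted(required)}, got {list(df.columns)}"
        )
    bad = ~df["context"].isin(_VALID_CONTEXTS)
    if bad.any():
        lines = [str(i + 2) for i in df.index[bad]]  # +2: header + 1-based
        vals = sorted(df.loc[bad, "context"].unique())
        raise ValidationError(
            f"unknown survey context(s) {vals} on line(s) {', '.join(lines)}"
        )
    return [ResightRecord(str(r.animal_id), int(r.year), str(r.context))
            for r in df.itertuples(index=False)]


def write_resights_csv(records: Iterable[ResightRecord], path) -> None:
    pd.DataFrame([(r.animal_id, r.year, r.context) for r in records],
                 columns=["animal_id", "year", "context"]).to_csv(path, index=False)


def write_histories_csv(dataset: Dataset, path) -> None:
    """One row per history: ``animal_id``, one event column per year, ``count``."""
    _, events, counts = dataset.dense_arrays()
    df = pd.DataFrame(events, columns=[str(y) for y in dataset.years])
    df.insert(0, "animal_id", [h.animal_id for h in dataset.histories])
    df["count"] = counts
    df.to_csv(path, index=False)


def read_histories_csv(path) -> tuple[Dataset, BuildReport]:
    """Read an encounter-history CSV (inverse of :func:`write_histories_csv`).

    First-capture conditioning is re-applied, so tables with leading
    nonbreeding events load cleanly.
    """
    df = pd.read_csv(path, dtype={"animal_id": str})
    if "animal_id" not in df.columns:
        raise ValidationError("history CSV needs an animal_id column")
    counts = df.pop("count").to_numpy(dtype=np.int64) if "count" in df.columns else None
    ids = df.pop("animal_id").tolist()
    try:
        years = [int(c) for c in df.columns]
    except ValueError:
        raise ValidationError(f"history CSV year columns must be integers, got {list(df.columns)}")
    events = df.to_numpy(dtype=np.int64)
    if events.size and (events.min() < 0 or events.max() > 7):
        raise ValidationError("history CSV cells must be event codes 0-7")
    dataset, report = condition_event_matrix(ids, events, years)
    if counts is not None:
        kept = [i for i, a in enumerate(ids) if a not in set(report.excluded_ids)]
        dataset = Dataset(years, dataset.histories, counts[kept])
    return dataset, report


def write_mark_inp(dataset: Dataset, path) -> None:
    """Write histories as MARK-style ``/* id */ <digits> <count> ;`` lines."""
    _, events, counts = dataset.dense_arrays()
    with open(path, "w") as fh:
        for h, row, c in zip(dataset.histories, events, counts):
            digits = "".join(str(int(e)) for e in row)
            fh.write(f"/* {h.animal_id} */ {digits} {int(c)} ;\n")


# ---------------------------------------------------------------------------
# Calendar-date support
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeasonCalendar:
    """Maps calendar dates to (seal year, survey context).

    The breeding window opens on the first survey date of each season
    (default 15 September) and is partitioned into eight weekly bins;
    dates in the window before the anchor clamp to week 1 and dates past
    week 8 within the breeding months clamp to week 8.  All other dates are
    nonbreeding: November-February -> moult, otherwise winter (both collapse
    to capture period M).
    """

    first_survey_month: int = 9
    first_survey_day: int = 15

    def seal_year(self, date: _dt.date) -> int:
        return date.year if date.month >= 9 else date.year - 1

    def context(self, date: _dt.date) -> str:
        year = self.seal_year(date)
        anchor = _dt.date(year, self.first_survey_month, self.first_survey_day)
        days = (date - anchor).days
        if date.month in (9, 10) or (date.month == 11 and days < 56):
            week = min(max(days // 7 + 1, 1), 8)
            return f"breed_week_{week}"
        return "moult" if date.month in (11, 12, 1, 2) else "winter"

    def record(self, animal_id: str, date: _dt.date) -> ResightRecord:
        return ResightRecord(animal_id, self.seal_year(date), self.context(date))


def read_dated_resights_csv(path, calendar: SeasonCalendar | None = None) -> list[ResightRecord]:
    """Read a headed ``animal_id,date`` CSV and assign seal years and contexts."""
    calendar = calendar or SeasonCalendar()
    df = pd.read_csv(path, dtype={"animal_id": str})
    if not {"animal_id", "date"} <= set(df.columns):
        raise ValidationError("dated resight CSV needs columns animal_id,date")
    dates = pd.to_datetime(df["date"], format="%Y-%m-%d").dt.date
    return [calendar.record(str(a), d) for a, d in zip(df["animal_id"], dates)]
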