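"""Domain types and CSV readers/writers for the OMOP-lite table dialect.

All dates are ``datetime.date`` (whole calendar days, no time-of-day);
window arithmetic throughout the package is integer-day arithmetic on
these dates.  Identifiers are opaque strings.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from datetime import date
from enum import Enum
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

from .errors import RowError, SchemaError, ValidationError

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .concepts import Category


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


class Domain(str, Enum):
    CONDITION = "condition"
    PROCEDURE = "procedure"
    OBSERVATION = "observation"
    DRUG = "drug"


class OutcomeClass(str, Enum):
    """Pregnancy outcome classes.

    ``DELIVERY`` is transient: delivery-only candidates are re-labelled
    live births on acceptance and never appear in a final episode.
    """

    LIVE_BIRTH = "live_birth"
    STILLBIRTH = "stillbirth"
    ECTOPIC = "ectopic"
    ABORTION = "abortion"
    DELIVERY = "delivery"


#: Classes a finalized episode may carry.
FINAL_OUTCOME_CLASSES = (
    OutcomeClass.LIVE_BIRTH,
    OutcomeClass.STILLBIRTH,
    OutcomeClass.ECTOPIC,
    OutcomeClass.ABORTION,
)


class StartMethod(str, Enum):
    LMP = "lmp"
    GEST_AGE = "gest_age"
    FERTILITY = "fertility"
    NUCHAL_ULTRASOUND = "nuchal_ultrasound"
    AFP = "afp"
    AMENORRHEA = "amenorrhea"
    URINE_TEST = "urine_test"
    OUTCOME_ESTIMATE = "outcome_estimate"


class TermStatus(str, Enum):
    FULL_TERM = "full_term"
    PRETERM = "preterm"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class Person:
    person_id: str
    sex: Sex
    birth_date: date

    def age_at(self, on: date) -> int:
        """Completed years of age on a given calendar date."""
        b = self.birth_date
        return on.year - b.year - ((on.month, on.day) < (b.month, b.day))


@dataclass(frozen=True)
class ObservationPeriod:
    person_id: str
    period_start: date
    period_end: date

    def __post_init__(self):
        if self.period_start > self.period_end:
            raise ValidationError(
                f"observation period for {self.person_id}: start after end"
            )

    def covers(self, start: date, end: date) -> bool:
        return self.period_start <= start and end <= self.period_end


@dataclass(frozen=True)
class ClinicalEvent:
    """One dated coded record; the atom the algorithm reads.

    ``category`` is filled in by :func:`pregepi.concepts.categorize_events`
    and is ``None`` for raw or uncategorized events.  ``value`` carries a
    gestational age when the category requires one (unit ``weeks`` or
    ``days``).
    """

    person_id: str
    concept_id: str
    domain: Domain
    event_date: date
    value: float | None = None
    unit: str | None = None
    category: "Category | None" = field(default=None, compare=True)

    def with_category(self, category: "Category | None") -> "ClinicalEvent":
        return replace(self, category=category)


@dataclass(frozen=True)
class PregnancyEpisode:
    person_id: str
    episode_index: int
    outcome_class: OutcomeClass
    outcome_date: date
    start_date: date
    start_method: StartMethod
    term_status: TermStatus = TermStatus.NOT_APPLICABLE

    def __post_init__(self):
        if self.start_date > self.outcome_date:
            raise ValidationError(
                f"episode {self.person_id}/{self.episode_index}: "
                "start_date after outcome_date"
            )
        if self.outcome_class not in FINAL_OUTCOME_CLASSES:
            raise ValidationError(
                f"episode {self.person_id}/{self.episode_index}: "
                f"transient class {self.outcome_class.value} not allowed"
            )

    @property
    def duration_days(self) -> int:
        return (self.outcome_date - self.start_date).days


@dataclass
class Cohort:
    persons: list[Person]
    observation_periods: list[ObservationPeriod]
    events: list[ClinicalEvent]

    def person_ids(self) -> list[str]:
        return [p.person_id for p in self.persons]

    def events_for(self, person_id: str) -> list[ClinicalEvent]:
        return [e for e in self.events if e.person_id == person_id]

    def periods_for(self, person_id: str) -> list[ObservationPeriod]:
        return [p for p in self.observation_periods if p.person_id == person_id]


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

#: event-table name -> Domain
EVENT_TABLES: dict[str, Domain] = {
    "condition_occurrence": Domain.CONDITION,
    "procedure_occurrence": Domain.PROCEDURE,
    "observation": Domain.OBSERVATION,
    "drug_exposure": Domain.DRUG,
}

_PERSON_COLUMNS = ("person_id", "sex", "birth_date")
_PERIOD_COLUMNS = ("person_id", "period_start", "period_end")
_EVENT_COLUMNS = ("person_id", "concept_id", "event_date")

EPISODE_COLUMNS = (
    "person_id",
    "episode_index",
    "outcome_class",
    "outcome_date",
    "start_date",
    "start_method",
    "term_status",
)


def _parse_date(raw: str, table: str, line: int, column: str) -> date:
    try:
        return date.fromisoformat(raw.strip())
    except ValueError as exc:
        raise RowError(table, line, f"bad {column} {raw!r}: {exc}") from None


def _open_reader(path: Path, table: str, required: Iterable[str]) -> list[dict]:
    if not path.exists():
        raise SchemaError(table, f"file not found: {path}")
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in required:
            if col not in header:
                raise SchemaError(table, f"missing required column {col!r}")
        return [(i, row) for i, row in enumerate(reader, start=2)]


def read_cohort(paths: Mapping[str, str | Path]) -> Cohort:
    """Read person/observation_period/event tables into a validated Cohort.

    ``paths`` maps table names (``person``, ``observation_period`` and any
    of the event tables in :data:`EVENT_TABLES`) to CSV file paths.
    Duplicate event rows are preserved — repeat billings are meaningful.
    """
    persons: list[Person] = []
    if "person" in paths:
        for line, row in _open_reader(Path(paths["person"]), "person", _PERSON_COLUMNS):
            sex_raw = (row["sex"] or "").strip().lower()
            try:
                sex = Sex(sex_raw) if sex_raw else Sex.UNKNOWN
            except ValueError:
                raise RowError("person", line, f"unknown sex {row['sex']!r}") from None
            persons.append(
                Person(
                    person_id=row["person_id"].strip(),
                    sex=sex,
                    birth_date=_parse_date(row["birth_date"], "person", line, "birth_date"),
                )
            )
    seen = set()
    for p in persons:
        if p.person_id in seen:
            raise ValidationError(f"duplicate person_id {p.person_id!r}")
        seen.add(p.person_id)

    periods: list[ObservationPeriod] = []
    if "observation_period" in paths:
        for line, row in _open_reader(
            Path(paths["observation_period"]), "observation_period", _PERIOD_COLUMNS
        ):
            periods.append(
                ObservationPeriod(
                    person_id=row["person_id"].strip(),
                    period_start=_parse_date(
                        row["period_start"], "observation_period", line, "period_start"
                    ),
                    period_end=_parse_date(
                        row["period_end"], "observation_period", line, "period_end"
                    ),
                )
            )

    events: list[ClinicalEvent] = []
    for table, domain in EVENT_TABLES.items():
        if table not in paths:
            continue
        for line, row in _open_reader(Path(paths[table]), table, _EVENT_COLUMNS):
            raw_value = (row.get("value") or "").strip()
            value: float | None = None
            if raw_value:
                try:
                    value = float(raw_value)
                except ValueError:
                    raise RowError(table, line, f"bad value {raw_value!r}") from None
            events.append(
                ClinicalEvent(
                    person_id=row["person_id"].strip(),
                    concept_id=row["concept_id"].strip(),
                    domain=domain,
                    event_date=_parse_date(row["event_date"], table, line, "event_date"),
                    value=value,
                    unit=(row.get("unit") or "").strip() or None,
                )
            )
    return Cohort(persons=persons, observation_periods=periods, events=events)


def read_cohort_dir(directory: str | Path) -> Cohort:
    """Read every recognized table present in ``directory``."""
    directory = Path(directory)
    paths: dict[str, Path] = {}
    for table in ("person", "observation_period", *EVENT_TABLES):
        candidate = directory / f"{table}.csv"
        if candidate.exists():
            paths[table] = candidate
    return read_cohort(paths)


def events_outside_observation(cohort: Cohort) -> list[ClinicalEvent]:
    """Events not covered by any observation period (validator warning list)."""
    by_person: dict[str, list[ObservationPeriod]] = {}
    for p in cohort.observation_periods:
        by_person.setdefault(p.person_id, []).append(p)
    out = []
    for e in cohort.events:
        periods = by_person.get(e.person_id, [])
        if not any(p.period_start <= e.event_date <= p.period_end for p in periods):
            out.append(e)
    return out


def write_episodes(episodes: Iterable[PregnancyEpisode], path: str | Path) -> None:
    """Write episodes as CSV, one row per episode; dates in ISO-8601."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(EPISODE_COLUMNS)
        for ep in episodes:
            writer.writerow(
                [
                    ep.person_id,
                    ep.episode_index,
                    ep.outcome_class.value,
                    ep.outcome_date.isoformat(),
                    ep.start_date.isoformat(),
                    ep.start_method.value,
                    ep.term_status.value,
                ]
            )


def read_episodes(path: str | Path) -> list[PregnancyEpisode]:
    episodes = []
    for line, row in _open_reader(Path(path), "pregnancy_episodes", EPISODE_COLUMNS):
        try:
            episodes.append(
                PregnancyEpisode(
                    person_id=row["person_id"],
                    episode_index=int(row["episode_index"]),
                    outcome_class=OutcomeClass(row["outcome_class"]),
                    outcome_date=_parse_date(
                        row["outcome_date"], "pregnancy_episodes", line, "outcome_date"
                    ),
                    start_date=_parse_date(
                        row["start_date"], "pregnancy_episodes", line, "start_date"
                    ),
                    start_method=StartMethod(row["start_method"]),
                    term_status=TermStatus(row["term_status"]),
                )
            )
        except ValueError as exc:
            raise RowError("pregnancy_episodes", line, str(exc)) from None
    return episodes
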