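"""Concept categorization and the ectopic disproportionality screen.

A :class:`ConceptSet` maps opaque concept identifiers to exactly one
algorithm category.  Categories split into two disjoint families:
outcome-classification categories and start-marker categories.  Events
whose concept is absent from the set are simply uncategorized and
ignored by every downstream stage.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import date, timedelta
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import RowError, SchemaError, ValidationError
from .model import ClinicalEvent, ObservationPeriod, Person, Sex


class Category(str, Enum):
    # outcome-classification categories
    LIVE_BIRTH = "live_birth"
    STILLBIRTH = "stillbirth"
    ABORTION = "abortion"
    DELIVERY = "delivery"
    ECTOPIC = "ectopic"
    METHOTREXATE = "methotrexate"
    ECTOPIC_SURGERY = "ectopic_surgery"
    ECTOPIC_ASSOCIATED = "ectopic_associated"
    # start-marker categories
    PRETERM = "preterm"
    GEST_AGE = "gest_age"
    LMP = "lmp"
    PREG_CONFIRMATION = "preg_confirmation"
    ANTENATAL_VISIT = "antenatal_visit"
    COMPLICATION = "complication"
    THREATENED_ABORTION = "threatened_abortion"
    AFP = "afp"
    NUCHAL_ULTRASOUND = "nuchal_ultrasound"
    FERTILITY_DATING = "fertility_dating"
    AMENORRHEA = "amenorrhea"
    CONTRACEPTIVE = "contraceptive"
    URINE_TEST = "urine_test"


OUTCOME_CATEGORIES = frozenset(
    {
        Category.LIVE_BIRTH,
        Category.STILLBIRTH,
        Category.ABORTION,
        Category.DELIVERY,
        Category.ECTOPIC,
        Category.METHOTREXATE,
        Category.ECTOPIC_SURGERY,
        Category.ECTOPIC_ASSOCIATED,
    }
)

START_CATEGORIES = frozenset(set(Category) - OUTCOME_CATEGORIES)


@dataclass
class ConceptSet:
    """One category per concept identifier; unknown concepts uncategorized."""

    entries: dict[str, Category] = field(default_factory=dict)

    def category(self, concept_id: str) -> Category | None:
        return self.entries.get(concept_id)

    def add(self, concept_id: str, category: Category) -> None:
        existing = self.entries.get(concept_id)
        if existing is not None and existing is not category:
            raise ValidationError(
                f"concept {concept_id!r} assigned conflicting categories "
                f"{existing.value!r} and {category.value!r}"
            )
        self.entries[concept_id] = category

    def __len__(self) -> int:
        return len(self.entries)


def load_concept_sets(path: str | Path) -> ConceptSet:
    """Load a ``concept_id,category`` CSV into a :class:`ConceptSet`."""
    path = Path(path)
    if not path.exists():
        raise SchemaError("concept_sets", f"file not found: {path}")
    cs = ConceptSet()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in ("concept_id", "category"):
            if col not in header:
                raise SchemaError("concept_sets", f"missing required column {col!r}")
        for line, row in enumerate(reader, start=2):
            raw = row["category"].strip()
            try:
                category = Category(raw)
            except ValueError:
                valid = ", ".join(sorted(c.value for c in Category))
                raise RowError(
                    "concept_sets",
                    line,
                    f"unknown category {raw!r}; valid names: {valid}",
                ) from None
            cs.add(row["concept_id"].strip(), category)
    return cs


def write_concept_sets(concept_set: ConceptSet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["concept_id", "category"])
        for concept_id, category in sorted(concept_set.entries.items()):
            writer.writerow([concept_id, category.value])


def categorize_events(
    events: Iterable[ClinicalEvent], concept_set: ConceptSet
) -> list[ClinicalEvent]:
    """Annotate each event with its category (or None); count unchanged."""
    return [e.with_category(concept_set.category(e.concept_id)) for e in events]


# ---------------------------------------------------------------------------
# Disproportionality screen for ectopic-associated concepts
# ---------------------------------------------------------------------------


def ectopic_disproportionality(
    events: Sequence[ClinicalEvent],
    persons: Sequence[Person],
    observation_periods: Sequence[ObservationPeriod],
    reference_year: int = 2012,
    age_range: tuple[int, int] = (15, 55),
    episode_window_days: int = 60,
    pr_threshold: float = 5.0,
) -> pd.DataFrame:
    """Screen uncategorized concepts for association with ectopic diagnoses.

    Reference prevalence is person-level: the proportion of women in
    ``age_range`` with a full calendar year of observation in
    ``reference_year`` that have at least one record of the concept dated
    in that year.  Ectopic prevalence is window-level: the proportion of
    closed windows ``[diagnosis, diagnosis + episode_window_days]`` around
    categorized ectopic diagnoses that contain at least one record of the
    concept for the same person.  Concepts with
    ``prevalence_ect / prevalence_ref > pr_threshold`` are returned;
    concepts never seen in the reference group but seen in ectopic windows
    are returned with ``infinite_ratio=True``.
    """
    events = list(events)
    year_start = date(reference_year, 1, 1)
    year_end = date(reference_year, 12, 31)
    # age anchored at mid-year of the reference year
    midyear = date(reference_year, 7, 1)

    covered = {
        p.person_id
        for p in observation_periods
        if p.period_start <= year_start and p.period_end >= year_end
    }
    eligible = {
        p.person_id
        for p in persons
        if p.sex is Sex.FEMALE
        and age_range[0] <= p.age_at(midyear) <= age_range[1]
        and p.person_id in covered
    }
    if not eligible:
        raise ValidationError(
            "no eligible reference women: reference prevalence undefined"
        )

    # screen only concepts not already carrying a category
    candidate_concepts = {e.concept_id for e in events if e.category is None}

    ref_hits: dict[str, set[str]] = {c: set() for c in candidate_concepts}
    for e in events:
        if e.category is None and e.person_id in eligible and year_start <= e.event_date <= year_end:
            ref_hits[e.concept_id].add(e.person_id)

    ectopic_windows = sorted(
        {
            (e.person_id, e.event_date)
            for e in events
            if e.category is Category.ECTOPIC
        }
    )
    n_windows = len(ectopic_windows)
    ect_hits: dict[str, int] = {c: 0 for c in candidate_concepts}
    by_person: dict[str, list[ClinicalEvent]] = {}
    for e in events:
        if e.category is None:
            by_person.setdefault(e.person_id, []).append(e)
    for person_id, dx_date in ectopic_windows:
        window_end = dx_date + timedelta(days=episode_window_days)
        seen_in_window = {
            e.concept_id
            for e in by_person.get(person_id, [])
            if dx_date <= e.event_date <= window_end
        }
        for concept in seen_in_window:
            ect_hits[concept] += 1

    rows = []
    n_eligible = len(eligible)
    for concept in sorted(candidate_concepts):
        prev_ref = len(ref_hits[concept]) / n_eligible
        prev_ect = ect_hits[concept] / n_windows if n_windows else 0.0
        if prev_ect == 0.0:
            continue
        if prev_ref == 0.0:
            rows.append((concept, 0.0, prev_ect, float("inf"), True))
            continue
        ratio = prev_ect / prev_ref
        if ratio > pr_threshold:
            rows.append((concept, prev_ref, prev_ect, ratio, False))
    return pd.DataFrame(
        rows,
        columns=["concept_id", "prevalence_ref", "prevalence_ect", "ratio", "infinite_ratio"],
    )
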