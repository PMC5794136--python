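"""Synthetic cohorts with planted ground truth and configurable claims noise.

Every planted pregnancy has a known conception anchor (true start) and
outcome; markers are emitted at their category's gestational offset, so a
noise-free cohort is exactly recoverable by the algorithm.  Noise
injection adds the artifacts real claims data exhibit: repeat billings of
one delivery, rule-out abortion codes before preterm births, and isolated
historical outcome codes.

Randomness: one seed per run; each person draws from a substream derived
with a person-indexed spawn key, so person ``i`` is stable when
``n_persons`` changes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np

from .concepts import Category, ConceptSet, write_concept_sets
from .errors import ValidationError
from .model import (
    ClinicalEvent,
    Domain,
    ObservationPeriod,
    OutcomeClass,
    Person,
    Sex,
)
from .start import default_term_windows

#: synthetic concept vocabulary: category -> (concept_id, domain)
CATEGORY_CONCEPTS: dict[Category, tuple[str, Domain]] = {
    Category.LIVE_BIRTH: ("LB001", Domain.CONDITION),
    Category.STILLBIRTH: ("SB001", Domain.CONDITION),
    Category.ABORTION: ("AB001", Domain.CONDITION),
    Category.DELIVERY: ("DEL001", Domain.PROCEDURE),
    Category.ECTOPIC: ("ECT001", Domain.CONDITION),
    Category.METHOTREXATE: ("MTX001", Domain.DRUG),
    Category.ECTOPIC_SURGERY: ("ECTSURG001", Domain.PROCEDURE),
    Category.ECTOPIC_ASSOCIATED: ("ECTASSOC001", Domain.CONDITION),
    Category.PRETERM: ("PRETERM001", Domain.CONDITION),
    Category.GEST_AGE: ("GEST001", Domain.OBSERVATION),
    Category.LMP: ("LMP001", Domain.OBSERVATION),
    Category.PREG_CONFIRMATION: ("PCONF001", Domain.CONDITION),
    Category.ANTENATAL_VISIT: ("ANTE001", Domain.OBSERVATION),
    Category.COMPLICATION: ("COMPL001", Domain.CONDITION),
    Category.THREATENED_ABORTION: ("THREAB001", Domain.CONDITION),
    Category.AFP: ("AFP001", Domain.PROCEDURE),
    Category.NUCHAL_ULTRASOUND: ("ULS001", Domain.PROCEDURE),
    Category.FERTILITY_DATING: ("FERT001", Domain.PROCEDURE),
    Category.AMENORRHEA: ("AMEN001", Domain.CONDITION),
    Category.CONTRACEPTIVE: ("CONTRA001", Domain.DRUG),
    Category.URINE_TEST: ("URINE001", Domain.PROCEDURE),
}


def default_concept_set() -> ConceptSet:
    cs = ConceptSet()
    for category, (concept_id, _) in CATEGORY_CONCEPTS.items():
        cs.add(concept_id, category)
    return cs


@dataclass(frozen=True)
class MarkerSchedule:
    """Emission rule for one marker category: probability of appearing in
    an episode and the gestational day (with optional uniform jitter) on
    which the record is dated."""

    probability: float
    day: int
    jitter: int = 0


def default_marker_schedules() -> dict[Category, MarkerSchedule]:
    return {
        Category.LMP: MarkerSchedule(0.45, 0),
        Category.GEST_AGE: MarkerSchedule(0.30, 70),
        Category.FERTILITY_DATING: MarkerSchedule(0.06, 13),
        Category.NUCHAL_ULTRASOUND: MarkerSchedule(0.55, 89),
        Category.AFP: MarkerSchedule(0.40, 123),
        Category.AMENORRHEA: MarkerSchedule(0.25, 55),
        Category.URINE_TEST: MarkerSchedule(0.25, 55),
        # day 42 sits below every outcome's minimum term, so each planted
        # episode carries at least one care record besides the outcome
        Category.PREG_CONFIRMATION: MarkerSchedule(1.0, 42),
        Category.ANTENATAL_VISIT: MarkerSchedule(0.70, 63),
        Category.COMPLICATION: MarkerSchedule(0.10, 150),
    }


@dataclass
class SimConfig:
    n_persons: int = 100
    seed: int = 0
    epoch: date = date(2010, 1, 1)
    observation_days: int = 1095
    male_fraction: float = 0.0
    no_pregnancy_prob: float = 0.10
    second_episode_prob: float = 0.20
    outcome_probs: dict[OutcomeClass, float] = field(
        default_factory=lambda: {
            OutcomeClass.LIVE_BIRTH: 0.72,
            OutcomeClass.ABORTION: 0.25,
            OutcomeClass.STILLBIRTH: 0.01,
            OutcomeClass.ECTOPIC: 0.02,
        }
    )
    term_distributions: dict[OutcomeClass, tuple[float, float]] = field(
        default_factory=lambda: {
            OutcomeClass.LIVE_BIRTH: (280.0, 10.0),
            OutcomeClass.STILLBIRTH: (196.0, 20.0),
            OutcomeClass.ECTOPIC: (56.0, 7.0),
            OutcomeClass.ABORTION: (70.0, 12.0),
        }
    )
    markers: dict[Category, MarkerSchedule] = field(
        default_factory=default_marker_schedules
    )
    preterm_threshold_days: int = 259
    # noise rates
    repeat_billing_rate: float = 0.0
    repeat_billing_span_days: int = 3
    ruleout_rate: float = 0.0
    historical_rate: float = 0.0

    def validate(self) -> None:
        if self.n_persons < 0:
            raise ValidationError("n_persons must be non-negative")
        probs = [
            self.male_fraction,
            self.no_pregnancy_prob,
            self.second_episode_prob,
            self.repeat_billing_rate,
            self.ruleout_rate,
            self.historical_rate,
            *self.outcome_probs.values(),
            *(s.probability for s in self.markers.values()),
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValidationError("probabilities must lie in [0, 1]")
        total = sum(self.outcome_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError("outcome_probs must sum to 1")
        for schedule in self.markers.values():
            if schedule.day < 0 or schedule.jitter < 0:
                raise ValidationError("marker schedule days must be non-negative")


@dataclass
class GroundTruthEpisode:
    person_id: str
    true_start_date: date
    true_outcome_class: OutcomeClass
    true_outcome_date: date
    markers: tuple[str, ...] = ()
    noise: list[str] = field(default_factory=list)


def _person_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _draw_term(rng: np.random.Generator, config: SimConfig, outcome: OutcomeClass) -> int:
    mean, sd = config.term_distributions[outcome]
    windows = default_term_windows()[outcome]
    lo, hi = windows.min_term_days + 1, windows.max_term_days - 1
    for _ in range(1000):
        term = int(round(rng.normal(mean, sd)))
        if lo <= term <= hi:
            return term
    return int(np.clip(round(mean), lo, hi))


def _emit(category: Category, person_id: str, day: date, value: float | None = None) -> ClinicalEvent:
    concept_id, domain = CATEGORY_CONCEPTS[category]
    unit = "weeks" if category is Category.GEST_AGE else None
    return ClinicalEvent(
        person_id=person_id,
        concept_id=concept_id,
        domain=domain,
        event_date=day,
        value=value,
        unit=unit,
    )


def generate_cohort(
    config: SimConfig,
) -> tuple[list[Person], list[ObservationPeriod], list[ClinicalEvent], list[GroundTruthEpisode]]:
    """Generate a cohort with planted pregnancies; reproducible by seed."""
    config.validate()
    retry = {oc: w.retry_days for oc, w in default_term_windows().items()}
    outcome_classes = list(config.outcome_probs)
    outcome_p = np.array([config.outcome_probs[oc] for oc in outcome_classes])

    persons: list[Person] = []
    periods: list[ObservationPeriod] = []
    events: list[ClinicalEvent] = []
    ground_truth: list[GroundTruthEpisode] = []

    for i in range(config.n_persons):
        rng = _person_rng(config.seed, i)
        person_id = f"P{i:06d}"
        sex = Sex.MALE if rng.random() < config.male_fraction else Sex.FEMALE
        age_at_epoch = int(rng.integers(18, 41))
        birth_date = config.epoch - timedelta(
            days=age_at_epoch * 365 + int(rng.integers(0, 365))
        )
        persons.append(Person(person_id=person_id, sex=sex, birth_date=birth_date))
        period_end = config.epoch + timedelta(days=config.observation_days)
        periods.append(
            ObservationPeriod(
                person_id=person_id, period_start=config.epoch, period_end=period_end
            )
        )
        if rng.random() < config.no_pregnancy_prob:
            continue

        n_episodes = 2 if rng.random() < config.second_episode_prob else 1
        cursor: date | None = None  # prior outcome date
        prior_class: OutcomeClass | None = None
        for _ in range(n_episodes):
            outcome_class = outcome_classes[rng.choice(len(outcome_classes), p=outcome_p)]
            term = _draw_term(rng, config, outcome_class)
            if cursor is None:
                start = config.epoch + timedelta(days=int(rng.integers(400, 481)))
            else:
                gap = retry[prior_class] + 30 + int(rng.integers(0, 61))
                start = cursor + timedelta(days=gap)
            outcome_date = start + timedelta(days=term)
            if outcome_date > period_end - timedelta(days=20):
                break
            emitted: list[str] = []
            # outcome records
            events.append(_emit(_outcome_category(outcome_class), person_id, outcome_date))
            if outcome_class is OutcomeClass.ECTOPIC:
                events.append(_emit(Category.METHOTREXATE, person_id, outcome_date))
            if outcome_class is OutcomeClass.LIVE_BIRTH and term < config.preterm_threshold_days:
                events.append(
                    _emit(Category.PRETERM, person_id, start + timedelta(days=max(term - 7, 0)))
                )
            # markers on schedule
            for category, schedule in config.markers.items():
                if rng.random() >= schedule.probability:
                    continue
                day = schedule.day
                if schedule.jitter:
                    day += int(rng.integers(-schedule.jitter, schedule.jitter + 1))
                if not (0 <= day < term):
                    continue
                value = day / 7.0 if category is Category.GEST_AGE else None
                events.append(
                    _emit(category, person_id, start + timedelta(days=day), value)
                )
                emitted.append(category.value)
            ground_truth.append(
                GroundTruthEpisode(
                    person_id=person_id,
                    true_start_date=start,
                    true_outcome_class=outcome_class,
                    true_outcome_date=outcome_date,
                    markers=tuple(emitted),
                )
            )
            cursor = outcome_date
            prior_class = outcome_class

    if config.repeat_billing_rate or config.ruleout_rate or config.historical_rate:
        events = inject_noise(
            events, config, ground_truth, [p.person_id for p in persons]
        )

    events.sort(key=lambda e: (e.person_id, e.event_date, e.concept_id))
    return persons, periods, events, ground_truth


def _outcome_category(outcome_class: OutcomeClass) -> Category:
    return {
        OutcomeClass.LIVE_BIRTH: Category.LIVE_BIRTH,
        OutcomeClass.STILLBIRTH: Category.STILLBIRTH,
        OutcomeClass.ECTOPIC: Category.ECTOPIC,
        OutcomeClass.ABORTION: Category.ABORTION,
        OutcomeClass.DELIVERY: Category.DELIVERY,
    }[outcome_class]


def inject_noise(
    events: list[ClinicalEvent],
    config: SimConfig,
    ground_truth: list[GroundTruthEpisode],
    person_ids: list[str] | None = None,
) -> list[ClinicalEvent]:
    """Add claims noise; provenance tags are appended to the ground truth.

    - repeat billing: extra outcome-category rows 1..span days after each
      planted outcome;
    - rule-out abortion: an abortion code 5-30 days before a preterm live
      birth, together with an antenatal visit on the delivery date (the
      ongoing-care record that lets the classifier discard the rule-out);
    - historical codes: an isolated outcome code early in the observation
      period, far from any planted episode.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(999_983,)))
    out = list(events)
    for gt in ground_truth:
        if config.repeat_billing_rate and rng.random() < config.repeat_billing_rate:
            category = _outcome_category(gt.true_outcome_class)
            for extra in range(1 + int(rng.integers(0, 2))):
                offset = 1 + int(
                    rng.integers(0, max(config.repeat_billing_span_days, 1))
                )
                out.append(
                    _emit(
                        category,
                        gt.person_id,
                        gt.true_outcome_date + timedelta(days=offset),
                    )
                )
            gt.noise.append("repeat_billing")
        if (
            config.ruleout_rate
            and gt.true_outcome_class is OutcomeClass.LIVE_BIRTH
            and (gt.true_outcome_date - gt.true_start_date).days
            < config.preterm_threshold_days
            and rng.random() < config.ruleout_rate
        ):
            k = int(rng.integers(5, 31))
            out.append(
                _emit(
                    Category.ABORTION,
                    gt.person_id,
                    gt.true_outcome_date - timedelta(days=k),
                )
            )
            out.append(
                _emit(Category.ANTENATAL_VISIT, gt.person_id, gt.true_outcome_date)
            )
            gt.noise.append("ruleout_abortion")

    if config.historical_rate:
        if person_ids is not None:
            all_person_ids = sorted(person_ids)
        else:
            all_person_ids = sorted(
                {e.person_id for e in events} | {gt.person_id for gt in ground_truth}
            )
        historical_classes = [
            OutcomeClass.LIVE_BIRTH,
            OutcomeClass.STILLBIRTH,
            OutcomeClass.ABORTION,
        ]
        for person_id in all_person_ids:
            if rng.random() < config.historical_rate:
                outcome_class = historical_classes[int(rng.integers(0, 3))]
                day = config.epoch + timedelta(days=int(rng.integers(290, 331)))
                out.append(_emit(_outcome_category(outcome_class), person_id, day))
                for gt in ground_truth:
                    if gt.person_id == person_id:
                        gt.noise.append("historical_code")
    return out


# ---------------------------------------------------------------------------
# CSV writers (same dialect core_model reads)
# ---------------------------------------------------------------------------

_TABLE_FOR_DOMAIN = {
    Domain.CONDITION: "condition_occurrence",
    Domain.PROCEDURE: "procedure_occurrence",
    Domain.OBSERVATION: "observation",
    Domain.DRUG: "drug_exposure",
}


def write_cohort(
    out_dir: str | Path,
    persons: list[Person],
    periods: list[ObservationPeriod],
    events: list[ClinicalEvent],
    ground_truth: list[GroundTruthEpisode],
    concept_set: ConceptSet | None = None,
) -> None:
    """Write the cohort tables, ground truth, and concept set to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "person.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["person_id", "sex", "birth_date"])
        for p in persons:
            writer.writerow([p.person_id, p.sex.value, p.birth_date.isoformat()])
    with open(out_dir / "observation_period.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["person_id", "period_start", "period_end"])
        for op in periods:
            writer.writerow(
                [op.person_id, op.period_start.isoformat(), op.period_end.isoformat()]
            )
    by_table: dict[str, list[ClinicalEvent]] = {t: [] for t in _TABLE_FOR_DOMAIN.values()}
    for e in sorted(events, key=lambda e: (e.person_id, e.event_date, e.concept_id)):
        by_table[_TABLE_FOR_DOMAIN[e.domain]].append(e)
    for table, rows in by_table.items():
        with open(out_dir / f"{table}.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["person_id", "concept_id", "event_date", "value", "unit"])
            for e in rows:
                writer.writerow(
                    [
                        e.person_id,
                        e.concept_id,
                        e.event_date.isoformat(),
                        "" if e.value is None else repr(e.value),
                        e.unit or "",
                    ]
                )
    with open(out_dir / "ground_truth.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "person_id",
                "true_start_date",
                "true_outcome_class",
                "true_outcome_date",
                "markers",
                "noise",
            ]
        )
        for gt in ground_truth:
            writer.writerow(
                [
                    gt.person_id,
                    gt.true_start_date.isoformat(),
                    gt.true_outcome_class.value,
                    gt.true_outcome_date.isoformat(),
                    ";".join(gt.markers),
                    ";".join(gt.noise),
                ]
            )
    write_concept_sets(concept_set or default_concept_set(), out_dir / "concept_sets.csv")


def read_ground_truth(path: str | Path) -> list[GroundTruthEpisode]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                GroundTruthEpisode(
                    person_id=row["person_id"],
                    true_start_date=date.fromisoformat(row["true_start_date"]),
                    true_outcome_class=OutcomeClass(row["true_outcome_class"]),
                    true_outcome_date=date.fromisoformat(row["true_outcome_date"]),
                    markers=tuple(m for m in row["markers"].split(";") if m),
                    noise=[n for n in row["noise"].split(";") if n],
                )
            )
    return out
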