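"""Cohort orchestration: categorize -> classify -> estimate -> include."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

from .concepts import ConceptSet, categorize_events
from .config import AlgorithmConfig
from .model import (
    ClinicalEvent,
    Cohort,
    ObservationPeriod,
    Person,
    PregnancyEpisode,
    Sex,
)
from .outcomes import classify_outcomes
from .start import estimate_start

logger = logging.getLogger(__name__)


@dataclass
class InclusionReport:
    """Counts of candidate episodes excluded by each criterion, in the
    order the criteria are checked; each episode counts once under the
    first criterion it fails."""

    total_candidates: int = 0
    included: int = 0
    not_female: int = 0
    age_out_of_range: int = 0
    enrollment_gap: int = 0
    fewer_than_two_markers: int = 0

    @property
    def excluded(self) -> int:
        return (
            self.not_female
            + self.age_out_of_range
            + self.enrollment_gap
            + self.fewer_than_two_markers
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["excluded"] = self.excluded
        return d


def _marker_count(
    events: list[ClinicalEvent],
    start,
    end,
    count_outcome_as_marker: bool,
) -> int:
    from .concepts import START_CATEGORIES

    n = 0
    for e in events:
        if e.category is None or not (start <= e.event_date <= end):
            continue
        if not count_outcome_as_marker and e.category not in START_CATEGORIES:
            continue
        n += 1
    return n


def build_person_episodes(
    person: Person,
    periods: list[ObservationPeriod],
    events: list[ClinicalEvent],
    config: AlgorithmConfig,
    report: InclusionReport,
) -> list[PregnancyEpisode]:
    """Episodes for one person; exclusion counts accumulate into ``report``."""
    accepted = classify_outcomes(
        events,
        config.spacing_table,
        followup_window_days=config.followup_window_days,
        ectopic_confirm_days=config.ectopic_confirm_days,
        reassign_window_days=config.reassign_window_days,
        inclusive_spacing=config.inclusive_spacing,
    )
    episodes: list[PregnancyEpisode] = []
    prior = None
    index = 0
    for outcome in accepted:
        result = estimate_start(outcome, events, config, prior)
        prior = outcome
        report.total_candidates += 1
        if person.sex is not Sex.FEMALE:
            report.not_female += 1
            continue
        age = person.age_at(result.start_date)
        if not (config.min_age <= age <= config.max_age):
            report.age_out_of_range += 1
            continue
        if not any(p.covers(result.start_date, outcome.final_date) for p in periods):
            report.enrollment_gap += 1
            continue
        n_markers = _marker_count(
            events,
            result.start_date,
            outcome.final_date,
            config.count_outcome_as_marker,
        )
        if n_markers < config.min_markers:
            report.fewer_than_two_markers += 1
            continue
        report.included += 1
        episodes.append(
            PregnancyEpisode(
                person_id=person.person_id,
                episode_index=index,
                outcome_class=outcome.outcome_class,
                outcome_date=outcome.final_date,
                start_date=result.start_date,
                start_method=result.start_method,
                term_status=result.term_status,
            )
        )
        index += 1
    return episodes


def build_episodes(
    cohort: Cohort,
    concept_set: ConceptSet,
    config: AlgorithmConfig | None = None,
) -> tuple[list[PregnancyEpisode], InclusionReport]:
    """Run the full algorithm over a cohort.

    Per-person processing is independent: an unexpected failure on one
    person is logged and does not abort the run (configuration errors do
    propagate).
    """
    from .errors import ConfigurationError

    if config is None:
        config = AlgorithmConfig()
    config.validate()
    categorized = categorize_events(cohort.events, concept_set)
    events_by_person: dict[str, list[ClinicalEvent]] = {}
    for e in categorized:
        events_by_person.setdefault(e.person_id, []).append(e)
    periods_by_person: dict[str, list[ObservationPeriod]] = {}
    for p in cohort.observation_periods:
        periods_by_person.setdefault(p.person_id, []).append(p)

    episodes: list[PregnancyEpisode] = []
    report = InclusionReport()
    for person in cohort.persons:
        person_events = events_by_person.get(person.person_id, [])
        if not person_events:
            continue
        try:
            episodes.extend(
                build_person_episodes(
                    person,
                    periods_by_person.get(person.person_id, []),
                    person_events,
                    config,
                    report,
                )
            )
        except ConfigurationError:
            raise
        except Exception:  # noqa: BLE001 - isolate per-person failures
            logger.exception("processing failed for person %s", person.person_id)
    return episodes, report
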