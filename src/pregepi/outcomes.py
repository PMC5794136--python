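"""Outcome assessment: hierarchy walk, spacing, invalidation, confirmation.

Classes are processed in a fixed order (live birth, stillbirth, ectopic,
abortion, delivery-only) and, within a class, records in date order.
Same-day duplicate records of one class collapse to a single candidate
(repeat billing).  Accepted delivery-only candidates are re-labelled
live births.

Window conventions: every "N day period after" check excludes day 0 and
includes day N, i.e. ``(date, date + N]`` — except the 14-day ectopic
confirmation / abortion reassignment window, which includes day 0
because same-day treatment counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .concepts import Category
from .errors import ConfigurationError
from .model import ClinicalEvent, OutcomeClass

#: hierarchy order of assessment
OUTCOME_HIERARCHY = (
    OutcomeClass.LIVE_BIRTH,
    OutcomeClass.STILLBIRTH,
    OutcomeClass.ECTOPIC,
    OutcomeClass.ABORTION,
    OutcomeClass.DELIVERY,
)

_CLASS_CATEGORY = {
    OutcomeClass.LIVE_BIRTH: Category.LIVE_BIRTH,
    OutcomeClass.STILLBIRTH: Category.STILLBIRTH,
    OutcomeClass.ECTOPIC: Category.ECTOPIC,
    OutcomeClass.ABORTION: Category.ABORTION,
    OutcomeClass.DELIVERY: Category.DELIVERY,
}

_FOLLOWUP_CATEGORIES = frozenset({Category.ANTENATAL_VISIT, Category.PREG_CONFIRMATION})
_TREATMENT_CATEGORIES = frozenset({Category.METHOTREXATE, Category.ECTOPIC_SURGERY})


class RejectionReason(str, Enum):
    SPACING = "spacing"
    INVALIDATED_BY_FOLLOWUP = "invalidated_by_followup"
    UNCONFIRMED_ECTOPIC = "unconfirmed_ectopic"
    NONE = "none"


@dataclass(frozen=True)
class SpacingTable:
    """Minimum day gaps between ordered pairs of outcome classes.

    Keys are ``(earlier_class, later_class)``; the applicable entry for a
    comparison is chosen by date order of the two outcomes.  The shipped
    defaults are clearly-labelled configuration, clinically plausible but
    not ground truth; analyses should set their own table.
    """

    min_days: Mapping[tuple[OutcomeClass, OutcomeClass], int]

    def entry(self, earlier: OutcomeClass, later: OutcomeClass) -> int:
        try:
            return self.min_days[(earlier, later)]
        except KeyError:
            raise ConfigurationError(
                f"spacing table has no entry for ({earlier.value}, {later.value})"
            ) from None

    def validate(self) -> None:
        for a in OUTCOME_HIERARCHY:
            for b in OUTCOME_HIERARCHY:
                days = self.entry(a, b)
                if days <= 0:
                    raise ConfigurationError(
                        f"spacing entry ({a.value}, {b.value}) must be positive"
                    )

    @classmethod
    def default(cls) -> "SpacingTable":
        table: dict[tuple[OutcomeClass, OutcomeClass], int] = {}
        for a in OUTCOME_HIERARCHY:
            for b in OUTCOME_HIERARCHY:
                if a is OutcomeClass.ABORTION:
                    days = 14
                elif b in (OutcomeClass.ABORTION, OutcomeClass.ECTOPIC):
                    days = 56
                elif a is OutcomeClass.ECTOPIC:
                    days = 56
                else:
                    days = 182
                table[(a, b)] = days
        return cls(min_days=table)


@dataclass(frozen=True)
class OutcomeCandidate:
    person_id: str
    outcome_class: OutcomeClass
    record_date: date
    final_date: date
    accepted: bool = False
    rejection_reason: RejectionReason = RejectionReason.NONE


def spacing_ok(
    candidate_date: date,
    candidate_class: OutcomeClass,
    accepted_outcomes: Sequence[OutcomeCandidate],
    spacing_table: SpacingTable,
    inclusive: bool = True,
) -> bool:
    """True iff the candidate clears the minimum gap vs every accepted outcome.

    With ``inclusive`` (default) a gap exactly equal to the table entry
    passes; set False for the strict reading.
    """
    for accepted in accepted_outcomes:
        gap = abs((candidate_date - accepted.final_date).days)
        if accepted.final_date <= candidate_date:
            required = spacing_table.entry(accepted.outcome_class, candidate_class)
        else:
            required = spacing_table.entry(candidate_class, accepted.outcome_class)
        if (gap < required) if inclusive else (gap <= required):
            return False
    return True


def invalidated_by_followup(
    candidate_date: date,
    events: Iterable[ClinicalEvent],
    window_days: int = 42,
) -> bool:
    """Antenatal visit or pregnancy confirmation in ``(date, date + window]``?"""
    window_end = candidate_date + timedelta(days=window_days)
    return any(
        e.category in _FOLLOWUP_CATEGORIES
        and candidate_date < e.event_date <= window_end
        for e in events
    )


def confirm_and_date_ectopic(
    candidate: OutcomeCandidate,
    events: Iterable[ClinicalEvent],
    confirm_window_days: int = 14,
) -> tuple[bool, date]:
    """Check the ectopic confirmation requirement and reassign the date.

    Confirmation requires a methotrexate exposure, ectopic surgery, or an
    ectopic-associated concept in ``[record, record + window]``.  The final
    date becomes the latest treatment (methotrexate/surgery) date in that
    window; association-only confirmation keeps the record date.
    """
    window_end = candidate.record_date + timedelta(days=confirm_window_days)
    treatment_dates = [
        e.event_date
        for e in events
        if e.category in _TREATMENT_CATEGORIES
        and candidate.record_date <= e.event_date <= window_end
    ]
    if treatment_dates:
        return True, max(treatment_dates)
    associated = any(
        e.category is Category.ECTOPIC_ASSOCIATED
        and candidate.record_date <= e.event_date <= window_end
        for e in events
    )
    return associated, candidate.record_date


def reassign_abortion_date(
    candidate: OutcomeCandidate,
    events: Iterable[ClinicalEvent],
    window_days: int = 14,
) -> date:
    """Latest abortion-category record date in ``[record, record + window]``."""
    window_end = candidate.record_date + timedelta(days=window_days)
    dates = [
        e.event_date
        for e in events
        if e.category is Category.ABORTION
        and candidate.record_date <= e.event_date <= window_end
    ]
    return max(dates, default=candidate.record_date)


def assess_outcomes(
    person_events: Sequence[ClinicalEvent],
    spacing_table: SpacingTable,
    *,
    followup_window_days: int = 42,
    ectopic_confirm_days: int = 14,
    reassign_window_days: int = 14,
    inclusive_spacing: bool = True,
) -> list[OutcomeCandidate]:
    """Walk the hierarchy and return every candidate, accepted or not."""
    all_candidates: list[OutcomeCandidate] = []
    accepted: list[OutcomeCandidate] = []

    for outcome_class in OUTCOME_HIERARCHY:
        category = _CLASS_CATEGORY[outcome_class]
        record_dates = sorted(
            {e.event_date for e in person_events if e.category is category}
        )
        for record_date in record_dates:
            candidate = OutcomeCandidate(
                person_id=person_events[0].person_id,
                outcome_class=outcome_class,
                record_date=record_date,
                final_date=record_date,
            )
            if not spacing_ok(
                record_date, outcome_class, accepted, spacing_table, inclusive_spacing
            ):
                all_candidates.append(
                    replace(candidate, rejection_reason=RejectionReason.SPACING)
                )
                continue
            # live births are never tested for follow-up invalidation
            if outcome_class is not OutcomeClass.LIVE_BIRTH and invalidated_by_followup(
                record_date, person_events, followup_window_days
            ):
                all_candidates.append(
                    replace(
                        candidate,
                        rejection_reason=RejectionReason.INVALIDATED_BY_FOLLOWUP,
                    )
                )
                continue
            final_date = record_date
            if outcome_class is OutcomeClass.ECTOPIC:
                confirmed, final_date = confirm_and_date_ectopic(
                    candidate, person_events, ectopic_confirm_days
                )
                if not confirmed:
                    all_candidates.append(
                        replace(
                            candidate,
                            rejection_reason=RejectionReason.UNCONFIRMED_ECTOPIC,
                        )
                    )
                    continue
            elif outcome_class is OutcomeClass.ABORTION:
                final_date = reassign_abortion_date(
                    candidate, person_events, reassign_window_days
                )
            final_class = (
                OutcomeClass.LIVE_BIRTH
                if outcome_class is OutcomeClass.DELIVERY
                else outcome_class
            )
            done = replace(
                candidate,
                outcome_class=final_class,
                final_date=final_date,
                accepted=True,
            )
            accepted.append(done)
            all_candidates.append(done)
    return all_candidates


def classify_outcomes(
    person_events: Sequence[ClinicalEvent],
    spacing_table: SpacingTable,
    **kwargs,
) -> list[OutcomeCandidate]:
    """Accepted outcome candidates for one person, sorted by final date."""
    if not person_events:
        return []
    candidates = assess_outcomes(person_events, spacing_table, **kwargs)
    return sorted(
        (c for c in candidates if c.accepted),
        key=lambda c: (c.final_date, c.record_date),
    )
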