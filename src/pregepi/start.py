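"""Start-date estimation via the ranked marker hierarchy.

For each accepted outcome the highest-ranked eligible marker wins; its
category-specific offset is subtracted from the marker date.  A marker is
eligible when the implied term is strictly between the outcome's minimum
and maximum term lengths and the marker does not predate the prior
outcome's retry period.  With no eligible marker, an outcome- and
term-specific average gestational length is subtracted from the outcome
date, and the result is clamped forward to the prior outcome date plus
its retry period.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import TYPE_CHECKING, Iterable, Sequence

from .concepts import Category
from .errors import ConfigurationError
from .model import ClinicalEvent, OutcomeClass, StartMethod, TermStatus
from .outcomes import OutcomeCandidate

if TYPE_CHECKING:  # pragma: no cover
    from .config import AlgorithmConfig


@dataclass(frozen=True)
class OutcomeWindows:
    """Term search windows and retry period for one outcome class."""

    max_term_days: int
    min_term_days: int
    retry_days: int

    def __post_init__(self):
        if not (0 < self.min_term_days < self.max_term_days):
            raise ConfigurationError(
                "term windows require 0 < min_term_days < max_term_days"
            )
        if self.retry_days <= 0:
            raise ConfigurationError("retry_days must be positive")


def default_term_windows() -> dict[OutcomeClass, OutcomeWindows]:
    """Shipped term windows.  The live-birth 301/161 bounds come from the
    published definition; retry periods and non-live-birth bounds are
    labelled configuration."""
    return {
        OutcomeClass.LIVE_BIRTH: OutcomeWindows(301, 161, 28),
        OutcomeClass.STILLBIRTH: OutcomeWindows(301, 140, 28),
        OutcomeClass.ECTOPIC: OutcomeWindows(112, 42, 14),
        OutcomeClass.ABORTION: OutcomeWindows(168, 42, 14),
    }


#: (category, method, offset in days); None offset means use the event's
#: gestational-age value.  Order is the ranked hierarchy.
START_HIERARCHY: tuple[tuple[Category, StartMethod, int | None], ...] = (
    (Category.LMP, StartMethod.LMP, 0),
    (Category.GEST_AGE, StartMethod.GEST_AGE, None),
    (Category.FERTILITY_DATING, StartMethod.FERTILITY, 13),
    (Category.NUCHAL_ULTRASOUND, StartMethod.NUCHAL_ULTRASOUND, 89),
    (Category.AFP, StartMethod.AFP, 123),
    (Category.AMENORRHEA, StartMethod.AMENORRHEA, 55),
    (Category.URINE_TEST, StartMethod.URINE_TEST, 55),
)

#: methods whose final start is adjustable by contraceptive/confirmation
ADJUSTABLE_METHODS = frozenset(
    {StartMethod.AMENORRHEA, StartMethod.URINE_TEST, StartMethod.OUTCOME_ESTIMATE}
)


@dataclass(frozen=True)
class GestationalEstimates:
    """Average gestational length (days) by outcome and term status.

    Full-term values are the published averages; the preterm live-birth
    value is configuration.
    """

    estimates: dict[tuple[OutcomeClass, TermStatus], int] = field(
        default_factory=lambda: {
            (OutcomeClass.LIVE_BIRTH, TermStatus.FULL_TERM): 280,
            (OutcomeClass.LIVE_BIRTH, TermStatus.PRETERM): 245,
            (OutcomeClass.STILLBIRTH, TermStatus.FULL_TERM): 196,
            (OutcomeClass.ECTOPIC, TermStatus.FULL_TERM): 56,
            (OutcomeClass.ABORTION, TermStatus.FULL_TERM): 70,
        }
    )

    def lookup(self, outcome_class: OutcomeClass, term_status: TermStatus) -> int:
        key = (outcome_class, term_status)
        if key in self.estimates:
            return self.estimates[key]
        fallback = (outcome_class, TermStatus.FULL_TERM)
        if fallback in self.estimates:
            return self.estimates[fallback]
        raise ConfigurationError(
            f"no gestational estimate for {outcome_class.value}/{term_status.value}"
        )


@dataclass(frozen=True)
class EligibleMarker:
    category: Category
    method: StartMethod
    event_date: date
    implied_start: date


@dataclass(frozen=True)
class StartResult:
    start_date: date
    start_method: StartMethod
    term_status: TermStatus
    clamped: bool = False
    adjusted: bool = False


def _gest_age_days(event: ClinicalEvent) -> int | None:
    if event.value is None:
        return None
    if event.unit == "days":
        return int(round(event.value))
    # default unit is weeks
    return int(round(event.value * 7))


def _implied_start(event: ClinicalEvent, offset: int | None) -> date | None:
    if offset is None:
        ga = _gest_age_days(event)
        if ga is None:
            return None
        return event.event_date - timedelta(days=ga)
    return event.event_date - timedelta(days=offset)


def eligible_markers(
    outcome: OutcomeCandidate,
    events: Iterable[ClinicalEvent],
    term_windows: dict[OutcomeClass, OutcomeWindows],
    prior_outcome: OutcomeCandidate | None = None,
    offsets: dict[StartMethod, int] | None = None,
) -> list[EligibleMarker]:
    """All hierarchy markers eligible for this outcome, in hierarchy order
    then event-date order.  Term bounds are strict; markers dated before
    the prior outcome's retry horizon are excluded."""
    windows = term_windows[outcome.outcome_class]
    retry_floor: date | None = None
    if prior_outcome is not None:
        prior_windows = term_windows[prior_outcome.outcome_class]
        retry_floor = prior_outcome.final_date + timedelta(days=prior_windows.retry_days)
    out: list[EligibleMarker] = []
    for category, method, default_offset in START_HIERARCHY:
        offset = default_offset
        if offsets is not None and default_offset is not None:
            offset = offsets.get(method, default_offset)
        for event in sorted(
            (e for e in events if e.category is category), key=lambda e: e.event_date
        ):
            implied = _implied_start(event, offset)
            if implied is None:
                continue
            term = (outcome.final_date - implied).days
            if not (windows.min_term_days < term < windows.max_term_days):
                continue
            if retry_floor is not None and event.event_date < retry_floor:
                continue
            out.append(
                EligibleMarker(
                    category=category,
                    method=method,
                    event_date=event.event_date,
                    implied_start=implied,
                )
            )
    return out


def adjust_start(
    start: date,
    method: StartMethod,
    events: Iterable[ClinicalEvent],
    config: "AlgorithmConfig",
    outcome: OutcomeCandidate,
    prior_outcome: OutcomeCandidate | None = None,
) -> tuple[date, bool]:
    """Contraceptive/confirmation adjustment for the weaker start methods.

    This rule is a documented reconstruction (the published appendix with
    the exact rule is not reproducible here): a contraceptive exposure
    strictly after the estimated start and earlier than ``outcome -
    min_term`` moves the start to the day after the last such exposure;
    then, if the earliest pregnancy-confirmation record precedes the
    start, the start moves back to that record date minus
    ``confirmation_lead_days``.  A move is suppressed when it would leave
    the strict term bounds or violate the prior outcome's retry horizon.
    """
    if method not in ADJUSTABLE_METHODS:
        return start, False
    windows = config.term_windows[outcome.outcome_class]
    retry_floor: date | None = None
    if prior_outcome is not None:
        prior_windows = config.term_windows[prior_outcome.outcome_class]
        retry_floor = prior_outcome.final_date + timedelta(days=prior_windows.retry_days)

    def acceptable(candidate: date) -> bool:
        term = (outcome.final_date - candidate).days
        if not (windows.min_term_days < term < windows.max_term_days):
            return False
        if retry_floor is not None and candidate < retry_floor:
            return False
        return True

    adjusted = False
    current = start
    latest_allowed = outcome.final_date - timedelta(days=windows.min_term_days)
    contraceptive_dates = [
        e.event_date
        for e in events
        if e.category is Category.CONTRACEPTIVE
        and current < e.event_date < latest_allowed
    ]
    if contraceptive_dates:
        candidate = max(contraceptive_dates) + timedelta(days=1)
        if acceptable(candidate):
            current = candidate
            adjusted = True
    confirmation_dates = [
        e.event_date for e in events if e.category is Category.PREG_CONFIRMATION
    ]
    if confirmation_dates:
        earliest = min(confirmation_dates)
        if earliest < current:
            candidate = earliest - timedelta(days=config.confirmation_lead_days)
            if acceptable(candidate):
                current = candidate
                adjusted = True
    return current, adjusted


def estimate_start(
    outcome: OutcomeCandidate,
    events: Sequence[ClinicalEvent],
    config: "AlgorithmConfig",
    prior_outcome: OutcomeCandidate | None = None,
) -> StartResult:
    """Estimate the start date for one accepted outcome."""
    markers = eligible_markers(
        outcome, events, config.term_windows, prior_outcome, config.offsets
    )
    clamped = False
    if markers:
        best = markers[0]  # hierarchy order, then earliest event date
        start = best.implied_start
        method = best.method
        term_status = TermStatus.NOT_APPLICABLE
    else:
        method = StartMethod.OUTCOME_ESTIMATE
        windows = config.term_windows[outcome.outcome_class]
        search_start = outcome.final_date - timedelta(days=windows.max_term_days)
        preterm = any(
            e.category is Category.PRETERM
            and search_start <= e.event_date <= outcome.final_date
            for e in events
        )
        term_status = TermStatus.PRETERM if preterm else TermStatus.FULL_TERM
        estimate = config.gestational_estimates.lookup(
            outcome.outcome_class, term_status
        )
        start = outcome.final_date - timedelta(days=estimate)
    if prior_outcome is not None:
        prior_windows = config.term_windows[prior_outcome.outcome_class]
        floor = prior_outcome.final_date + timedelta(days=prior_windows.retry_days)
        if floor > start:
            start = floor
            clamped = True
    adjusted = False
    if method in ADJUSTABLE_METHODS:
        start, adjusted = adjust_start(
            start, method, events, config, outcome, prior_outcome
        )
    return StartResult(
        start_date=start,
        start_method=method,
        term_status=term_status,
        clamped=clamped,
        adjusted=adjusted,
    )
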