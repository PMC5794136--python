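from datetime import date, timedelta

import numpy as np
import pytest

from pregepi.concepts import Category
from pregepi.errors import ConfigurationError
from pregepi.model import OutcomeClass
from pregepi.outcomes import (
    OutcomeCandidate,
    RejectionReason,
    SpacingTable,
    assess_outcomes,
    classify_outcomes,
    confirm_and_date_ectopic,
    invalidated_by_followup,
    reassign_abortion_date,
    spacing_ok,
)

from support import day, ev, explicit_spacing

LB = OutcomeClass.LIVE_BIRTH
SB = OutcomeClass.STILLBIRTH
ECT = OutcomeClass.ECTOPIC
AB = OutcomeClass.ABORTION
DEL = OutcomeClass.DELIVERY


def _accepted(cls, offset):
    return OutcomeCandidate("P1", cls, day(offset), day(offset), accepted=True)


# --- spacing_ok -------------------------------------------------------------


def test_spacing_vacuous_without_accepted():
    assert spacing_ok(day(0), LB, [], explicit_spacing())


def test_spacing_one_day_apart_fails():
    table = explicit_spacing(lb_lb=182)
    assert not spacing_ok(day(1), LB, [_accepted(LB, 0)], table)


def test_spacing_boundary_inclusive():
    table = explicit_spacing(lb_lb=182)
    assert spacing_ok(day(182), LB, [_accepted(LB, 0)], table)
    assert not spacing_ok(day(181), LB, [_accepted(LB, 0)], table)


def test_spacing_strict_switch():
    table = explicit_spacing(lb_lb=182)
    assert not spacing_ok(day(182), LB, [_accepted(LB, 0)], table, inclusive=False)
    assert spacing_ok(day(183), LB, [_accepted(LB, 0)], table, inclusive=False)


def test_spacing_uses_date_ordered_pair():
    table = explicit_spacing(lb_ab=100, ab_lb=10)
    # abortion candidate AFTER the live birth -> (lb, ab) entry applies
    assert not spacing_ok(day(50), AB, [_accepted(LB, 0)], table)
    # abortion candidate BEFORE the live birth -> (ab, lb) entry applies
    assert spacing_ok(day(-50), AB, [_accepted(LB, 0)], table)


def test_spacing_missing_entry_is_config_error():
    table = SpacingTable(min_days={})
    with pytest.raises(ConfigurationError, match="live_birth"):
        spacing_ok(day(1), LB, [_accepted(LB, 0)], table)


# --- invalidated_by_followup ------------------------------------------------


def test_followup_confirmation_30_days_after_invalidates():
    events = [ev(Category.STILLBIRTH, 0), ev(Category.PREG_CONFIRMATION, 30)]
    assert invalidated_by_followup(day(0), events)


def test_no_followup_events():
    assert not invalidated_by_followup(day(0), [ev(Category.STILLBIRTH, 0)])


def test_followup_window_sweep_boundary_is_42():
    # independent sweep oracle: offsets 1..100, window (0, 42]
    for offset in range(1, 101):
        events = [ev(Category.ANTENATAL_VISIT, offset)]
        expected = 1 <= offset <= 42
        assert invalidated_by_followup(day(0), events) == expected, offset


def test_followup_same_day_does_not_invalidate():
    assert not invalidated_by_followup(day(0), [ev(Category.PREG_CONFIRMATION, 0)])


# --- confirm_and_date_ectopic ----------------------------------------------


def _ect_candidate(offset=0):
    return OutcomeCandidate("P1", ECT, day(offset), day(offset))


def test_ectopic_methotrexate_reassigns_to_treatment_date():
    events = [ev(Category.ECTOPIC, 0), ev(Category.METHOTREXATE, 10)]
    confirmed, final = confirm_and_date_ectopic(_ect_candidate(), events)
    assert confirmed and final == day(10)


def test_ectopic_unconfirmed_without_qualifying_events():
    confirmed, final = confirm_and_date_ectopic(_ect_candidate(), [ev(Category.ECTOPIC, 0)])
    assert not confirmed and final == day(0)


def test_ectopic_confirmation_sweep_boundary_is_14():
    for offset in range(0, 61):
        events = [ev(Category.ECTOPIC, 0), ev(Category.METHOTREXATE, offset)]
        confirmed, _ = confirm_and_date_ectopic(_ect_candidate(), events)
        assert confirmed == (offset <= 14), offset


def test_ectopic_association_only_keeps_record_date():
    events = [ev(Category.ECTOPIC, 0), ev(Category.ECTOPIC_ASSOCIATED, 5)]
    confirmed, final = confirm_and_date_ectopic(_ect_candidate(), events)
    assert confirmed and final == day(0)


def test_ectopic_latest_treatment_wins():
    events = [
        ev(Category.ECTOPIC, 0),
        ev(Category.METHOTREXATE, 3),
        ev(Category.ECTOPIC_SURGERY, 9),
        ev(Category.METHOTREXATE, 20),  # outside window
    ]
    _, final = confirm_and_date_ectopic(_ect_candidate(), events)
    assert final == day(9)


# --- reassign_abortion_date -------------------------------------------------


def test_abortion_reassigned_to_latest_in_window():
    events = [ev(Category.ABORTION, d) for d in (0, 3, 9)]
    candidate = OutcomeCandidate("P1", AB, day(0), day(0))
    assert reassign_abortion_date(candidate, events) == day(9)


def test_abortion_single_record_keeps_date():
    candidate = OutcomeCandidate("P1", AB, day(0), day(0))
    assert reassign_abortion_date(candidate, [ev(Category.ABORTION, 0)]) == day(0)


def test_abortion_ignores_beyond_window():
    events = [ev(Category.ABORTION, 0), ev(Category.ABORTION, 20)]
    candidate = OutcomeCandidate("P1", AB, day(0), day(0))
    assert reassign_abortion_date(candidate, events) == day(0)


# --- classify_outcomes ------------------------------------------------------


def test_single_live_birth():
    out = classify_outcomes([ev(Category.LIVE_BIRTH, 100)], explicit_spacing())
    assert len(out) == 1
    assert out[0].outcome_class is LB
    assert out[0].final_date == day(100)


def test_abortion_rejected_by_spacing():
    table = explicit_spacing(lb_ab=56)
    events = [ev(Category.LIVE_BIRTH, 0), ev(Category.ABORTION, 10)]
    out = classify_outcomes(events, table)
    assert [c.outcome_class for c in out] == [LB]
    rejected = [c for c in assess_outcomes(events, table) if not c.accepted]
    assert rejected[0].rejection_reason is RejectionReason.SPACING


def test_delivery_relabeled_live_birth():
    out = classify_outcomes([ev(Category.DELIVERY, 50)], explicit_spacing())
    assert len(out) == 1
    assert out[0].outcome_class is LB


def test_delivery_invalidated_by_followup():
    events = [ev(Category.DELIVERY, 50), ev(Category.ANTENATAL_VISIT, 70)]
    assert classify_outcomes(events, explicit_spacing()) == []


def test_live_birth_not_invalidated_by_followup():
    events = [ev(Category.LIVE_BIRTH, 50), ev(Category.ANTENATAL_VISIT, 70)]
    assert len(classify_outcomes(events, explicit_spacing())) == 1


def test_same_day_duplicates_collapse():
    events = [ev(Category.LIVE_BIRTH, 50), ev(Category.LIVE_BIRTH, 50)]
    assert len(classify_outcomes(events, explicit_spacing())) == 1


def test_empty_events():
    assert classify_outcomes([], explicit_spacing()) == []


def test_locality_later_event_no_effect():
    table = explicit_spacing(lb_lb=182)
    events = [ev(Category.LIVE_BIRTH, 0), ev(Category.ABORTION, 300)]
    baseline = classify_outcomes(events, table)
    with_late = classify_outcomes(
        events + [ev(Category.PREG_CONFIRMATION, 500)], table
    )
    assert baseline == with_late


# --- brute-force oracle -----------------------------------------------------

_ORACLE_ORDER = (
    (Category.LIVE_BIRTH, LB),
    (Category.STILLBIRTH, SB),
    (Category.ECTOPIC, ECT),
    (Category.ABORTION, AB),
    (Category.DELIVERY, DEL),
)


def oracle_classify(events, table):
    """Naive independent re-derivation of the classification rules."""
    accepted = []  # (class, final_date)
    for category, cls in _ORACLE_ORDER:
        for d in sorted({e.event_date for e in events if e.category is category}):
            ok = True
            for acls, adate in accepted:
                gap = abs((d - adate).days)
                pair = (acls, cls) if adate <= d else (cls, acls)
                if gap < table.min_days[pair]:
                    ok = False
            if not ok:
                continue
            if cls is not LB:
                invalid = False
                for e in events:
                    if e.category in (Category.ANTENATAL_VISIT, Category.PREG_CONFIRMATION):
                        delta = (e.event_date - d).days
                        if 1 <= delta <= 42:
                            invalid = True
                if invalid:
                    continue
            final = d
            if cls is ECT:
                treatments = []
                associated = False
                for e in events:
                    delta = (e.event_date - d).days
                    if 0 <= delta <= 14:
                        if e.category in (Category.METHOTREXATE, Category.ECTOPIC_SURGERY):
                            treatments.append(e.event_date)
                        if e.category is Category.ECTOPIC_ASSOCIATED:
                            associated = True
                if treatments:
                    final = max(treatments)
                elif not associated:
                    continue
            if cls is AB:
                dates = [
                    e.event_date
                    for e in events
                    if e.category is Category.ABORTION
                    and 0 <= (e.event_date - d).days <= 14
                ]
                final = max(dates)
            out_cls = LB if cls is DEL else cls
            accepted.append((out_cls, final))
    return sorted(accepted, key=lambda pair: (pair[1], pair[0].value))


_NOISE_CATEGORIES = [
    Category.LIVE_BIRTH,
    Category.STILLBIRTH,
    Category.ECTOPIC,
    Category.ABORTION,
    Category.DELIVERY,
    Category.METHOTREXATE,
    Category.ECTOPIC_SURGERY,
    Category.ECTOPIC_ASSOCIATED,
    Category.ANTENATAL_VISIT,
    Category.PREG_CONFIRMATION,
]


def random_case(rng):
    n = int(rng.integers(1, 9))
    events = [
        ev(
            _NOISE_CATEGORIES[int(rng.integers(0, len(_NOISE_CATEGORIES)))],
            int(rng.integers(0, 400)),
        )
        for _ in range(n)
    ]
    table = explicit_spacing(default=int(rng.integers(1, 200)))
    return events, table


def run_oracle_equivalence(n_cases, seed=0):
    rng = np.random.default_rng(seed)
    for case in range(n_cases):
        events, table = random_case(rng)
        got = sorted(
            ((c.outcome_class, c.final_date) for c in classify_outcomes(events, table)),
            key=lambda pair: (pair[1], pair[0].value),
        )
        expected = oracle_classify(events, table)
        assert got == expected, f"case {case}: {events}"


def test_oracle_equivalence_smoke():
    run_oracle_equivalence(2000, seed=123)


def test_no_pair_closer_than_spacing_table():
    rng = np.random.default_rng(42)
    for _ in range(500):
        events, table = random_case(rng)
        accepted = classify_outcomes(events, table)
        for i, a in enumerate(accepted):
            for b in accepted[i + 1 :]:
                gap = abs((a.final_date - b.final_date).days)
                earlier, later = (
                    (a, b) if a.final_date <= b.final_date else (b, a)
                )
                required = table.min_days[(earlier.outcome_class, later.outcome_class)]
                # reassignment may shrink a record-date gap; the record dates
                # themselves must have satisfied the table
                record_gap = abs((a.record_date - b.record_date).days)
                assert gap >= required or record_gap != gap
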