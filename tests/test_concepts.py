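from datetime import date

import pytest
from hypothesis import given, strategies as st

from pregepi.concepts import (
    Category,
    ConceptSet,
    OUTCOME_CATEGORIES,
    START_CATEGORIES,
    categorize_events,
    ectopic_disproportionality,
    load_concept_sets,
    write_concept_sets,
)
from pregepi.errors import RowError, ValidationError
from pregepi.model import ClinicalEvent, Domain, ObservationPeriod, Person, Sex

from support import ev


def test_category_families_disjoint_and_complete():
    assert OUTCOME_CATEGORIES.isdisjoint(START_CATEGORIES)
    assert OUTCOME_CATEGORIES | START_CATEGORIES == frozenset(Category)
    assert len(OUTCOME_CATEGORIES) == 8
    assert len(START_CATEGORIES) == 13


def test_load_empty_file(tmp_path):
    path = tmp_path / "cs.csv"
    path.write_text("concept_id,category\n")
    assert len(load_concept_sets(path)) == 0


def test_load_single_row(tmp_path):
    path = tmp_path / "cs.csv"
    path.write_text("concept_id,category\nC1,live_birth\n")
    cs = load_concept_sets(path)
    assert cs.category("C1") is Category.LIVE_BIRTH


def test_conflicting_duplicate_rejected(tmp_path):
    path = tmp_path / "cs.csv"
    path.write_text("concept_id,category\nC1,live_birth\nC1,abortion\n")
    with pytest.raises(ValidationError):
        load_concept_sets(path)


def test_consistent_duplicate_allowed(tmp_path):
    path = tmp_path / "cs.csv"
    path.write_text("concept_id,category\nC1,live_birth\nC1,live_birth\n")
    assert len(load_concept_sets(path)) == 1


def test_unknown_category_lists_valid_names(tmp_path):
    path = tmp_path / "cs.csv"
    path.write_text("concept_id,category\nC1,nonsense\n")
    with pytest.raises(RowError) as excinfo:
        load_concept_sets(path)
    assert "live_birth" in str(excinfo.value)


def test_concept_set_roundtrip(tmp_path):
    cs = ConceptSet()
    cs.add("C1", Category.LIVE_BIRTH)
    cs.add("C2", Category.NUCHAL_ULTRASOUND)
    path = tmp_path / "cs.csv"
    write_concept_sets(cs, path)
    assert load_concept_sets(path).entries == cs.entries


def _raw(concept_id, d, person="P1"):
    return ClinicalEvent(person, concept_id, Domain.CONDITION, d)


def test_all_unknown_concepts_uncategorized():
    events = [_raw("X1", date(2010, 1, 1)), _raw("X2", date(2010, 1, 2))]
    out = categorize_events(events, ConceptSet())
    assert all(e.category is None for e in out)
    assert len(out) == len(events)


def test_mixed_known_unknown():
    cs = ConceptSet()
    cs.add("C1", Category.ECTOPIC)
    events = [_raw("C1", date(2010, 1, 1)), _raw("X1", date(2010, 1, 2))]
    out = categorize_events(events, cs)
    assert out[0].category is Category.ECTOPIC
    assert out[1].category is None


@given(st.permutations(list(range(6))))
def test_categorization_stable_under_reordering(order):
    cs = ConceptSet()
    cs.add("C1", Category.LIVE_BIRTH)
    cs.add("C2", Category.LMP)
    events = [
        _raw(concept, date(2010, 1, 1 + i))
        for i, concept in enumerate(["C1", "C2", "X1", "C1", "X2", "C2"])
    ]
    shuffled = [events[i] for i in order]
    out = categorize_events(shuffled, cs)
    expected = {e: e.with_category(cs.category(e.concept_id)) for e in events}
    assert out == [expected[e] for e in shuffled]


# --- disproportionality -----------------------------------------------------


def _reference_population(n, year=2012):
    persons = [
        Person(f"R{i}", Sex.FEMALE, date(year - 30, 1, 1)) for i in range(n)
    ]
    periods = [
        ObservationPeriod(f"R{i}", date(year - 1, 1, 1), date(year + 1, 1, 1))
        for i in range(n)
    ]
    return persons, periods


def test_disproportionality_direct_count_oracle():
    from datetime import timedelta

    # 10 eligible women; concept X appears for 1 of them in the reference year
    persons, periods = _reference_population(10)
    events = [ClinicalEvent("R0", "X", Domain.CONDITION, date(2012, 5, 1))]
    # 5 ectopic windows; X present in every window, 10 days after diagnosis
    for i in range(5):
        pid = f"E{i}"
        persons.append(Person(pid, Sex.FEMALE, date(1985, 1, 1)))
        # not reference-eligible: no full-year observation in 2012
        periods.append(ObservationPeriod(pid, date(2009, 1, 1), date(2011, 1, 1)))
        dx = ev(Category.ECTOPIC, 100 + 50 * i, person=pid)
        events.append(dx)
        events.append(
            ClinicalEvent(pid, "X", Domain.CONDITION, dx.event_date + timedelta(days=10))
        )
    result = ectopic_disproportionality(events, persons, periods)
    row = result[result.concept_id == "X"].iloc[0]
    # brute-force double count: 1/10 reference, 5/5 windows
    assert row.prevalence_ref == pytest.approx(0.1)
    assert row.prevalence_ect == pytest.approx(1.0)
    assert row.ratio == pytest.approx(10.0)


def test_equal_prevalence_excluded():
    persons, periods = _reference_population(4)
    events = [
        ClinicalEvent(f"R{i}", "X", Domain.CONDITION, date(2012, 3, 1))
        for i in range(4)
    ]
    persons.append(Person("E0", Sex.FEMALE, date(1985, 1, 1)))
    periods.append(ObservationPeriod("E0", date(2009, 1, 1), date(2011, 1, 1)))
    events.append(ev(Category.ECTOPIC, 30, person="E0"))
    events.append(ClinicalEvent("E0", "X", Domain.CONDITION, date(2010, 2, 10)))
    result = ectopic_disproportionality(events, persons, periods)
    assert result[result.concept_id == "X"].empty  # PR == 1, excluded


def test_infinite_ratio_flagged():
    persons, periods = _reference_population(3)
    persons.append(Person("E0", Sex.FEMALE, date(1985, 1, 1)))
    periods.append(ObservationPeriod("E0", date(2009, 1, 1), date(2011, 1, 1)))
    events = [
        ev(Category.ECTOPIC, 30, person="E0"),
        ClinicalEvent("E0", "Y", Domain.CONDITION, date(2010, 2, 10)),
    ]
    result = ectopic_disproportionality(events, persons, periods)
    row = result[result.concept_id == "Y"].iloc[0]
    assert row.infinite_ratio
    assert row.prevalence_ref == 0.0


def test_no_eligible_reference_women_errors():
    persons = [Person("E0", Sex.FEMALE, date(1985, 1, 1))]
    periods = [ObservationPeriod("E0", date(2013, 1, 1), date(2013, 12, 31))]
    with pytest.raises(ValidationError):
        ectopic_disproportionality([ev(Category.ECTOPIC, 30, person="E0")], persons, periods)


def test_window_is_closed_60_days():
    persons, periods = _reference_population(5)
    persons.append(Person("E0", Sex.FEMALE, date(1985, 1, 1)))
    periods.append(ObservationPeriod("E0", date(2009, 1, 1), date(2011, 1, 1)))
    from datetime import timedelta

    dx = ev(Category.ECTOPIC, 30, person="E0")
    # day 60 exactly: included; day 61: excluded
    at60 = ClinicalEvent("E0", "AT60", Domain.CONDITION, dx.event_date + timedelta(days=60))
    at61 = ClinicalEvent("E0", "AT61", Domain.CONDITION, dx.event_date + timedelta(days=61))
    result = ectopic_disproportionality([dx, at60, at61], persons, periods)
    assert "AT60" in set(result.concept_id)
    assert "AT61" not in set(result.concept_id)


def test_threshold_monotonicity():
    persons, periods = _reference_population(10)
    events = [ClinicalEvent("R0", "X", Domain.CONDITION, date(2012, 5, 1))]
    persons.append(Person("E0", Sex.FEMALE, date(1985, 1, 1)))
    periods.append(ObservationPeriod("E0", date(2009, 1, 1), date(2011, 1, 1)))
    events.append(ev(Category.ECTOPIC, 30, person="E0"))
    events.append(ClinicalEvent("E0", "X", Domain.CONDITION, date(2010, 2, 10)))
    previous = None
    for threshold in (1, 2, 5, 9, 11, 100):
        got = set(
            ectopic_disproportionality(
                events, persons, periods, pr_threshold=threshold
            ).concept_id
        )
        if previous is not None:
            assert got <= previous
        previous = got
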