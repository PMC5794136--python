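"""Shared fixture builders for the test suite.

Events are built pre-categorized (category set directly) so classifier
and estimator stages can be exercised without a concept table; day
numbers are offsets from BASE (2010-01-01).
"""

from datetime import date, timedelta

from pregepi.concepts import Category
from pregepi.config import AlgorithmConfig
from pregepi.model import ClinicalEvent, Domain, OutcomeClass
from pregepi.outcomes import SpacingTable

BASE = date(2010, 1, 1)

_DOMAIN_FOR = {
    Category.METHOTREXATE: Domain.DRUG,
    Category.CONTRACEPTIVE: Domain.DRUG,
    Category.ECTOPIC_SURGERY: Domain.PROCEDURE,
    Category.NUCHAL_ULTRASOUND: Domain.PROCEDURE,
    Category.AFP: Domain.PROCEDURE,
    Category.FERTILITY_DATING: Domain.PROCEDURE,
    Category.URINE_TEST: Domain.PROCEDURE,
    Category.LMP: Domain.OBSERVATION,
    Category.GEST_AGE: Domain.OBSERVATION,
    Category.ANTENATAL_VISIT: Domain.OBSERVATION,
}


def day(offset: int) -> date:
    return BASE + timedelta(days=offset)


def ev(
    category: Category | None,
    offset: int,
    person: str = "P1",
    value: float | None = None,
    unit: str | None = None,
    concept_id: str | None = None,
) -> ClinicalEvent:
    domain = _DOMAIN_FOR.get(category, Domain.CONDITION)
    return ClinicalEvent(
        person_id=person,
        concept_id=concept_id or (category.value.upper() if category else "UNKNOWN"),
        domain=domain,
        event_date=day(offset),
        value=value,
        unit=unit,
        category=category,
    )


def explicit_spacing(default: int = 56, **overrides: int) -> SpacingTable:
    """Uniform spacing table with named overrides like lb_lb=182."""
    classes = {
        "lb": OutcomeClass.LIVE_BIRTH,
        "sb": OutcomeClass.STILLBIRTH,
        "ect": OutcomeClass.ECTOPIC,
        "ab": OutcomeClass.ABORTION,
        "del": OutcomeClass.DELIVERY,
    }
    table = {(a, b): default for a in classes.values() for b in classes.values()}
    for key, days in overrides.items():
        a, b = key.split("_")
        table[(classes[a], classes[b])] = days
    return SpacingTable(min_days=table)


def make_config(**kwargs) -> AlgorithmConfig:
    cfg = AlgorithmConfig(**kwargs)
    cfg.validate()
    return cfg
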