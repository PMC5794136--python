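"""Characterization and validation analytics over an episode table."""

from __future__ import annotations

from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .concepts import Category
from .config import AlgorithmConfig
from .errors import ValidationError
from .model import ClinicalEvent, OutcomeClass, PregnancyEpisode, StartMethod
from .outcomes import OutcomeCandidate
from .start import eligible_markers, estimate_start

#: start-method display groups used in the characterization figures
METHOD_GROUPS: dict[StartMethod, str] = {
    StartMethod.LMP: "group_1",
    StartMethod.GEST_AGE: "group_1",
    StartMethod.FERTILITY: "group_1",
    StartMethod.AFP: "group_2",
    StartMethod.NUCHAL_ULTRASOUND: "group_2",
    StartMethod.AMENORRHEA: "group_3",
    StartMethod.URINE_TEST: "group_3",
    StartMethod.OUTCOME_ESTIMATE: "group_4",
}

SENSITIVITY_BINS = ("<=7", "8-14", ">14")


def _episodes_frame(episodes: Sequence[PregnancyEpisode]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "person_id": [e.person_id for e in episodes],
            "episode_index": [e.episode_index for e in episodes],
            "outcome_class": [e.outcome_class.value for e in episodes],
            "start_method": [e.start_method.value for e in episodes],
            "duration": [e.duration_days for e in episodes],
        }
    )


def duration_bin_label(duration: int, width: int = 10) -> str:
    lo = (duration // width) * width
    return f"{lo}-{lo + width - 1}"


def characterize(episodes: Sequence[PregnancyEpisode]) -> dict[str, pd.DataFrame]:
    """Outcome proportions, start-method distributions (raw and grouped),
    10-day duration histograms and per-method duration medians."""
    if not episodes:
        return {
            "outcome_proportions": pd.DataFrame(columns=["outcome_class", "n", "percent"]),
            "start_methods": pd.DataFrame(
                columns=["outcome_class", "start_method", "n", "percent"]
            ),
            "method_groups": pd.DataFrame(columns=["outcome_class", "group", "n", "percent"]),
            "duration_bins": pd.DataFrame(
                columns=["start_method", "bin", "n", "percent"]
            ),
            "duration_medians": pd.DataFrame(
                columns=["outcome_class", "start_method", "n", "median_days"]
            ),
        }
    frame = _episodes_frame(episodes).sort_values(
        ["person_id", "episode_index"], kind="stable"
    )
    total = len(frame)

    proportions = (
        frame.groupby("outcome_class", sort=True).size().reset_index(name="n")
    )
    proportions["percent"] = proportions["n"] / total * 100.0

    methods = (
        frame.groupby(["outcome_class", "start_method"], sort=True)
        .size()
        .reset_index(name="n")
    )
    methods["percent"] = methods.groupby("outcome_class")["n"].transform(
        lambda s: s / s.sum() * 100.0
    )

    frame["group"] = frame["start_method"].map(
        {m.value: g for m, g in METHOD_GROUPS.items()}
    )
    groups = (
        frame.groupby(["outcome_class", "group"], sort=True).size().reset_index(name="n")
    )
    groups["percent"] = groups.groupby("outcome_class")["n"].transform(
        lambda s: s / s.sum() * 100.0
    )

    frame["bin"] = frame["duration"].map(duration_bin_label)
    bins = (
        frame.groupby(["start_method", "bin"], sort=True).size().reset_index(name="n")
    )
    bins["bin_start"] = bins["bin"].str.split("-").str[0].astype(int)
    bins = bins.sort_values(["start_method", "bin_start"], kind="stable").drop(
        columns="bin_start"
    )
    bins["percent"] = bins.groupby("start_method")["n"].transform(
        lambda s: s / s.sum() * 100.0
    )

    medians = (
        frame.groupby(["outcome_class", "start_method"], sort=True)["duration"]
        .agg(n="size", median_days="median")
        .reset_index()
    )
    return {
        "outcome_proportions": proportions,
        "start_methods": methods,
        "method_groups": groups,
        "duration_bins": bins.reset_index(drop=True),
        "duration_medians": medians,
    }


def _candidates_with_priors(
    episodes: Sequence[PregnancyEpisode],
) -> list[tuple[PregnancyEpisode, OutcomeCandidate, OutcomeCandidate | None]]:
    """Rebuild (episode, outcome candidate, prior candidate) triples from a
    finalized episode table, per person in date order."""
    by_person: dict[str, list[PregnancyEpisode]] = {}
    for ep in episodes:
        by_person.setdefault(ep.person_id, []).append(ep)
    out = []
    for person_id in sorted(by_person):
        ordered = sorted(by_person[person_id], key=lambda e: e.outcome_date)
        prior: OutcomeCandidate | None = None
        for ep in ordered:
            candidate = OutcomeCandidate(
                person_id=person_id,
                outcome_class=ep.outcome_class,
                record_date=ep.outcome_date,
                final_date=ep.outcome_date,
                accepted=True,
            )
            out.append((ep, candidate, prior))
            prior = candidate
    return out


def sensitivity_bin(diff_days: int) -> str:
    if diff_days <= 7:
        return "<=7"
    if diff_days <= 14:
        return "8-14"
    return ">14"


def fertility_sensitivity(
    episodes: Sequence[PregnancyEpisode],
    events: Sequence[ClinicalEvent],
    config: AlgorithmConfig,
) -> pd.DataFrame:
    """Compare fertility-procedure starts with the next-best estimate.

    For every episode whose start used a fertility-dating procedure, the
    start is re-estimated with fertility markers masked and the absolute
    day difference is binned (<=7, 8-14, >14) per outcome.  ``events``
    must be categorized.
    """
    events_by_person: dict[str, list[ClinicalEvent]] = {}
    for e in events:
        events_by_person.setdefault(e.person_id, []).append(e)
    rows = []
    for ep, candidate, prior in _candidates_with_priors(episodes):
        if ep.start_method is not StartMethod.FERTILITY:
            continue
        masked = [
            e
            for e in events_by_person.get(ep.person_id, [])
            if e.category is not Category.FERTILITY_DATING
        ]
        alt = estimate_start(candidate, masked, config, prior)
        diff = abs((alt.start_date - ep.start_date).days)
        rows.append(
            {
                "outcome_class": ep.outcome_class.value,
                "bin": sensitivity_bin(diff),
                "alt_method": alt.start_method.value,
            }
        )
    if not rows:
        return pd.DataFrame(columns=["outcome_class", "bin", "n", "percent"])
    frame = pd.DataFrame(rows)
    counts = (
        frame.groupby(["outcome_class", "bin"], sort=True).size().reset_index(name="n")
    )
    # emit all bins per outcome so the partition is explicit
    full = (
        pd.MultiIndex.from_product(
            [sorted(frame["outcome_class"].unique()), SENSITIVITY_BINS],
            names=["outcome_class", "bin"],
        )
        .to_frame(index=False)
        .merge(counts, how="left")
        .fillna({"n": 0})
    )
    full["n"] = full["n"].astype(int)
    full["percent"] = full.groupby("outcome_class")["n"].transform(
        lambda s: s / s.sum() * 100.0 if s.sum() else 0.0
    )
    return full


def marker_proximity(
    episodes: Sequence[PregnancyEpisode],
    events: Sequence[ClinicalEvent],
    anchor_category: Category,
    config: AlgorithmConfig,
    window_days: int = 14,
) -> pd.DataFrame:
    """Share of other markers whose implied start falls within
    ``window_days`` of the anchor-implied start, among episodes carrying
    an eligible anchor marker."""
    if anchor_category not in (Category.FERTILITY_DATING, Category.NUCHAL_ULTRASOUND):
        raise ValidationError(
            "anchor must be fertility_dating or nuchal_ultrasound"
        )
    events_by_person: dict[str, list[ClinicalEvent]] = {}
    for e in events:
        events_by_person.setdefault(e.person_id, []).append(e)
    counts: dict[str, list[int]] = {}
    for ep, candidate, prior in _candidates_with_priors(episodes):
        person_events = events_by_person.get(ep.person_id, [])
        markers = eligible_markers(
            candidate, person_events, config.term_windows, prior, config.offsets
        )
        anchors = [m for m in markers if m.category is anchor_category]
        if not anchors:
            continue
        anchor_start = min(anchors, key=lambda m: m.event_date).implied_start
        for m in markers:
            if m.category is anchor_category:
                continue
            within = abs((m.implied_start - anchor_start).days) <= window_days
            counts.setdefault(m.category.value, []).append(int(within))
    rows = [
        {
            "category": category,
            "n_markers": len(flags),
            "n_within": sum(flags),
            "percent": sum(flags) / len(flags) * 100.0,
        }
        for category, flags in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["category", "n_markers", "n_within", "percent"])


def export_profiles(
    episodes: Sequence[PregnancyEpisode],
    events: Sequence[ClinicalEvent],
    config: AlgorithmConfig,
    out_dir: str | Path,
    per_outcome: int = 50,
    seed: int = 0,
) -> list[Path]:
    """Write reviewer profiles for a seeded, outcome-stratified sample.

    Each profile lists the episode header (including every candidate
    start the hierarchy identified) followed by all of the person's
    events with day offsets from the inferred start.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    triples = _candidates_with_priors(episodes)
    by_outcome: dict[str, list] = {}
    for triple in triples:
        by_outcome.setdefault(triple[0].outcome_class.value, []).append(triple)
    events_by_person: dict[str, list[ClinicalEvent]] = {}
    for e in events:
        events_by_person.setdefault(e.person_id, []).append(e)

    paths = []
    for outcome_class in sorted(by_outcome):
        pool = by_outcome[outcome_class]
        if len(pool) > per_outcome:
            idx = rng.choice(len(pool), size=per_outcome, replace=False)
            pool = [pool[i] for i in sorted(idx)]
        for ep, candidate, prior in pool:
            person_events = sorted(
                events_by_person.get(ep.person_id, []), key=lambda e: e.event_date
            )
            markers = eligible_markers(
                candidate, person_events, config.term_windows, prior, config.offsets
            )
            path = out_dir / f"profile_{ep.person_id}_{ep.episode_index}.txt"
            with open(path, "w") as fh:
                fh.write(f"person_id: {ep.person_id}\n")
                fh.write(f"episode_index: {ep.episode_index}\n")
                fh.write(f"outcome_class: {ep.outcome_class.value}\n")
                fh.write(f"outcome_date: {ep.outcome_date.isoformat()}\n")
                fh.write(f"start_date: {ep.start_date.isoformat()}\n")
                fh.write(f"start_method: {ep.start_method.value}\n")
                candidate_starts = ", ".join(
                    f"{m.category.value}={m.implied_start.isoformat()}" for m in markers
                )
                fh.write(f"candidate_starts: {candidate_starts}\n")
                fh.write("day\tdate\tdomain\tconcept_id\tcategory\n")
                for e in person_events:
                    day = (e.event_date - ep.start_date).days
                    category = e.category.value if e.category else ""
                    fh.write(
                        f"{day}\t{e.event_date.isoformat()}\t{e.domain.value}\t"
                        f"{e.concept_id}\t{category}\n"
                    )
            paths.append(path)
    return paths
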