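"""Algorithm configuration: every window table in one object, YAML-backed."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .model import OutcomeClass, StartMethod, TermStatus
from .outcomes import SpacingTable
from .start import GestationalEstimates, OutcomeWindows, default_term_windows

#: default marker offsets (days subtracted from the marker date)
DEFAULT_OFFSETS: dict[StartMethod, int] = {
    StartMethod.LMP: 0,
    StartMethod.FERTILITY: 13,
    StartMethod.NUCHAL_ULTRASOUND: 89,
    StartMethod.AFP: 123,
    StartMethod.AMENORRHEA: 55,
    StartMethod.URINE_TEST: 55,
}


@dataclass
class AlgorithmConfig:
    spacing_table: SpacingTable = field(default_factory=SpacingTable.default)
    term_windows: dict[OutcomeClass, OutcomeWindows] = field(
        default_factory=default_term_windows
    )
    gestational_estimates: GestationalEstimates = field(
        default_factory=GestationalEstimates
    )
    offsets: dict[StartMethod, int] = field(default_factory=lambda: dict(DEFAULT_OFFSETS))
    followup_window_days: int = 42
    ectopic_confirm_days: int = 14
    reassign_window_days: int = 14
    inclusive_spacing: bool = True
    confirmation_lead_days: int = 28
    min_age: int = 12
    max_age: int = 55
    min_markers: int = 2
    count_outcome_as_marker: bool = True

    def validate(self) -> None:
        self.spacing_table.validate()
        for outcome_class in (
            OutcomeClass.LIVE_BIRTH,
            OutcomeClass.STILLBIRTH,
            OutcomeClass.ECTOPIC,
            OutcomeClass.ABORTION,
        ):
            if outcome_class not in self.term_windows:
                raise ConfigurationError(
                    f"term_windows missing outcome {outcome_class.value}"
                )
            windows = self.term_windows[outcome_class]
            estimate = self.gestational_estimates.lookup(
                outcome_class, TermStatus.FULL_TERM
            )
            if not (windows.min_term_days <= estimate <= windows.max_term_days):
                raise ConfigurationError(
                    f"gestational estimate for {outcome_class.value} outside "
                    "its term window"
                )
        for method, offset in self.offsets.items():
            if offset < 0:
                raise ConfigurationError(f"offset for {method.value} is negative")

    # -- YAML round-trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "spacing_table": {
                f"{a.value}->{b.value}": days
                for (a, b), days in self.spacing_table.min_days.items()
            },
            "term_windows": {
                oc.value: {
                    "max_term_days": w.max_term_days,
                    "min_term_days": w.min_term_days,
                    "retry_days": w.retry_days,
                }
                for oc, w in self.term_windows.items()
            },
            "gestational_estimates": {
                f"{oc.value}/{ts.value}": days
                for (oc, ts), days in self.gestational_estimates.estimates.items()
            },
            "offsets": {m.value: v for m, v in self.offsets.items()},
            "followup_window_days": self.followup_window_days,
            "ectopic_confirm_days": self.ectopic_confirm_days,
            "reassign_window_days": self.reassign_window_days,
            "inclusive_spacing": self.inclusive_spacing,
            "confirmation_lead_days": self.confirmation_lead_days,
            "min_age": self.min_age,
            "max_age": self.max_age,
            "min_markers": self.min_markers,
            "count_outcome_as_marker": self.count_outcome_as_marker,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "AlgorithmConfig":
        cfg = cls()
        if "spacing_table" in data:
            table = {}
            for key, days in data["spacing_table"].items():
                try:
                    earlier, later = key.split("->")
                    pair = (OutcomeClass(earlier), OutcomeClass(later))
                except ValueError:
                    raise ConfigurationError(
                        f"bad spacing table key {key!r}; expected 'class->class'"
                    ) from None
                table[pair] = int(days)
            cfg.spacing_table = SpacingTable(min_days=table)
        if "term_windows" in data:
            cfg.term_windows = {
                OutcomeClass(oc): OutcomeWindows(
                    max_term_days=int(w["max_term_days"]),
                    min_term_days=int(w["min_term_days"]),
                    retry_days=int(w["retry_days"]),
                )
                for oc, w in data["term_windows"].items()
            }
        if "gestational_estimates" in data:
            estimates = {}
            for key, days in data["gestational_estimates"].items():
                oc, ts = key.split("/")
                estimates[(OutcomeClass(oc), TermStatus(ts))] = int(days)
            cfg.gestational_estimates = GestationalEstimates(estimates=estimates)
        if "offsets" in data:
            cfg.offsets = {
                StartMethod(m): int(v) for m, v in data["offsets"].items()
            }
        for name in (
            "followup_window_days",
            "ectopic_confirm_days",
            "reassign_window_days",
            "inclusive_spacing",
            "confirmation_lead_days",
            "min_age",
            "max_age",
            "min_markers",
            "count_outcome_as_marker",
        ):
            if name in data:
                setattr(cfg, name, data[name])
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AlgorithmConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
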