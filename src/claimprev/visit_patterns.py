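"""Visit-pattern grouping over the three-year study window.

Each deduplicated patient is labelled by the subset of study years in
which they had any coded billing: the years are lettered a < b < c and
the label is the chronological concatenation of the letters present
(``{2004, 2006}`` → ``"ac"``).  The seven labels partition the cohort.

The subgroup prevalence estimator applies per-group positive predictive
values to the four groups judged most likely to contain true cases —
``abc``, ``bc``, ``ac`` and ``c``, i.e. patients whose billing either
spans all three years or persists to the most recent year.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .claims_core import StudyWindow

#: The seven visit-pattern labels, in (subset-size, chronological) order.
PATTERN_LABELS = ("a", "b", "c", "ab", "ac", "bc", "abc")

#: Groups carrying a PPV in the default subgroup estimator.
DEFAULT_ESTIMATOR_GROUPS = ("abc", "bc", "ac", "c")


def assign_pattern(years_billed: Iterable[int], window: StudyWindow | None = None) -> str:
    """Label a non-empty set of billed study years.

    Raises ``ValueError`` for an empty set or a year outside the window.
    """
    if window is None:
        window = StudyWindow()
    years = set(years_billed)
    if not years:
        raise ValueError("years_billed must be non-empty")
    label = "".join(letter for letter, year in zip(window.letters, window.years) if year in years)
    if len(label) != len(years):
        raise ValueError(f"year(s) {sorted(years - set(window.years))} outside study window {window.years}")
    return label


@dataclass
class PatternTable:
    """Per-group patient counts, optionally with per-group PPVs."""

    counts: dict[str, int]
    ppv: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(PATTERN_LABELS)
        if unknown:
            raise ValueError(f"unknown pattern label(s): {sorted(unknown)}")
        self.counts = {label: int(self.counts.get(label, 0)) for label in PATTERN_LABELS}
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("pattern counts must be non-negative")
        for label, p in self.ppv.items():
            if label not in PATTERN_LABELS:
                raise ValueError(f"PPV given for unknown pattern label {label!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"PPV for group {label!r} outside [0, 1]: {p}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_json(self) -> str:
        payload = {
            label: {"count": self.counts[label], "ppv": self.ppv.get(label)}
            for label in PATTERN_LABELS
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PatternTable":
        payload = json.loads(text)
        counts = {label: entry["count"] for label, entry in payload.items()}
        ppv = {
            label: entry["ppv"]
            for label, entry in payload.items()
            if entry.get("ppv") is not None
        }
        return cls(counts=counts, ppv=ppv)

    def with_ppv(self, ppv: Mapping[str, float]) -> "PatternTable":
        return PatternTable(counts=dict(self.counts), ppv=dict(ppv))


def tabulate_patterns(patients: pd.DataFrame, ppv: Mapping[str, float] | None = None) -> PatternTable:
    """Count patients per visit-pattern group.

    The input is a patient-summary frame (one row per patient, with a
    ``visit_pattern`` column as produced by deduplication); the seven
    counts partition the patients.
    """
    if len(patients):
        counts = patients["visit_pattern"].value_counts().to_dict()
    else:
        counts = {}
    return PatternTable(counts=counts, ppv=dict(ppv) if ppv else {})
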