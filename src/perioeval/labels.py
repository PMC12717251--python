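"""Complication label set, severity grades, and the diagnosis data model.

The evaluation framework scores predictions over a configurable set of
perioperative complication labels (EPCO-style: most labels carry a
mild/moderate/severe grade, a few are ungraded).  Nothing downstream
hard-codes the label set; the default here covers the 20 complications
with published dual-center prevalences plus two configurable placeholders
to reach the 22-label EPCO panel.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

#: Literal string a predictor emits when no complication is detected.
#: Parsed to the empty diagnosis set everywhere downstream.
SENTINEL = "no postoperative complications"

#: Label that a specific infectious diagnosis supersedes during targeted
#: aggregation (redundancy rule of the targeted strategy).
UNKNOWN_SOURCE_INFECTION = "infection of unknown source"

#: Default "specific infectious complications" whose presence suppresses an
#: unknown-source-infection verdict.  Configurable at the aggregation call.
SPECIFIC_INFECTIONS = frozenset(
    {
        "pneumonia",
        "superficial surgical site infection",
        "deep surgical site infection",
        "organ/space surgical site infection",
        "bloodstream infection",
    }
)


class Severity(enum.Enum):
    """Severity grade of a complication.

    Graded labels use mild/moderate/severe; ungraded labels carry
    ``UNSPECIFIED``.  Ordering (by ``rank``) is used for conservative
    tie-breaking: ties resolve toward the more severe grade.
    """

    UNSPECIFIED = "unspecified"
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"

    @property
    def rank(self) -> int:
        return _SEVERITY_RANK[self]

    @classmethod
    def parse(cls, value: "str | Severity") -> "Severity":
        if isinstance(value, Severity):
            return value
        return cls(canonical_name(value))


_SEVERITY_RANK = {
    Severity.UNSPECIFIED: 0,
    Severity.MILD: 1,
    Severity.MODERATE: 2,
    Severity.SEVERE: 3,
}

GRADED_SEVERITIES = (Severity.MILD, Severity.MODERATE, Severity.SEVERE)


def canonical_name(name: str) -> str:
    """Canonicalize a label or grade name: lowercase, collapse whitespace.

    Deliberately no fuzzy matching — an unrecognized name is surfaced as a
    flag by the parser rather than silently mapped.
    """
    return re.sub(r"\s+", " ", name.strip()).lower()


@dataclass(frozen=True)
class ComplicationLabel:
    """A complication category; ``graded`` marks mild/moderate/severe support."""

    name: str
    graded: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "name", canonical_name(self.name))


@dataclass(frozen=True, order=True)
class Diagnosis:
    """One predicted or gold complication: a label with a severity grade."""

    label: str
    grade: Severity = Severity.UNSPECIFIED

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", canonical_name(self.label))
        object.__setattr__(self, "grade", Severity.parse(self.grade))


@dataclass(frozen=True)
class LabelSet:
    """An ordered, unique collection of complication labels."""

    labels: tuple[ComplicationLabel, ...]

    def __post_init__(self) -> None:
        names = [lab.name for lab in self.labels]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate label names: {dupes}")

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def __contains__(self, name: object) -> bool:
        return canonical_name(str(name)) in self.names()

    def names(self) -> tuple[str, ...]:
        return tuple(lab.name for lab in self.labels)

    def get(self, name: str) -> ComplicationLabel:
        key = canonical_name(name)
        for lab in self.labels:
            if lab.name == key:
                return lab
        raise KeyError(f"unknown complication label: {name!r}")

    @classmethod
    def from_names(
        cls, names: Iterable[str], ungraded: Iterable[str] = ()
    ) -> "LabelSet":
        ungraded_set = {canonical_name(n) for n in ungraded}
        return cls(
            tuple(
                ComplicationLabel(n, graded=canonical_name(n) not in ungraded_set)
                for n in names
            )
        )


# Published dual-center complication counts (cases per center with each
# complication; cohort sizes 146 and 102).  Basis for default synthetic
# prevalences; label set remains fully configurable.
TABLE1_COUNTS: Mapping[str, tuple[int, int]] = {
    "paralytic ileus": (36, 20),
    "organ/space surgical site infection": (21, 16),
    "infection of unknown source": (22, 3),
    "myocardial injury after non-cardiac surgery": (20, 7),
    "anastomotic leakage": (15, 10),
    "pneumonia": (10, 17),
    "postoperative bleeding": (10, 15),
    "acute kidney injury": (7, 12),
    "superficial surgical site infection": (4, 8),
    "arrhythmia": (7, 6),
    "cardiogenic pulmonary edema": (7, 1),
    "deep vein thrombosis": (5, 9),
    "deep surgical site infection": (3, 7),
    "gastrointestinal bleeding": (4, 6),
    "delirium": (5, 0),
    "acute respiratory distress syndrome": (4, 2),
    "pulmonary embolism": (3, 1),
    "myocardial infarction": (2, 1),
    "bloodstream infection": (1, 2),
    "stroke": (0, 1),
}

#: Placeholder names completing the 22-label panel (the published table
#: enumerates 20; the remaining two are configuration slots, not guesses).
PLACEHOLDER_LABELS = ("other complication a", "other complication b")

CENTER_SIZES = (146, 102)


def default_label_set() -> LabelSet:
    """The default 22-label panel: 20 published labels + 2 placeholders."""
    return LabelSet.from_names(list(TABLE1_COUNTS) + list(PLACEHOLDER_LABELS))


def default_prevalences() -> dict[str, tuple[float, float]]:
    """Per-label (center1, center2) prevalence from the published counts."""
    prev = {
        name: (c1 / CENTER_SIZES[0], c2 / CENTER_SIZES[1])
        for name, (c1, c2) in TABLE1_COUNTS.items()
    }
    for name in PLACEHOLDER_LABELS:
        prev[name] = (0.0, 0.0)
    return prev
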