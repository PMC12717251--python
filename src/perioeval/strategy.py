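"""Comprehensive and targeted evaluation strategies over a pluggable
predictor contract.

The comprehensive strategy issues one structured-output request per case
covering the full complication panel.  The targeted strategy decomposes
that request into one single-complication task per label (22 calls per
case for the default panel), then combines the per-label verdicts with two
deterministic rules:

* Rule 1 — if every verdict is negative, the final output is the sentinel
  "no postoperative complications" (the empty diagnosis set).
* Rule 2 — a positive verdict for any configured specific infectious
  complication suppresses a positive "infection of unknown source"
  verdict, keeping diagnoses mutually exclusive.

The same decomposition doubles as training-data expansion: a cohort of n
cases over L labels becomes exactly n × L single-complication examples
(146 cases × 22 labels = 3212).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Protocol, Sequence

from .labels import (
    SENTINEL,
    SPECIFIC_INFECTIONS,
    UNKNOWN_SOURCE_INFECTION,
    Diagnosis,
    LabelSet,
    Severity,
    canonical_name,
)


# ---------------------------------------------------------------------------
# Structured-output dialect
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OutputSchema:
    """Field names of the structured JSON output dialect (configurable)."""

    think_field: str = "think"
    list_field: str = "complications"
    label_field: str = "complication"
    severity_field: str = "severity"


@dataclass(frozen=True)
class ParseResult:
    diagnoses: tuple[Diagnosis, ...]
    think: str | None
    status: str  # "ok" | "failed"
    message: str = ""
    sentinel: bool = False
    unknown_labels: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def serialize_output(
    diagnoses: Sequence[Diagnosis],
    think: str | None = None,
    schema: OutputSchema = OutputSchema(),
) -> str:
    """Render a diagnosis list as one structured-output JSON record.

    The empty list renders as the single-element sentinel response.
    Inverse of :func:`parse_model_output` on well-formed records.
    """
    record: dict = {}
    if think is not None:
        record[schema.think_field] = think
    if diagnoses:
        record[schema.list_field] = [
            {schema.label_field: d.label, schema.severity_field: d.grade.value}
            for d in diagnoses
        ]
    else:
        record[schema.list_field] = [SENTINEL]
    return json.dumps(record, ensure_ascii=False)


def parse_model_output(
    raw_text: str,
    expect_think: bool = False,
    schema: OutputSchema = OutputSchema(),
    label_set: LabelSet | None = None,
) -> ParseResult:
    """Parse and validate one raw structured-output record.

    Never raises on content: structural problems yield status "failed"
    with a diagnostic message.  The sentinel maps to an empty diagnosis
    list; label names outside ``label_set`` (when given) are kept but
    flagged in ``unknown_labels``.
    """

    def fail(msg: str) -> ParseResult:
        return ParseResult((), None, "failed", msg)

    try:
        record = json.loads(raw_text)
    except (json.JSONDecodeError, TypeError) as exc:
        return fail(f"invalid JSON: {exc}")
    if not isinstance(record, dict):
        return fail("top-level value is not an object")

    think = record.get(schema.think_field)
    if think is not None and not isinstance(think, str):
        return fail(f"field {schema.think_field!r} is not a string")
    if expect_think and not think:
        return fail(f"missing expected {schema.think_field!r} field")

    items = record.get(schema.list_field)
    if not isinstance(items, list):
        return fail(f"field {schema.list_field!r} missing or not a list")

    diagnoses: list[Diagnosis] = []
    unknown: list[str] = []
    sentinel = False
    for item in items:
        if isinstance(item, str):
            if canonical_name(item) == SENTINEL:
                sentinel = True
                continue
            return fail(f"unexpected bare string {item!r} in diagnosis list")
        if not isinstance(item, dict) or schema.label_field not in item:
            return fail(f"diagnosis entry {item!r} lacks {schema.label_field!r}")
        label = canonical_name(str(item[schema.label_field]))
        raw_grade = item.get(schema.severity_field, Severity.UNSPECIFIED.value)
        try:
            grade = Severity.parse(str(raw_grade))
        except ValueError:
            return fail(f"unrecognized severity grade {raw_grade!r}")
        if label_set is not None and label not in label_set:
            unknown.append(label)
        diagnoses.append(Diagnosis(label, grade))

    if sentinel and diagnoses:
        return fail("sentinel mixed with explicit diagnoses")
    return ParseResult(
        tuple(diagnoses),
        think,
        "ok",
        sentinel=sentinel or not diagnoses,
        unknown_labels=tuple(unknown),
    )


# ---------------------------------------------------------------------------
# Task decomposition and aggregation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskUnit:
    """One single-complication evaluation request."""

    case_id: str
    target_label: str
    record_text: str


def decompose_targeted(
    case_id: str, record_text: str, label_set: LabelSet
) -> list[TaskUnit]:
    """Split one case into |label_set| single-complication task units,
    each carrying the identical record text and one distinct target label."""
    if len(label_set) == 0:
        raise ValueError("label set must be non-empty")
    return [TaskUnit(case_id, lab.name, record_text) for lab in label_set]


def aggregate_targeted(
    verdicts: Mapping[str, tuple[bool, Severity]],
    label_set: LabelSet,
    specific_infections: Iterable[str] = SPECIFIC_INFECTIONS,
    unknown_source_label: str = UNKNOWN_SOURCE_INFECTION,
) -> list[Diagnosis]:
    """Combine per-label verdicts into the final diagnosis list.

    Applies Rule 1 (all-negative → sentinel, returned as the empty list)
    and Rule 2 (a positive specific infection suppresses the
    unknown-source-infection verdict).  Every label in ``label_set`` must
    have a verdict.
    """
    keyed = {canonical_name(k): v for k, v in verdicts.items()}
    missing = [n for n in label_set.names() if n not in keyed]
    if missing:
        raise ValueError(f"missing verdicts for labels: {missing}")
    specific = {canonical_name(s) for s in specific_infections}
    unknown_source = canonical_name(unknown_source_label)

    positives = [
        (name, keyed[name][1]) for name in label_set.names() if keyed[name][0]
    ]
    if any(name in specific for name, _ in positives):
        positives = [p for p in positives if p[0] != unknown_source]
    return [Diagnosis(name, grade) for name, grade in positives]


# ---------------------------------------------------------------------------
# Strategy execution over a predictor contract
# ---------------------------------------------------------------------------

class Predictor(Protocol):
    """Callable contract abstracting any diagnostic backend.

    Given the record text, the labels under evaluation, the strategy mode
    ("comprehensive" | "targeted") and whether chain-of-thought output is
    requested, returns one raw structured-output text.  May be stochastic;
    must be stateless with respect to evaluation bookkeeping.
    """

    def __call__(
        self, record_text: str, labels: Sequence[str], mode: str, cot: bool
    ) -> str:
        ...


@dataclass(frozen=True)
class StrategyRun:
    """Final diagnoses for one case plus an audit trail of the calls made."""

    case_id: str
    diagnoses: tuple[Diagnosis, ...]
    n_calls: int
    parse_failures: tuple[str, ...] = ()  # labels (targeted) or "" (comprehensive)
    failed: bool = False


def run_comprehensive(
    case_id: str,
    record_text: str,
    predictor: Predictor,
    label_set: LabelSet,
    schema: OutputSchema = OutputSchema(),
    cot: bool = False,
    retries: int = 2,
) -> StrategyRun:
    """One request evaluating the full complication panel simultaneously.

    A record that still fails to parse after the retry budget becomes a
    failed run with an empty prediction — recorded, never silent.
    """
    n_calls = 0
    for _ in range(retries + 1):
        raw = predictor(record_text, label_set.names(), "comprehensive", cot)
        n_calls += 1
        parsed = parse_model_output(raw, expect_think=cot, schema=schema,
                                    label_set=label_set)
        if parsed.ok:
            return StrategyRun(case_id, parsed.diagnoses, n_calls)
    return StrategyRun(case_id, (), n_calls, parse_failures=("",), failed=True)


def run_targeted(
    case_id: str,
    record_text: str,
    predictor: Predictor,
    label_set: LabelSet,
    schema: OutputSchema = OutputSchema(),
    cot: bool = False,
    retries: int = 2,
    specific_infections: Iterable[str] = SPECIFIC_INFECTIONS,
) -> StrategyRun:
    """|label_set| single-complication requests combined by Rules 1–2.

    A unit whose output cannot be parsed within the retry budget
    contributes a negative verdict and is listed in ``parse_failures`` so
    the aggregation stays total while failures remain auditable.
    """
    verdicts: dict[str, tuple[bool, Severity]] = {}
    failures: list[str] = []
    n_calls = 0
    for unit in decompose_targeted(case_id, record_text, label_set):
        verdict: tuple[bool, Severity] | None = None
        for _ in range(retries + 1):
            raw = predictor(unit.record_text, (unit.target_label,), "targeted", cot)
            n_calls += 1
            parsed = parse_model_output(raw, expect_think=cot, schema=schema)
            if parsed.ok:
                hit = next(
                    (d for d in parsed.diagnoses if d.label == unit.target_label),
                    None,
                )
                verdict = (hit is not None, hit.grade if hit else Severity.UNSPECIFIED)
                break
        if verdict is None:
            verdict = (False, Severity.UNSPECIFIED)
            failures.append(unit.target_label)
        verdicts[unit.target_label] = verdict
    diagnoses = aggregate_targeted(
        verdicts, label_set, specific_infections=specific_infections
    )
    return StrategyRun(
        case_id,
        tuple(diagnoses),
        n_calls,
        parse_failures=tuple(failures),
        failed=len(failures) == len(label_set),
    )


# ---------------------------------------------------------------------------
# Training-example expansion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainingExample:
    """One single-complication training example derived from case truth."""

    case_id: str
    target_label: str
    record_text: str
    present: bool
    grade: Severity


def expand_training_examples(
    cohort: Sequence[tuple[str, str, Sequence[Diagnosis]]],
    label_set: LabelSet,
) -> list[TrainingExample]:
    """Expand (case_id, record_text, truth) triples into n × |label_set|
    single-complication examples; each example's verdict restates the case
    truth for its target label."""
    examples: list[TrainingExample] = []
    for case_id, record_text, truth in cohort:
        truth_by_label = {d.label: d.grade for d in truth}
        for lab in label_set:
            grade = truth_by_label.get(lab.name, Severity.UNSPECIFIED)
            examples.append(
                TrainingExample(
                    case_id=case_id,
                    target_label=lab.name,
                    record_text=record_text,
                    present=lab.name in truth_by_label,
                    grade=grade,
                )
            )
    return examples
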