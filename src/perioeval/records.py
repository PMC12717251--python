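"""Clinical record sections, markdown assembly, time-shift anonymization,
and token counting.

A record holds four components: general information, dated postoperative
notes, dated abnormal laboratory results, and dated examination reports.
Anonymization removes structured direct identifiers and shifts every date
by one per-patient offset, preserving all intervals between clinical
events (the time-shifting scheme used by de-identified clinical databases).
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

DatedEntry = tuple[_dt.date, str]

SECTION_HEADERS = (
    "## General Information",
    "## Postoperative Medical Records",
    "## Abnormal Test Results",
    "## Examination Results",
)

#: Default bound (days) for the random per-patient time shift.
MAX_OFFSET_DAYS = 3650


def _coerce_date(value: "_dt.date | str", context: str) -> _dt.date:
    if isinstance(value, _dt.date):
        return value
    try:
        return _dt.date.fromisoformat(value)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-parseable date {value!r} in {context}") from exc


def _coerce_section(entries: Sequence[DatedEntry], name: str) -> tuple[DatedEntry, ...]:
    coerced = tuple((_coerce_date(d, name), str(t)) for d, t in entries)
    dates = [d for d, _ in coerced]
    if any(b < a for a, b in zip(dates, dates[1:])):
        raise ValueError(f"dated entries in {name} are not sorted by date")
    return coerced


@dataclass(frozen=True)
class ClinicalRecord:
    """Four-component clinical narrative for one surgical case.

    ``identifiers`` holds structured direct-identifier fields slated for
    removal (name, record number, ...); free-text de-identification is out
    of scope.
    """

    general_info: str = ""
    postop_notes: tuple[DatedEntry, ...] = ()
    abnormal_labs: tuple[DatedEntry, ...] = ()
    exam_reports: tuple[DatedEntry, ...] = ()
    identifiers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("postop_notes", "abnormal_labs", "exam_reports"):
            object.__setattr__(self, name, _coerce_section(getattr(self, name), name))

    def dated_sections(self) -> dict[str, tuple[DatedEntry, ...]]:
        return {
            "postop_notes": self.postop_notes,
            "abnormal_labs": self.abnormal_labs,
            "exam_reports": self.exam_reports,
        }


def timeshift_anonymize(
    record: ClinicalRecord,
    offset_days: int | None = None,
    seed: int | None = None,
) -> ClinicalRecord:
    """Remove direct identifiers and shift all dates by one patient offset.

    Either pass ``offset_days`` explicitly or a ``seed`` from which a
    uniform offset in [-MAX_OFFSET_DAYS, MAX_OFFSET_DAYS] is drawn
    deterministically.  Every date in every section moves by the same
    offset, so all pairwise day-differences between entries are unchanged.
    Identifier removal is idempotent.
    """
    if offset_days is None:
        if seed is None:
            raise ValueError("provide offset_days or seed")
        rng = np.random.default_rng(seed)
        offset_days = int(rng.integers(-MAX_OFFSET_DAYS, MAX_OFFSET_DAYS + 1))
    delta = _dt.timedelta(days=int(offset_days))

    def shift(entries: tuple[DatedEntry, ...]) -> tuple[DatedEntry, ...]:
        return tuple((d + delta, t) for d, t in entries)

    return replace(
        record,
        postop_notes=shift(record.postop_notes),
        abnormal_labs=shift(record.abnormal_labs),
        exam_reports=shift(record.exam_reports),
        identifiers=(),
    )


def assemble_markdown(record: ClinicalRecord) -> str:
    """Render a record into the standardized four-section markdown layout.

    Sections appear in fixed order; dated entries keep chronological order
    and are rendered as ``### <ISO date>`` blocks.  Empty sections render
    as a bare header so the structure is always recoverable.
    """
    parts: list[str] = []
    parts.append(SECTION_HEADERS[0])
    if record.general_info:
        parts.append(record.general_info.strip())
    for header, entries in zip(
        SECTION_HEADERS[1:],
        (record.postop_notes, record.abnormal_labs, record.exam_reports),
    ):
        parts.append(header)
        for date, text in entries:
            parts.append(f"### {date.isoformat()}")
            if text:
                parts.append(text.strip())
    return "\n\n".join(parts) + "\n"


_MARKDOWN_DATE = re.compile(r"^### (\d{4}-\d{2}-\d{2})$")


def parse_markdown(text: str) -> ClinicalRecord:
    """Inverse of :func:`assemble_markdown` for structurally clean input.

    Used as a round-trip oracle in tests and for re-ingesting rendered
    records; tolerant only of the layout the assembler itself emits.
    """
    sections: dict[str, list[str]] = {h: [] for h in SECTION_HEADERS}
    current: list[str] | None = None
    for line in text.splitlines():
        if line in sections:
            current = sections[line]
        elif current is not None:
            current.append(line)

    def parse_dated(lines: list[str]) -> tuple[DatedEntry, ...]:
        entries: list[DatedEntry] = []
        date: _dt.date | None = None
        buf: list[str] = []
        for line in lines:
            m = _MARKDOWN_DATE.match(line)
            if m:
                if date is not None:
                    entries.append((date, "\n".join(buf).strip()))
                date = _dt.date.fromisoformat(m.group(1))
                buf = []
            elif line.strip():
                buf.append(line)
        if date is not None:
            entries.append((date, "\n".join(buf).strip()))
        return tuple(entries)

    return ClinicalRecord(
        general_info="\n".join(
            l for l in sections[SECTION_HEADERS[0]] if l.strip()
        ).strip(),
        postop_notes=parse_dated(sections[SECTION_HEADERS[1]]),
        abnormal_labs=parse_dated(sections[SECTION_HEADERS[2]]),
        exam_reports=parse_dated(sections[SECTION_HEADERS[3]]),
    )


def _is_cjk(ch: str) -> bool:
    cp = ord(ch)
    return (
        0x4E00 <= cp <= 0x9FFF
        or 0x3400 <= cp <= 0x4DBF
        or 0xF900 <= cp <= 0xFAFF
        or 0x3040 <= cp <= 0x30FF
    )


def default_tokenizer(text: str) -> int:
    """Heuristic token count: whitespace-separated words, with CJK
    characters counted individually.

    The published token statistics come from an unstated subword
    tokenizer; stratification only needs a deterministic, consistent
    ordering, which this provides.  Real tokenizers plug in via the
    ``tokenizer`` argument of :func:`count_tokens`.
    """
    count = 0
    for chunk in text.split():
        cjk = sum(1 for ch in chunk if _is_cjk(ch))
        non_cjk = len(chunk) - cjk
        count += cjk + (1 if non_cjk else 0)
    return count


def count_tokens(text: str, tokenizer: Callable[[str], int] | None = None) -> int:
    """Count tokens in ``text`` with a pluggable tokenizer contract."""
    fn = tokenizer or default_tokenizer
    n = int(fn(text))
    if n < 0:
        raise ValueError("tokenizer returned a negative count")
    return n
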