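"""Sensitivity analyses: document-length quartiles, complication-count
strata, and documentation-quality median split, with per-stratum metrics.

Each scheme partitions the evaluated cases — disjointly and exhaustively —
and the metrics module is then applied within every stratum, so pooled
micro TP/FP/FN totals equal the sum of the per-stratum totals.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .labels import Diagnosis
from .metrics import (
    Averaging,
    MetricsResult,
    counts_for_run,
    macro_metrics,
    micro_metrics,
    normalize,
)
from .synthetic import PatientCase


class Scheme(enum.Enum):
    TOKEN_QUARTILE = "token_quartile"
    COMPLICATION_COUNT = "complication_count"
    PDQI_QUALITY = "pdqi_quality"


@dataclass(frozen=True)
class StratumAssignment:
    case_id: str
    scheme: Scheme
    stratum: str


@dataclass(frozen=True)
class StratumReport:
    scheme: Scheme
    stratum: str
    n_cases: int
    result: MetricsResult | None
    mean_token_count: float | None = None
    flags: tuple[str, ...] = ()


def token_quartiles(cases: Sequence[PatientCase]) -> list[StratumAssignment]:
    """Assign cases to document-length quartiles Q1 (shortest) … Q4.

    Quartiles are positional on the stable sort by (token_count, input
    order): the sorted cases are split into four near-equal groups, so
    ties — including the all-equal degenerate case — resolve by stable
    order and stratum mean token counts are non-decreasing Q1→Q4.
    """
    if len(cases) < 4:
        raise ValueError("token quartiles require at least 4 cases")
    order = sorted(range(len(cases)), key=lambda i: (cases[i].token_count, i))
    assignments: list[StratumAssignment | None] = [None] * len(cases)
    for q, chunk in enumerate(np.array_split(np.asarray(order), 4), start=1):
        for i in chunk:
            assignments[int(i)] = StratumAssignment(
                cases[int(i)].case_id, Scheme.TOKEN_QUARTILE, f"Q{q}"
            )
    return [a for a in assignments if a is not None]


#: Complication-count stratification presets.  The default follows the
#: figure-legend scheme (≤1 / 2 / ≥3); "zero_one_two_plus" exposes the
#: alternative narrative reading (0 / 1 / ≥2).
COUNT_PRESETS = {
    "default": ((1, "≤1"), (2, "2"), (None, "≥3")),
    "zero_one_two_plus": ((0, "0"), (1, "1"), (None, "≥2")),
}


def complication_strata(
    cases: Sequence[PatientCase],
    gold: Mapping[str, Sequence[Diagnosis]],
    preset: str = "default",
) -> list[StratumAssignment]:
    """Stratify by the number of gold-standard complications per case."""
    try:
        bounds = COUNT_PRESETS[preset]
    except KeyError:
        raise ValueError(f"unknown complication-count preset {preset!r}") from None
    out = []
    for case in cases:
        k = len(normalize(list(gold[case.case_id])).items)
        for bound, name in bounds:
            if bound is None or k <= bound:
                out.append(
                    StratumAssignment(case.case_id, Scheme.COMPLICATION_COUNT, name)
                )
                break
    return out


def quality_strata(cases: Sequence[PatientCase]) -> list[StratumAssignment]:
    """Median split on PDQI-9 documentation quality.

    ``high`` iff the score exceeds the cohort median; ties at the median
    (including the all-equal degenerate cohort) go to ``low``.
    """
    scores = [c.pdqi_score for c in cases]
    if any(s is None for s in scores):
        raise ValueError("quality strata require a PDQI-9 score on every case")
    median = float(np.median(scores))
    return [
        StratumAssignment(
            c.case_id,
            Scheme.PDQI_QUALITY,
            "high" if c.pdqi_score > median else "low",
        )
        for c in cases
    ]


_STRATUM_ORDER = {
    Scheme.TOKEN_QUARTILE: ("Q1", "Q2", "Q3", "Q4"),
    Scheme.COMPLICATION_COUNT: ("≤1", "2", "≥3", "0", "1", "≥2"),
    Scheme.PDQI_QUALITY: ("low", "high"),
}


def stratified_metrics(
    assignments: Sequence[StratumAssignment],
    gold: Mapping[str, Sequence[Diagnosis]],
    predictions: Mapping[str, Sequence[Diagnosis]],
    cases: Sequence[PatientCase] | None = None,
    mode: Averaging = Averaging.MICRO,
    strict: bool = False,
) -> list[StratumReport]:
    """Apply the metrics module within each stratum of one scheme.

    ``predictions`` is a single run (case_id → diagnoses).  Every
    evaluated case must carry an assignment.  An empty stratum yields a
    flagged n=0 row with no metrics rather than being dropped.
    """
    schemes = {a.scheme for a in assignments}
    if len(schemes) != 1:
        raise ValueError("assignments must all belong to one scheme")
    scheme = schemes.pop()
    by_stratum: dict[str, list[str]] = {}
    for a in assignments:
        by_stratum.setdefault(a.stratum, []).append(a.case_id)
    missing = sorted(set(gold) - {a.case_id for a in assignments})
    if missing:
        raise ValueError(f"cases without a stratum assignment: {missing[:5]}")

    tokens = (
        {c.case_id: c.token_count for c in cases} if cases is not None else None
    )
    names = [s for s in _STRATUM_ORDER[scheme] if s in by_stratum]
    names += sorted(set(by_stratum) - set(names))
    reports = []
    for name in names:
        ids = [cid for cid in by_stratum[name] if cid in gold]
        if not ids:
            reports.append(
                StratumReport(scheme, name, 0, None, flags=("empty stratum",))
            )
            continue
        counts = counts_for_run(
            {cid: list(gold[cid]) for cid in ids},
            {cid: list(predictions[cid]) for cid in ids},
            strict=strict,
        )
        result = (
            micro_metrics(counts, strict=strict)
            if mode is Averaging.MICRO
            else macro_metrics(counts, strict=strict)
        )
        mean_tokens = (
            float(np.mean([tokens[cid] for cid in ids])) if tokens else None
        )
        reports.append(StratumReport(scheme, name, len(ids), result, mean_tokens))
    return reports
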