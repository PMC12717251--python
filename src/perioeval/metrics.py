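"""Set-based multi-label metrics: per-case TP/FP/FN and micro/macro
precision, recall, F1, in lenient (label-only) and strict (label+grade)
modes.

Each case contributes a gold diagnosis set Y_i and a predicted set Yhat_i.
Per case, TP_i = |Y_i ∩ Yhat_i|, FP_i = |Yhat_i − Y_i|, FN_i = |Y_i − Yhat_i|.
Micro-averaging pools these counts globally before forming
precision/recall/F1; macro-averaging computes per-case metrics first, with
per-case zero-denominator rules, then takes the unweighted mean over cases.

Edge rules (applied exactly as published):

* micro: precision = 0 when no predictions exist globally; recall = 0 when
  no gold labels exist globally; F1 = 0 when precision + recall = 0.
* macro, per case: precision_i = 0 when the case has no predictions;
  recall_i = 0 when it has no gold labels; F1_i = 0 when
  precision_i + recall_i = 0.  A consequence worth knowing: a case with
  empty gold and an empty — i.e. correct — prediction scores F1_i = 0,
  dragging the macro mean down.  ``score_empty_match`` flips that single
  behaviour to score such cases 1.0 for sensitivity analyses; the default
  stays faithful to the published rules.

In strict mode a prediction matches only if both the complication label and
its severity grade agree; in lenient mode diagnoses are projected to labels.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

from .labels import SENTINEL, Diagnosis, Severity, canonical_name


class Averaging(enum.Enum):
    MICRO = "micro"
    MACRO = "macro"


@dataclass(frozen=True)
class DiagnosisSet:
    """Normalized per-case diagnosis set (gold Y_i or prediction Yhat_i).

    ``items`` holds hashable match keys: bare labels in lenient mode,
    (label, grade) pairs in strict mode.  The sentinel response is
    represented as the empty set.
    """

    case_id: str
    items: frozenset[Hashable]
    strict: bool = False
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class CaseCounts:
    """Per-case true/false positive and false negative counts."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class MetricsResult:
    """Precision/recall/F1 summary with its averaging mode and provenance."""

    precision: float
    recall: float
    f1: float
    mode: Averaging
    strict: bool
    n_cases: int
    tp_global: int | None = None
    fp_global: int | None = None
    fn_global: int | None = None


def normalize(
    diagnoses: Iterable[Diagnosis | str],
    strict: bool = False,
    case_id: str = "",
) -> DiagnosisSet:
    """Deduplicate diagnoses into the set the metrics operate on.

    Lenient mode projects each diagnosis to its label; strict mode keys on
    (label, grade).  The sentinel string maps to the empty set.  If one
    label appears with conflicting grades in strict mode, the more severe
    grade is kept and a warning flag is attached.
    """
    flags: list[str] = []
    by_label: dict[str, Severity] = {}
    for d in diagnoses:
        if isinstance(d, str):
            if canonical_name(d) == SENTINEL:
                continue
            d = Diagnosis(d)
        prev = by_label.get(d.label)
        if prev is None:
            by_label[d.label] = d.grade
        elif prev != d.grade:
            keep = max(prev, d.grade, key=lambda g: g.rank)
            by_label[d.label] = keep
            flags.append(f"conflicting grades for {d.label!r}; kept {keep.value}")
    if strict:
        items = frozenset((lab, grade) for lab, grade in by_label.items())
    else:
        items = frozenset(by_label)
    return DiagnosisSet(case_id=case_id, items=items, strict=strict, flags=tuple(flags))


def case_counts(gold: DiagnosisSet, pred: DiagnosisSet) -> CaseCounts:
    """TP/FP/FN for one case by literal set arithmetic."""
    if gold.case_id != pred.case_id:
        raise ValueError(
            f"case id mismatch: gold {gold.case_id!r} vs prediction {pred.case_id!r}"
        )
    tp = len(gold.items & pred.items)
    return CaseCounts(tp=tp, fp=len(pred.items) - tp, fn=len(gold.items) - tp)


def _prf(tp: float, fp: float, fn: float) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return precision, recall, f1


def micro_metrics(
    counts: Sequence[CaseCounts], strict: bool = False
) -> MetricsResult:
    """Globally pooled precision/recall/F1 with the zero-denominator rules."""
    if not counts:
        raise ValueError("micro_metrics requires at least one case")
    tp = sum(c.tp for c in counts)
    fp = sum(c.fp for c in counts)
    fn = sum(c.fn for c in counts)
    precision, recall, f1 = _prf(tp, fp, fn)
    return MetricsResult(
        precision=precision,
        recall=recall,
        f1=f1,
        mode=Averaging.MICRO,
        strict=strict,
        n_cases=len(counts),
        tp_global=tp,
        fp_global=fp,
        fn_global=fn,
    )


def per_case_metrics(
    c: CaseCounts, score_empty_match: bool = False
) -> tuple[float, float, float]:
    """Per-case precision/recall/F1 with the per-case edge rules."""
    if score_empty_match and c.tp == 0 and c.fp == 0 and c.fn == 0:
        return 1.0, 1.0, 1.0
    return _prf(c.tp, c.fp, c.fn)


def macro_metrics(
    counts: Sequence[CaseCounts],
    strict: bool = False,
    score_empty_match: bool = False,
) -> MetricsResult:
    """Unweighted mean of per-case precision/recall/F1 over all cases."""
    if not counts:
        raise ValueError("macro_metrics requires at least one case")
    triples = [per_case_metrics(c, score_empty_match) for c in counts]
    n = len(triples)
    return MetricsResult(
        precision=sum(t[0] for t in triples) / n,
        recall=sum(t[1] for t in triples) / n,
        f1=sum(t[2] for t in triples) / n,
        mode=Averaging.MACRO,
        strict=strict,
        n_cases=n,
    )


def counts_for_run(
    gold: dict[str, list[Diagnosis]],
    predictions: dict[str, list[Diagnosis]],
    strict: bool = False,
) -> list[CaseCounts]:
    """Per-case counts for one inference run over a matched cohort."""
    missing = sorted(set(gold) - set(predictions))
    extra = sorted(set(predictions) - set(gold))
    if missing or extra:
        raise ValueError(
            f"case mismatch between gold and predictions: "
            f"missing={missing[:5]} extra={extra[:5]}"
        )
    out = []
    for case_id in gold:
        g = normalize(gold[case_id], strict=strict, case_id=case_id)
        p = normalize(predictions[case_id], strict=strict, case_id=case_id)
        out.append(case_counts(g, p))
    return out


def evaluate(
    gold: dict[str, list[Diagnosis]],
    runs: Sequence[dict[str, list[Diagnosis]]],
    mode: Averaging = Averaging.MICRO,
    strict: bool = False,
    score_empty_match: bool = False,
) -> list[MetricsResult]:
    """One MetricsResult per repeated inference run.

    ``runs`` is a sequence of per-run mappings case_id → predicted
    diagnoses; every run must cover exactly the gold case set.
    """
    if not runs:
        raise ValueError("evaluate requires at least one run")
    results = []
    for run in runs:
        counts = counts_for_run(gold, run, strict=strict)
        if mode is Averaging.MICRO:
            results.append(micro_metrics(counts, strict=strict))
        else:
            results.append(
                macro_metrics(counts, strict=strict, score_empty_match=score_empty_match)
            )
    return results
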