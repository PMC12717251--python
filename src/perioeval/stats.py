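"""Patient-level bootstrap paired testing, confidence intervals,
multiple-comparison correction, inter-rater agreement, and consensus gold
standards.

The paired comparison between two strategies resamples patients with
replacement and, per bootstrap iteration, draws one random inference run
per strategy, so the bootstrap distribution reflects both patient-level
and run-to-run variability.  Defaults follow the published protocol:
2000 iterations, single-sided (greater) tests, percentile 95% CIs,
Bonferroni correction with a family size of 2 (the two sequential
strategy comparisons).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from pydantic import BaseModel, Field
from scipy import stats as _sps
from statsmodels.stats import inter_rater as _ir

from .labels import Diagnosis, LabelSet, Severity, canonical_name
from .metrics import Averaging, counts_for_run, normalize, per_case_metrics

_METRIC_INDEX = {"precision": 0, "recall": 1, "f1": 2}


class BootstrapConfig(BaseModel):
    """Bootstrap test parameters (defaults follow the published protocol)."""

    model_config = {"frozen": True}

    iterations: int = Field(ge=1, default=2000)
    side: Literal["greater", "less", "two_sided"] = "greater"
    alpha: float = Field(gt=0.0, lt=1.0, default=0.05)
    family_size: int = Field(ge=1, default=2)
    seed: int = 0


@dataclass(frozen=True)
class BootstrapResult:
    """Paired-comparison summary: B − A on the chosen metric."""

    mean_diff: float
    ci_low: float
    ci_high: float
    p: float
    p_corrected: float
    iterations: int
    metric: str
    mode: Averaging
    strict: bool
    n_cases: int
    warnings: tuple[str, ...] = ()

    @property
    def significant(self) -> bool:
        return self.p_corrected < 0.05


def bonferroni(p: float, m: int) -> float:
    """Family-wise Bonferroni correction: min(1, m·p)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if m < 1:
        raise ValueError("family size must be >= 1")
    return min(1.0, m * p)


def t_interval(values: Sequence[float], level: float = 0.95) -> tuple[float, float, float]:
    """(mean, lo, hi): t-distribution CI from repeated-run values.

    mean ± t_{level, df=R−1} · sd/√R — the parametric interval used for
    displaying per-run metric uncertainty.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise ValueError("t_interval requires at least two values")
    mean = float(vals.mean())
    se = float(vals.std(ddof=1) / np.sqrt(vals.size))
    half = float(_sps.t.ppf((1 + level) / 2, df=vals.size - 1) * se)
    return mean, mean - half, mean + half


# ---------------------------------------------------------------------------
# Bootstrap paired test
# ---------------------------------------------------------------------------

def _metric_arrays(
    gold: Mapping[str, Sequence[Diagnosis]],
    runs: Sequence[Mapping[str, Sequence[Diagnosis]]],
    strict: bool,
    case_order: Sequence[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-(case, run) count and per-case-metric arrays.

    Returns ``counts`` with shape (n, R, 3) holding (tp, fp, fn) and
    ``pcm`` with shape (n, R, 3) holding per-case (precision, recall, f1)
    under the per-case edge rules.
    """
    n, R = len(case_order), len(runs)
    counts = np.zeros((n, R, 3), dtype=np.int64)
    pcm = np.zeros((n, R, 3), dtype=float)
    gold_dict = {cid: list(gold[cid]) for cid in case_order}
    for r, run in enumerate(runs):
        cc = counts_for_run(gold_dict, {cid: list(run[cid]) for cid in case_order},
                            strict=strict)
        for i, c in enumerate(cc):
            counts[i, r] = (c.tp, c.fp, c.fn)
            pcm[i, r] = per_case_metrics(c)
    return counts, pcm


def _micro_from_sums(tp: float, fp: float, fn: float, idx: int) -> float:
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    if idx == 0:
        return precision
    if idx == 1:
        return recall
    return (
        2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    )


def bootstrap_paired_test(
    gold: Mapping[str, Sequence[Diagnosis]],
    runs_a: Sequence[Mapping[str, Sequence[Diagnosis]]],
    runs_b: Sequence[Mapping[str, Sequence[Diagnosis]]],
    metric: Literal["f1", "precision", "recall"] = "f1",
    mode: Averaging = Averaging.MICRO,
    strict: bool = False,
    config: BootstrapConfig | None = None,
) -> BootstrapResult:
    """Patient-level bootstrap paired test of strategy B against A.

    Per iteration: resample the n patients with replacement, draw one run
    index per strategy uniformly, recompute the metric for each strategy
    on the resample (micro metrics re-pooled on the resample), and record
    the difference B − A.  ``mean_diff`` is the bootstrap mean difference,
    the CI the percentile [2.5%, 97.5%] interval, and the single-sided
    (greater) p-value the plain proportion of bootstrap differences ≤ 0 —
    hence always a multiple of 1/B.  Deterministic under ``config.seed``.
    """
    config = config or BootstrapConfig()
    case_order = sorted(gold)
    for name, runs in (("A", runs_a), ("B", runs_b)):
        for run in runs:
            if set(run) != set(case_order):
                raise ValueError(f"strategy {name} runs do not cover the gold cases")
    warnings: tuple[str, ...] = ()
    if config.iterations < 100:
        warnings = ("fewer than 100 bootstrap iterations; CI unreliable",)

    counts_a, pcm_a = _metric_arrays(gold, runs_a, strict, case_order)
    counts_b, pcm_b = _metric_arrays(gold, runs_b, strict, case_order)
    n = len(case_order)
    midx = _METRIC_INDEX[metric]
    rng = np.random.default_rng(config.seed)
    B = config.iterations

    idx = rng.integers(0, n, size=(B, n))
    run_a = rng.integers(0, len(runs_a), size=B)
    run_b = rng.integers(0, len(runs_b), size=B)

    diffs = np.empty(B)
    for b in range(B):
        rows = idx[b]
        if mode is Averaging.MICRO:
            sa = counts_a[rows, run_a[b]].sum(axis=0)
            sb = counts_b[rows, run_b[b]].sum(axis=0)
            va = _micro_from_sums(*sa, midx)
            vb = _micro_from_sums(*sb, midx)
        else:
            va = float(pcm_a[rows, run_a[b], midx].mean())
            vb = float(pcm_b[rows, run_b[b], midx].mean())
        diffs[b] = vb - va

    p_greater = float(np.mean(diffs <= 0))
    p_less = float(np.mean(diffs >= 0))
    if config.side == "greater":
        p = p_greater
    elif config.side == "less":
        p = p_less
    else:
        p = min(1.0, 2 * min(p_greater, p_less))
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return BootstrapResult(
        mean_diff=float(diffs.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        p=p,
        p_corrected=bonferroni(p, config.family_size),
        iterations=B,
        metric=metric,
        mode=mode,
        strict=strict,
        n_cases=n,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# Inter-rater agreement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgreementResult:
    kappa: float
    ci_low: float | None
    ci_high: float | None
    n_cases: int
    n_raters: int
    n_items: int


def _kappa_from_table(table: np.ndarray) -> float:
    """Fleiss kappa with degenerate-table guards.

    Delegates the regular computation to statsmodels; when expected
    chance agreement is 1 (every rating in one category) the statistic is
    0/0 and perfect agreement is returned as 1.0 by convention.
    """
    n_raters = table.sum(axis=1)[0]
    props = table.sum(axis=0) / table.sum()
    p_e = float((props**2).sum())
    p_bar = float(
        ((table**2).sum(axis=1) - n_raters).mean() / (n_raters * (n_raters - 1))
    )
    if abs(1.0 - p_e) < 1e-12:
        return 1.0 if p_bar > 1.0 - 1e-12 else 0.0
    return float(_ir.fleiss_kappa(table, method="fleiss"))


def fleiss_kappa(
    annotations: Sequence[Mapping[str, Sequence[Diagnosis]]],
    label_set: LabelSet,
    ci_iterations: int = 2000,
    seed: int = 0,
) -> AgreementResult:
    """Fleiss κ over all (case, label) presence/absence items pooled.

    Every rater must cover the identical case set.  Each of the
    n_cases × |label_set| items is rated present/absent by all raters —
    the "all complication categories combined" pooling.  The CI is a
    case-level bootstrap percentile interval (resampling cases, keeping
    each case's block of label items intact); pass ``ci_iterations=0`` to
    skip it.
    """
    if len(annotations) < 2:
        raise ValueError("fleiss_kappa requires at least two raters")
    case_sets = [set(a) for a in annotations]
    if any(s != case_sets[0] for s in case_sets[1:]):
        raise ValueError("raters cover different case sets")
    cases = sorted(case_sets[0])
    labels = label_set.names()
    n_raters = len(annotations)

    # table rows: one per (case, label); columns: [absent, present] counts
    present = np.zeros((len(cases), len(labels)), dtype=np.int64)
    for ann in annotations:
        for i, cid in enumerate(cases):
            marked = {d.label for d in ann[cid]}
            for j, lab in enumerate(labels):
                present[i, j] += lab in marked
    flat = present.reshape(-1)
    table = np.column_stack([n_raters - flat, flat])
    kappa = _kappa_from_table(table)

    ci_low = ci_high = None
    if ci_iterations > 0:
        rng = np.random.default_rng(seed)
        boot = np.empty(ci_iterations)
        for b in range(ci_iterations):
            rows = rng.integers(0, len(cases), size=len(cases))
            sub = present[rows].reshape(-1)
            boot[b] = _kappa_from_table(np.column_stack([n_raters - sub, sub]))
        ci_low, ci_high = (float(q) for q in np.percentile(boot, [2.5, 97.5]))

    return AgreementResult(
        kappa=kappa,
        ci_low=ci_low,
        ci_high=ci_high,
        n_cases=len(cases),
        n_raters=n_raters,
        n_items=len(cases) * len(labels),
    )


# ---------------------------------------------------------------------------
# Consensus gold standard
# ---------------------------------------------------------------------------

def consensus_gold(
    annotations: Sequence[Mapping[str, Sequence[Diagnosis]]],
    threshold: int = 2,
) -> dict[str, tuple[tuple[Diagnosis, ...], tuple[str, ...]]]:
    """Majority-consensus gold standard from independent rater annotations.

    A diagnosis enters the gold set for a case iff at least ``threshold``
    raters include its label; its grade is the majority grade among the
    including raters, with ties broken toward the more severe grade and
    flagged.  Returns case_id → (gold diagnoses, audit flags).
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    if len(annotations) < threshold:
        raise ValueError("fewer raters than the consensus threshold")
    case_sets = [set(a) for a in annotations]
    if any(s != case_sets[0] for s in case_sets[1:]):
        raise ValueError("raters cover different case sets")

    gold: dict[str, tuple[tuple[Diagnosis, ...], tuple[str, ...]]] = {}
    for cid in sorted(case_sets[0]):
        votes: dict[str, list[Severity]] = {}
        for ann in annotations:
            for d in ann[cid]:
                votes.setdefault(d.label, []).append(d.grade)
        items: list[Diagnosis] = []
        flags: list[str] = []
        for label in sorted(votes):
            grades = votes[label]
            if len(grades) < threshold:
                continue
            tally: dict[Severity, int] = {}
            for g in grades:
                tally[g] = tally.get(g, 0) + 1
            top = max(tally.values())
            winners = [g for g, c in tally.items() if c == top]
            grade = max(winners, key=lambda g: g.rank)
            if len(winners) > 1:
                flags.append(f"grade tie for {label!r}; kept {grade.value}")
            items.append(Diagnosis(label, grade))
        gold[cid] = (tuple(items), tuple(flags))
    return gold
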