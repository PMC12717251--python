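"""Synthetic dual-center cohorts, stochastic predictor outputs, and rater
annotations.

Real perioperative records and model outputs are private, so every
downstream stage — strategies, metrics, bootstrap comparisons, agreement,
stratification — is exercised on synthetic data with the same statistical
structure: a two-center cohort with per-label complication prevalences and
severity grades, right-skewed document token counts with distinct
per-center distributions, documentation-quality (PDQI-9) scores, repeated
stochastic predictor runs with controllable sensitivity/false-positive
profiles, and independent expert raters conditioned on case truth.

All generators are deterministic given (spec, seed); child seeds are
spawned via :class:`numpy.random.SeedSequence` so draws for one component
never perturb another.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .labels import (
    GRADED_SEVERITIES,
    SPECIFIC_INFECTIONS,
    UNKNOWN_SOURCE_INFECTION,
    Diagnosis,
    LabelSet,
    Severity,
    canonical_name,
    default_label_set,
    default_prevalences,
)
from .records import ClinicalRecord
from .strategy import OutputSchema, serialize_output

CENTERS = ("center1", "center2")

#: Default per-center log-normal token-count parameters.  Means match the
#: published per-center document-length averages; the shape parameters
#: encode the narrower Center 1 vs broader Center 2 distributions.
DEFAULT_TOKEN_DIST = {
    "center1": {"mean": 6841.6, "sigma": 0.35},
    "center2": {"mean": 8084.3, "sigma": 0.55},
}

#: Default grade distribution for graded labels (mild-skewed, as most
#: detected complications are low grade).
DEFAULT_SEVERITY_DIST = {"mild": 0.5, "moderate": 0.3, "severe": 0.2}


class CohortSpec(BaseModel):
    """Parameters of a synthetic dual-center cohort.

    ``label_prevalence`` maps each label to its per-center probabilities;
    ``severity_dist`` maps each graded label to a distribution over
    mild/moderate/severe (ungraded labels map to ``{"unspecified": 1.0}``).
    """

    model_config = {"frozen": True}

    n_patients: int = Field(gt=0)
    center_mix: tuple[float, float] = (146 / 248, 102 / 248)
    label_prevalence: dict[str, tuple[float, float]] = Field(
        default_factory=default_prevalences
    )
    severity_dist: dict[str, dict[str, float]] = Field(default_factory=dict)
    token_count_dist: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {c: dict(DEFAULT_TOKEN_DIST[c]) for c in CENTERS}
    )
    pdqi_dist: tuple[float, float] = (3.8, 0.5)
    ungraded_labels: tuple[str, ...] = ()
    #: Keep "infection of unknown source" out of any truth that contains a
    #: specific infectious complication, mirroring the mutual-exclusion
    #: convention of clinically coherent gold standards.  The conditional
    #: draw preserves the label's configured marginal prevalence.
    infection_exclusivity: bool = True
    seed: int = 0

    @field_validator("center_mix")
    @classmethod
    def _mix_sums_to_one(cls, v: tuple[float, float]) -> tuple[float, float]:
        if any(p < 0 for p in v) or abs(sum(v) - 1.0) > 1e-9:
            raise ValueError("center_mix proportions must be >= 0 and sum to 1")
        return v

    @field_validator("label_prevalence")
    @classmethod
    def _prevalence_in_unit_interval(cls, v):
        for label, probs in v.items():
            for p in probs:
                if not 0.0 <= p <= 1.0:
                    raise ValueError(
                        f"label_prevalence[{label!r}] has probability {p} outside [0, 1]"
                    )
        return {canonical_name(k): tuple(p) for k, p in v.items()}

    @field_validator("severity_dist")
    @classmethod
    def _severity_rows_sum_to_one(cls, v):
        for label, dist in v.items():
            if any(p < 0 for p in dist.values()):
                raise ValueError(f"severity_dist[{label!r}] has a negative probability")
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"severity_dist[{label!r}] does not sum to 1")
        return {canonical_name(k): dict(d) for k, d in v.items()}

    @field_validator("token_count_dist")
    @classmethod
    def _token_dist_positive(cls, v):
        for center, params in v.items():
            if params.get("mean", 0) <= 0 or params.get("sigma", 0) <= 0:
                raise ValueError(
                    f"token_count_dist[{center!r}] requires positive mean and sigma"
                )
        return v

    def label_set(self) -> LabelSet:
        return LabelSet.from_names(self.label_prevalence, ungraded=self.ungraded_labels)

    def grade_distribution(self, label: str) -> dict[Severity, float]:
        label = canonical_name(label)
        if label in {canonical_name(u) for u in self.ungraded_labels}:
            return {Severity.UNSPECIFIED: 1.0}
        raw = self.severity_dist.get(label, DEFAULT_SEVERITY_DIST)
        return {Severity.parse(g): p for g, p in raw.items()}


def default_cohort_spec(n_patients: int = 248, seed: int = 0, **overrides) -> CohortSpec:
    """Spec emulating the published dual-center cohort structure."""
    return CohortSpec(n_patients=n_patients, seed=seed, **overrides)


@dataclass(frozen=True)
class PatientCase:
    """One synthetic surgical case."""

    case_id: str
    center: str
    truth: tuple[Diagnosis, ...]
    token_count: int
    pdqi_score: float
    record: ClinicalRecord | None = None

    def __post_init__(self) -> None:
        labels = [d.label for d in self.truth]
        if len(set(labels)) != len(labels):
            raise ValueError(f"case {self.case_id}: duplicate labels in truth")
        if self.token_count < 1:
            raise ValueError(f"case {self.case_id}: token_count must be >= 1")


def _draw_grade(
    rng: np.random.Generator, dist: Mapping[Severity, float]
) -> Severity:
    grades = sorted(dist, key=lambda g: g.rank)
    probs = np.array([dist[g] for g in grades])
    return grades[rng.choice(len(grades), p=probs / probs.sum())]


def _schematic_record(
    rng: np.random.Generator, case_id: str, truth: Sequence[Diagnosis]
) -> ClinicalRecord:
    """Schematic four-section record: placeholder prose sufficient for
    markdown assembly and token counting, not realistic clinical text."""
    base = _dt.date(2024, 1, 1) + _dt.timedelta(days=int(rng.integers(0, 365)))
    n_notes = int(rng.integers(2, 5))
    notes = tuple(
        (
            base + _dt.timedelta(days=i),
            f"postoperative day {i} course note for {case_id}",
        )
        for i in range(n_notes)
    )
    labs = (
        (base + _dt.timedelta(days=1), "abnormal laboratory panel summary"),
    )
    mentions = ", ".join(d.label for d in truth) or "none recorded"
    exams = ((base + _dt.timedelta(days=2), f"imaging impression: {mentions}"),)
    return ClinicalRecord(
        general_info=f"synthetic case {case_id}: demographics and procedure summary",
        postop_notes=notes,
        abnormal_labs=labs,
        exam_reports=exams,
        identifiers=(f"name-{case_id}", f"mrn-{case_id}"),
    )


def generate_cohort(spec: CohortSpec, with_records: bool = False) -> list[PatientCase]:
    """Draw a cohort of :class:`PatientCase` from ``spec``.

    Centers are assigned by ``center_mix``; each label enters a case's
    truth independently with its per-center prevalence; grades follow the
    label's severity distribution; token counts are log-normal per center
    with the configured mean/shape; PDQI-9 scores are normal clipped to
    [1, 5].  Deterministic given ``spec.seed``.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_center, rng_labels, rng_tokens, rng_pdqi, rng_rec = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    labels = list(spec.label_prevalence)
    grade_dists = {lab: spec.grade_distribution(lab) for lab in labels}
    u_src = canonical_name(UNKNOWN_SOURCE_INFECTION)
    specific = [lab for lab in labels if lab in SPECIFIC_INFECTIONS]
    exclusive = spec.infection_exclusivity and u_src in labels and specific

    cases: list[PatientCase] = []
    width = len(str(spec.n_patients))
    for i in range(spec.n_patients):
        center_idx = int(rng_center.random() >= spec.center_mix[0])
        center = CENTERS[center_idx]
        present: dict[str, bool] = {}
        for lab in labels:
            if exclusive and lab == u_src:
                continue
            present[lab] = bool(
                rng_labels.random() < spec.label_prevalence[lab][center_idx]
            )
        if exclusive:
            # conditional draw: never co-occurs with a specific infection,
            # marginal prevalence preserved via p_u / P(no specific infection)
            if any(present[s] for s in specific):
                present[u_src] = False
            else:
                p_u = spec.label_prevalence[u_src][center_idx]
                p_no_spec = float(
                    np.prod(
                        [1.0 - spec.label_prevalence[s][center_idx] for s in specific]
                    )
                )
                threshold = min(1.0, p_u / p_no_spec) if p_no_spec > 0 else 0.0
                present[u_src] = bool(rng_labels.random() < threshold)
        truth = tuple(
            Diagnosis(lab, _draw_grade(rng_labels, grade_dists[lab]))
            for lab in labels
            if present[lab]
        )
        params = spec.token_count_dist[center]
        sigma = params["sigma"]
        mu = float(np.log(params["mean"]) - sigma**2 / 2)
        token_count = max(1, int(round(rng_tokens.lognormal(mu, sigma))))
        pdqi = float(np.clip(rng_pdqi.normal(*spec.pdqi_dist), 1.0, 5.0))
        case_id = f"case-{i:0{width}d}"
        record = _schematic_record(rng_rec, case_id, truth) if with_records else None
        cases.append(
            PatientCase(
                case_id=case_id,
                center=center,
                truth=truth,
                token_count=token_count,
                pdqi_score=round(pdqi, 2),
                record=record,
            )
        )
    return cases


# ---------------------------------------------------------------------------
# Predictor profiles and repeated-run predictions
# ---------------------------------------------------------------------------

class PredictorProfile(BaseModel):
    """Error profile of a simulated diagnostic annotator.

    ``sensitivity`` / ``false_positive_rate`` apply to every label unless
    overridden per label.  ``severity_confusion`` is the probability a
    correctly detected label's grade is perturbed; ``run_flip`` is the
    probability a per-label verdict is re-randomized between repeated runs
    (0 → all runs identical, 1 → runs fully independent).  ``style``
    documents the intended error signature: AI-like profiles trade
    precision for recall, human-like profiles the converse.
    """

    model_config = {"frozen": True}

    sensitivity: float = Field(ge=0.0, le=1.0, default=0.8)
    false_positive_rate: float = Field(ge=0.0, le=1.0, default=0.05)
    per_label_sensitivity: dict[str, float] = Field(default_factory=dict)
    per_label_fpr: dict[str, float] = Field(default_factory=dict)
    severity_confusion: float = Field(ge=0.0, le=1.0, default=0.0)
    run_flip: float = Field(ge=0.0, le=1.0, default=0.2)
    style: Literal["ai_like", "human_like", "custom"] = "custom"

    @model_validator(mode="after")
    def _canonical_overrides(self):
        for name in ("per_label_sensitivity", "per_label_fpr"):
            overrides = getattr(self, name)
            for p in overrides.values():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name} probability {p} outside [0, 1]")
            object.__setattr__(
                self, name, {canonical_name(k): v for k, v in overrides.items()}
            )
        return self

    def sens(self, label: str) -> float:
        return self.per_label_sensitivity.get(canonical_name(label), self.sensitivity)

    def fpr(self, label: str) -> float:
        return self.per_label_fpr.get(canonical_name(label), self.false_positive_rate)

    @classmethod
    def ai_like(cls, **overrides) -> "PredictorProfile":
        """High recall, lower precision — the AI error signature."""
        defaults = dict(
            sensitivity=0.85, false_positive_rate=0.06, severity_confusion=0.1,
            run_flip=0.2, style="ai_like",
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def human_like(cls, **overrides) -> "PredictorProfile":
        """Conservative: high precision, lower recall — the expert signature."""
        defaults = dict(
            sensitivity=0.60, false_positive_rate=0.01, severity_confusion=0.05,
            run_flip=0.05, style="human_like",
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass(frozen=True)
class PredictionSet:
    """Per-case predicted diagnosis sets across R repeated inference runs."""

    case_id: str
    source: str
    runs: tuple[tuple[Diagnosis, ...], ...]

    def __post_init__(self) -> None:
        if len(self.runs) < 1:
            raise ValueError(f"case {self.case_id}: at least one run required")


def _check_profile_labels(profile: PredictorProfile, label_set: LabelSet) -> None:
    known = set(label_set.names())
    unknown = sorted(
        (set(profile.per_label_sensitivity) | set(profile.per_label_fpr)) - known
    )
    if unknown:
        raise ValueError(f"profile references labels absent from the cohort: {unknown}")


def generate_predictions(
    cohort: Sequence[PatientCase],
    profile: PredictorProfile,
    label_set: LabelSet | None = None,
    n_runs: int = 5,
    seed: "int | np.random.SeedSequence" = 0,
    source: str = "synthetic",
) -> list[PredictionSet]:
    """Simulate R repeated inference runs for every case.

    For each (case, label) a base verdict is drawn — present with
    probability ``sensitivity`` when the label is in the case truth,
    otherwise with probability ``false_positive_rate``.  Each run either
    keeps the base verdict or, with probability ``run_flip``, re-draws it
    from the same marginal, reproducing run-to-run randomness without
    changing per-run detection rates.  A detected true label carries the
    truth grade, perturbed with probability ``severity_confusion``; a
    false positive carries a uniform grade over mild/moderate/severe.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if label_set is None:
        label_set = default_label_set()
    _check_profile_labels(profile, label_set)
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(seed)
    rng = np.random.default_rng(seed)

    out: list[PredictionSet] = []
    graded = list(GRADED_SEVERITIES)
    for case in cohort:
        truth = {d.label: d.grade for d in case.truth}
        runs: list[tuple[Diagnosis, ...]] = []
        base: dict[str, bool] = {}
        pred_grade: dict[str, Severity] = {}
        for lab in label_set.names():
            p = profile.sens(lab) if lab in truth else profile.fpr(lab)
            base[lab] = bool(rng.random() < p)
            if lab in truth:
                grade = truth[lab]
                if grade is not Severity.UNSPECIFIED and (
                    rng.random() < profile.severity_confusion
                ):
                    others = [g for g in graded if g is not grade]
                    grade = others[int(rng.integers(len(others)))]
            else:
                grade = graded[int(rng.integers(len(graded)))]
            pred_grade[lab] = grade
        for _ in range(n_runs):
            items = []
            for lab in label_set.names():
                verdict = base[lab]
                if profile.run_flip > 0 and rng.random() < profile.run_flip:
                    p = profile.sens(lab) if lab in truth else profile.fpr(lab)
                    verdict = bool(rng.random() < p)
                if verdict:
                    items.append(Diagnosis(lab, pred_grade[lab]))
            runs.append(tuple(items))
        out.append(PredictionSet(case_id=case.case_id, source=source, runs=tuple(runs)))
    return out


def generate_rater_annotations(
    cohort: Sequence[PatientCase],
    n_raters: int,
    rater_profiles: Sequence[PredictorProfile] | None = None,
    label_set: LabelSet | None = None,
    seed: int = 0,
) -> list[dict[str, tuple[Diagnosis, ...]]]:
    """Independent per-rater annotations conditional on case truth.

    Returns one mapping case_id → diagnosis tuple per rater.  Agreement
    between raters arises only through the shared truth, matching the
    independence assumption of the downstream kappa statistic.
    """
    if n_raters < 2:
        raise ValueError("n_raters must be >= 2 (agreement is undefined otherwise)")
    if rater_profiles is None:
        rater_profiles = [PredictorProfile.human_like()] * n_raters
    if len(rater_profiles) != n_raters:
        raise ValueError("need one profile per rater")
    seeds = np.random.SeedSequence(seed).spawn(n_raters)
    annotations = []
    for r, (profile, child) in enumerate(zip(rater_profiles, seeds)):
        preds = generate_predictions(
            cohort,
            profile,
            label_set=label_set,
            n_runs=1,
            seed=child,
            source=f"rater-{r + 1}",
        )
        annotations.append({p.case_id: p.runs[0] for p in preds})
    return annotations


# ---------------------------------------------------------------------------
# Raw structured-output records (parser exercise)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RawOutput:
    """One serialized model response, possibly deliberately corrupted."""

    case_id: str
    source: str
    run_index: int
    text: str
    corrupted: bool


def generate_raw_outputs(
    predictions: Sequence[PredictionSet],
    with_think: bool = False,
    malformed_fraction: float = 0.0,
    seed: int = 0,
    schema: OutputSchema = OutputSchema(),
) -> list[RawOutput]:
    """Serialize every run as a structured-output JSON record.

    A ``malformed_fraction`` of records is corrupted (truncation or stray
    prose prefix) to exercise the parser's failure path.
    """
    if not 0.0 <= malformed_fraction <= 1.0:
        raise ValueError("malformed_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    records: list[RawOutput] = []
    for pred in predictions:
        for r, run in enumerate(pred.runs):
            think = (
                f"reviewed record for {pred.case_id}; "
                f"{len(run)} complication(s) supported by the documentation"
                if with_think
                else None
            )
            text = serialize_output(list(run), think=think, schema=schema)
            corrupted = bool(rng.random() < malformed_fraction)
            if corrupted:
                if rng.random() < 0.5 and len(text) > 2:
                    text = text[: int(rng.integers(1, len(text) - 1))]
                else:
                    text = "model preamble outside JSON " + text[:-1]
            records.append(
                RawOutput(
                    case_id=pred.case_id,
                    source=pred.source,
                    run_index=r,
                    text=text,
                    corrupted=corrupted,
                )
            )
    return records
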