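"""JSONL and CSV plumbing: cohort, prediction, and annotation files plus
report tables.

One JSON object per line; every line carries ``schema_version`` for
forward compatibility.  Readers report schema violations with their line
number.  Diagnoses serialize as ``{"complication": ..., "severity": ...}``
objects; the sentinel convention (empty list ⇔ "no postoperative
complications") lives in the strategy module's dialect, not here — stored
diagnosis lists are already normalized.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .labels import Diagnosis, Severity
from .metrics import MetricsResult
from .stats import BootstrapResult
from .stratify import StratumReport
from .synthetic import PatientCase, PredictionSet

SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """A JSONL line violating the expected schema, with its line number."""

    def __init__(self, path: Path | str, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.line_no = line_no


def _diag_to_obj(d: Diagnosis) -> dict:
    return {"complication": d.label, "severity": d.grade.value}


def _diag_from_obj(obj: dict, path, line_no: int) -> Diagnosis:
    try:
        return Diagnosis(obj["complication"], Severity.parse(obj.get("severity", "unspecified")))
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(path, line_no, f"bad diagnosis object {obj!r}: {exc}")


def _iter_jsonl(path: Path | str):
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise SchemaError(path, line_no, f"invalid JSON: {exc}") from None
            if not isinstance(obj, dict):
                raise SchemaError(path, line_no, "line is not a JSON object")
            yield line_no, obj


def _require(obj: dict, keys: Sequence[str], path, line_no: int) -> None:
    missing = [k for k in keys if k not in obj]
    if missing:
        raise SchemaError(path, line_no, f"missing fields: {missing}")


def write_cases(cases: Sequence[PatientCase], path: Path | str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for case in cases:
            fh.write(
                json.dumps(
                    {
                        "schema_version": SCHEMA_VERSION,
                        "case_id": case.case_id,
                        "center": case.center,
                        "truth": [_diag_to_obj(d) for d in case.truth],
                        "token_count": case.token_count,
                        "pdqi_score": case.pdqi_score,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_cases(path: Path | str) -> list[PatientCase]:
    cases = []
    for line_no, obj in _iter_jsonl(path):
        _require(obj, ("case_id", "center", "truth", "token_count"), path, line_no)
        cases.append(
            PatientCase(
                case_id=str(obj["case_id"]),
                center=str(obj["center"]),
                truth=tuple(_diag_from_obj(o, path, line_no) for o in obj["truth"]),
                token_count=int(obj["token_count"]),
                pdqi_score=float(obj.get("pdqi_score", float("nan"))),
            )
        )
    return cases


def write_predictions(predictions: Sequence[PredictionSet], path: Path | str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pred in predictions:
            fh.write(
                json.dumps(
                    {
                        "schema_version": SCHEMA_VERSION,
                        "case_id": pred.case_id,
                        "source": pred.source,
                        "runs": [
                            [_diag_to_obj(d) for d in run] for run in pred.runs
                        ],
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_predictions(path: Path | str) -> list[PredictionSet]:
    preds = []
    for line_no, obj in _iter_jsonl(path):
        _require(obj, ("case_id", "source", "runs"), path, line_no)
        if not isinstance(obj["runs"], list) or not obj["runs"]:
            raise SchemaError(path, line_no, "'runs' must be a non-empty list")
        preds.append(
            PredictionSet(
                case_id=str(obj["case_id"]),
                source=str(obj["source"]),
                runs=tuple(
                    tuple(_diag_from_obj(o, path, line_no) for o in run)
                    for run in obj["runs"]
                ),
            )
        )
    return preds


def write_annotations(
    annotations: Sequence[Mapping[str, Sequence[Diagnosis]]], path: Path | str
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r, ann in enumerate(annotations, start=1):
            for case_id in sorted(ann):
                fh.write(
                    json.dumps(
                        {
                            "schema_version": SCHEMA_VERSION,
                            "case_id": case_id,
                            "rater": f"rater-{r}",
                            "diagnoses": [_diag_to_obj(d) for d in ann[case_id]],
                        },
                        ensure_ascii=False,
                    )
                    + "\n"
                )


def read_annotations(path: Path | str) -> list[dict[str, tuple[Diagnosis, ...]]]:
    by_rater: dict[str, dict[str, tuple[Diagnosis, ...]]] = {}
    for line_no, obj in _iter_jsonl(path):
        _require(obj, ("case_id", "rater", "diagnoses"), path, line_no)
        by_rater.setdefault(str(obj["rater"]), {})[str(obj["case_id"])] = tuple(
            _diag_from_obj(o, path, line_no) for o in obj["diagnoses"]
        )
    return [by_rater[r] for r in sorted(by_rater)]


def runs_by_case_to_run_dicts(
    predictions: Sequence[PredictionSet],
) -> list[dict[str, list[Diagnosis]]]:
    """Reshape per-case PredictionSets into per-run case→diagnoses dicts."""
    n_runs = {len(p.runs) for p in predictions}
    if len(n_runs) != 1:
        raise ValueError(f"inconsistent run counts across cases: {sorted(n_runs)}")
    R = n_runs.pop()
    return [
        {p.case_id: list(p.runs[r]) for p in predictions} for r in range(R)
    ]


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def metrics_table(rows: Iterable[tuple[str, int, MetricsResult]]) -> pd.DataFrame:
    """Long-format metrics table: one row per (source, run, mode, strict)."""
    return pd.DataFrame(
        [
            {
                "source": source,
                "run": run,
                "mode": res.mode.value,
                "strict": res.strict,
                "n_cases": res.n_cases,
                "precision": res.precision,
                "recall": res.recall,
                "f1": res.f1,
            }
            for source, run, res in rows
        ]
    )


def comparison_table(
    rows: Iterable[tuple[str, str, str, BootstrapResult]]
) -> pd.DataFrame:
    """Comparison report mirroring the published table layout:
    one row per (center, model, comparison, metric)."""
    return pd.DataFrame(
        [
            {
                "center": center,
                "model": model,
                "comparison": comparison,
                "metric": res.metric,
                "mode": res.mode.value,
                "strict": res.strict,
                "mean_diff": res.mean_diff,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p_value": res.p,
                "p_corrected": res.p_corrected,
            }
            for center, model, comparison, res in rows
        ]
    )


def strata_table(reports: Iterable[StratumReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "scheme": rep.scheme.value,
                "stratum": rep.stratum,
                "n": rep.n_cases,
                "mode": rep.result.mode.value if rep.result else None,
                "mean_token_count": rep.mean_token_count,
                "precision": rep.result.precision if rep.result else None,
                "recall": rep.result.recall if rep.result else None,
                "f1": rep.result.f1 if rep.result else None,
                "flags": ";".join(rep.flags),
            }
            for rep in reports
        ]
    )


def config_hash(config_obj: Mapping) -> str:
    """Stable short hash of a resolved, JSON-serializable config."""
    blob = json.dumps(config_obj, sort_keys=True, ensure_ascii=False).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
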