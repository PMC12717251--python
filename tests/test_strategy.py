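"""Task decomposition, aggregation rules, parsing, and strategy execution."""

import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perioeval.labels import (
    SENTINEL,
    UNKNOWN_SOURCE_INFECTION,
    Diagnosis,
    LabelSet,
    Severity,
)
from perioeval.strategy import (
    OutputSchema,
    aggregate_targeted,
    decompose_targeted,
    expand_training_examples,
    parse_model_output,
    run_comprehensive,
    run_targeted,
    serialize_output,
)


def negative_verdicts(label_set):
    return {n: (False, Severity.UNSPECIFIED) for n in label_set.names()}


class TestDecompose:
    def test_one_unit_per_label_with_shared_record(self, label_set):
        units = decompose_targeted("case-1", "record text", label_set)
        assert len(units) == 22
        assert {u.target_label for u in units} == set(label_set.names())
        assert all(u.record_text == "record text" for u in units)

    def test_single_label_degenerate(self):
        ls = LabelSet.from_names(["pneumonia"])
        assert len(decompose_targeted("c", "t", ls)) == 1

    def test_empty_label_set_rejected(self):
        with pytest.raises(ValueError):
            decompose_targeted("c", "t", LabelSet(()))


class TestAggregate:
    def test_all_negative_yields_sentinel_empty_set(self, label_set):
        assert aggregate_targeted(negative_verdicts(label_set), label_set) == []

    def test_specific_infection_suppresses_unknown_source(self, label_set):
        v = negative_verdicts(label_set)
        v["pneumonia"] = (True, Severity.MODERATE)
        v[UNKNOWN_SOURCE_INFECTION] = (True, Severity.MILD)
        out = aggregate_targeted(v, label_set)
        assert [d.label for d in out] == ["pneumonia"]

    def test_unknown_source_alone_is_kept(self, label_set):
        v = negative_verdicts(label_set)
        v[UNKNOWN_SOURCE_INFECTION] = (True, Severity.MILD)
        out = aggregate_targeted(v, label_set)
        assert [d.label for d in out] == [UNKNOWN_SOURCE_INFECTION]

    def test_nonspecific_positive_does_not_trigger_suppression(self, label_set):
        v = negative_verdicts(label_set)
        v["delirium"] = (True, Severity.MILD)
        v[UNKNOWN_SOURCE_INFECTION] = (True, Severity.MILD)
        out = aggregate_targeted(v, label_set)
        assert {d.label for d in out} == {"delirium", UNKNOWN_SOURCE_INFECTION}

    def test_missing_verdicts_listed(self, label_set):
        v = negative_verdicts(label_set)
        v.pop("pneumonia")
        with pytest.raises(ValueError, match="pneumonia"):
            aggregate_targeted(v, label_set)

    def test_never_emits_unknown_source_with_specific_infection(self, label_set):
        """Invariant over random verdict maps."""
        import random

        rng = random.Random(0)
        specific = {"pneumonia", "bloodstream infection"}
        for _ in range(200):
            v = {
                n: (rng.random() < 0.3, Severity.MILD) for n in label_set.names()
            }
            out = {d.label for d in aggregate_targeted(v, label_set)}
            if out & specific:
                assert UNKNOWN_SOURCE_INFECTION not in out


class TestParse:
    def test_single_diagnosis_record(self):
        raw = json.dumps(
            {"complications": [{"complication": "Pneumonia", "severity": "moderate"}]}
        )
        parsed = parse_model_output(raw)
        assert parsed.ok
        assert parsed.diagnoses == (Diagnosis("pneumonia", Severity.MODERATE),)

    def test_sentinel_record_maps_to_empty(self):
        parsed = parse_model_output(json.dumps({"complications": [SENTINEL]}))
        assert parsed.ok and parsed.diagnoses == () and parsed.sentinel

    def test_truncated_text_fails_gracefully(self):
        parsed = parse_model_output('{"complications": [{"complication":')
        assert parsed.status == "failed" and "JSON" in parsed.message

    def test_missing_think_fails_when_expected(self):
        parsed = parse_model_output(
            json.dumps({"complications": [SENTINEL]}), expect_think=True
        )
        assert not parsed.ok

    def test_unknown_label_flagged_not_dropped(self, label_set):
        raw = json.dumps(
            {"complications": [{"complication": "martian fever", "severity": "mild"}]}
        )
        parsed = parse_model_output(raw, label_set=label_set)
        assert parsed.ok
        assert parsed.unknown_labels == ("martian fever",)
        assert len(parsed.diagnoses) == 1

    def test_sentinel_mixed_with_diagnoses_rejected(self):
        raw = json.dumps(
            {"complications": [SENTINEL, {"complication": "pneumonia"}]}
        )
        assert not parse_model_output(raw).ok

    def test_configurable_schema_fields(self):
        schema = OutputSchema(
            think_field="reasoning", list_field="findings",
            label_field="type", severity_field="grade",
        )
        raw = serialize_output(
            [Diagnosis("delirium", Severity.MILD)], think="because", schema=schema
        )
        parsed = parse_model_output(raw, expect_think=True, schema=schema)
        assert parsed.ok and parsed.think == "because"
        assert parsed.diagnoses[0].label == "delirium"

    grades = st.sampled_from([Severity.MILD, Severity.MODERATE, Severity.SEVERE])

    @given(
        st.lists(
            st.builds(
                Diagnosis,
                st.sampled_from(["pneumonia", "delirium", "stroke", "arrhythmia"]),
                grades,
            ),
            max_size=4,
            unique_by=lambda d: d.label,
        ),
        st.one_of(st.none(), st.text(min_size=1, max_size=20)),
    )
    @settings(max_examples=150, deadline=None)
    def test_serialize_parse_roundtrip(self, diagnoses, think):
        parsed = parse_model_output(
            serialize_output(diagnoses, think=think),
            expect_think=think is not None,
        )
        assert parsed.ok
        assert set(parsed.diagnoses) == set(diagnoses)
        assert parsed.think == think


def truth_echo_predictor(truth):
    """Deterministic predictor returning exactly the case truth."""

    def predict(record_text, labels, mode, cot):
        if mode == "comprehensive":
            return serialize_output(list(truth))
        return serialize_output([d for d in truth if d.label == labels[0]])

    return predict


class TestStrategyExecution:
    def test_truth_echo_strategies_agree(self, small_cohort, label_set):
        for case in small_cohort:
            predictor = truth_echo_predictor(case.truth)
            comp = run_comprehensive(case.case_id, "txt", predictor, label_set)
            targ = run_targeted(case.case_id, "txt", predictor, label_set)
            assert set(comp.diagnoses) == set(targ.diagnoses) == set(case.truth)
            assert comp.n_calls == 1
            assert targ.n_calls == len(label_set)

    def test_targeted_single_positive_label(self, label_set):
        truth = (Diagnosis("paralytic ileus", Severity.MODERATE),)
        run = run_targeted("c", "txt", truth_echo_predictor(truth), label_set)
        assert run.diagnoses == truth

    def test_comprehensive_sentinel_output(self, label_set):
        run = run_comprehensive("c", "txt", truth_echo_predictor(()), label_set)
        assert run.diagnoses == () and not run.failed

    def test_comprehensive_parse_failure_recorded(self, label_set):
        run = run_comprehensive(
            "c", "txt", lambda *a: "not json at all", label_set, retries=0
        )
        assert run.failed and run.diagnoses == () and run.n_calls == 1

    def test_comprehensive_retry_budget_recovers(self, label_set):
        calls = iter(["garbage", serialize_output([Diagnosis("stroke")])])

        def flaky(*args):
            return next(calls)

        run = run_comprehensive("c", "txt", flaky, label_set, retries=1)
        assert not run.failed and run.n_calls == 2

    def test_targeted_all_units_failing_yield_flagged_sentinel(self, label_set):
        run = run_targeted(
            "c", "txt", lambda *a: "garbage", label_set, retries=0
        )
        assert run.diagnoses == ()
        assert run.failed
        assert len(run.parse_failures) == len(label_set)


class TestTrainingExpansion:
    def test_cohort_times_labels(self, small_cohort, label_set):
        triples = [(c.case_id, "txt", c.truth) for c in small_cohort]
        examples = expand_training_examples(triples, label_set)
        assert len(examples) == len(small_cohort) * len(label_set)

    def test_empty_truth_yields_all_negative(self, label_set):
        examples = expand_training_examples([("c", "txt", ())], label_set)
        assert len(examples) == 22
        assert not any(e.present for e in examples)

    def test_positive_counts_conserve_truth_totals(self, small_cohort, label_set):
        triples = [(c.case_id, "txt", c.truth) for c in small_cohort]
        examples = expand_training_examples(triples, label_set)
        truth_count = {lab.name: 0 for lab in label_set}
        for c in small_cohort:
            for d in c.truth:
                truth_count[d.label] += 1
        for lab in label_set.names():
            positives = sum(
                1 for e in examples if e.target_label == lab and e.present
            )
            assert positives == truth_count[lab]
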