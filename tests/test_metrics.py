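"""Set-based micro/macro metrics against an independent brute-force oracle."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perioeval.labels import Diagnosis, Severity
from perioeval.metrics import (
    Averaging,
    CaseCounts,
    case_counts,
    evaluate,
    macro_metrics,
    micro_metrics,
    normalize,
)

# ---------------------------------------------------------------------------
# Independent oracle: literal set enumeration + direct formula evaluation,
# written without reference to the implementation under test.
# ---------------------------------------------------------------------------

def oracle_metrics(gold_sets, pred_sets, mode):
    """gold_sets/pred_sets: lists of python sets of hashable keys."""

    def prf(tp, fp, fn):
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        return p, r, f

    triples = [
        (len(g & h), len(h - g), len(g - h)) for g, h in zip(gold_sets, pred_sets)
    ]
    if mode == "micro":
        return prf(
            sum(t[0] for t in triples),
            sum(t[1] for t in triples),
            sum(t[2] for t in triples),
        )
    per_case = [prf(*t) for t in triples]
    n = len(per_case)
    return tuple(sum(v[i] for v in per_case) / n for i in range(3))


LABELS = ["a", "b", "c", "d", "e", "f"]
GRADES = [Severity.MILD, Severity.MODERATE, Severity.SEVERE]


def random_instance(rng, max_cases=10):
    n = rng.randint(1, max_cases)
    gold, pred = {}, {}
    for i in range(n):
        cid = f"c{i}"
        gold[cid] = [
            Diagnosis(lab, rng.choice(GRADES))
            for lab in LABELS
            if rng.random() < 0.35
        ]
        pred[cid] = [
            Diagnosis(lab, rng.choice(GRADES))
            for lab in LABELS
            if rng.random() < 0.35
        ]
    return gold, pred


def as_key_sets(diag_map, strict):
    out = []
    for cid in sorted(diag_map):
        if strict:
            out.append({(d.label, d.grade) for d in diag_map[cid]})
        else:
            out.append({d.label for d in diag_map[cid]})
    return out


class TestOracleEquivalence:
    @pytest.mark.parametrize("mode", ["micro", "macro"])
    @pytest.mark.parametrize("strict", [False, True])
    def test_matches_brute_force_on_random_instances(self, mode, strict):
        rng = random.Random(20240917)
        for _ in range(250):
            gold, pred = random_instance(rng)
            counts = [
                case_counts(
                    normalize(gold[cid], strict=strict, case_id=cid),
                    normalize(pred[cid], strict=strict, case_id=cid),
                )
                for cid in sorted(gold)
            ]
            res = (
                micro_metrics(counts) if mode == "micro" else macro_metrics(counts)
            )
            exp = oracle_metrics(
                as_key_sets(gold, strict), as_key_sets(pred, strict), mode
            )
            assert abs(res.precision - exp[0]) < 1e-12
            assert abs(res.recall - exp[1]) < 1e-12
            assert abs(res.f1 - exp[2]) < 1e-12


class TestNormalize:
    def test_dedupes_identical_diagnoses(self):
        ds = normalize([Diagnosis("pneumonia", Severity.MILD)] * 2, strict=True)
        assert len(ds.items) == 1

    def test_sentinel_maps_to_empty_set(self):
        assert normalize(["no postoperative complications"]).items == frozenset()

    def test_lenient_projection_ignores_grades(self):
        a = normalize([Diagnosis("pneumonia", Severity.MILD)])
        b = normalize([Diagnosis("pneumonia", Severity.SEVERE)])
        assert a.items == b.items

    def test_conflicting_grades_keep_more_severe_with_flag(self):
        ds = normalize(
            [Diagnosis("pneumonia", Severity.MILD), Diagnosis("pneumonia", Severity.SEVERE)],
            strict=True,
        )
        assert ds.items == frozenset({("pneumonia", Severity.SEVERE)})
        assert any("conflicting" in f for f in ds.flags)


class TestCaseCounts:
    def test_set_arithmetic(self):
        g = normalize([Diagnosis("a"), Diagnosis("b")], case_id="x")
        p = normalize([Diagnosis("b"), Diagnosis("c")], case_id="x")
        assert case_counts(g, p) == CaseCounts(tp=1, fp=1, fn=1)

    def test_both_empty(self):
        g = normalize([], case_id="x")
        assert case_counts(g, g) == CaseCounts(0, 0, 0)

    def test_strict_severity_mismatch_counts_both_ways(self):
        g = normalize([Diagnosis("pneumonia", Severity.MILD)], strict=True, case_id="x")
        p = normalize([Diagnosis("pneumonia", Severity.SEVERE)], strict=True, case_id="x")
        assert case_counts(g, p) == CaseCounts(tp=0, fp=1, fn=1)

    def test_mismatched_case_ids_rejected(self):
        with pytest.raises(ValueError, match="case id mismatch"):
            case_counts(normalize([], case_id="x"), normalize([], case_id="y"))


class TestAverages:
    def test_micro_hand_example(self):
        res = micro_metrics([CaseCounts(1, 1, 1), CaseCounts(1, 0, 0)])
        assert res.precision == pytest.approx(2 / 3)
        assert res.recall == pytest.approx(2 / 3)
        assert res.f1 == pytest.approx(2 / 3)

    def test_micro_zero_denominators(self):
        res = micro_metrics([CaseCounts(0, 0, 0)])
        assert (res.precision, res.recall, res.f1) == (0.0, 0.0, 0.0)

    def test_macro_hand_example(self):
        res = macro_metrics([CaseCounts(1, 1, 1), CaseCounts(1, 0, 0)])
        assert res.f1 == pytest.approx((0.5 + 1.0) / 2)

    def test_macro_empty_empty_scores_zero_by_default(self):
        res = macro_metrics([CaseCounts(0, 0, 0)])
        assert res.f1 == 0.0

    def test_macro_empty_empty_optionally_scores_one(self):
        res = macro_metrics([CaseCounts(0, 0, 0)], score_empty_match=True)
        assert res.f1 == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            micro_metrics([])
        with pytest.raises(ValueError):
            macro_metrics([])

    def test_micro_f1_algebraic_identity(self):
        rng = random.Random(7)
        for _ in range(100):
            counts = [
                CaseCounts(rng.randint(0, 4), rng.randint(0, 4), rng.randint(0, 4))
                for _ in range(rng.randint(1, 8))
            ]
            tp = sum(c.tp for c in counts)
            fp = sum(c.fp for c in counts)
            fn = sum(c.fn for c in counts)
            if 2 * tp + fp + fn == 0:
                continue
            assert micro_metrics(counts).f1 == pytest.approx(
                2 * tp / (2 * tp + fp + fn)
            )


@st.composite
def paired_instances(draw):
    n = draw(st.integers(1, 6))
    gold, pred = {}, {}
    for i in range(n):
        cid = f"c{i}"
        gold[cid] = [
            Diagnosis(lab, draw(st.sampled_from(GRADES)))
            for lab in LABELS[:4]
            if draw(st.booleans())
        ]
        pred[cid] = [
            Diagnosis(lab, draw(st.sampled_from(GRADES)))
            for lab in LABELS[:4]
            if draw(st.booleans())
        ]
    return gold, pred


class TestProperties:
    @given(paired_instances())
    @settings(max_examples=150, deadline=None)
    def test_strict_never_exceeds_lenient(self, instance):
        gold, pred = instance
        for mode in (Averaging.MICRO, Averaging.MACRO):
            lenient = evaluate(gold, [pred], mode=mode, strict=False)[0]
            strict = evaluate(gold, [pred], mode=mode, strict=True)[0]
            assert strict.precision <= lenient.precision + 1e-12
            assert strict.recall <= lenient.recall + 1e-12

    @given(paired_instances())
    @settings(max_examples=100, deadline=None)
    def test_adding_correct_prediction_never_decreases_micro_recall(self, instance):
        gold, pred = instance
        target = next(
            (cid for cid in gold if {d.label for d in gold[cid]} - {d.label for d in pred[cid]}),
            None,
        )
        if target is None:
            return
        missing_label = next(
            iter({d.label for d in gold[target]} - {d.label for d in pred[target]})
        )
        grade = next(d.grade for d in gold[target] if d.label == missing_label)
        before = evaluate(gold, [pred])[0]
        pred2 = {cid: list(v) for cid, v in pred.items()}
        pred2[target] = pred2[target] + [Diagnosis(missing_label, grade)]
        after = evaluate(gold, [pred2])[0]
        assert after.recall >= before.recall - 1e-12

    @given(paired_instances())
    @settings(max_examples=100, deadline=None)
    def test_adding_incorrect_prediction_never_increases_micro_precision(self, instance):
        gold, pred = instance
        target = sorted(gold)[0]
        wrong = next(
            (lab for lab in LABELS if lab not in {d.label for d in gold[target]}
             and lab not in {d.label for d in pred[target]}),
            None,
        )
        if wrong is None:
            return
        before = evaluate(gold, [pred])[0]
        pred2 = {cid: list(v) for cid, v in pred.items()}
        pred2[target] = pred2[target] + [Diagnosis(wrong, Severity.MILD)]
        after = evaluate(gold, [pred2])[0]
        assert after.precision <= before.precision + 1e-12


class TestEvaluate:
    def test_identical_runs_give_identical_results(self, small_gold):
        runs = [dict(small_gold) for _ in range(5)]
        results = evaluate(small_gold, runs)
        assert all(r == results[0] for r in results)

    def test_truth_echo_is_perfect(self, small_gold):
        res = evaluate(small_gold, [dict(small_gold)])[0]
        assert (res.precision, res.recall, res.f1) == (1.0, 1.0, 1.0)

    def test_unmatched_cases_listed(self, small_gold):
        run = dict(small_gold)
        run.pop(sorted(run)[0])
        with pytest.raises(ValueError, match="case mismatch"):
            evaluate(small_gold, [run])
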