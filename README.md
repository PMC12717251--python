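# perioeval

Evaluation and statistical-comparison framework for multi-label detection
of perioperative complications from clinical narratives.

Automated complication surveillance treats each surgical case as carrying
a *set* of diagnoses — a complication label (paralytic ileus, anastomotic
leakage, pneumonia, …) with a severity grade (mild / moderate / severe).
A predictor (a language model, a clinician, anything) proposes such a set
per case, usually over several repeated stochastic inference runs.
`perioeval` is for the people who have to decide whether one predictor or
prompting strategy is actually better than another: it implements the
set-based scoring, the patient-level statistics, and the sensitivity
analyses, and ships a synthetic dual-center cohort generator so the whole
pipeline is testable without access to any protected clinical data.

## What it computes

**Metrics.** Per case *i* with gold set Y_i and prediction Ŷ_i:
TP_i = |Y_i ∩ Ŷ_i|, FP_i = |Ŷ_i − Y_i|, FN_i = |Y_i − Ŷ_i|.
Micro-averaged precision/recall/F1 pool these counts globally;
macro-averaged metrics are per-case scores (with explicit
zero-denominator rules) averaged over cases. Lenient mode matches labels;
strict mode requires the grade to match too.

**Strategies.** The *comprehensive* strategy asks a predictor about all
labels in one request; the *targeted* strategy asks one label per request
and recombines verdicts deterministically (all-negative → "no
postoperative complications"; a specific infection suppresses "infection
of unknown source"). The same decomposition expands n cases × L labels
into single-complication training examples.

**Statistics.** Patient-level bootstrap paired testing (resample patients
with replacement, draw one random inference run per strategy per
iteration, default 2000 iterations, single-sided, percentile CIs,
Bonferroni correction), t-distribution intervals across repeated runs,
Fleiss' κ over pooled (case, label) items with a case-level bootstrap CI,
and majority-consensus gold standards.

**Sensitivity analyses.** Stratified metrics by document-length
quartiles, gold complication count (≤1 / 2 / ≥3), and documentation
quality (PDQI-9 median split).

See `docs/methods.md` for the model, assumptions, defaults, and
limitations.

## Worked example

Compare a weak "comprehensive-like" predictor (sensitivity 0.55) against
a strong "targeted-like" one (sensitivity 0.85) on a 248-case synthetic
dual-center cohort, five runs each:

```python
import perioeval as pe
from perioeval.io import runs_by_case_to_run_dicts

spec = pe.default_cohort_spec(n_patients=248, seed=42)
cohort = pe.generate_cohort(spec)
gold = {c.case_id: list(c.truth) for c in cohort}

comp = pe.PredictorProfile(sensitivity=0.55, false_positive_rate=0.02, run_flip=0.05)
targ = pe.PredictorProfile(sensitivity=0.85, false_positive_rate=0.03, run_flip=0.05)
runs_a = runs_by_case_to_run_dicts(pe.generate_predictions(cohort, comp, n_runs=5, seed=1))
runs_b = runs_by_case_to_run_dicts(pe.generate_predictions(cohort, targ, n_runs=5, seed=2))

f1s = [r.f1 for r in pe.evaluate(gold, runs_b)]
mean, lo, hi = pe.t_interval(f1s)
print(f"targeted micro-F1 across 5 runs: {mean:.3f} (95% CI {lo:.3f}-{hi:.3f})")

res = pe.bootstrap_paired_test(gold, runs_a, runs_b, metric="f1",
                               config=pe.BootstrapConfig(iterations=2000, seed=3))
print(f"delta-F1 = {res.mean_diff:.3f}  95% CI [{res.ci_low:.3f}, {res.ci_high:.3f}]  "
      f"p = {res.p:.4f}  p_corrected = {res.p_corrected:.4f}")
```

Output:

```
targeted micro-F1 across 5 runs: 0.750 (95% CI 0.742-0.758)
delta-F1 = 0.173  95% CI [0.114, 0.233]  p = 0.0000  p_corrected = 0.0000
```

The first line is the strong predictor's pooled micro-F1 with its
t-interval across the five repeated runs. The second is the paired
bootstrap comparison: the strong predictor beats the weak one by 0.173 F1
on average, the percentile CI excludes zero, and the single-sided p-value
is below 1/2000 (printed as 0.0000), surviving the family-size-2
Bonferroni correction.

The same pipeline is available from the shell:

```sh
perioeval simulate --out-dir out --seed 42
perioeval evaluate out/cohort.jsonl out/predictions_ai.jsonl --out metrics.csv
perioeval compare  out/cohort.jsonl out/predictions_human.jsonl \
                   out/predictions_ai.jsonl --out comparison.csv
perioeval stratify out/cohort.jsonl out/predictions_ai.jsonl --out strata.csv
```

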