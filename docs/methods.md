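# Methods

`perioeval` evaluates multi-label detection of perioperative complications
from clinical narratives: each case carries a *set* of diagnoses (a
complication label, optionally with a mild/moderate/severe grade), a
predictor proposes such a set, and the package scores, compares, and
stress-tests predictors under a fully synthetic stand-in for private
clinical data. This note records the model, its assumptions, the defaults
that matter, and the design choices made where the design was genuinely
open.

## Set-based metrics

For case *i* with gold set Y_i and predicted set Ŷ_i:

    TP_i = |Y_i ∩ Ŷ_i|,  FP_i = |Ŷ_i − Y_i|,  FN_i = |Y_i − Ŷ_i|

**Micro-averaging** pools TP/FP/FN over all cases before forming
precision, recall, and F1. **Macro-averaging** computes per-case
precision/recall/F1 first — with per-case zero-denominator rules — then
takes the unweighted mean over cases. The zero-denominator rules are:
precision = 0 when there are no predictions, recall = 0 when there are no
gold labels, F1 = 0 when precision + recall = 0, applied globally for
micro and per case for macro.

A consequence worth flagging: under the macro rules a case with *empty
gold and a correctly empty prediction* scores per-case F1 = 0, so a
perfect predictor does not reach macro F1 = 1 on a cohort containing
zero-complication cases (roughly a third of cases under the default
prevalences). This is implemented faithfully as the default;
`macro_metrics(..., score_empty_match=True)` flips that single behaviour
for sensitivity analyses. Real cohorts' macro numbers may have used
either convention; both are exposed, neither is treated as ground truth.

**Strict mode** keys matching on (label, grade) pairs instead of labels
alone; an "unspecified" grade matches only "unspecified" (no partial
credit). Duplicate labels with conflicting grades normalize to the more
severe grade with a warning flag — conservative and deterministic.

Correctness is anchored by an independent brute-force oracle (literal set
enumeration plus direct formula evaluation) that the test suite runs
against hundreds of random small instances; agreement is required to
1e-12.

## Strategies

The **comprehensive** strategy issues one structured-output request per
case covering the full panel (22 labels by default). The **targeted**
strategy decomposes it into one single-complication request per label and
recombines verdicts with two deterministic rules: all-negative → the
sentinel "no postoperative complications" (the empty set), and a positive
specific infectious complication (default subset: pneumonia, the three
surgical-site infections, bloodstream infection) suppresses a positive
"infection of unknown source". The specific-infection subset is
configuration, not hard-coded. The same decomposition implements
training-data expansion: n cases × L labels single-complication examples
(146 × 22 = 3212 under the default panel).

Predictors are a pluggable callable contract returning raw structured
JSON (field names configurable; defaults `think` / `complications` /
`complication` / `severity`). Parsing never raises on content; failures
carry a diagnostic status. In targeted mode a unit that fails parsing
after the retry budget (default 2 retries) contributes a *negative*
verdict plus an audit flag, keeping aggregation total while failures stay
visible; a comprehensive-mode failure becomes an explicit failed run with
an empty prediction. Label canonicalization is case-insensitive exact
matching after whitespace collapse — no fuzzy matching; unknown labels
are flagged, not mapped.

## Statistical comparison

`bootstrap_paired_test` compares strategy B against A at the patient
level: each of B = 2000 iterations (default) resamples the n patients
with replacement, draws one of the R repeated inference runs per strategy
uniformly at random, recomputes the metric on the resample (micro counts
re-pooled within the resample), and records the difference B − A. The
reported quantities are the bootstrap mean difference, the percentile
[2.5%, 97.5%] interval, and a single-sided (greater) p-value equal to the
plain proportion of bootstrap differences ≤ 0 — hence always a multiple
of 1/B, with no +1 smoothing. Bonferroni correction uses family size
m = 2 by default (two sequential strategy comparisons); m is
configurable. Display intervals across repeated runs use the
t-distribution: mean ± t_{0.975, R−1}·sd/√R.

Two calibration properties are computed by the acceptance script and
tests under fixed study conditions (n = 100 cases, R = 5 runs, B = 500
scaled down from 2000, 200 replicate datasets):

* **Type-I error**: with both strategies drawn from one profile, the
  rejection rate at α = 0.05 stays near nominal.
* **Power**: between profiles whose asymptotic micro-F1 differ by ≈0.15
  (sensitivity 0.65 vs 0.90 at false-positive rate 0.02), rejection is
  nearly certain.

A real property of the single-run-per-iteration design: the bootstrap
spread includes the *full* run-to-run variance, while the dataset-level
difference effectively averages over runs, so the test grows conservative
as run-to-run variability increases (with a per-label flip rate of 0.2
the null rejection rate drops to ≈0.01). The calibration experiments
therefore fix a modest flip rate of 0.05, reflecting near-deterministic
structured-output inference; the conservatism under noisier predictors is
inherent to the method, not a bug in it.

## Agreement and consensus

Fleiss' κ treats every (case, label) pair as one item rated
present/absent by all raters — all complication categories pooled. The
point estimate delegates to `statsmodels`; degenerate tables (expected
chance agreement 1) return κ = 1 under perfect agreement by convention.
The CI is a case-level bootstrap percentile interval (2000 resamples,
keeping each case's block of label items intact), since no analytic
method is canonical for pooled binary items. The consensus gold standard
admits a diagnosis iff ≥ threshold raters (default 2 of 3) include its
label; the grade is the majority among including raters, ties broken
toward the more severe grade with an audit flag — clinically
conservative.

## Stratified sensitivity analyses

Three partitioning schemes, each disjoint and exhaustive, so pooled micro
counts equal the sum of per-stratum counts:

* **Token quartiles** — positional quartiles on the stable sort by
  (token count, input order); ties, including an all-equal cohort,
  resolve by stable order. Per-stratum mean token counts are reported.
* **Complication count** — |gold set| in ≤1 / 2 / ≥3 (default), with a
  0 / 1 / ≥2 preset exposed as an alternative reading.
* **Documentation quality** — PDQI-9 median split; "high" strictly above
  the median, ties to "low" (deterministic and conservative).

## Synthetic cohort generator

The generator defines the study conditions; it emulates the structure of
a dual-center surgical cohort, not its content:

* **Label prevalences** — per-center probabilities from the published
  dual-center complication table (20 named labels; counts over cohorts of
  146 and 102). Two placeholder labels complete the 22-label panel, since
  only 20 are enumerated publicly; the label set is configuration, never
  hard-coded. Labels are sampled independently, with one exception below.
* **Infection exclusivity** — "infection of unknown source" never
  co-occurs with a specific infectious complication in generated truth,
  mirroring the mutual-exclusion convention the targeted aggregation rule
  enforces; a coherent gold standard obeys the same convention, and
  without it the comprehensive/targeted equivalence under a perfect
  predictor would fail by construction. The conditional draw
  (p_u / P(no specific infection), applied only when no specific
  infection was drawn) preserves the label's marginal prevalence exactly.
  `CohortSpec(infection_exclusivity=False)` restores fully independent
  sampling.
* **Severity grades** — graded labels draw mild/moderate/severe with
  default weights 0.5/0.3/0.2 (detected complications skew mild);
  configurable per label; ungraded labels carry "unspecified".
* **Token counts** — log-normal per center with means matched to the
  published per-center averages (6841.6 and 8084.3 tokens) and shape
  parameters σ = 0.35 / 0.55 encoding the narrower center-1 vs broader
  center-2 distributions. The reference tokenizer is unstated upstream,
  so quartile boundaries are structural, not replicable; the default
  in-package tokenizer (whitespace words, CJK characters counted
  individually) only needs to induce a consistent ordering.
* **PDQI-9 scores** — normal(3.8, 0.5) clipped to [1, 5], the plausible
  range for mean-of-nine-dimension quality scores.
* **Predictor profiles** — per-label Bernoulli detection with
  `sensitivity` on true labels and `false_positive_rate` on absent ones;
  a detected true label's grade is perturbed with probability
  `severity_confusion`; run-to-run variation re-draws each verdict with
  probability `run_flip` from the same marginal, so per-run detection
  rates are unchanged while runs decorrelate. `ai_like()`
  (0.85 sensitivity / 0.06 fpr) yields recall > precision and
  `human_like()` (0.60 / 0.01) the converse, matching the observed error
  signatures of models vs clinicians.
* **Raters** — independent draws conditional on truth, so inter-rater
  agreement arises only through the shared truth.

What the generator does *not* emulate: realistic clinical prose (records
are schematic placeholders sufficient for markdown assembly and token
counting), label co-occurrence beyond the infection-exclusivity
constraint (real complications cluster), center-specific severity
distributions, and any coupling between documentation quality and
predictor difficulty unless a test constructs one explicitly. Passing
tests therefore demonstrate correctness of the *evaluation machinery*
under known data-generating processes — not clinical performance claims.

## Records and anonymization

Clinical records hold four components (general information, dated
postoperative notes, dated abnormal labs, dated examination reports) and
render to a fixed four-section markdown layout with ISO-8601 dates; a
strict inverse parser supports round-trip checks. Time-shift
anonymization applies one uniform per-patient offset (±3650 days,
seedable) to every date, preserving all pairwise intervals, and strips
structured direct identifiers (free-text de-identification is a non-goal).

## Numerical and reproducibility choices

All randomness flows through `numpy.random.default_rng` seeded from
`SeedSequence` spawns, so components draw from independent streams and
every generator is byte-identical under identical (spec, seed).
Bootstrap p-values are exact multiples of 1/B by construction. Problem
sizes used by the shipped experiments — 250 oracle instances, 100-case
equivalence check, 200 bootstrap replicates at B = 500, 500-case
recovery checks, 1000-item agreement check — were chosen as the smallest
sizes at which the binomial/bootstrap noise is far from the decision
thresholds.

## Known limitations

* Macro edge rules make macro scores cohort-composition dependent (see
  above); compare macro numbers only within a fixed cohort.
* The bootstrap test is conservative under large run-to-run variance (see
  above).
* Per-label (one-vs-rest) metrics, AUROC, calibration curves, permutation
  tests, and mixed-effects models are deliberately out of scope.
* The two placeholder labels carry zero prevalence by default; analyses
  exercising all 22 labels' positives must configure them.
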