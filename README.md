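# abscreen

Criterion-decomposed title/abstract screening for systematic reviews, with
a pluggable LLM-style judge and a full dual-reviewer evaluation suite.

## The problem

The first selection stage of a systematic review ("screening 1") asks two
independent reviewers to read every title and abstract a literature search
returned — often thousands of records — and apply pre-registered
inclusion/exclusion criteria. A language-model judge can stand in for the
second reviewer: it answers each named criterion with a Boolean verdict
and a brief justification, a record is machine-included only when *all*
criteria are true, and the second human then only needs to read the
records where machine and first reviewer disagree (plus anything the
pipeline failed to process). `abscreen` implements that pipeline end to
end for methodologists who want to measure — not just hope — how much
second-reviewer workload such a judge removes.

## What it computes

With machine decisions $\hat{y}$ and first-reviewer labels $y$ tallied
into a 2×2 confusion matrix $(TP, FP, FN, TN)$, $n = TP+FP+FN+TN$:

- precision, recall, specificity, $F_1$, and the Matthews correlation
  coefficient
  $\mathrm{MCC} = \frac{TP\cdot TN - FP\cdot FN}{\sqrt{(TP+FP)(TP+FN)(TN+FP)(TN+FN)}}$;
- observed agreement $p_0 = (TP+TN)/n$, Cohen's
  $\kappa = (p_0 - p_e)/(1 - p_e)$ with marginal-product chance agreement
  $p_e$, and the prevalence-adjusted bias-adjusted kappa
  $\mathrm{PABAK} = 2p_0 - 1$, which fixes chance agreement at 0.5 and is
  therefore robust to the extreme class imbalance of screening corpora;
- workload reduction against the *original* number of identified records:
  records where machine and reviewer agree need no second look, while
  disagreements, processing failures and records dropped in preprocessing
  remain second-reviewer workload.

Two decision rules are provided as scikit-learn estimators: the strict
all-criteria-true conjunction (`AllCriteriaTrueClassifier`) and a
random-forest combiner (`RandomForestCriterionCombiner`, 100 trees,
balanced class weights) that learns how criteria jointly predict the
human decision, evaluated with out-of-fold predictions from stratified
k-fold cross-validation where k adapts to the minority class size
(min 2, max 5). Per-criterion point-biserial correlations with the human
label identify which criteria carry signal.

Because live model output is messy, the judging layer handles prose-prefixed
JSON, string-typed Booleans and missing criteria (defaulted to false),
retries rate-limited calls with exponential backoff (2^attempt seconds,
at most five attempts), caps concurrency at five in-flight judgments, and
checkpoints progress atomically with provably disjoint succeeded/missing
sets so interrupted runs resume without re-judging.

A first-class simulator (`abscreen.simulate`) generates synthetic corpora
with a known inclusion prevalence, per-criterion sensitivity and
false-positive rate, and a record-level failure rate — so every stage is
testable offline against closed-form operating points
($\mathrm{recall} = \prod_c s_c$, $\mathrm{specificity} = 1 - \prod_c f_c$).

## Worked example

```python
from abscreen import (
    CriterionProfile, SimulationConfig, generate_review, simulate_verdicts,
    all_true_rule, evaluate_decisions, expected_operating_point,
)

profiles = [
    CriterionProfile("population",   sensitivity=0.95, false_positive_rate=0.30),
    CriterionProfile("intervention", sensitivity=0.90, false_positive_rate=0.25),
    CriterionProfile("outcome",      sensitivity=0.92, false_positive_rate=0.40),
]
config = SimulationConfig(n_records=2000, prevalence=0.05,
                          profiles=profiles, failure_rate=0.01, seed=28)
dataset = generate_review(config)
matrix = simulate_verdicts(dataset, profiles, config.failure_rate, config.seed)

decisions = all_true_rule(matrix)
report = evaluate_decisions(decisions, dataset.labels(),
                            dataset.original_total, status=matrix.status)
print("expected operating point:", expected_operating_point(profiles))
m, a, w = report["metrics"], report["agreement"], report["workload"]
print(f"recall={m.recall:.3f} specificity={m.specificity:.3f} mcc={m.mcc:.3f}")
print(f"p0={a.p0:.3f} kappa={a.kappa:.3f} pabak={a.pabak:.3f}")
print(f"workload: {w.correct} correct of {w.original_total} -> "
      f"{w.remaining} remaining ({w.reduction_percent}% reduction)")
```

prints

```
expected operating point: (0.7866, 0.97)
recall=0.776 specificity=0.976 mcc=0.645
p0=0.968 kappa=0.636 pabak=0.937
workload: 1922 correct of 2000 -> 78 remaining (96% reduction)
```

The empirical recall and specificity of the strict rule sit on the
closed-form operating point (0.787, 0.970) up to binomial noise; of the
2,000 originally identified records, only 78 — disagreements plus the ~1%
the judge failed to process — would still need the second reviewer.

The same flow is available from the shell: `abscreen simulate`,
`abscreen preprocess`, `abscreen embed`, `abscreen screen`,
`abscreen decide`, `abscreen evaluate` (see `abscreen --help`). Three
example criteria configurations (a physiotherapy economics review, a
hereditary-neuropathy treatment review, a digital-health
cost-effectiveness review) ship under `abscreen.bundled_criteria`.

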