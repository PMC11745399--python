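# Methods

## Pipeline model

`abscreen` models machine-assisted title/abstract screening as five
composable stages.

**Preprocessing** (`records`). Raw exports are delimited tables with one
row per record. Cleanup removes rows with an empty abstract, duplicates
(first occurrence kept), and non-English records; the surviving rows get
deterministic ids (`rec-00000`, … from surviving row order) and a
`record_text` joining title and abstract — the unit of judging. Two
choices here were genuinely open and are package decisions: duplicates
are defined by case-folded, whitespace-normalized equality of
(title, abstract), and the title/abstract join defaults to a labeled form
(`Title: … Abstract: …`), with a plain single-space variant selectable,
because explicit field labels help an instruction-following judge parse
the record. Language filtering trusts a `language` column when present
and otherwise defers to a pluggable detector whose default accepts
everything — guessing a detection method would bake in silent data loss.
Rows whose screening-1 label is missing are dropped and counted: every
downstream comparison needs a Boolean human label. The count of records
*before* preprocessing is carried on the dataset because it is the
denominator of workload accounting (dropped records still reach the
second reviewer). Preprocessing is idempotent and id assignment is
reproducible run-to-run.

**Indexing** (`store`). Records are embedded in batches (default 100, the
usual embedding-API batch size) into an id-addressed index persisted as a
vectors file plus a JSON manifest, written atomically (temp file +
rename). Retrieval is exact-ID only — an unknown id raises, and there is
deliberately no similarity fallback, so a judging call can never receive
a near-duplicate of its intended record. Completeness is validated by
comparing dataset and index id sets (missing/extra reports). The default
embedder is a deterministic hash-based pseudo-embedding (SHAKE-128,
dimension 64): retrieval in this design never uses vector geometry, so a
semantically meaningless but reproducible embedding exercises the whole
contract offline; live embedding services implement the same two-method
interface. The stage is optional — the judge can read `record_text`
directly — and is kept because ID-filtered retrieval from a persistent
store is the deployment shape for large corpora.

**Judging** (`judge`, `backends`). One prompt per record lists every
criterion's key and instruction and demands a JSON-only response keyed by
criterion, each entry a Boolean `value` plus a brief `justification`.
Decoding parameters for live backends default to temperature 0.0,
top-p 0.95, seed 28, a 25,000-token context window and unlimited response
length (so JSON is never truncated). The parser is total: it extracts
the first decodable JSON object even when prefaced or followed by prose,
normalizes string Booleans ("True"/"false"/"1"…), matches criterion keys
case-insensitively, and fills absent or uninterpretable criteria with
`false` plus a placeholder justification — the conservative default,
since a false verdict can only push a record toward machine exclusion,
which adds second-reviewer workload but never silently includes. A
response with no recoverable JSON object fails the record (failure class
`parse`). Rate-limit errors are the only retriable class: after attempt
k the judge waits 2^k seconds (2, 4, 8, 16 s for retries 1–4), giving up
after five attempts; attempts are counted from 1 and the clock is
injected so backoff is testable without real delays. Any other backend
error fails the record immediately. Failed records carry a complete
all-false verdict map (so decision rules consume them uniformly) but
keep `status="failed"` so evaluation can refuse to credit them. Corpus
runs hold at most five judgments in flight, checkpoint atomically after
every batch (default 20 records — a checkpoint cadence, chosen small
enough that an interruption loses under a minute of work), verify
succeeded/missing disjointness at every checkpoint, and on resume skip
succeeded records while re-attempting failed ones.

**Decision rules** (`decide`). The strict rule includes a record iff every
criterion verdict is true; zero criteria are rejected rather than
vacuously including everything. The random-forest combiner (100 trees,
class weights inversely proportional to class frequencies) learns the
joint criterion→decision mapping and is evaluated by out-of-fold
prediction: stratified k-fold with k = min(5, max(2, minority class
size)), shuffled with a fixed seed, so every record is predicted by a
forest trained without its fold and each fold contains both classes. The
inclusion threshold is the forest's majority vote (probability ≥ 0.5) —
the natural default where none is prescribed. Records with failed status
are excluded from training and always decide false. Both rules are
scikit-learn estimators and compose with sklearn pipelines and model
selection; constant criterion columns trigger a warning but decisions
are still produced. The combiner is fit per screening run (one corpus,
one judge) rather than pooled across judges.

**Evaluation** (`evaluate`). Confusion cells treat "included at
screening 1" as positive. Metrics with zero denominators are reported as
`None`, an explicit undefined flag, never coerced to 0, so aggregation
cannot silently average them. PABAK = 2·p₀ − 1 exactly; Cohen's kappa
uses marginal-product chance agreement and is undefined when pₑ = 1.
Workload reduction divides the number of correctly classified records by
the *original* total and rounds half-away-from-zero to an integer
percent — the rule consistent with every unambiguous printed pair we
anchor to in tests (4,294/4,662 → 92%; 1,539/1,741 → 88%; 4,329/4,662 →
93%; 4,130/4,662 → 89%). When per-record statuses are supplied, failed
records never count as agreement even if their defaulted all-false
decision coincides with the human label: they are unprocessed, so they
stay in the remaining workload. Criterion–label correlations are Pearson
r on 0/1 codings (equivalently point-biserial), constant columns flagged
undefined, output sorted by key for stable heatmaps; no p-values are
attached.

## Synthetic corpus model (`simulate`)

The generator emulates the statistical skeleton of a screening task:
n records (templated English titles/abstracts; each abstract embeds its
record id, which is how the simulated judge backend recovers ground
truth), i.i.d. Bernoulli(π) inclusion labels, and — conditionally
independent given the true label — per-criterion verdicts that are true
with probability s (sensitivity) for includable records and f
(false-positive rate) for excludable ones, plus an outright failure rate
per record. Conditional independence is the simplest generative model
consistent with per-criterion judging; correlated criteria are real but
unmodelled, so the closed forms recall = Π s_c and specificity =
1 − Π f_c are exact only under this assumption. All randomness flows
through one seeded generator per call; fixed seeds give byte-identical
corpora. What passing tests therefore demonstrate is that the *pipeline
arithmetic and bookkeeping* are correct under known conditions — not
that any particular language model screens well: synthetic abstracts
carry no medical content, criterion verdicts have no semantics, and the
profiles are user-supplied rather than calibrated to any measured model.

Defaults used in tests and examples: prevalences 0.05–0.5 (real
screening corpora are heavily imbalanced, a few percent includable;
concentration checks use 0.5 for balanced binomial error), sensitivities
0.9–0.95 and false-positive rates 0.1–0.4 (mid-range criterion quality —
strong enough to carry signal, weak enough that the strict rule visibly
loses recall), failure rates 0–5% (observed processing-gap rates are
well under 1%, so this is a stress level), and seed 28 wherever a seed
is needed. Closed-form recovery checks use 40,000 records at prevalence
0.5 so both classes have ~20,000 members and three binomial standard
errors are a tight band; combiner checks use 200 records, enough for
five stratified folds on separable data while keeping the default suite
under half a minute.

## Numerical and degenerate-input choices

- Percent rounding: half-away-from-zero (`floor(x + 0.5)` for x ≥ 0),
  not banker's rounding.
- MCC is computed from the four cells with the product-denominator
  formula; a zero factor makes it undefined (`None`).
- A degenerate prevalence draw (single class) is resampled by default
  (up to 100 redraws) or raised as an error per option.
- Duplicate collapse keeps the first occurrence; ties in fold assignment
  are broken by the seeded shuffle of `StratifiedKFold`.
- An empty title is allowed; only an empty abstract removes a record.
- screening2 = included on a record with screening1 = excluded violates
  the two-stage design and raises rather than being silently repaired.

## Known limitations

- Live judge adapters (OpenAI-compatible, Ollama) are thin stdlib-HTTP
  wrappers and are not exercised by the offline test matrix.
- The simulator models a single ground-truth label; reviewer
  disagreement, criterion correlation and abstract-content effects are
  out of scope.
- Criteria refinement loops, full-text (screening 2) logic, fuzzy
  cross-database deduplication and PRISMA reporting are out of scope.
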