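# Methods

## Sequence construction

An event table (one row per event: patient, admission, timestamp, category,
code) is converted into prediction instances as follows.

1. **Tokenization.** Codes are prefixed by category — `l_` labs, `p_`
   prescriptions, `d_` diagnoses, `c_` conditions, `s_` symptoms — so equal
   raw identifiers from different sources remain distinct. ICD-9 diagnosis
   strings are kept verbatim at the recorded specificity (no hierarchy
   rollup), so predictions are made at the granularity physicians used.
2. **Admission chaining.** A patient's admissions are sorted by start time
   (earliest event in the admission); maximal runs with every consecutive
   start-to-start gap ≤ 365 days form one chain. The anchor is
   start-to-start because it is the simplest auditable choice; the boundary
   is inclusive (a gap of exactly 365 days chains). Chains with fewer than
   two admissions carry no history/label split and are discarded. One
   patient can contribute several chains, hence several sequences.
3. **Slicing.** The last admission of a chain is the prediction window: its
   diagnosis tokens are the labels, *everything* in it is excluded from the
   history (labs and prescriptions of the prediction window would leak the
   very encounter being predicted). All earlier admissions' tokens form the
   history, sorted oldest→latest; tied timestamps are ordered by token text
   so runs are reproducible. Each history token carries t_c, its age in
   days relative to the latest history event. Labels never seen in the
   history are marked *novel*.
4. **Rare-event filtering.** A non-diagnosis token is kept iff it appears in
   ≥ 1% of sequences **and** in ≥ 50 distinct admissions (both
   configurable; both boundaries inclusive, i.e. only strictly rarer tokens
   are removed). Diagnosis tokens are held to the sequence-fraction rule
   only. Duplicate tokens within an admission are kept — repeated abnormal
   labs carry signal. Filtering is a vocabulary definition and is computed
   on the full corpus; target selection, by contrast, happens inside each
   training fold.

## Embedding

Token vectors are trained with a two-layer network and negative sampling
(noise distribution ∝ unigram^0.75, hierarchical softmax not implemented).
Three modes:

- `skipgram` — center predicts each context token within `window` positions;
- `cbow` — the mean of context vectors predicts the center;
- `dynamic` — skip-gram pair generation with the additional constraint that
  a context token's timestamp lies within `dynamic_horizon_days` (default
  365) of the center token's. The preceding and succeeding sides are
  filtered independently, giving each token its own effective prefix/suffix
  window. The horizon is anchored on the center token by default; anchoring
  on the sequence end (discarding all events older than the horizon
  outright) is available via `horizon_anchor="end"`.

Defaults: `size=100`, `window=10`, `negative_samples=5`, `epochs=10`,
`learning_rate=0.025` with linear decay to ~0 across all updates, and
`min_count=1` — rare tokens were already removed upstream, and a second
frequency filter here would silently shrink the vocabulary.

Numerical/determinism choices: vectors are initialised uniformly in
±0.5/size, output vectors at zero; negatives are pre-drawn per epoch from a
2^20-entry table; the SGD inner loop is a single-threaded numba kernel; the
usual word2vec *reduced-window* subsampling is deliberately omitted so that
(a) the training-pair multiset of dynamic mode with an infinite horizon is
*exactly* plain skip-gram's, and (b) identical corpus + params + seed give
bit-identical vectors. The analytic gradients behind the kernels are exposed
as plain NumPy functions and verified against central differences in the
test suite (max relative error ~1e-8, asserted at 1e-5).

Training sentences are history + that sequence's label tokens (appended at
age 0): diagnosis tokens must acquire vectors near their antecedent events
for any diagnosis-similarity scoring to exist. Inside cross-validation the
corpus is built from training folds only, so test labels never reach the
embedding.

Two-dimensional views (`project_2d`) use PCA for `size>2` models and the
identity for `size=2`.

## Scorers

With temporal factor w_c = e^(−λ·t_c), λ ≥ 0 per day (λ=0 ⇒ all weights 1):

- **PDPS**: cos(Σ_c w_c V[c], V[d]). Invariant to common rescaling of all
  vectors and to history permutation.
- **PDES**: (1/σ) Σ_c w_c S[c,d], with S the vocabulary × targets cosine
  matrix and σ = Σ_c w_c. Negative entries of S are clipped to zero by
  default (dissimilar events are noise, not anti-evidence); clipping the
  final score instead is exposed as a flag. σ defined as the sum of
  temporal factors makes the score a weighted mean — comparable across
  history lengths and invariant to duplicating every event.
- **CF**: project every training sequence the same way; a test patient's
  score for d is the cosine-weighted fraction of (the k most similar)
  training patients whose final admission carried d. Negative cosines are
  floored at zero to keep scores in [0,1]; the default neighborhood is the
  whole training set (k=∞), with k configurable. Returns 0 when all
  weights vanish.
- **LR baseline**: one L2-regularised logistic regression per diagnosis
  (liblinear, C=1 — no tuning claims intended) on features
  x_c = Σ occurrences of c weighted by w_c. Single-class training labels
  yield a constant scorer with a warning.

OOV history tokens are skipped and counted everywhere; all-OOV histories are
an error, not a silent zero.

## Evaluation

Patient-grouped k-fold cross-validation (default 10): all sequences of one
patient share a fold, so overlapping chains of the same patient cannot
straddle train/test. Per fold, the target list (default: 80 most common
label diagnoses, ties lexicographic), the embedding, the similarity matrix,
optional balancing, and decision thresholds are all derived from the
training fold; fitted objects carry a `trained_on_fold_` tag.

- **AUC** is the Mann–Whitney rank statistic (ties counted ½), verified in
  tests against exhaustive positive×negative pair counting and sklearn.
- **Thresholds** maximise F1 over midpoints of sorted unique training
  scores (ties → the lower threshold, favouring recall). Youden's J
  (max TPR−FPR) is available as an alternative objective; the two are
  different statistics and F1 is the default.
- **Modes**: `all` scores every (sequence, target) pair; `novel` scores only
  pairs whose diagnosis is absent from the history — chronic diagnoses
  recur trivially, so the novel task is the informative one. Masked pairs
  are excluded from both threshold selection and test metrics, and counted.
- **Pooling**: test scores are pooled across folds per (diagnosis, method);
  AUC is computed on pooled scores, accuracy/F1 on pooled thresholded
  predictions (per-fold thresholds). Per-fold macro averaging was rejected
  as the default because per-fold positive counts are sparse.
- **Balancing** (off by default): training-fold sequences containing the
  currently most deficient target are duplicated until every target labels
  ≥ 8% of the training multiset. Because labels co-occur, duplicating for
  one target dilutes others; joint feasibility is therefore not guaranteed
  (e.g. >12 disjoint single-label targets at an 8% floor is impossible) and
  the loop raises after a bounded number of rounds instead of spinning.
- **λ sweep**: the embedding does not depend on λ, so the sweep trains once
  per fold and repeats only the scoring across the grid (default
  {0, 0.001, 0.005, 0.01, 0.05, 0.1} per day).

## Synthetic cohorts

The generator emulates the regime the pipeline targets: multiple admissions
per patient (uniform 2–5, stays 1–10 days, start-to-start gaps uniform
30–300 days so chains hold), Poisson background events (mean 5 per
admission) drawn uniformly from the lab+prescription vocabulary, and one
*destined* diagnosis per patient recorded in the final admission. Each
diagnosis owns a disjoint signature set (4 lab/rx events); each signature
event is emitted into the patient's prior history independently with
probability `signature_strength`. A `recency_mix` fraction of diagnoses are
recency-type: their signatures land only in the admission immediately
preceding the final one, while other diagnoses' signatures land in strictly
older admissions when the patient has any — a sharp planted contrast that
makes the decay-sweep ordering (recency-type diagnoses peak at larger λ)
well defined. The ground truth (patient → destined diagnosis, signature
map) is returned as a separate artifact, never mixed into the event table.

With `signature_strength=1` and `background_rate=0` the conditional
frequency of signature events is exactly 1 given the destined diagnosis and
0 otherwise, giving exact oracles for sequence construction and embedding
recovery.

What the generator does **not** emulate: realistic ICD-9 marginals or code
co-occurrence beyond the planted signatures, multi-label final admissions
(one destined diagnosis per patient by default), category-specific context
structure (labs and prescriptions are statistically interchangeable — so
2-d layouts cluster by planted signature, not by event type), demographics,
and measurement noise in timestamps. Passing tests therefore establish that
the pipeline recovers planted co-occurrence and recency structure, not that
it attains any particular performance on real clinical data.

## Problem sizes and test design

The test suite runs the full recovery experiment on a 2000-patient cohort
(12 diagnoses, signature strength 1, background rate 5) under 10-fold CV
with a 32-dimensional embedding — large enough that per-target AUC > 0.9 is
a meaningful bar and a shuffled-label control sits at 0.5, small enough to
run in seconds thanks to the compiled SGD kernel. The acceptance script uses
generator defaults (1000 patients, strength 0.8) for the headline AUCs and
an 800-patient recency-contrast cohort for the decay sweep.

## Known limitations

- CBOW mode averages context vectors and distributes the gradient equally;
  no dynamic-window variant of CBOW is offered (the dynamic mode is defined
  over skip-gram pairs).
- CF is O(train × test) dense cosine; no approximate nearest-neighbor
  index.
- `evaluate` retrains the embedding per fold by design (no leakage); there
  is no warm-start between folds.
- Scores of PDPS/PDES/CF are similarities, not calibrated probabilities;
  thresholds, not calibration, make them decisions.
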