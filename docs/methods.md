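# Methods

`ecbench` evaluates protein → EC-number predictors. An EC number is a
four-level hierarchical identifier (class.subclass.sub-subclass.serial,
e.g. `1.1.1.1`); partial annotations leave trailing levels undefined
(`1.1.-.-`). The framework is model-agnostic: a "model" is nothing but a
TSV of `(protein, EC, score ∈ [0,1])` rows, so any predictor — homology
search, deep network, language model, or ensemble — can be scored on equal
footing. This note records the models and procedures implemented, the
choices made where the design was genuinely open, and what the synthetic
fixtures do and do not demonstrate.

## Task 1 — exact hierarchical prediction

Prediction is multi-label (an enzyme may catalyze several reactions) and
scored at increasing specificity: at level *k* every true and predicted
label is truncated to its first *k* levels and de-duplicated per protein,
then binary confusion counts are accumulated one-vs-rest over the union
label space. Reported aggregates:

- **micro**: precision/recall/F1 from summed tp/fp/fn;
- **macro**: unweighted mean over classes with support > 0;
- **weighted**: mean weighted by true support (tp + fn), so classes that
  appear only in predictions cannot inflate the score.

Conventions that were open choices:

- *Partial labels at deep levels.* A protein whose every true label is
  shallower than the evaluated level is **excluded** from that level
  rather than zero-scored: a `1.1.-.-` annotation carries no level-3/4
  ground truth, and completing it is Task 2's job, not a Task 1 error.
  Predicted labels shallower than the level are likewise dropped.
- *0/0 cells are 0* (the conservative standard convention); every report
  carries a note stating this.
- Batched variance (`evaluate_batched`) shuffles the eligible proteins
  with the run seed, splits them into `n_batches` (default 5) disjoint
  subsets whose sizes differ by at most one (468 proteins → 94/94/94/93/93),
  and reports the mean and sample standard deviation (ddof = 1) of every
  aggregate — the error bars used when comparing models.

## Thresholding

Scores become label sets in one of two ways:

- **regular** — emit the argmax label always, plus any label scoring
  ≥ `t_extra` (default 0.5). Argmax ties break to the lexicographically
  smallest canonical EC string. This fixed rule is our documented
  stand-in for per-model probability rules and is configurable per model.
- **learnt** — per-class thresholds fitted on a *separate validation
  split* (the CLI refuses to fit without one, to avoid leakage). For each
  class with a validation positive, the candidate set is exactly the
  class's observed scores; the candidate maximizing binary F1 wins, ties
  going to the smallest candidate (favours recall). Classes never
  positive in validation are marked `NEVER` and suppressed. Comparison is
  inclusive (≥) so a threshold equal to a positive's score keeps it.
  Scanning observed scores gives the exact optimum at finite cost; a grid
  could only do worse.

At a few hundred validation proteins spread over ~100+ classes, learnt
thresholds frequently mark rare classes `NEVER` and can underperform the
regular rule; the benefit materializes with validation sets large enough
to observe each class several times. The acceptance suite asserts
per-class optimality on the validation data itself, which holds at any
scale.

## Ensembles

- **Majority voting**: each base model casts its top label per protein
  (abstainers cast nothing); all modal labels are emitted with score
  `count/n`. Ties emit every tied label — which is precisely how voting
  ensembles end up suggesting additional EC numbers for multi-function
  enzymes. The denominator is the voting models by default (so sparse
  models do not dilute a confident consensus); `denominator="all"` is
  available.
- **Stacking**: base models' score vectors over a shared, ordered label
  space are concatenated into features (missing score = 0, meaning "not
  predicted"); a one-vs-rest L2 logistic regression (C = 1000, lbfgs) is
  fitted per label with validation positives. The family was an open
  choice; a regularized linear meta-model is deterministic, fast, and
  pluggable behind the `StackerModel` interface if a tree ensemble is
  preferred. Labels unseen in validation are never emitted. Proteins on
  which every base model abstained carry no signal and are scored by the
  validation class priors — the intercept-only limit of the meta-model.

## Task 2 — completion by inter-model agreement

True completions of partial annotations are unknown, so completion is
scored by consensus: an incomplete `(protein, partial EC)` entry *agrees*
when strictly more than half of the compared models return the same top
prediction for that protein (a 2–2 split of four models is **not** a
majority). "Half of the models" counts all models in the comparison,
abstainers included — the literal reading — with a predictors-only
denominator available. Top predictions are not required to extend the
partial prefix (models are scored on consensus, not consistency), but a
per-model prefix-consistency fraction is reported alongside.

The consensus metric is validated on fully annotated proteins: each
model's agreement count is correlated (Pearson, two-sided t-test p-value)
with its weighted F1 from Task 1. A strong positive correlation justifies
using agreement as a confidence proxy where truth is missing; zero
variance in either variable reports `NA` rather than a fabricated r.

## Task 3 — recommendation by reaction similarity

EC numbers denote reactions, so a wrong-but-close prediction is credited
by chemistry: similarity between two ECs is the maximum Tanimoto
similarity between fingerprints of their reaction records (max over
records: an EC matches if *any* reaction it catalyzes matches — the
per-record aggregation was our choice; across EC labels the maximum over
(predicted, true) pairs is taken). Fingerprint backends are pluggable
behind a two-method contract:

- `rdkit_difference` — RDKit's chemical difference fingerprint
  (production backend, optional `chem` extra);
- `token_hash` — SHA-1 hashing of side-tagged molecule tokens into a
  2048-bit space (deterministic, chemistry-free; the default in tests).

Reaction tables are incomplete in practice, so an EC absent from the
table (or partial) is scored through surrogate sampling: up to
`max_samples` (default 10; the sampling count was unspecified upstream)
table ECs sharing its first three defined levels are drawn without
replacement — seeded per EC so results do not depend on evaluation
order — and their similarities to the other EC are averaged, relaxing to
two then one shared levels when no sibling exists. A pair with no
surrogate at any level scores 0 (logged), keeping report denominators
well defined. Model-level summaries:

    coverage  = 100 · #proteins with ≥1 prediction / #proteins
    average   = mean over predicted proteins of best-pair similarity
    weighted  = average · coverage / 100

so a model is not rewarded for predicting only where it is confident.
The identity `weighted = average · coverage/100` is asserted to 1e-12 on
every report. Whether predictions are truncated to levels 1–3 before
scoring is ambiguous for the partial task; both modes are exposed
(`truncate_predictions`), full predictions being the default.

## Curation

Train/test leakage control: drop non-enzymes, de-duplicate identical
sequences within a split (representative = smallest identifier,
annotations merged by union), then cluster the union of train + test at a
percent-identity threshold (30/50/70/90/100 by convention) and remove
every *training* sequence sharing a cluster with a test sequence.
Cluster-membership removal (not pairwise-hit removal) is implemented
deliberately even though transitive clusters can over-remove — it matches
the stated procedure. The test split is never modified, and retained
training size is monotone non-decreasing in the threshold.

The built-in clusterer is greedy and deterministic: sequences by
descending length, each joining the first representative whose global
percent identity (matches / alignment length, via edlib's
Needleman–Wunsch alignment) reaches the threshold, with a k-mer
containment screen (k = 4) to skip hopeless pairs. It exists so the
pipeline runs with no external binary; production-scale clustering should
use a dedicated tool (e.g. MMseqs2), whose two-column cluster TSV the
adapter consumes directly. Structure-availability filtering and metadata
(GO/taxonomy) attachment are pluggable hooks taking local files only.

## Synthetic fixtures

The generator emulates the statistical structure the tasks assume, at the
benchmark's default test conditions: 468 proteins, ~2/3 of annotations
partial, 10% multi-label, a 4×3×3×4 label tree with long-tailed
(geometric, q = 0.55) leaf frequencies, five model profiles spanning
strong/full-coverage to weak/sparse, and family-structured toy reactions
(one base reaction per 3-level family, level-4 siblings mutating 20% of
tokens, 10% of ECs held out to exercise the fallback).

Key mechanisms:

- A profile's per-level accuracies (a₁ ≥ a₂ ≥ a₃ ≥ a₄) are *marginal*
  probabilities of being correct at each level: the erred level is drawn
  with P(first error at k) = aₖ₋₁ − aₖ, and an error at level k predicts
  a sibling sharing the first k−1 levels. Measured level-k micro
  precision therefore converges to aₖ (verified at n = 2000 within
  ±0.03), and metrics degrade with depth the way real models' do.
- Scores are the designed level-4 accuracy for hits and its complement
  for misses, plus uniform ±0.1 clipped noise — informative ranking with
  enough overlap to make threshold learning non-trivial. (An a-priori
  constant score would carry no information and make thresholding
  meaningless.)
- A partial annotation's latent full label is derived deterministically
  from (protein, label, seed), not from each model's stream: a partially
  annotated enzyme still catalyzes one definite reaction, so independent
  perfect models agree on its completion.

What passing on fixtures does *not* show: real sequence homology (toy
sequences are i.i.d. random), real chemistry (toy reactions are token
strings, though valid SMILES), calibration pathologies of real models, or
the taxonomic and database biases of curated annotation sources. The
fixtures validate the *measurement machinery*, not any predictor.

## Numerical and reproducibility notes

- All randomness flows through `numpy.random.default_rng` seeded from the
  run seed (default 17); every CLI manifest echoes the seed, input hashes
  and package version, and outputs are removed on failure.
- Ties break lexicographically on the canonical EC string everywhere
  (argmax, top prediction, vote ordering), making every path
  deterministic.
- Degenerate inputs: empty truth tables and empty validation sets are
  errors; a batch level with no eligible proteins is skipped with a
  warning; zero-variance correlation reports `NA`; two empty fingerprints
  compare as similarity 1 (indistinguishable).
- Efficiency records (wall time, peak RSS via `getrusage`, artifact
  bytes) are attached to every run manifest for deployment planning and
  are never compared across machines.
- Problem sizes in the test suite (200 random metric instances, n = 2000
  parameter recovery, 500-sequence curation families, 1000 similarity
  pairs) were chosen as the smallest sizes at which the checked
  statistics are stable.

## Known limitations

- The built-in clusterer is O(n · clusters) alignments and meant for
  desk-scale data only.
- Transferred/deleted EC numbers are taken at face value; no registry
  validation is attempted.
- Learnt thresholds and stacking need validation sets that observe each
  class repeatedly; below that they conservatively suppress rare classes.
- The surrogate-sampling fallback averages over siblings, which blurs
  genuinely novel chemistry; a pair with no relative in the reaction
  table at any level scores 0 even if the prediction were chemically
  sensible.
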