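# Methods

`hichkit` is a desk-scale, fully seeded implementation of a knowledge-graph-
enhanced decision-support workflow for hypertensive intracerebral hemorrhage
(HICH): extract key clinical entities from EMR-like text with a neural
sequence labeler, normalize them against a medical knowledge graph, map the
normalized patient state to a four-branch treatment plan through a weighted
rule engine with explanation traces, and assess plans with a 100-point
rubric plus standard classification statistics.  Every stage is exercised on
synthetic records generated inside the package, so the whole loop is
reproducible without any clinical data.

## The synthetic EMR generator

`emr_synth` samples a structured `PatientProfile` and renders it into an
annotated English note.  The profile fields and units are: age (years,
10-80), sex, Glasgow Coma Score (3-15), systolic/diastolic pressure (mmHg),
pupil and airway state, SpO2 (%), hematoma location (basal ganglia,
thalamus, lobar, cerebellar, brainstem), hematoma volume (mL, one decimal),
midline shift (mm), ventricular compression and intraventricular extension
flags, and history/suspicion flag sets.

Default prevalences are chosen so that the corpus exercises both plan
branches rather than to match epidemiology: volume is log-normal (median
~18 mL), midline shift is zero-inflated, one quarter of cases are comatose
(GCS <= 8), and locations are weighted toward the basal ganglia with 12%
cerebellar and 8% brainstem.  Under the default ruleset this yields roughly
30% surgical cases (the acceptance script reports the realized rate).  All
sampling distributions are data in the prevalence config; a degenerate
config can pin any field.

Rendering uses a small template bank with one tagged span per verbalized
finding, over a 12-type BIO alphabet covering clinical/CT manifestations
(chief complaint, vital signs, GCS, pupils, airway, location, nature,
history and suspicion items) and quantitative hematoma parameters (volume,
midline shift, ventricular involvement).  The tag alphabet is configuration,
not a constant.  Two kinds of corruption can be injected, both invertible by
design: misspellings are restricted to edit-distance-1 variants that the
spell corrector (nearest lexicon entry at edit distance 1; ties broken by
lexicon frequency, then lexicographically) resolves uniquely back to the
original, and abbreviation contraction replaces a registered multi-token
phrase ("blood pressure" -> "BP") with its short form inside a single tag
region.  Corruption never moves tag boundaries, so `preprocess` applied to a
corrupted note reproduces the clean token stream exactly — a property the
suite tests.

What the generator does *not* emulate: free prose variability, negation
beyond the fixed patterns, contradictory findings, multiple hematomas,
Chinese text, OCR noise, or report-structure variation across hospitals.
Green tests therefore demonstrate that the pipeline is internally coherent
and that extraction errors degrade plans gracefully — not that the system
performs at any particular level on real records.

Age and sex are not part of the entity inventory; they travel as structured
demographics beside each document (comment headers in the CoNLL files) and
enter the patient state with source "structured input".

## The sequence labeler

`ner` implements seven composable variants, all terminated by a linear-chain
CRF: IDCNN-CRF, BiLSTM-CRF, BiLSTM-IDCNN-CRF, and the same plus a small
transformer encoder pretrained by masked-token prediction (BERT-CRF,
BERT-IDCNN-CRF, BERT-BiLSTM-CRF, BERT-IDCNN-BiLSTM-CRF).  The encoder is a
2-layer, 2-head transformer of width 48 trained from scratch on the
synthetic corpus — a deliberately small, pretrainable stand-in sized for a
single CPU, not a full-scale pretrained language model.

The functional cores are exposed as plain-numpy reference functions and
verified against independent oracles:

- **Attention** is standard scaled dot-product attention
  softmax(QK^T / sqrt(d_k)) V; rows of the weight matrix are checked to sum
  to one and outputs to be convex combinations of V's rows.
- **Dilated receptive field** is computed as the exact input-support count
  of the stacked kernels (kernel 3 with dilations 1, 2, 4 gives 3, 7, 15 =
  2^(i+2)-1) and is tested against brute-force support enumeration,
  including gappy schedules where the support count is smaller than the
  span.
- **LSTM cell** follows the conventional gate equations with logistic gates
  and tanh state/output nonlinearities (checked by pencil arithmetic and
  saturation limits).
- **CRF**: the partition function uses the log-space forward recursion;
  log-likelihood is path score minus log-partition; decoding is Viterbi with
  first-argmax backpointers, which realizes the documented tie-break (lowest
  tag index at the latest differing position).  All three are tested against
  full enumeration over tag sequences.  Boundary terms use learned start and
  stop vectors — a convention choice, documented as such.

Training runs on an in-repo reverse-mode autodiff engine over float64 numpy
arrays (`autodiff.py`: broadcasting elementwise ops, matmul, log-sum-exp,
gather, slicing, concat, Adam).  Everything is seeded; repeated runs are
bit-identical, which the determinism tests rely on.  Default training
hyperparameters (Adam lr 0.01, batch 32, 8-10 epochs, hidden width 48) were
sized so the full variant trains on a 500-document corpus in about a minute
on one CPU; the best dev-F1 checkpoint is retained and per-epoch precision/
recall traces are recorded.  No claim is made about matching any particular
convergence point beyond reaching a plateau.

Entity-level precision/recall/F1 use exact (span, type) matching on the
0-100 scale; zero denominators are defined as 0 with a warning (the CoNLL
convention).  Exact matching is the strictest choice; no partial credit.

## The knowledge graph

`hkg` is a set-semantics triple store with subject/predicate/object indexes.
Triples carry one of three knowledge tiers — general (textbook facts,
categories, synonyms), subdomain (guideline/consensus links), and
subdomain-specific (the scoring rules, each citing a source string) — plus a
free-text citation.  The shipped seed graph (~150 triples) encodes the plan
taxonomy, entity synonyms and the rule provenance; it is data and editable
without code changes.  Its scope is a reconstruction from the domain's
public conventions, not a transcription of any proprietary schema.

Queries are conjunctive basic graph patterns only (variables `?x`, shared
variables join); results are returned in sorted order and are property-
tested against a nested linear-scan oracle.  Full SPARQL, OPTIONAL/FILTER
and OWL reasoning are out of scope: the decision engine only needs
retrieval.

Mention alignment tries the synonym table first (no similarity computation
on exact hits), then falls back to argmax similarity over same-category
entities with a threshold (default 0.5) and lexicographic tie-break.  The
default similarity is the character-bigram Dice coefficient; any symmetric
similarity with self-similarity 1 can be passed in.  Persistence is a
5-column TSV natively; N-Triples import/export carries s/p/o only (tier and
source have no slot without reification).

## Semantic representation

`semantics` trains skip-gram word vectors with negative sampling (window 2,
5 negatives, unigram^0.75 noise distribution, frequency floor 1 — suitable
for desk-scale corpora), deterministically under a seed.  A sentence vector
is the weighted mean of in-vocabulary token vectors; the default weight is
the smoothed inverse frequency a/(a + p(token)) with a = 1e-3, with a
uniform-weight option — the weighting term is config because the exact
intended form is underdetermined, and both options are shipped.
Out-of-vocabulary tokens are skipped, not zero-imputed, and do not count
toward the token count m.  Cosine similarity rejects zero vectors rather
than silently returning 0.

## The decision engine

`hws` normalizes mentions into a `PatientState` whose every field carries a
value, a source span (or "structured input"), a canonical knowledge-graph
entity and a confidence flag.  Numeric values are parsed with their units
(mL, mm, mmHg, %); out-of-range values are recorded as missing with a
warning, never a crash.  Conflicting duplicate mentions resolve to the later
mention in document order (rationale: later text, typically the CT report,
supersedes triage notes) and the conflict is logged.

Rules are data (`data/ruleset_r0.yaml`): an antecedent conjunction of field
predicates, a weight, consequent plan items, a tier, a source citation and a
basis template.  An item activates when the summed weight of its fired rules
reaches the item's activation threshold (default 1.0).  With the default
unit weights the system is crisp; the ventilator item demonstrates genuinely
cumulative weighting (coma 0.6 + hypoxemia 0.6).  Whether such weights
should be continuous or crisp is an open design question; point semantics
with a per-item threshold keeps the default auditable while allowing either.

R0's thresholds follow the guideline tradition: supratentorial volume >= 30
mL, cerebellar >= 10 mL or ventricular compression, midline shift >= 5 mm,
GCS <= 8 for airway protection / ICP lowering / stress-ulcer prophylaxis,
SBP >= 180 mmHg for antihypertensives, SpO2 <= 91% contributing to
respirator support.  Brainstem hemorrhage defaults to conservative
management via a zero-weight rule that still fires, so the "not indicated"
explanation cites the location rule.  R0 is explicitly a reconstruction:
tests trace R0's own behavior and claim no fidelity to any unpublished
weight table.

Missing-data semantics are directional: positive predicates are false on a
missing field, negated predicates are true, so absence of evidence can
escalate diagnostics (safe direction) but never fabricates a positive
finding.  An all-missing state yields the minimal safe plan (repeat head CT
+ vital-sign monitoring).  Plan invariants (intubation implies airway
clearance; CPR implies vital-sign monitoring) are enforced by an idempotent
closure pass.  Property tests check determinism (hash-identical plans),
explanation completeness with antecedent replay, monotonicity of the
surgical indication in volume and midline shift, and that dropping any
single field never removes vital-sign monitoring.

The gold plans emitted with synthetic corpora come from the same R0 ruleset
the pipeline applies.  This circularity is deliberate and load-bearing: the
closed-loop benchmark measures extraction and plumbing fidelity, not
clinical correctness.

## Evaluation

`evaluation` provides the closed forms: sensitivity/specificity/accuracy/
PPV/NPV from confusion counts (zero denominators flagged `None`, not 0);
ROC-AUC via the Mann-Whitney rank formulation with ties counted one half
(cross-checked against scikit-learn in the tests); Cohen kappa from a square
contingency table; and case-weighted pooled accuracy.

The rubric splits 100 points into diagnostic 15 and therapeutic 85
(surgical 40 + rescue 35 + drug 10).  Surgical is all-or-nothing; the other
categories split their points equally across their decisive items and award
a share whenever prediction and gold agree on an item's presence *or*
absence.  Equal shares are a choice — only the category maxima and bins are
fixed externally — and the shares live in `RubricConfig`.  Score
distributions bin at >80% / 60-80% / <60% of the maximum.  For ROC analysis
of binary plan decisions the rule engine's summed fired weight is the
ranking score.  Reported values round half-up to two decimals; internal
arithmetic keeps full precision.

## Pipeline and problem sizes

`pipeline.run_pipeline` executes the stages per document with per-document
error isolation and writes a manifest (config snapshot, SHA-256 checksums,
timings); identical configs produce byte-identical plan JSONs.  The
benchmark generates 500 documents (70/10/20 train/dev/test split, 2%
misspelling and 10% abbreviation rates), pretrains the encoder for 3 epochs
and trains for 8; the closed-loop check uses 1000 profiles.  These sizes
were chosen so the full suite and the acceptance script each run in minutes
on a single CPU while keeping the NER task non-trivial (held-out numbers are
unseen vocabulary; misspellings hit keyword tokens).

## Known limitations

- The synthetic corpus is far easier than real clinical text; NER scores
  here are upper bounds of plumbing quality, not clinical performance.
- R0 and the seed graph are reconstructions; clinical deployment would
  require replacing both with validated content.
- The rule language is conjunctive only (disjunction is expressed as
  multiple rules); no temporal reasoning, dosing, surgical-approach choice
  or prognosis.
- Confidence intervals for accuracies are not computed; the construction
  used in the tables this design mirrors is unstated, so none is guessed.
- N-Triples interchange drops tier/source provenance (use the TSV dialect
  for full fidelity).
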