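# Methods

This note documents the models, rules, and numerical choices behind
`stigma_screen`, and what its synthetic-data experiments do and do not
show about real clinical corpora.

## Task and data model

The unit of analysis is the clinical note: an opaque identifier, free
text, optional encounter/patient/caregiver identifiers, and an optional
gold category from {STIGMATIZING, CONTEXTUAL_NONSTIGMA, CLEAN}.  The
binary detection label is 1 exactly for STIGMATIZING; contextually
non-stigmatizing notes (a potentially stigmatizing term used
non-stigmatically) count as negatives, which is what makes the task
harder than keyword search.  Text is normalized to NFC on read and
otherwise untouched: quotation detection needs the original curly/straight
quote characters, so all further normalization happens in the matching
layer.

## Keyword baseline

Tokens are maximal non-whitespace runs, lowercased, with leading and
trailing Unicode punctuation stripped; internal hyphens and slashes are
kept (an optional flag additionally splits on them so "drug-seeking"
can match the bigram "drug seeking").  Matching is leftmost-longest
n-gram lookup against the lexicon, with n up to the longest lexicon
entry: at a given position the longest matching entry wins and the scan
resumes after it, so "abuse" is never double-counted inside "alcohol
abuse".  Plain single-token comparison cannot represent the multi-word
terms that dominate real term-frequency tables ("etoh abuse", "alcohol
abuse"), which is why n-gram matching is the baseline's definition here.
The baseline classifies a note positive iff any match exists — no
context logic of any kind, by design.

## Contextual rule annotator

The annotator makes explicit the semi-manual labeling criteria named in
the guidance this task follows — quotation marks, speaker attribution,
and linguistic context — and routes everything else to a human:

1. **Quotation spans.**  Straight double quotes toggle; curly double and
   curly single quotes pair an opener with the nearest same-style closer.
   A lone right single quote is an apostrophe, not an unpaired quote.
   Nested pairs keep the innermost span so spans are non-overlapping.
   Any other unpaired quote character sets a dangling flag.
2. **Attribution.**  A quote span is patient-attributed iff a cue phrase
   ("patient states", "he feels", ...) ends within K normalized tokens
   before the span start.  Default K = 10, configurable; the window is
   deliberately small to avoid crediting cues from earlier sentences.
   The cue list is a documented default and user-replaceable — the
   phenomenon is established, the exact inventory is not.
3. **Benign senses.**  A lexicon term may carry literal adjacent-context
   patterns (`next:cough` for "junky"); a match whose neighbor token
   satisfies a pattern is benign.

Decision rule: no match → CLEAN; every match attributed-quoted or benign
→ CONTEXTUAL_NONSTIGMA; otherwise STIGMATIZING.  A match inside an
*unattributed* quote, or any match in a note with dangling quotes, sets
`needs_review`: the note still receives the category the rule cascade
produces (an uncovered match falls through to provider voice), but it is
queued rather than silently trusted.  Whether unattributed quoted terms
are stigmatizing is genuinely undecidable from the published criteria,
so the package surfaces them instead of deciding.

## Chunking and prompting

Long notes are segmented into windows of N tokens with overlap M
(step N−M); the last chunk is truncated, never padded, because padding
would change the content a detector sees.  A note is positive iff any
chunk is.  The token unit is pluggable (default: whitespace tokens) so a
model tokenizer's counting can be injected without changing the
arithmetic.  The selected operating point carried through the examples
and scripts is N = 1000, M = 100; the sweepable grid is sizes
{None, 200, 1000} × overlaps {None, 20, 100} restricted to 0 < M < N,
i.e. five chunk options.

Prompts serialize deterministically as system / numbered-context / note /
question blocks; the serialization is versioned and frozen in a
golden-file test because downstream labels depend on exact prompt bytes.
Zero-shot bundles carry no context; in-context bundles carry the full
configured guideline table (14-entry substance-use-specific table or
30-entry systematic-review table); retrieval bundles carry the top-n
entries by cosine or dot-product similarity between the note embedding
and entry embeddings (ties broken by entry id, grid n ∈ {1, 3, 5}).
Responses are parsed by a case-insensitive scan for the first standalone
"yes"/"no" token — first occurrence wins on ambiguous responses, and a
response with neither is a ParseFailure value (never an exception) so
unreadable outputs can be tallied; during classification a ParseFailure
chunk is conservatively scored 0.

Backends implement two functions: `complete(bundle) -> str` and
`embed(text) -> vector`.  The shipped backend is a deterministic stub
whose classification rule is lexicon matching on the note block and
whose embeddings are seeded content hashes; it exists so that every
pipeline path — chunking, retrieval, parsing, aggregation, error
analysis — executes end-to-end offline and reproducibly.  Embedding
pooling for real model backends is a backend parameter (mean pooling as
the default convention); no model weights ship with the package.

## Dataset construction

Grouping for leakage control is the connected-components closure of
"shares a non-empty encounter, patient, or caregiver identifier" — the
strictest reading, chosen because leakage prevention is the purpose;
empty identifiers create no links.  Splitting shuffles groups with a
seed and greedily assigns each to the most under-filled split within its
stratum (the group's majority category), targets 70/15/15.  Whole-group
assignment means fractions are approximate; a group larger than a
split's entire target is still assigned intact, with a warning — leakage
safety dominates fraction fidelity.  The no-group-spans-splits invariant
is asserted on every build, not just in tests.

Balanced down-sampling keeps every minority-class note and an
equal-sized seeded sample of the majority class.  Reported percentages
(prevalence, term note-frequencies) are rounded half-up at two decimals,
the printed precision of the field's tables.  The instruction-tuning
exporter writes alpaca-style records (the binary question as
instruction, note text as input, "yes"/"no" as output) plus a companion
training-config file (LoRA rank 8, alpha 8, all target modules, 3
epochs, lr 1e-4 with cosine schedule, effective batch 64); training
itself is out of scope.

## Evaluation

Macro F1 is the unweighted mean of positive-class and negative-class F1,
with zero-denominator F1 defined as 0.  Confidence intervals are
percentile bootstrap (2.5/97.5) over B note-level resamples with
replacement, B = 1000 by default; percentile rather than
normal-approximation because it is distribution-free and standard for
F1, and the choice is recorded in the report metadata.  The resampling
unit is the note — metrics are note-level, so resampling chunks or
encounters would answer a different question.  Approach comparison is a
two-sample Student t-test (equal variance) on the two bootstrap score
vectors, Welch's variant available by flag.  The challenging subset is
defined purely by the keyword detector: every note containing at least
one lexicon term, whatever its gold label — the stratum where context,
not keywords, carries the signal.

## Error analysis

For each false positive the backend is asked to explain its original
positive call and restate yes/no, with the same context entries the
classifier saw.  The machine decides only what parsing can decide:
UNREADABLE (no standalone yes/no, or empty/failed response) and
DECISION_SWITCH (restated answer is no).  The two remaining categories —
TOO_SENSITIVE_OR_UNRELATED and VALID — are expert judgments by
definition; they live in an editable CSV sidecar merged at tally time,
so human review is replayable and the automated pipeline never
impersonates the adjudicator.  Row totals always equal the
false-positive count fed in.

## Synthetic corpus generator

The generator plants exactly the structure the rules read: stigmatizing
notes carry 1–2 provider-voice term sentences (no quotes, no cues, no
benign neighbors); contextual notes carry quoted terms immediately
preceded by a cue phrase (probability `quote_prob`) or benign-sense
pairs like "junky cough" (`benign_prob`, renormalized); clean notes are
filler only.  Filler sentences are clinical-register templates validated
at generation time to contain no lexicon term words, no cue words, and
no quote characters, so cross-sentence token adjacency cannot create
accidental matches or attributions — clean notes provably never match.
An `adversarial_prob` knob plants quoted terms *without* attribution;
these are exactly the rule-uncovered cases, and the tests assert they
surface in the review queue rather than being silently labeled.

Defaults are chosen to mirror the corpus regime the task is studied in:
category mix (0.50, 0.05, 0.45) — about half stigmatizing, a small
contextual stratum among term-containing notes, clean notes filling the
negative class; note lengths normal(1250, 400) tokens, matching the
average progress-note length of the emulated corpora; group sizes
1/2/3 with probabilities 0.7/0.2/0.1.  Structural tests whose measured
quantity is length-invariant (grouping, splitting, count-forced
prevalence) use shorter notes (means 25–120 tokens) as the package's own
problem-size choice; recovery and detection experiments use 120–300
token means at 200–1000 notes.  The low-prevalence generator forces the
positive count to round(prevalence·n) exactly rather than sampling it,
so regimes like 0.72% are reproduced to the printed decimal.

What passing these tests shows: the rule system is a faithful, total,
deterministic implementation of the three published context cues, and
the pipeline's plumbing (chunking, parsing, splitting, resampling) is
correct.  What it does not show: performance on real clinical text,
whose stigmatizing language is lexically and syntactically far more
varied than the planted templates, whose quotes are messier, and whose
annotation required expert judgment precisely where these rules enqueue
for review.  The synthetic 100% rule-recovery figure is a soundness
check, not a clinical performance claim.

## Numerical and degenerate-input choices

* Percent rounding: decimal half-up at 2 d.p. everywhere a percentage is
  printed.
* Retrieval ties: descending score, then ascending entry id; cosine of a
  zero-norm vector is a validation error rather than 0.
* Aggregation of zero chunks, empty lexicons, zero-total prevalence,
  balancing with an empty minority class, and unaligned
  prediction/gold id sets are all validation errors, not silent results.
* All randomness (generation, shuffling, resampling, stub embeddings)
  flows through seeded `numpy` generators; identical seeds reproduce
  corpora, predictions, and reports byte-for-byte.

## Known limitations

* The shipped lexicon, cue list, and guideline tables are documented
  placeholders; real deployments must supply the authoritative lists.
* Attribution looks only backwards within K tokens; forward attribution
  ("...he says") and cross-sentence attribution are not modeled.
* Benign-sense patterns are literal neighbor-word checks, not sense
  disambiguation.
* No negation handling, stemming, or typo tolerance anywhere in the
  matching layer (the baseline is defined context-blind and
  surface-form-exact).
* Only the deterministic stub backend ships; hosted or local chat-model
  backends are user-implemented against the two-function contract.
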