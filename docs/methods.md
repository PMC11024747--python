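# Methods

This note documents the models and procedures implemented in
`rehab-extract`, the parameters that matter, the synthetic data the
test suite runs on, and the design decisions taken where the design was
genuinely open.

## The ontology and its label universe

The ontology is a two-level schema: categories, then concepts with
surface-form lexicons. The enumerated and binary categories contribute
exactly 101 binary-classifiable concepts:

| category | concepts |
|---|---|
| exercise description (status) | 3 |
| type of motion | 4 |
| side of body | 6 |
| location on body | 21 |
| plane of motion | 41 |
| exercise purpose | 14 |
| exercise type | 10 |
| body position | 2 |

Duration, sets and reps are integer categories with no enumerated
concepts; they are handled by the numeric parser, not by classifiers.
Nine *scoring dimensions* feed the section enrichment score: motion,
side, location, plane, duration, sets-and-reps (the sets and reps
categories share one dimension via a common `scoring_key`), purpose,
exercise type and body position. The status dimension does not score.

Negation/hypothetical markers ("held", "deferred", "not performed",
"HEP") are modelled as lexicons on the three status concepts rather
than as separate label dimensions; this is what keeps the binary
universe at 101.

Two deliberate lexicon ambiguities exist. The fused laterality tokens
(`LUE`, `LLE`, `RUE`, `RLE`) map to a side *and* a location
simultaneously; both mentions share one span. A bare `ROM` (or the
spelled-out "range of motion") names both the motion-type concept and
the range-of-motion exercise type — the two concepts intentionally
share their lexicon, and both labels are always assigned together.
`AROM`/`AAROM`/`PROM` map only to their specific motion concepts.

## Preprocessing and enrichment scoring

Therapy visits are identified by the literal substring `THERAPY` in the
filename; matching is case-sensitive by default (note-type strings are
upper case in practice) with a CLI flag to relax it. The
therapeutic-procedures section is taken as the text between a
`THERAP(Y|EUTIC)`-style header and the next all-caps header line (or
end of note); real note layouts vary, so the pattern is replaceable
everywhere one is accepted, and an absent header simply yields no
section. Offsets are 0-based half-open character positions on
LF-normalised text.

The enrichment score of a section is the number of scoring dimensions
(0–9) with at least one keyword hit. Matching is whole-token — a
pattern never fires inside a longer alphanumeric run, so "extension"
does not fire inside "tension" — and case-insensitive except for
abbreviations that collide with ordinary words in lower case (`ROM`,
`HEP`, `ER`, `IR`, `WB`, ...), which match upper case only. Sampling for
annotation takes every maximum-scoring section plus uniformly sampled
score-8 sections up to the enriched quota (300 by default), and a
uniform random sample (300) of sections at least 200 characters long,
disjoint from the enriched set. Whether the length floor should also
apply to the enriched set is unspecified in the source design; here it
applies only to the random sample. Score-8 sampling is uniform.

## Rule-based extraction

**Segmentation.** Exercise items are recognised by list markers: `N:`,
`N.` or `N)` at line starts, plus inline `N:` after whitespace (notes
are frequently run-on single lines). An item spans from its marker to
the next marker; printed numbers are kept verbatim, including gaps.
Items with no content after the marker are dropped — an empty numbered
slot is not a procedure.

**Tagging.** All lexicon patterns plus the refinement rules are run
over the item; overlapping candidates are resolved longest-first (ties
by leftmost position), and candidates with *identical* spans are all
kept. Hence "upper extremity strength" tags only the exercise-type
concept, suppressing the nested location and purpose words, while `LUE`
yields its side and location mentions on one span. De-identification
placeholders (`[PERSONALNAME]`, `[ADDRESS]`) are masked before matching
and can never fire a rule.

**Context rules.** Single-letter abbreviations are interpretable only
in context. `L`/`R` count as a side exactly when immediately followed
by a limb or location word ("L knee"), so machine settings like the
`L5` resistance level never read as "left". A bare `A` (occasionally
shorthand for anterior) is matched by no rule: locally it is noise, and
tagging it would trade precision for little recall. A bare `SL`
likewise matches nothing — side-lying and single-leg cannot be told
apart locally and neither is itself an ontology concept — while the
lexicalised `SLR` (straight-leg raise) tags lower-extremity strength.

**Status.** Not-performed markers outrank HEP markers outrank the
in-office default: "deferred to HEP" describes an exercise that did not
happen in the office. The mention set keeps both description labels in
that case; only the status field takes the precedence decision.

**Numeric parsing.** Findings are extracted in a fixed pass order, each
consuming its span so later passes cannot re-read the same digits:
minute/second quantities and apostrophe/feet quantities first, then
`AxB` (sets=A, reps=B), then explicit `N rep(s)` / `N set(s)`, then
`x N` and `N x` rep counts. Durations are always reported in seconds
(`unit_normalized` marks minute conversion). A number followed by an
apostrophe is a duration in minutes unless a locomotion verb
immediately precedes it ("walking: 25' x 2"), in which case it is a
distance in feet; distances are recognised but excluded from the label
schema by default, since dosage-by-distance is out of scope. When two
findings of the same kind conflict, the first in span order wins and
the collision is logged.

**Projection.** Sequence-level labels are the distinct mention concepts
plus the status concept; the operation is idempotent and insensitive to
mention order.

## Per-concept classifiers

Tokens are maximal alphanumeric runs, lower-cased, so dosage compounds
("2x10") survive as single tokens; features are raw counts from a
vocabulary fitted on training texts only. No TF-IDF and no n-grams by
default. Four families, one independent model per (family, concept):

- logistic regression — balanced class weights, `tol = 1e-4`. The
  tolerance encodes a stated learning rate of 1e-4 that has no direct
  logistic-regression counterpart here; it is configurable.
- SVM — polynomial kernel, degree 2, balanced class weights.
- AdaBoost — 100 estimators.
- gradient boosting — 50 estimators.

All other hyperparameters are the scikit-learn defaults. The 100/50
split between AdaBoost and gradient boosting follows the order in which
the families are named in the source design; both are configurable. A
`random_state` (default 0) is passed to the ensemble methods so that
training is reproducible. Concepts whose training labels are
single-class cannot be fitted; the bank records them as skipped and
predicts the constant observed class for them.

## Prompt harness

Each prompt opens with a System turn — "You are an assistant assigned
to determine if a given text segment from a medical record contains
mentions of *{concept name}*. You must answer yes or no." — and ends
with the unanswered User query. Few-shot prompts insert exactly four
complete example exchanges (positive/negative/positive/negative with
Model answers "Yes."/"No.") between the two, for 10 turns total;
zero-shot prompts have 2. Prompt construction is pure: the concept
name, mode, examples and query fully determine the byte sequence.

Candidates for prompting are the 101 binary concepts minus the three
status concepts (98); concepts with fewer than 2 positive training
sequences are then dropped because a few-shot prompt cannot be
assembled. Example selection is seed-deterministic. Replies are parsed
by their leading word; anything other than yes/no is recorded as
indeterminate and scored as a negative prediction (conservative,
favouring precision) with the raw text kept for audit. The backend is
an interface: a deterministic keyword mock for offline use and a
generic chat-completion HTTP adapter for live runs; live calls are
never made by the test suite. Backend failures are retried and then
recorded per item without aborting the run.

## Synthetic data: what it emulates and what it does not

The generator emits numbered exercise items from a slot grammar —
[position] [motion] [side] [location(s)] [plane(s)] [filler] [type]
[purpose] [numerics] [status marker] — with surfaces drawn from the
ontology lexicon and a stylebook modelled on deidentified note
excerpts: run-on single-line sections, `flx/ext`-style plane pairs,
`B/L` after the rep count, occasional skipped list numbers, filler
tokens ("foam", "mat", "green TB"), deidentification placeholders, and
exercise types written as exercise keywords ("Lunges", "Dips",
"bridging") rather than descriptive category names. Gold labels and
mention spans are recorded *at emission time*; gold is correct by
construction and never produced by the extractor under test, and a
soundness validator checks every label has a witnessing span (the
in-office status is exempt — like human annotation, it is the default
reading of an unmarked item). Items that would come out empty force a
location slot instead.

Default slot probabilities and concept weights are loosely matched to
the prevalence pattern of annotated therapy corpora — laterality and
extremities common, most planes individually rare, roughly 15% home
exercise program and 8% not-performed items, 3–12 items per section —
and are documented in `GeneratorConfig`. With these defaults, 500
sequences cover every concept at least twice, which is what makes
few-shot example selection and per-concept evaluation possible.

The ambiguity tier (off by default; 10% of sequences when on) injects
the documented hard cases with known intended readings: single-letter
`L`/`R` sides before a limb word (resolvable by the context rule),
apostrophe distances after locomotion verbs (resolvable), and a bare
`A` for anterior, which the rules deliberately never match — those
emissions are intentional false negatives and are what keeps the
ambiguous-tier macro-F1 below 1. An optional typo channel perturbs
filler tokens only, so gold witnesses survive.

What the generator does **not** emulate: real vocabulary breadth and
spelling errors inside label-bearing words, section-extraction noise
(truncated or cross-contaminated sections), inter-annotator
disagreement, and genuinely undecidable abbreviations. A perfect
round-trip on unambiguous synthetic text therefore demonstrates the
internal consistency of lexicon, grammar and extractor — not
performance on hospital data, which is known to be substantially
harder.

## Evaluation conventions

Precision (or recall) is 0 when its denominator is 0; F1 is 0 when
P+R = 0. Concepts absent from both gold and predictions are dropped;
macro averages run over concepts with gold support ≥ 10 by default
(sparse concepts are reported but not averaged), configurable down to 1
for small experiments. Span-level scoring reports both exact and
any-overlap matching (greedy one-to-one within sequence and concept),
since either convention is defensible for NER. Numeric scoring matches
kind and exact integer value per sequence (multiset semantics, values
already unit-normalised); no tolerance is applied. Fleiss κ is computed
through `statsmodels`; a table whose ratings all fall in one category
raises an explicit degenerate-agreement error rather than returning a
number. The stratified split sends 125 sections per stratum to
training (a 5:1 train:test ratio at the design's 150-per-stratum
size); smaller strata fall back to the same proportion with a warning.

## Problem sizes used by the test suite

The suite runs entirely on generated data at desk scale: round-trip
checks on ~550 sequences (80 sections), classifier-recovery on a
1,000-sequence training set with a 300-sequence held-out split scoring
the concepts with ≥ 100 positive training examples, agreement
null-distribution checks on 10,000 simulated items, and 50 random
small corpora against a brute-force confusion-matrix oracle. All
randomness is seeded; reruns are byte-identical.

## Known limitations

- The lexicon is a curated transcription plus note-style
  abbreviations; real clinics use wider and drifting vocabularies, and
  the rule file is the intended surface for such refinement.
- Technique names (e.g. PNF patterns like "D1/D2") are tagged only as
  diagonal-plane surfaces, not mapped to their implied motion types.
- Sets and reps are only recognised in the common dosage shapes; prose
  dosages ("three sets of ten") are not parsed.
- Distances are detected but not part of the label schema.
- The keyword mock backend exists to test the harness plumbing, not to
  approximate the behaviour of any live language model.
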