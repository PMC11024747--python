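# rehab-extract

Extraction of physical-rehabilitation exercise information from the
free-text therapy notes of electronic health records.

Physical therapy procedures — what exercise was done, on which side and
body part, in which anatomical plane, for how many sets/reps or how
long, and whether it was performed in the clinic, prescribed for home,
or deferred — are documented as terse numbered lists inside clinical
notes ("1: AROM right elbow flx/ext HEP", "6: Dips 4" stair: 2x10
B/L"). Structured access to this information is a prerequisite for
precision-rehabilitation research, e.g. modelling which exercise
programs work for which stroke patients. `rehab-extract` provides the
full toolchain for turning such notes into labelled data:

- **Clinical ontology** — 12 categories of exercise documentation
  (type of motion, side, body location, plane of motion, duration,
  sets, reps, purpose, exercise type, body position, exercise status),
  whose enumerated/binary members form a 101-concept label universe.
  Each concept carries a lexicon of surface forms, including the
  clinical abbreviations notes actually use (AROM, B/L, flx, HEP, LUE).
- **Preprocessing** — therapy-note filtering by filename, regex
  extraction of the therapeutic-procedures section, and a 0–9
  *enrichment score* (number of scoring category dimensions with at
  least one keyword hit) used to oversample information-dense sections.
- **Rule-based extractor** — segments a section into its numbered
  exercise items, tags concept mentions with character spans
  (leftmost-longest, non-overlapping; context rules for single-letter
  abbreviations), resolves exercise status (in-office / home exercise
  program / not performed), and parses dosage numerics: `AxB` → sets
  and reps, `x N`/`N x` → reps, `N'`/`N min` → duration with minutes
  converted to seconds, with apostrophe quantities read as distances
  after locomotion verbs.
- **Per-concept classifiers** — one binary model per (family, concept)
  over an uncased bag-of-words space: logistic regression and degree-2
  polynomial SVM with balanced class weights, AdaBoost (100
  estimators), gradient boosting (50 estimators).
- **Prompt harness** — auto-generated per-concept yes/no prompts for a
  chat-model backend, zero-shot or few-shot (2 positive + 2 negative
  worked examples), with a deterministic offline mock.
- **Synthetic note generator** — grammar-based sections in the style of
  real therapy notes with by-construction gold labels and mention
  spans; this stands in for protected hospital corpora and makes every
  other module testable end to end.
- **Evaluation** — per-concept precision/recall/F1 at sequence, span
  (exact and overlap) and numeric levels with F1 = 2PR/(P+R); Fleiss κ
  for interannotator agreement; the stratified 125-per-stratum
  train/test split.

## Worked example

```python
from rehab_extract import load_ontology, extract, RuleSet, Section

ontology = load_ontology()
rules = RuleSet.from_ontology(ontology)

text = ("1: AROM right elbow flx/ext HEP "
        "2: Dips 4\" stair: 2x10 B/L "
        "3: tandem stance on foam x 1'")
section = Section(source_filename="demo", text=text,
                  char_span=(0, len(text)), section_id="demo")

for seq, labels, mentions in extract(section, ontology, rules):
    print(f"item {seq.index_label}: status={labels.status!r}")
    print(f"  concepts: {sorted(labels.binary)}")
    print(f"  sets={labels.sets} reps={labels.reps} "
          f"duration_seconds={labels.duration_seconds}")
```

prints

```
item 1: status='home exercise program'
  concepts: ['desc_hep', 'loc_elbow', 'motion_arom', 'plane_extension', 'plane_flexion', 'side_right']
  sets=None reps=None duration_seconds=None
item 2: status='performed in-office'
  concepts: ['desc_in_office', 'side_bilateral', 'type_le_strength']
  sets=2 reps=10 duration_seconds=None
item 3: status='performed in-office'
  concepts: ['desc_in_office', 'type_balance']
  sets=None reps=None duration_seconds=60
```

Item 1 is an active-range-of-motion exercise of the right elbow in the
flexion and extension planes, prescribed as a home exercise program;
item 2 is a bilateral lower-extremity strength exercise dosed at 2 sets
of 10; item 3 is a balance exercise held for 1 minute (durations are
normalised to seconds).

The same pipeline is available from the shell:

```bash
rehab-extract simulate --n 300 --seed 7 --out gold.jsonl
rehab-extract run --sections gold.jsonl --out pred.jsonl
rehab-extract eval --pred pred.jsonl --gold gold.jsonl --out report/
rehab-extract pipeline --n 100 --seed 7 --workdir run/   # all of the above
```

Every command writes a manifest (config hash, ontology and rule-file
versions, seed, timestamps) so a run is reproducible from its manifest
alone.

## Layout

```
src/rehab_extract/
  ontology.py         ontology schema, loading, lexicon lookup
  resources/          ontology.yaml (the transcribed ontology), rules.yaml
  preprocess.py       note filtering, section extraction, enrichment score
  rule_extractor.py   segmentation, tagging, status, numeric parsing
  ml_models.py        bag-of-words vocabulary + per-concept model bank
  llm_interface.py    prompt generation, example selection, backends
  synthetic_notes.py  gold-labelled synthetic section generator
  evaluation.py       metrics, Fleiss kappa, stratified split
  standoff.py         standoff-annotation JSONL (shared gold/pred schema)
  cli.py              rehab-extract command-line interface
docs/methods.md       models, parameters, and design notes
```
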