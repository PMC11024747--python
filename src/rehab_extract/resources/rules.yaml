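# Refinement rules layered on top of the ontology lexicon.
#
# Each rule contributes extra match patterns for one concept. These handle
# the single-letter abbreviations that are only interpretable in context:
# "L"/"R" denote a side only when immediately followed by a limb or
# location word ("L knee"), never in machine settings like "L5". A bare
# "A" (sometimes shorthand for anterior) is deliberately matched by no
# rule: without wider context it is noise. "SL" is likewise unmatched
# (side-lying vs single-leg cannot be told apart locally and neither is an
# ontology concept); the lexicalized "SLR" is handled by the ontology.
#
# polarity is reserved for future negative (suppression) rules.
version: "1.0"
rules:
  - concept_id: side_left
    pattern: "L(?=\\s+(?i:arm|leg|knee|hip|ankle|foot|heel|toe|shoulder|elbow|forearm|wrist|hand|thumb|UE|LE|extremity|side)(?![A-Za-z0-9]))"
    case_sensitive: true
    polarity: positive
  - concept_id: side_right
    pattern: "R(?=\\s+(?i:arm|leg|knee|hip|ankle|foot|heel|toe|shoulder|elbow|forearm|wrist|hand|thumb|UE|LE|extremity|side)(?![A-Za-z0-9]))"
    case_sensitive: true
    polarity: positive
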