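"""Note filtering, therapeutic-procedures section extraction, and
enrichment-based section sampling.

Therapy visits are identified purely by filename (the literal substring
``THERAPY``). From each note the therapeutic-procedures section is pulled
with a configurable header regex. Sections are then scored 0-9 by how
many of the nine scoring category dimensions (motion, side, location,
plane, duration, sets-and-reps, purpose, exercise type, body position)
have at least one lexicon keyword present, and information-dense
("enriched") plus random section samples are drawn for annotation.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .ontology import Ontology

#: Header of the therapeutic-procedures section through the next
#: all-caps header line (or end of note). The exact layout of real notes
#: varies; this default assumes a "THERAPY:"-style header and is
#: replaceable everywhere a pattern is accepted.
DEFAULT_SECTION_PATTERN = (
    r"(?ms)^[ \t]*THERAP(?:Y|EUTIC)[A-Z ]*:?[ \t]*\n?"
    r"(?P<body>.*?)"
    r"(?=^[ \t]*[A-Z][A-Z /]{2,}:[ \t]*$|\Z)"
)


@dataclass
class NoteFile:
    """One clinical note: its filename (which encodes the note type) and
    its full LF-normalized text."""

    filename: str
    text: str

    def __post_init__(self) -> None:
        if not self.filename:
            raise ValueError("NoteFile.filename must be non-empty")
        self.text = self.text.replace("\r\n", "\n").replace("\r", "\n")


@dataclass
class Section:
    """An extracted therapeutic-procedures section.

    ``char_span`` is 0-based half-open into the note text;
    ``enrichment_score`` is None until scored.
    """

    source_filename: str
    text: str
    char_span: tuple[int, int]
    enrichment_score: Optional[int] = None
    section_id: Optional[str] = None

    def __post_init__(self) -> None:
        s, e = self.char_span
        if not (0 <= s <= e):
            raise ValueError(f"invalid char_span {self.char_span}")


def read_notes(notes_dir: str | Path, glob: str = "*.txt") -> list[NoteFile]:
    notes_dir = Path(notes_dir)
    return [
        NoteFile(filename=p.name, text=p.read_text())
        for p in sorted(notes_dir.glob(glob))
    ]


def filter_therapy_notes(
    files: Sequence[NoteFile], case_sensitive: bool = True
) -> list[NoteFile]:
    """Keep files whose *name* contains the literal substring THERAPY.

    Matching is case-sensitive by default (note-type strings are upper
    case in practice); pass ``case_sensitive=False`` to relax.
    """
    if case_sensitive:
        return [f for f in files if "THERAPY" in f.filename]
    return [f for f in files if "therapy" in f.filename.lower()]


def extract_section(
    note: NoteFile, section_pattern: str | re.Pattern = DEFAULT_SECTION_PATTERN
) -> Optional[Section]:
    """First therapeutic-procedures section of a note, or None.

    Empty-bodied sections are legitimate output (a header with nothing
    under it); absence of the header yields None.
    """
    try:
        pat = re.compile(section_pattern) if isinstance(section_pattern, str) else section_pattern
    except re.error as exc:
        raise ValueError(f"malformed section pattern: {exc}") from exc
    m = pat.search(note.text)
    if m is None:
        return None
    if "body" in (pat.groupindex or {}):
        start, end = m.span("body")
    else:
        start, end = m.span()
    return Section(
        source_filename=note.filename,
        text=note.text[start:end],
        char_span=(start, end),
        section_id=note.filename,
    )


def enrichment_score(section: Section | str, ontology: Ontology) -> int:
    """Number of scoring category dimensions (0-9) with >=1 keyword hit.

    A dimension counts if any concept lexicon entry of a category with
    that scoring key matches anywhere in the section text, whole-token;
    integer categories use their ``scoring_lexicon`` instead. Dimensions
    shared by several categories (sets and reps) count once.
    """
    text = section if isinstance(section, str) else section.text
    hit: set[str] = set()
    for cat in ontology.categories:
        key = cat.scoring_key
        if key is None or key in hit:
            continue
        patterns = [p for c in cat.concepts for p in c.compiled_lexicon]
        patterns += cat.compiled_scoring_lexicon
        if any(p.search(text) for p in patterns):
            hit.add(key)
    score = len(hit)
    if isinstance(section, Section):
        section.enrichment_score = score
    return score


@dataclass
class SampleShortfall(ValueError):
    """Not enough eligible sections to fill a requested sample."""

    pool: str
    requested: int
    available: int

    def __str__(self) -> str:
        return (
            f"cannot draw {self.requested} {self.pool} sections; only "
            f"{self.available} eligible"
        )


def sample_sections(
    sections: Sequence[Section],
    n_enriched: int = 300,
    n_random: int = 300,
    min_chars: int = 200,
    rng_seed: int = 0,
) -> tuple[list[Section], list[Section]]:
    """Draw the enriched and random annotation samples.

    Enriched: every section scoring the maximum (9) plus uniformly
    sampled score-8 sections up to ``n_enriched``. Random: a uniform
    sample of sections at least ``min_chars`` long, disjoint from the
    enriched set. All sections must already be scored. Reproducible
    under ``rng_seed``.
    """
    if any(s.enrichment_score is None for s in sections):
        raise ValueError("all sections must be scored before sampling")
    rng = random.Random(rng_seed)

    nines = [s for s in sections if s.enrichment_score == 9]
    eights = [s for s in sections if s.enrichment_score == 8]
    enriched = list(nines[:n_enriched])
    need = n_enriched - len(enriched)
    if need > 0:
        if len(eights) < need:
            raise SampleShortfall("enriched", n_enriched, len(nines) + len(eights))
        enriched += rng.sample(eights, need)

    taken = {id(s) for s in enriched}
    pool = [s for s in sections if len(s.text) >= min_chars and id(s) not in taken]
    if len(pool) < n_random:
        raise SampleShortfall("random", n_random, len(pool))
    randoms = rng.sample(pool, n_random)
    return enriched, randoms
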