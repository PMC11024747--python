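"""Clinical ontology for physical-rehabilitation exercise documentation.

The ontology is a two-level hierarchy: categories (type of motion, side of
body, location on body, plane of motion, duration, sets, reps, exercise
purpose, exercise type, body position, plus the exercise-description
status dimension) and the concepts within them. Enumerated and binary
concepts form the 101-label universe used by every downstream classifier;
the three integer categories (duration, sets, reps) carry no concepts and
are handled by the numeric parser instead.

Each concept ships a lexicon of surface forms — canonical names plus the
clinical abbreviations that actually occur in therapy notes (AROM, B/L,
flx, HEP, ...). Matching is whole-token: a pattern never fires inside a
longer alphanumeric token, so ``ROM`` does not fire inside ``AROM``.
"""

from __future__ import annotations

import re
from functools import cached_property
from importlib import resources as _ilres
from pathlib import Path
from typing import Iterator, Literal, Optional, Union

import yaml
from pydantic import BaseModel, Field, field_validator

#: Number of binary-classifiable concepts in the shipped ontology.
N_BINARY_CONCEPTS = 101
#: Number of category dimensions that participate in the enrichment score.
N_SCORING_CATEGORIES = 9

_TOKEN_GUARD_L = r"(?<![A-Za-z0-9])"
_TOKEN_GUARD_R = r"(?![A-Za-z0-9])"


class OntologyError(ValueError):
    """Raised when an ontology config violates a structural invariant."""


class LexiconEntry(BaseModel):
    """One surface pattern: a literal phrase or a regular expression."""

    pattern: str
    regex: bool = False
    case_sensitive: bool = False

    @field_validator("pattern")
    @classmethod
    def _non_empty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("lexicon pattern must be a non-empty string")
        return v

    def compile(self) -> re.Pattern:
        """Compile to a token-guarded regex.

        Literal phrases are escaped word-by-word with flexible internal
        whitespace; regex entries are used as written. Both are wrapped in
        alphanumeric-boundary guards so matches never start or end inside
        a longer token.
        """
        if self.regex:
            body = self.pattern
        else:
            body = r"\s+".join(re.escape(w) for w in self.pattern.split())
        flags = 0 if self.case_sensitive else re.IGNORECASE
        return re.compile(f"{_TOKEN_GUARD_L}(?:{body}){_TOKEN_GUARD_R}", flags)


def _coerce_lexicon(raw: list) -> list[LexiconEntry]:
    out = []
    for item in raw:
        if isinstance(item, str):
            out.append(LexiconEntry(pattern=item))
        else:
            out.append(LexiconEntry.model_validate(item))
    return out


class Concept(BaseModel):
    """A single labelable concept with its surface-form lexicon."""

    model_config = {"populate_by_name": True}

    id: str
    category: str = ""
    canonical_name: str = Field(alias="name")
    lexicon: list[LexiconEntry]

    @field_validator("lexicon", mode="before")
    @classmethod
    def _lex(cls, v):
        return _coerce_lexicon(v)

    @cached_property
    def compiled_lexicon(self) -> list[re.Pattern]:
        return [e.compile() for e in self.lexicon]

    def matches(self, surface: str) -> bool:
        """True when some lexicon entry matches the entire surface form."""
        s = surface.strip()
        for pat in self.compiled_lexicon:
            m = pat.search(s)
            if m and m.group(0) == s:
                return True
        return False


class Category(BaseModel):
    """A dimension of the ontology.

    ``scoring_key`` names the enrichment-score dimension this category
    feeds; categories sharing a key (sets and reps) count as one of the 9
    scoring dimensions, and ``null`` opts a category out of scoring.
    Integer categories have an empty concept list and instead may carry a
    ``scoring_lexicon`` of numeric-shaped patterns.
    """

    name: str
    data_type: Literal["enumerated", "integer", "binary"]
    scoring_key: Optional[str] = None
    concepts: list[Concept] = Field(default_factory=list)
    scoring_lexicon: list[LexiconEntry] = Field(default_factory=list)

    @field_validator("scoring_lexicon", mode="before")
    @classmethod
    def _lex(cls, v):
        return _coerce_lexicon(v or [])

    def model_post_init(self, __context) -> None:
        for c in self.concepts:
            c.category = self.name
        if self.data_type == "integer" and self.concepts:
            raise OntologyError(
                f"integer category {self.name!r} must not contain "
                f"enumerated concepts (found {self.concepts[0].id!r})"
            )

    @cached_property
    def compiled_scoring_lexicon(self) -> list[re.Pattern]:
        return [e.compile() for e in self.scoring_lexicon]


class Ontology(BaseModel):
    """The full validated ontology."""

    version: str = "0"
    categories: list[Category]

    # -- access ----------------------------------------------------------
    def iter_concepts(self) -> Iterator[Concept]:
        for cat in self.categories:
            yield from cat.concepts

    @cached_property
    def binary_concepts(self) -> list[Concept]:
        """Concepts of enumerated/binary categories — the label universe."""
        return [
            c
            for cat in self.categories
            if cat.data_type in ("enumerated", "binary")
            for c in cat.concepts
        ]

    @cached_property
    def binary_concept_ids(self) -> list[str]:
        return [c.id for c in self.binary_concepts]

    @cached_property
    def _by_id(self) -> dict[str, Concept]:
        return {c.id: c for c in self.iter_concepts()}

    def concept(self, concept_id: str) -> Concept:
        try:
            return self._by_id[concept_id]
        except KeyError:
            raise KeyError(f"unknown concept id {concept_id!r}") from None

    def category(self, name: str) -> Category:
        for cat in self.categories:
            if cat.name == name:
                return cat
        raise KeyError(f"unknown category {name!r}")

    @cached_property
    def scoring_keys(self) -> list[str]:
        seen: list[str] = []
        for cat in self.categories:
            if cat.scoring_key and cat.scoring_key not in seen:
                seen.append(cat.scoring_key)
        return seen

    # -- validation ------------------------------------------------------
    def validate_structure(self, expect_full: bool = True) -> None:
        """Check structural invariants; with ``expect_full`` also enforce
        the shipped-ontology counts (101 binary concepts, 9 scoring keys).
        """
        ids = [c.id for c in self.iter_concepts()]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise OntologyError(f"duplicate concept ids: {sorted(dupes)}")
        if expect_full:
            n = len(self.binary_concepts)
            if n != N_BINARY_CONCEPTS:
                per_cat = {
                    cat.name: len(cat.concepts)
                    for cat in self.categories
                    if cat.data_type in ("enumerated", "binary")
                }
                raise OntologyError(
                    f"expected {N_BINARY_CONCEPTS} binary concepts, found "
                    f"{n}; per-category counts: {per_cat}"
                )
            k = len(self.scoring_keys)
            if k != N_SCORING_CATEGORIES:
                raise OntologyError(
                    f"expected {N_SCORING_CATEGORIES} scoring categories, "
                    f"found {k}: {self.scoring_keys}"
                )


def default_ontology_path() -> Path:
    return Path(str(_ilres.files("rehab_extract"))) / "resources" / "ontology.yaml"


def default_rules_path() -> Path:
    return Path(str(_ilres.files("rehab_extract"))) / "resources" / "rules.yaml"


def load_ontology(
    config_path: Union[str, Path, None] = None, expect_full: bool = True
) -> Ontology:
    """Load and validate an ontology config.

    With no path the packaged ontology is loaded. ``expect_full=False``
    skips the shipped-ontology count checks (useful for reduced test
    ontologies) while still enforcing id uniqueness.
    """
    path = Path(config_path) if config_path is not None else default_ontology_path()
    if not path.exists():
        raise FileNotFoundError(f"ontology config not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not raw or "categories" not in raw:
        raise OntologyError(f"ontology config {path} is empty or lacks 'categories'")
    onto = Ontology.model_validate(raw)
    onto.validate_structure(expect_full=expect_full)
    return onto


def lookup(ontology: Ontology, surface: str) -> list[Concept]:
    """All concepts whose lexicon matches the whole surface form.

    Pure and deterministic; unknown surfaces yield an empty list. A
    surface may legitimately map to several concepts (``LUE`` names both
    a side and a location; a bare ``ROM`` is both a motion type and an
    exercise type).
    """
    return [c for c in ontology.iter_concepts() if c.matches(surface)]
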