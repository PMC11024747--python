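"""Rule-based extraction of exercise information from therapy sections.

The pipeline: ``segment`` splits a therapeutic-procedures section into
its enumerated exercise items ("sequences"), ``tag`` finds concept
mentions with character spans via the ontology lexicon plus refinement
rules, ``resolve_status`` decides whether the exercise was performed
in-office / prescribed as home exercise / not performed, ``parse_numeric``
pulls duration, sets and reps (minutes normalized to seconds), and
``project`` collapses everything to sequence-level binary labels.

Matching is leftmost-longest and non-overlapping: when two candidate
mentions overlap, the longer span wins ("upper extremity strength"
suppresses the inner "upper extremity" and "strength"); candidates with
identical spans are all kept (the token ``LUE`` is simultaneously a side
and a location). De-identification placeholders such as ``[PERSONALNAME]``
are masked out before matching and can never fire a rule.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence, Union

import yaml

from .ontology import Ontology, default_rules_path
from .preprocess import Section

logger = logging.getLogger(__name__)

Status = Literal["performed in-office", "home exercise program", "not performed"]
STATUS_IN_OFFICE: Status = "performed in-office"
STATUS_HEP: Status = "home exercise program"
STATUS_NOT_PERFORMED: Status = "not performed"

#: Exercise-description concept carried by each status value.
STATUS_CONCEPT: dict[Status, str] = {
    STATUS_IN_OFFICE: "desc_in_office",
    STATUS_HEP: "desc_hep",
    STATUS_NOT_PERFORMED: "desc_not_performed",
}

NumericKind = Literal["duration_seconds", "sets", "reps", "distance_feet"]

#: De-identification placeholders are opaque: they never match a rule.
_PLACEHOLDER = re.compile(r"\[[A-Z]+\]")

#: Enumerated-list markers: "3:", "3.", "3)" at line starts, plus inline
#: "3:" after whitespace (run-on sections write items on one line).
_MARKER = re.compile(r"(?m)^[ \t]*(\d+)[ \t]*[:.)]|(?<=\s)(\d+)[ \t]*:")

#: Words that put a number+apostrophe quantity in a locomotion (distance)
#: rather than timed-hold (duration) context.
_LOCOMOTION = re.compile(
    r"(?:walk\w*|stepp\w*|step|gait|ambulat\w*|march\w*)\W*$", re.IGNORECASE
)


class RuleConfigError(ValueError):
    """A refinement rule failed to compile."""


@dataclass
class ExerciseSequence:
    """One enumerated exercise item within a section."""

    section_ref: str
    index_label: str
    text: str
    char_span: tuple[int, int]

    @property
    def id(self) -> str:
        return f"{self.section_ref}#{self.index_label}"


@dataclass(frozen=True)
class ConceptMention:
    """A tagged span: (concept, character offsets within the sequence)."""

    sequence_ref: str
    concept_id: str
    char_span: tuple[int, int]
    matched_text: str


@dataclass(frozen=True)
class NumericFinding:
    """A parsed numeric quantity. Durations are always in seconds;
    ``unit_normalized`` marks minute-to-second conversion."""

    kind: NumericKind
    value: int
    char_span: tuple[int, int]
    unit_normalized: bool = False


@dataclass
class SequenceLabels:
    """Sequence-level labels: the binary concept set plus numerics."""

    sequence_ref: str
    binary: set[str] = field(default_factory=set)
    duration_seconds: Optional[int] = None
    sets: Optional[int] = None
    reps: Optional[int] = None
    status: Status = STATUS_IN_OFFICE


class RuleSet:
    """Compiled match patterns: ontology lexicons plus refinement rules.

    Refinement rules come from a YAML file of
    ``{concept_id, pattern, case_sensitive, polarity}`` records; they are
    regexes (typically with context lookarounds) that extend a concept's
    reach beyond its plain lexicon, e.g. a bare ``L`` directly before a
    limb word counting as "left".
    """

    def __init__(self, patterns: list[tuple[str, re.Pattern]], version: str = "0"):
        self.patterns = patterns
        self.version = version

    @classmethod
    def from_ontology(
        cls,
        ontology: Ontology,
        rules_path: Union[str, Path, None] = None,
        include_default_rules: bool = True,
    ) -> "RuleSet":
        patterns: list[tuple[str, re.Pattern]] = [
            (c.id, p) for c in ontology.binary_concepts for p in c.compiled_lexicon
        ]
        version = "0"
        if rules_path is None and include_default_rules:
            rules_path = default_rules_path()
        if rules_path is not None:
            raw = yaml.safe_load(Path(rules_path).read_text()) or {}
            version = str(raw.get("version", "0"))
            known = set(ontology.binary_concept_ids)
            for rule in raw.get("rules", []):
                cid = rule.get("concept_id", "?")
                if cid not in known:
                    raise RuleConfigError(f"rule targets unknown concept {cid!r}")
                flags = 0 if rule.get("case_sensitive", False) else re.IGNORECASE
                try:
                    pat = re.compile(rule["pattern"], flags)
                except re.error as exc:
                    raise RuleConfigError(
                        f"rule for {cid!r} does not compile: {exc}"
                    ) from exc
                patterns.append((cid, pat))
        return cls(patterns, version=version)


def segment(section: Section) -> list[ExerciseSequence]:
    """Split a section into its enumerated exercise items.

    Each item spans from its list marker to the next marker (or section
    end); printed numbers are preserved verbatim, including gaps in the
    numbering. Items with no non-whitespace content after the marker are
    dropped. With no markers at all the result is empty.
    """
    text = section.text
    sec_id = section.section_id or section.source_filename
    marks = [
        (m.start(), m.end(), m.group(1) or m.group(2))
        for m in _MARKER.finditer(text)
    ]
    out: list[ExerciseSequence] = []
    for i, (start, mark_end, label) in enumerate(marks):
        end = marks[i + 1][0] if i + 1 < len(marks) else len(text)
        if not text[mark_end:end].strip():
            continue
        out.append(
            ExerciseSequence(
                section_ref=sec_id,
                index_label=label,
                text=text[start:end],
                char_span=(start, end),
            )
        )
    return out


def _mask_placeholders(text: str) -> str:
    return _PLACEHOLDER.sub(lambda m: " " * (m.end() - m.start()), text)


def tag(
    sequence: Union[ExerciseSequence, str],
    ontology: Ontology,
    rules: Optional[RuleSet] = None,
) -> list[ConceptMention]:
    """All non-overlapping concept mentions in a sequence.

    Longer matches beat shorter overlapping ones; ties on identical spans
    are all kept; among same-length partial overlaps the leftmost wins.
    """
    if rules is None:
        rules = RuleSet.from_ontology(ontology)
    text = sequence.text if isinstance(sequence, ExerciseSequence) else sequence
    ref = sequence.id if isinstance(sequence, ExerciseSequence) else ""
    masked = _mask_placeholders(text)

    candidates: set[tuple[int, int, str]] = set()
    for cid, pat in rules.patterns:
        for m in pat.finditer(masked):
            if m.end() > m.start():
                candidates.add((m.start(), m.end(), cid))

    kept: list[tuple[int, int, str]] = []
    for s, e, cid in sorted(candidates, key=lambda t: (-(t[1] - t[0]), t[0], t[2])):
        ok = True
        for ks, ke, _ in kept:
            if (ks, ke) == (s, e):
                continue  # identical spans coexist
            if s < ke and ks < e:
                ok = False
                break
        if ok:
            kept.append((s, e, cid))
    kept.sort()
    return [
        ConceptMention(
            sequence_ref=ref, concept_id=cid, char_span=(s, e), matched_text=text[s:e]
        )
        for s, e, cid in kept
    ]


def resolve_status(
    sequence: Union[ExerciseSequence, str], mentions: Sequence[ConceptMention]
) -> Status:
    """Status precedence: not-performed markers beat HEP markers beat the
    in-office default."""
    ids = {m.concept_id for m in mentions}
    if "desc_not_performed" in ids:
        return STATUS_NOT_PERFORMED
    if "desc_hep" in ids:
        return STATUS_HEP
    return STATUS_IN_OFFICE


def parse_numeric(
    sequence: Union[ExerciseSequence, str], include_distances: bool = False
) -> list[NumericFinding]:
    """Parse duration / sets / reps quantities with spans.

    Recognized shapes: ``AxB`` (sets x reps), ``x N`` and ``N x`` (reps),
    ``N rep(s)`` / ``N set(s)``, ``N min``/``N sec``, and ``N'`` which is
    a duration in minutes (converted to seconds) unless a locomotion verb
    immediately precedes it, in which case it is a distance in feet.
    Distances are recognized but reported only when ``include_distances``
    is set, since they are not part of the label schema. Unparseable
    numerics are skipped.
    """
    text = sequence.text if isinstance(sequence, ExerciseSequence) else sequence
    masked = _mask_placeholders(text)
    findings: list[NumericFinding] = []
    consumed: list[tuple[int, int]] = []

    def taken(s: int, e: int) -> bool:
        return any(s < ce and cs < e for cs, ce in consumed)

    def add(kind: NumericKind, value: int, span: tuple[int, int],
            consume: tuple[int, int], normalized: bool = False) -> None:
        consumed.append(consume)
        if kind == "distance_feet" and not include_distances:
            logger.debug("distance finding %s ft at %s skipped", value, span)
            return
        findings.append(NumericFinding(kind, value, span, normalized))

    # durations and distances first: they own their digits
    for m in re.finditer(r"(\d+)\s*(?:min|mins|minute|minutes)(?![A-Za-z0-9])", masked, re.I):
        add("duration_seconds", int(m.group(1)) * 60, m.span(), m.span(), True)
    for m in re.finditer(r"(\d+)\s*(?:sec|secs|second|seconds)(?![A-Za-z0-9])", masked, re.I):
        add("duration_seconds", int(m.group(1)), m.span(), m.span())
    for m in re.finditer(r"(\d+)\s*(?:ft|feet)(?![A-Za-z0-9])", masked, re.I):
        add("distance_feet", int(m.group(1)), m.span(), m.span())
    for m in re.finditer(r"(\d+)\s*'", masked):
        if taken(*m.span()):
            continue
        if _LOCOMOTION.search(masked[: m.start()]):
            add("distance_feet", int(m.group(1)), m.span(), m.span())
        else:
            add("duration_seconds", int(m.group(1)) * 60, m.span(), m.span(), True)

    # A x B -> sets=A, reps=B
    for m in re.finditer(r"(?<![A-Za-z0-9'])(\d+)\s*[xX]\s*(\d+)(?![A-Za-z0-9])", masked):
        if taken(*m.span()):
            continue
        consumed.append(m.span())
        findings.append(NumericFinding("sets", int(m.group(1)), m.span(1)))
        findings.append(NumericFinding("reps", int(m.group(2)), m.span(2)))

    # explicit units
    for m in re.finditer(r"(?<![A-Za-z0-9'])(\d+)\s*reps?(?![A-Za-z0-9])", masked, re.I):
        if not taken(*m.span()):
            add("reps", int(m.group(1)), m.span(), m.span())
    for m in re.finditer(r"(?<![A-Za-z0-9'])(\d+)\s*sets?(?![A-Za-z0-9])", masked, re.I):
        if not taken(*m.span()):
            add("sets", int(m.group(1)), m.span(), m.span())

    # x N  /  N x
    for m in re.finditer(r"(?<![A-Za-z0-9])[xX]\s*(\d+)(?![A-Za-z0-9])", masked):
        if not taken(*m.span()):
            add("reps", int(m.group(1)), m.span(), m.span())
    for m in re.finditer(r"(?<![A-Za-z0-9'])(\d+)\s*[xX](?![A-Za-z0-9])", masked):
        if not taken(*m.span()):
            add("reps", int(m.group(1)), m.span(), m.span())

    findings.sort(key=lambda f: f.char_span)
    return findings


def project(
    mentions: Sequence[ConceptMention],
    numerics: Sequence[NumericFinding] = (),
    status: Status = STATUS_IN_OFFICE,
    sequence_ref: str = "",
) -> SequenceLabels:
    """Collapse span-level output to sequence-level labels.

    Binary labels are the distinct mention concepts plus the status
    concept. For each numeric kind the first finding in span order wins;
    later conflicting findings are logged and dropped.
    """
    labels = SequenceLabels(sequence_ref=sequence_ref, status=status)
    labels.binary = {m.concept_id for m in mentions} | {STATUS_CONCEPT[status]}
    fields = {"duration_seconds": None, "sets": None, "reps": None}
    for f in sorted(numerics, key=lambda f: f.char_span):
        if f.kind not in fields:
            continue
        if fields[f.kind] is None:
            fields[f.kind] = f.value
        elif fields[f.kind] != f.value:
            logger.warning(
                "conflicting %s findings in %s: keeping %s, dropping %s",
                f.kind, sequence_ref or "<sequence>", fields[f.kind], f.value,
            )
    labels.duration_seconds = fields["duration_seconds"]
    labels.sets = fields["sets"]
    labels.reps = fields["reps"]
    return labels


def extract(
    section: Section, ontology: Ontology, rules: Optional[RuleSet] = None
) -> list[tuple[ExerciseSequence, SequenceLabels, list[ConceptMention]]]:
    """Full rule pipeline on one section: segment, tag, parse, project."""
    if rules is None:
        rules = RuleSet.from_ontology(ontology)
    out = []
    for seq in segment(section):
        mentions = tag(seq, ontology, rules)
        numerics = parse_numeric(seq)
        status = resolve_status(seq, mentions)
        labels = project(mentions, numerics, status, sequence_ref=seq.id)
        out.append((seq, labels, mentions))
    return out
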