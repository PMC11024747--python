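"""Standoff-annotation containers and JSONL serialization.

Gold annotations and rule-extractor predictions share one schema so they
can be diffed directly: one JSON object per section, holding the section
text and, per exercise sequence, its span within the section, its
sequence-level labels, and its concept-mention spans (character offsets
relative to the sequence start).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .rule_extractor import SequenceLabels, Status


@dataclass
class AnnotatedSequence:
    index_label: str
    span: tuple[int, int]  # within the section text
    labels: SequenceLabels
    mentions: list[tuple[tuple[int, int], str]] = field(default_factory=list)


@dataclass
class AnnotatedSection:
    section_id: str
    text: str
    sequences: list[AnnotatedSequence]
    enrichment_score: Optional[int] = None

    def labels_by_sequence(self) -> dict[str, SequenceLabels]:
        return {s.labels.sequence_ref: s.labels for s in self.sequences}


def section_to_dict(sec: AnnotatedSection) -> dict:
    return {
        "section_id": sec.section_id,
        "text": sec.text,
        "score": sec.enrichment_score,
        "sequences": [
            {
                "index_label": q.index_label,
                "span": list(q.span),
                "labels": {
                    "binary": sorted(q.labels.binary),
                    "duration_seconds": q.labels.duration_seconds,
                    "sets": q.labels.sets,
                    "reps": q.labels.reps,
                    "status": q.labels.status,
                },
                "mentions": [
                    {"span": list(sp), "concept": cid} for sp, cid in q.mentions
                ],
            }
            for q in sec.sequences
        ],
    }


def section_from_dict(d: dict) -> AnnotatedSection:
    seqs = []
    for q in d["sequences"]:
        lab = q["labels"]
        ref = f"{d['section_id']}#{q['index_label']}"
        seqs.append(
            AnnotatedSequence(
                index_label=q["index_label"],
                span=tuple(q["span"]),
                labels=SequenceLabels(
                    sequence_ref=ref,
                    binary=set(lab["binary"]),
                    duration_seconds=lab["duration_seconds"],
                    sets=lab["sets"],
                    reps=lab["reps"],
                    status=lab["status"],
                ),
                mentions=[(tuple(m["span"]), m["concept"]) for m in q["mentions"]],
            )
        )
    return AnnotatedSection(
        section_id=d["section_id"],
        text=d["text"],
        sequences=seqs,
        enrichment_score=d.get("score"),
    )


def from_extraction(section, results) -> AnnotatedSection:
    """Package rule-extractor output for one section
    (see :func:`rehab_extract.rule_extractor.extract`) as standoff."""
    return AnnotatedSection(
        section_id=section.section_id or section.source_filename,
        text=section.text,
        enrichment_score=section.enrichment_score,
        sequences=[
            AnnotatedSequence(
                index_label=seq.index_label,
                span=seq.char_span,
                labels=labels,
                mentions=[(m.char_span, m.concept_id) for m in mentions],
            )
            for seq, labels, mentions in results
        ],
    )


def write_jsonl(sections: Iterable[AnnotatedSection], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for sec in sections:
            fh.write(json.dumps(section_to_dict(sec)) + "\n")


def read_jsonl(path: str | Path) -> list[AnnotatedSection]:
    out = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(section_from_dict(json.loads(line)))
    return out
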