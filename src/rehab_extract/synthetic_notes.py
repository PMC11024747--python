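"""Grammar-based generator of therapy-note sections with known gold labels.

Real therapeutic-procedures sections are numbered exercise lists written
in clinical shorthand ("1: AROM right elbow flx/ext HEP 2: foam Lunges:
x 20 B/L ..."). This module emits sections in that style from a slot
grammar — [position] [motion] [side] [location] [plane(s)] [type]
[purpose] [numerics] [status marker] — drawing surface forms from the
ontology lexicon, and records the gold labels and mention spans at
emission time. Gold is therefore correct by construction and never
produced by the extractor under test.

The ambiguity toggle injects the note-taking pathologies that make real
notes hard: single-letter "L"/"R" sides, a bare "A" for anterior (which
the rules deliberately never match), and apostrophe quantities that are
distances rather than durations after locomotion verbs. Emitted
distances are intentionally absent from the gold labels.
"""

from __future__ import annotations

import random
from typing import Optional

from pydantic import BaseModel, Field

from .ontology import Ontology, load_ontology
from .preprocess import NoteFile
from .rule_extractor import (
    STATUS_CONCEPT,
    STATUS_HEP,
    STATUS_IN_OFFICE,
    STATUS_NOT_PERFORMED,
    SequenceLabels,
    Status,
)
from .standoff import AnnotatedSection, AnnotatedSequence, write_jsonl

GoldSection = AnnotatedSection

# Filler tokens that match no lexicon entry (checked by test).
_FILLERS = ["foam", "mat", "towel", "green TB", "wand", "maze", "4\" stair"]

# side x extremity abbreviations: one token, two gold concepts.
_COMBINED = {
    ("side_left", "loc_upper_extremity"): "LUE",
    ("side_left", "loc_lower_extremity"): "LLE",
    ("side_right", "loc_upper_extremity"): "RUE",
    ("side_right", "loc_lower_extremity"): "RLE",
}


class GeneratorConfig(BaseModel):
    """Emission probabilities and style knobs.

    Slot inclusion probabilities and concept weights are loosely matched
    to the prevalence pattern of annotated therapy corpora (sides and
    extremities common, most planes rare); they are the defaults under
    which all round-trip and learning experiments run.
    """

    p_position: float = 0.18
    p_motion: float = 0.5
    p_side: float = 0.6
    p_location: float = 0.9
    p_second_location: float = 0.15
    p_plane: float = 0.7
    p_second_plane: float = 0.5
    p_type: float = 0.35
    p_purpose: float = 0.25
    p_numeric: float = 0.75
    p_filler: float = 0.25

    hep_rate: float = 0.15
    not_performed_rate: float = 0.08

    abbreviation_prob: float = 0.5
    combined_side_loc_prob: float = 0.3
    placeholder_rate: float = 0.05
    skip_number_prob: float = 0.05
    typo_rate: float = 0.0

    items_min: int = 3
    items_max: int = 12

    numeric_mix: dict[str, float] = Field(
        default_factory=lambda: {
            "axb": 0.3, "x_n": 0.25, "n_x": 0.15, "minutes": 0.2, "n_rep": 0.1
        }
    )

    motion_weights: dict[str, float] = Field(
        default_factory=lambda: {
            "motion_arom": 0.4, "motion_prom": 0.2,
            "motion_aarom": 0.2, "motion_rom": 0.2,
        }
    )
    side_weights: dict[str, float] = Field(
        default_factory=lambda: {
            "side_right": 0.3, "side_left": 0.3, "side_bilateral": 0.2,
            "side_unilateral": 0.1, "side_contralateral": 0.05,
            "side_ipsilateral": 0.05,
        }
    )
    location_weights: dict[str, float] = Field(
        default_factory=lambda: {
            "loc_upper_extremity": 0.14, "loc_lower_extremity": 0.14,
            "loc_shoulder": 0.09, "loc_knee": 0.08, "loc_hip": 0.08,
            "loc_wrist": 0.05, "loc_elbow": 0.05, "loc_hand": 0.05,
            "loc_ankle": 0.04, "loc_forearm": 0.03,
        }
    )
    plane_weights: dict[str, float] = Field(
        default_factory=lambda: {
            "plane_flexion": 0.12, "plane_extension": 0.12,
            "plane_abduction": 0.06, "plane_adduction": 0.05,
            "plane_internal_rotation": 0.04, "plane_external_rotation": 0.04,
        }
    )
    type_weights: dict[str, float] = Field(
        default_factory=lambda: {
            "type_gait": 0.18, "type_balance": 0.15, "type_le_strength": 0.15,
            "type_ue_strength": 0.1, "type_rom": 0.1, "type_flexibility": 0.08,
            "type_functional": 0.08, "type_cardio_aerobic": 0.06,
            "type_trunk_strength": 0.05, "type_scapular_strength": 0.05,
        }
    )

    ambiguity: bool = False
    ambiguity_rate: float = 0.1

    def validate_probs(self) -> None:
        for name in (
            "p_position", "p_motion", "p_side", "p_location", "p_plane",
            "p_type", "p_purpose", "p_numeric", "hep_rate",
            "not_performed_rate", "abbreviation_prob", "placeholder_rate",
            "ambiguity_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def _weighted_choice(rng: random.Random, weights: dict[str, float],
                     universe: list[str], residual: float = 1.0) -> str:
    """Weighted draw over ``universe``; ids absent from ``weights`` share
    the residual mass uniformly."""
    named = {k: w for k, w in weights.items() if k in universe}
    rest = [c for c in universe if c not in named]
    total_named = sum(named.values())
    rest_w = max(residual - total_named, 0.0) / len(rest) if rest else 0.0
    ids = list(named) + rest
    ws = list(named.values()) + [rest_w] * len(rest)
    return rng.choices(ids, weights=ws, k=1)[0]


class _SeqBuilder:
    """Accumulates item text while recording gold mention spans."""

    def __init__(self, marker: str):
        self.text = marker
        self.mentions: list[tuple[tuple[int, int], str]] = []

    def append(self, surface: str, concepts: tuple[str, ...] = (),
               sep: str = " ") -> None:
        start = len(self.text) + len(sep)
        self.text += sep + surface
        for cid in concepts:
            self.mentions.append(((start, start + len(surface)), cid))

    def append_group(self, parts: list[tuple[str, tuple[str, ...]]],
                     joiner: str = "/", sep: str = " ") -> None:
        """Append surfaces joined by a non-word character ('flx/ext')."""
        pos = len(self.text) + len(sep)
        frags = []
        for i, (surface, concepts) in enumerate(parts):
            if i > 0:
                pos += len(joiner)
            for cid in concepts:
                self.mentions.append(((pos, pos + len(surface)), cid))
            pos += len(surface)
            frags.append(surface)
        self.text += sep + joiner.join(frags)


# surfaces that map to several concepts at once; never drawn as a
# single-concept surface (the fused side+extremity tokens are emitted
# through _COMBINED with both gold ids instead)
_MULTI_CONCEPT_SURFACES = {"LUE", "LLE", "RUE", "RLE"}

# notes name strength exercises by the exercise ("Lunges", "Dips",
# "planks"), not by the descriptive category label; emit only the
# keyword-style surfaces for these types
_EMISSION_SURFACES = {
    "type_ue_strength": ["bicep curls", "rows"],
    "type_le_strength": ["squats", "lunges", "bridging", "dips"],
    "type_trunk_strength": ["planks", "sit-ups"],
}


def _surface(ontology: Ontology, cid: str, rng: random.Random,
             abbrev_prob: float) -> str:
    """Pick an emission surface for a concept from its literal lexicon:
    the first entry is canonical, the rest are abbreviation variants."""
    if cid in _EMISSION_SURFACES:
        return rng.choice(_EMISSION_SURFACES[cid])
    entries = [
        e.pattern
        for e in ontology.concept(cid).lexicon
        if not e.regex and e.pattern not in _MULTI_CONCEPT_SURFACES
    ]
    if len(entries) > 1 and rng.random() < abbrev_prob:
        return rng.choice(entries[1:])
    return entries[0]


def _gold_ids(cid: str) -> tuple[str, ...]:
    # every ROM / "range of motion" surface names both the motion type
    # and the exercise type (the two concepts share their lexicon)
    if cid in ("motion_rom", "type_rom"):
        return ("motion_rom", "type_rom")
    return (cid,)


def generate_sequence(
    config: GeneratorConfig,
    rng: random.Random,
    ontology: Optional[Ontology] = None,
    marker_number: int = 1,
) -> tuple[str, SequenceLabels, list[tuple[tuple[int, int], str]]]:
    """Emit one numbered exercise item; returns (text, gold labels,
    gold mention spans relative to the item start)."""
    if ontology is None:
        ontology = _default_onto()
    b = _SeqBuilder(f"{marker_number}:")
    cat = ontology.category

    def ids(name: str) -> list[str]:
        return [c.id for c in cat(name).concepts]

    ambiguous_case: Optional[str] = None
    if config.ambiguity and rng.random() < config.ambiguity_rate:
        ambiguous_case = rng.choice(["letter_side", "bare_a", "distance"])

    if rng.random() < config.placeholder_rate:
        b.append("[PERSONALNAME]")

    if rng.random() < config.p_position:
        pid = rng.choice(ids("body_position"))
        b.append(_surface(ontology, pid, rng, config.abbreviation_prob), (pid,))

    if rng.random() < config.p_motion:
        mid = _weighted_choice(rng, config.motion_weights, ids("type_of_motion"))
        b.append(_surface(ontology, mid, rng, config.abbreviation_prob),
                 _gold_ids(mid))

    # side and location, possibly fused into LUE-style tokens
    want_side = rng.random() < config.p_side
    want_loc = rng.random() < config.p_location
    side_id = (_weighted_choice(rng, config.side_weights, ids("side_of_body"))
               if want_side else None)
    loc_ids = []
    if want_loc:
        loc_ids.append(_weighted_choice(rng, config.location_weights,
                                        ids("location_on_body")))
        if rng.random() < config.p_second_location:
            second = _weighted_choice(rng, config.location_weights,
                                      ids("location_on_body"))
            if second != loc_ids[0]:
                loc_ids.append(second)

    deferred_bilateral = False
    if ambiguous_case == "letter_side" and side_id in ("side_left", "side_right"):
        # "L knee": resolvable only through the following-location context;
        # restricted to single-word limb locations the context rule knows
        loc = rng.choice(
            ["loc_knee", "loc_hip", "loc_ankle", "loc_shoulder",
             "loc_elbow", "loc_wrist", "loc_hand"]
        )
        b.append("L" if side_id == "side_left" else "R", (side_id,))
        b.append(ontology.concept(loc).lexicon[0].pattern, (loc,))
        loc_ids = []
        side_id = None
    elif side_id is not None:
        combo = _COMBINED.get((side_id, loc_ids[0])) if loc_ids else None
        if combo and rng.random() < config.combined_side_loc_prob:
            b.append(combo, (side_id, loc_ids[0]))
            loc_ids = loc_ids[1:]
            side_id = None
        elif side_id == "side_bilateral" and rng.random() < config.abbreviation_prob:
            deferred_bilateral = True  # "x 20 B/L" style: emit after numerics
        else:
            b.append(_surface(ontology, side_id, rng, config.abbreviation_prob),
                     (side_id,))
    if loc_ids:
        b.append_group(
            [(_surface(ontology, l, rng, config.abbreviation_prob), (l,))
             for l in loc_ids]
        )

    if ambiguous_case == "bare_a":
        # bare "A" for anterior: unresolvable locally, never matched
        b.append("A", ("plane_anterior",))
    elif rng.random() < config.p_plane:
        plane_ids = [_weighted_choice(rng, config.plane_weights,
                                      ids("plane_of_motion"))]
        if rng.random() < config.p_second_plane:
            second = _weighted_choice(rng, config.plane_weights,
                                      ids("plane_of_motion"))
            if second != plane_ids[0]:
                plane_ids.append(second)
        b.append_group(
            [(_surface(ontology, p, rng, config.abbreviation_prob), (p,))
             for p in plane_ids]
        )

    if rng.random() < config.p_filler:
        b.append(rng.choice(_FILLERS))

    if ambiguous_case == "distance":
        tid = "type_gait"
        b.append("walking", (tid,))
    elif rng.random() < config.p_type:
        tid = _weighted_choice(rng, config.type_weights, ids("exercise_type"))
        surf = _surface(ontology, tid, rng, config.abbreviation_prob)
        b.append(surf, _gold_ids(tid))

    if rng.random() < config.p_purpose:
        uid = _weighted_choice(rng, {"purpose_strength": 0.3},
                               ids("exercise_purpose"))
        b.append("for", ())
        b.append(_surface(ontology, uid, rng, config.abbreviation_prob), (uid,))

    duration = sets = reps = None
    if ambiguous_case == "distance":
        # "walking: 25' x 2": feet, then a rep count; no duration gold
        reps = rng.randint(2, 4)
        b.append(f"{rng.choice([10, 25, 50])}' x {reps}",
                 sep=": " if rng.random() < 0.5 else " ")
    elif rng.random() < config.p_numeric:
        form = rng.choices(list(config.numeric_mix),
                           weights=list(config.numeric_mix.values()), k=1)[0]
        sep = ": " if rng.random() < 0.4 else " "
        if form == "axb":
            sets, reps = rng.randint(2, 4), rng.choice([5, 8, 10, 12, 15])
            b.append(f"{sets}x{reps}", sep=sep)
        elif form == "x_n":
            reps = rng.choice([5, 10, 15, 20, 30])
            b.append(f"x {reps}", sep=sep)
        elif form == "n_x":
            reps = rng.choice([5, 10, 15, 20])
            b.append(f"{reps} x", sep=sep)
        elif form == "minutes":
            mins = rng.choice([1, 2, 5, 10])
            duration = mins * 60
            b.append(f"x {mins}'" if rng.random() < 0.6 else f"{mins} min",
                     sep=sep)
        else:
            reps = rng.randint(1, 5)
            b.append(f"{reps} rep" if reps == 1 else f"{reps} reps", sep=sep)

    if b.text == f"{marker_number}:":
        # every optional slot missed: force a location so the item has
        # content (enumerated items without text are not procedures)
        loc = _weighted_choice(rng, config.location_weights,
                               ids("location_on_body"))
        b.append(ontology.concept(loc).lexicon[0].pattern, (loc,))

    if deferred_bilateral:
        b.append("B/L", ("side_bilateral",))

    r = rng.random()
    status: Status = STATUS_IN_OFFICE
    if r < config.not_performed_rate:
        status = STATUS_NOT_PERFORMED
        b.append(rng.choice(["deferred", "held", "not performed"]),
                 ("desc_not_performed",))
    elif r < config.not_performed_rate + config.hep_rate:
        status = STATUS_HEP
        b.append("HEP", ("desc_hep",))

    if config.typo_rate and rng.random() < config.typo_rate:
        b.append(_typo(rng.choice(_FILLERS[:3]), rng))

    labels = SequenceLabels(
        sequence_ref="",
        binary={cid for _, cid in b.mentions} | {STATUS_CONCEPT[status]},
        duration_seconds=duration,
        sets=sets,
        reps=reps,
        status=status,
    )
    return b.text, labels, b.mentions


def _typo(word: str, rng: random.Random) -> str:
    if len(word) < 3:
        return word
    i = rng.randrange(len(word) - 1)
    return word[:i] + word[i + 1] + word[i] + word[i + 2:]


_ONTO_CACHE: Optional[Ontology] = None


def _default_onto() -> Ontology:
    global _ONTO_CACHE
    if _ONTO_CACHE is None:
        _ONTO_CACHE = load_ontology()
    return _ONTO_CACHE


def generate_section(
    config: GeneratorConfig,
    rng: random.Random,
    ontology: Optional[Ontology] = None,
    section_id: str = "synth-0000",
) -> GoldSection:
    """One section: several numbered items joined run-on with spaces,
    with occasional skipped list numbers."""
    if ontology is None:
        ontology = _default_onto()
    n_items = rng.randint(config.items_min, config.items_max)
    number = 0
    items = []
    for _ in range(n_items):
        number += 2 if rng.random() < config.skip_number_prob else 1
        items.append(
            generate_sequence(config, rng, ontology, marker_number=number)
        )

    text = " ".join(t for t, _, _ in items)
    sequences = []
    pos = 0
    for i, (t, labels, mentions) in enumerate(items):
        end = pos + len(t) + (1 if i + 1 < len(items) else 0)
        label = t.split(":", 1)[0]
        labels.sequence_ref = f"{section_id}#{label}"
        sequences.append(
            AnnotatedSequence(
                index_label=label, span=(pos, end), labels=labels,
                mentions=mentions,
            )
        )
        pos = end
    return GoldSection(section_id=section_id, text=text, sequences=sequences)


def generate_corpus(
    n_sections: int,
    config: Optional[GeneratorConfig] = None,
    rng_seed: int = 0,
    ontology: Optional[Ontology] = None,
) -> list[GoldSection]:
    """A corpus of sections with by-construction gold annotations."""
    if n_sections < 1:
        raise ValueError(f"n_sections must be >= 1, got {n_sections}")
    config = config or GeneratorConfig()
    config.validate_probs()
    rng = random.Random(rng_seed)
    ontology = ontology or _default_onto()
    return [
        generate_section(config, rng, ontology, section_id=f"synth-{i:04d}")
        for i in range(n_sections)
    ]


def validate_soundness(corpus: list[GoldSection]) -> None:
    """Every gold label must be witnessed by a span in the text.

    The in-office status concept is exempt: like human annotation, it is
    the default reading of an unmarked item, not an explicit mention.
    """
    for sec in corpus:
        for seq in sec.sequences:
            s, e = seq.span
            if not (0 <= s < e <= len(sec.text)):
                raise AssertionError(f"bad sequence span {seq.span} in {sec.section_id}")
            seq_text = sec.text[s:e]
            witnessed = {cid for _, cid in seq.mentions}
            missing = seq.labels.binary - witnessed - {"desc_in_office"}
            if missing:
                raise AssertionError(
                    f"{seq.labels.sequence_ref}: labels without witnessing "
                    f"spans: {sorted(missing)}"
                )
            for (ms, me), cid in seq.mentions:
                if not (0 <= ms < me <= len(seq_text)):
                    raise AssertionError(
                        f"{seq.labels.sequence_ref}: mention span ({ms},{me}) "
                        f"outside sequence for {cid}"
                    )


def export_gold(corpus: list[GoldSection], path) -> None:
    write_jsonl(corpus, path)


def generate_note_files(
    n_notes: int,
    config: Optional[GeneratorConfig] = None,
    rng_seed: int = 0,
    therapy_fraction: float = 0.8,
) -> list[NoteFile]:
    """Note files wrapping generated sections, for exercising the
    preprocessing path: a THERAPY header section inside boilerplate, with
    a fraction of non-therapy filler notes mixed in."""
    config = config or GeneratorConfig()
    rng = random.Random(rng_seed)
    ontology = _default_onto()
    notes = []
    for i in range(n_notes):
        if rng.random() < therapy_fraction:
            sec = generate_section(config, rng, ontology, section_id=f"note-{i}")
            text = (
                "PATIENT VISIT\nSeen today for follow-up.\n"
                f"THERAPY:\n{sec.text}\n"
                "PLAN:\nContinue as tolerated.\n"
            )
            notes.append(NoteFile(filename=f"PT_THERAPY_{i:04d}.txt", text=text))
        else:
            notes.append(
                NoteFile(
                    filename=f"CARDIOLOGY_{i:04d}.txt",
                    text="PATIENT VISIT\nRoutine cardiology follow-up.\n",
                )
            )
    return notes
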