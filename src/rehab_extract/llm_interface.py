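"""Auto-generated yes/no extraction prompts for a chat-model backend.

For each concept a prompt asks whether the concept is mentioned in a
given text segment. Prompts are built mechanically from a single
template plus the concept's display name; the few-shot variant prepends
exactly four worked example exchanges (2 positive, 2 negative,
alternating Yes/No), the zero-shot variant none. The backend is
pluggable: a deterministic keyword mock for offline use, and a generic
chat-completion HTTP adapter for live runs (never exercised by tests).
"""

from __future__ import annotations

import json
import logging
import random
import time
import urllib.request
from dataclasses import dataclass, field
from typing import Callable, Literal, Optional, Protocol, Sequence

from .ontology import Ontology
from .rule_extractor import SequenceLabels

logger = logging.getLogger(__name__)

Role = Literal["System", "User", "Model"]
Mode = Literal["zero_shot", "few_shot"]

SYSTEM_TEMPLATE = (
    "You are an assistant assigned to determine if a given text segment "
    "from a medical record contains mentions of {concept}. "
    "You must answer yes or no."
)

#: Exercise-description concepts are excluded from prompting: whether a
#: procedure happened in-office / at home / not at all is not a textual
#: "mention of X" question.
EXCLUDED_DESCRIPTION_CONCEPTS = ("desc_in_office", "desc_hep", "desc_not_performed")


@dataclass(frozen=True)
class DialogueTurn:
    role: Role
    text: str

    def render(self) -> str:
        return f"{self.role}: {self.text}"


@dataclass
class Prompt:
    concept_id: str
    mode: Mode
    turns: list[DialogueTurn]

    def __post_init__(self) -> None:
        if not self.turns or self.turns[0].role != "System":
            raise ValueError("a prompt starts with exactly one System turn")
        if any(t.role == "System" for t in self.turns[1:]):
            raise ValueError("System may appear only as the first turn")
        if self.turns[-1].role != "User":
            raise ValueError("the final turn must be the User query")
        n_examples = sum(1 for t in self.turns if t.role == "Model")
        expected = 4 if self.mode == "few_shot" else 0
        if n_examples != expected:
            raise ValueError(
                f"{self.mode} prompt must contain {expected} example "
                f"exchanges, found {n_examples}"
            )

    def render(self) -> str:
        return "\n".join(t.render() for t in self.turns)


def build_prompt(
    concept_name: str,
    mode: Mode,
    examples: Optional[Sequence[tuple[str, bool]]] = None,
    query_text: str = "",
    concept_id: str = "",
) -> Prompt:
    """Assemble the dialogue for one query.

    ``examples`` are (text, is_positive) pairs; few-shot mode requires
    exactly 2 positive and 2 negative, laid out positive / negative /
    positive / negative with Model answers "Yes." / "No.". The query is
    the final, unanswered User turn.
    """
    turns = [DialogueTurn("System", SYSTEM_TEMPLATE.format(concept=concept_name))]
    if mode == "few_shot":
        examples = list(examples or [])
        pos = [t for t, y in examples if y]
        neg = [t for t, y in examples if not y]
        if len(pos) != 2 or len(neg) != 2:
            raise ValueError(
                f"few_shot needs exactly 2 positive and 2 negative examples, "
                f"got {len(pos)} positive / {len(neg)} negative"
            )
        for text, answer in ((pos[0], "Yes."), (neg[0], "No."),
                             (pos[1], "Yes."), (neg[1], "No.")):
            turns.append(DialogueTurn("User", text))
            turns.append(DialogueTurn("Model", answer))
    elif mode != "zero_shot":
        raise ValueError(f"unknown prompt mode {mode!r}")
    turns.append(DialogueTurn("User", query_text))
    return Prompt(concept_id=concept_id or concept_name, mode=mode, turns=turns)


def eligible_concepts(
    ontology: Ontology,
    train_set: Sequence[tuple[str, SequenceLabels | set]],
    min_positives: int = 2,
) -> list[str]:
    """Concepts that can be prompted for.

    The candidate pool is the binary-concept universe minus the three
    exercise-description concepts (the numeric categories are already
    structurally absent from that universe); concepts with fewer than
    ``min_positives`` positive training sequences are then dropped,
    since a few-shot prompt cannot be assembled for them.
    """
    counts: dict[str, int] = {}
    for _, lab in train_set:
        binary = lab.binary if isinstance(lab, SequenceLabels) else lab
        for cid in binary:
            counts[cid] = counts.get(cid, 0) + 1
    return [
        cid
        for cid in ontology.binary_concept_ids
        if cid not in EXCLUDED_DESCRIPTION_CONCEPTS
        and counts.get(cid, 0) >= min_positives
    ]


def select_examples(
    train_set: Sequence[tuple[str, SequenceLabels | set]],
    concept_id: str,
    rng_seed: int = 0,
) -> list[tuple[str, bool]]:
    """Deterministically sample 2 positive and 2 negative example texts."""
    pos, neg = [], []
    for text, lab in train_set:
        binary = lab.binary if isinstance(lab, SequenceLabels) else lab
        (pos if concept_id in binary else neg).append(text)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError(
            f"concept {concept_id!r} is ineligible: {len(pos)} positive / "
            f"{len(neg)} negative training sequences (need 2 of each)"
        )
    rng = random.Random(rng_seed)
    chosen_pos = rng.sample(pos, 2)
    chosen_neg = rng.sample(neg, 2)
    return [(chosen_pos[0], True), (chosen_neg[0], False),
            (chosen_pos[1], True), (chosen_neg[1], False)]


Indeterminate = object()


def parse_response(text: str):
    """Leading yes -> True, leading no -> False, else ``Indeterminate``.

    Case-insensitive; punctuation after the word is ignored. Indeterminate
    replies are scored as negative downstream but preserved for audit.
    """
    word = text.strip().split()[0].strip(".,!:;\"'").lower() if text.strip() else ""
    if word == "yes":
        return True
    if word == "no":
        return False
    return Indeterminate


class Backend(Protocol):
    def send(self, turns: Sequence[DialogueTurn]) -> str: ...


class KeywordMockBackend:
    """Deterministic offline stand-in: answers Yes when any keyword for
    the prompted concept occurs in the final User turn.

    The concept is recovered from the System turn (the template embeds
    the concept display name)."""

    def __init__(self, keyword_table: dict[str, list[str]]):
        self.keyword_table = keyword_table

    def send(self, turns: Sequence[DialogueTurn]) -> str:
        system = turns[0].text
        query = turns[-1].text.lower()
        for name, keywords in self.keyword_table.items():
            if name in system:
                hit = any(k.lower() in query for k in keywords)
                return "Yes." if hit else "No."
        return "No."


class CallableBackend:
    """Adapter for tests: wraps any (turns -> str) callable."""

    def __init__(self, fn: Callable[[Sequence[DialogueTurn]], str]):
        self.fn = fn

    def send(self, turns: Sequence[DialogueTurn]) -> str:
        return self.fn(turns)


class ChatCompletionHTTPBackend:
    """Generic chat-completion endpoint adapter (OpenAI-style JSON).

    Maps System/User/Model roles onto system/user/assistant messages.
    Live network calls never run in the test suite.
    """

    def __init__(self, url: str, api_key: str = "", model: str = "",
                 timeout: float = 30.0):
        self.url = url
        self.api_key = api_key
        self.model = model
        self.timeout = timeout

    def send(self, turns: Sequence[DialogueTurn]) -> str:
        role_map = {"System": "system", "User": "user", "Model": "assistant"}
        payload = {
            "model": self.model,
            "messages": [
                {"role": role_map[t.role], "content": t.text} for t in turns
            ],
        }
        req = urllib.request.Request(
            self.url,
            data=json.dumps(payload).encode(),
            headers={
                "Content-Type": "application/json",
                **({"Authorization": f"Bearer {self.api_key}"} if self.api_key else {}),
            },
        )
        with urllib.request.urlopen(req, timeout=self.timeout) as resp:
            body = json.loads(resp.read().decode())
        return body["choices"][0]["message"]["content"]


@dataclass
class ClassificationRecord:
    concept_id: str
    query_text: str
    prediction: Optional[bool]
    raw_response: Optional[str] = None
    indeterminate: bool = False
    error: Optional[str] = None


def classify_with_backend(
    prompts: Sequence[Prompt],
    backend: Backend,
    max_retries: int = 2,
    retry_wait: float = 0.0,
) -> list[ClassificationRecord]:
    """Send every prompt; one record per prompt, errors included.

    Indeterminate replies are scored as negative (conservative) and
    flagged; backend failures are retried and, if persistent, recorded
    as per-item errors without aborting the run.
    """
    records = []
    for prompt in prompts:
        query = prompt.turns[-1].text
        raw = None
        err = None
        for attempt in range(max_retries + 1):
            try:
                raw = backend.send(prompt.turns)
                err = None
                break
            except Exception as exc:  # noqa: BLE001 - per-item error contract
                err = f"{type(exc).__name__}: {exc}"
                if retry_wait and attempt < max_retries:
                    time.sleep(retry_wait)
        if err is not None:
            records.append(
                ClassificationRecord(prompt.concept_id, query, None, error=err)
            )
            continue
        parsed = parse_response(raw)
        if parsed is Indeterminate:
            logger.info(
                "indeterminate reply for %s: %r", prompt.concept_id, raw
            )
            records.append(
                ClassificationRecord(
                    prompt.concept_id, query, False, raw, indeterminate=True
                )
            )
        else:
            records.append(
                ClassificationRecord(prompt.concept_id, query, bool(parsed), raw)
            )
    return records
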