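"""Scoring predictions against gold at sequence, span and numeric levels,
plus interannotator agreement and the stratified train/test split.

Conventions: precision (or recall) is 0 when its denominator is 0, and
F1 is 0 when P+R is 0. Concepts absent from both gold and predictions
are dropped; macro averages run over concepts whose gold support meets
``min_support`` (default 10, mirroring the omission of sparse concepts
from reported results).
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence, TypeVar, Union

import numpy as np
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss_kappa

from .standoff import AnnotatedSection

T = TypeVar("T")

LabelSets = Mapping[str, set]  # sequence id -> set of concept ids
DEFAULT_MIN_SUPPORT = 10


@dataclass
class ConceptScore:
    concept_id: str
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def support(self) -> int:
        return self.tp + self.fn

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


@dataclass
class EvalReport:
    """Per-concept confusion counts and P/R/F1 with macro averages."""

    level: str
    scores: dict[str, ConceptScore]
    min_support: int = DEFAULT_MIN_SUPPORT

    @property
    def reported_concepts(self) -> list[str]:
        return sorted(
            c for c, s in self.scores.items() if s.support >= self.min_support
        )

    def _macro(self, attr: str) -> float:
        cs = self.reported_concepts
        if not cs:
            return float("nan")
        return float(np.mean([getattr(self.scores[c], attr) for c in cs]))

    @property
    def macro_precision(self) -> float:
        return self._macro("precision")

    @property
    def macro_recall(self) -> float:
        return self._macro("recall")

    @property
    def macro_f1(self) -> float:
        return self._macro("f1")

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "concept": cid,
                "tp": s.tp, "fp": s.fp, "fn": s.fn, "tn": s.tn,
                "support": s.support,
                "precision": s.precision, "recall": s.recall, "f1": s.f1,
            }
            for cid, s in sorted(self.scores.items())
        ]
        return pd.DataFrame(rows)


def _as_label_sets(obj: Union[LabelSets, Sequence[AnnotatedSection]]) -> dict[str, set]:
    if isinstance(obj, Mapping):
        return {k: set(v) for k, v in obj.items()}
    out: dict[str, set] = {}
    for sec in obj:
        for seq in sec.sequences:
            out[seq.labels.sequence_ref] = set(seq.labels.binary)
    return out


def sequence_metrics(
    pred: Union[LabelSets, Sequence[AnnotatedSection]],
    gold: Union[LabelSets, Sequence[AnnotatedSection]],
    min_support: int = DEFAULT_MIN_SUPPORT,
    concepts: Optional[Sequence[str]] = None,
) -> EvalReport:
    """Per-concept binary P/R/F1 over sequences.

    ``pred`` and ``gold`` must cover the same sequence ids; a mismatch is
    an error listing the orphan ids on each side.
    """
    p = _as_label_sets(pred)
    g = _as_label_sets(gold)
    if p.keys() != g.keys():
        only_p = sorted(p.keys() - g.keys())[:10]
        only_g = sorted(g.keys() - p.keys())[:10]
        raise ValueError(
            f"sequence id mismatch; only in pred: {only_p}, only in gold: {only_g}"
        )
    universe = (
        list(concepts)
        if concepts is not None
        else sorted(set().union(*p.values(), *g.values()) if p else set())
    )
    n = len(g)
    scores: dict[str, ConceptScore] = {}
    for cid in universe:
        s = ConceptScore(cid)
        for sid in g:
            in_p, in_g = cid in p[sid], cid in g[sid]
            if in_p and in_g:
                s.tp += 1
            elif in_p:
                s.fp += 1
            elif in_g:
                s.fn += 1
        s.tn = n - s.tp - s.fp - s.fn
        if concepts is not None or s.tp + s.fp + s.fn > 0:
            scores[cid] = s
    return EvalReport(level="sequence", scores=scores, min_support=min_support)


MatchMode = Literal["exact", "overlap"]


def span_metrics(
    pred: Sequence[AnnotatedSection],
    gold: Sequence[AnnotatedSection],
    match_mode: Optional[MatchMode] = None,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> dict[str, EvalReport]:
    """NER-level scoring of mention spans.

    A predicted mention is a true positive when a gold mention of the
    same concept in the same sequence corresponds under the match mode
    (exact span equality, or any character overlap) — matched greedily
    one-to-one in span order. Both modes are returned unless one is
    requested.
    """
    modes = [match_mode] if match_mode else ["exact", "overlap"]
    gold_by_seq: dict[str, list] = {}
    for sec in gold:
        for seq in sec.sequences:
            for (s, e), cid in seq.mentions:
                if not 0 <= s < e:
                    raise ValueError(f"invalid gold span ({s},{e}) for {cid}")
                gold_by_seq.setdefault(seq.labels.sequence_ref, []).append((s, e, cid))
    pred_by_seq: dict[str, list] = {}
    for sec in pred:
        for seq in sec.sequences:
            for (s, e), cid in seq.mentions:
                if not 0 <= s < e:
                    raise ValueError(f"invalid predicted span ({s},{e}) for {cid}")
                pred_by_seq.setdefault(seq.labels.sequence_ref, []).append((s, e, cid))

    out = {}
    for mode in modes:
        scores: dict[str, ConceptScore] = {}

        def sc(cid: str) -> ConceptScore:
            return scores.setdefault(cid, ConceptScore(cid))

        for sid in set(gold_by_seq) | set(pred_by_seq):
            gold_ms = sorted(gold_by_seq.get(sid, []))
            pred_ms = sorted(pred_by_seq.get(sid, []))
            used: set[int] = set()
            for ps, pe, pc in pred_ms:
                hit = None
                for j, (gs, ge, gc) in enumerate(gold_ms):
                    if j in used or gc != pc:
                        continue
                    if mode == "exact" and (ps, pe) == (gs, ge):
                        hit = j
                        break
                    if mode == "overlap" and ps < ge and gs < pe:
                        hit = j
                        break
                if hit is None:
                    sc(pc).fp += 1
                else:
                    used.add(hit)
                    sc(pc).tp += 1
            for j, (gs, ge, gc) in enumerate(gold_ms):
                if j not in used:
                    sc(gc).fn += 1
        out[mode] = EvalReport(level=f"span:{mode}", scores=scores,
                               min_support=min_support)
    return out


def numeric_metrics(
    pred: Sequence[AnnotatedSection],
    gold: Sequence[AnnotatedSection],
) -> dict[str, ConceptScore]:
    """Per-kind P/R/F1 on duration/sets/reps values.

    A prediction is a true positive iff its kind and integer value both
    match a gold finding of the same sequence (multiset matching; values
    must already be unit-normalized, i.e. durations in seconds).
    """
    kinds = ("duration_seconds", "sets", "reps")

    def values(secs: Sequence[AnnotatedSection]) -> dict[str, dict[str, list[int]]]:
        out: dict[str, dict[str, list[int]]] = {k: {} for k in kinds}
        for sec in secs:
            for seq in sec.sequences:
                for k in kinds:
                    v = getattr(seq.labels, k)
                    if v is not None:
                        out[k].setdefault(seq.labels.sequence_ref, []).append(int(v))
        return out

    gv, pv = values(gold), values(pred)
    scores = {}
    for k in kinds:
        s = ConceptScore(k)
        for sid in set(gv[k]) | set(pv[k]):
            g = list(gv[k].get(sid, []))
            for v in pv[k].get(sid, []):
                if v in g:
                    g.remove(v)
                    s.tp += 1
                else:
                    s.fp += 1
            s.fn += len(g)
        scores[k] = s
    return scores


class DegenerateAgreementError(ValueError):
    """All ratings fall in one category: kappa is undefined (0/0)."""


def fleiss_kappa(matrix) -> float:
    """Fleiss' kappa for an items x categories table of rating counts.

    Requires >=2 ratings per item with identical totals across items.
    Raises :class:`DegenerateAgreementError` when every rating uses the
    same category (chance agreement is 1, kappa is 0/0).
    """
    table = np.asarray(matrix, dtype=float)
    if table.ndim != 2 or table.shape[0] < 1 or table.shape[1] < 2:
        raise ValueError("need an items x categories matrix with >=2 categories")
    m = table.sum(axis=1)
    if not np.all(m == m[0]) or m[0] < 2:
        raise ValueError("each item needs the same number (>=2) of ratings")
    if np.count_nonzero(table.sum(axis=0)) < 2:
        raise DegenerateAgreementError(
            "all ratings use a single category; kappa is undefined"
        )
    return float(_sm_fleiss_kappa(table, method="fleiss"))


def split_train_test(
    enriched: Sequence[T],
    random_sections: Sequence[T],
    n_train_per_stratum: int = 125,
    rng_seed: int = 0,
    expected_stratum_size: int = 150,
) -> tuple[list[T], list[T]]:
    """Stratified random split: a fixed number of sections per stratum to
    train, the remainder to test (125 of 150 per stratum by default, i.e.
    a 5:1 train:test ratio).

    When a stratum is smaller than requested the split falls back to the
    same 5:1 proportion (with a warning)."""
    rng = random.Random(rng_seed)
    train: list[T] = []
    test: list[T] = []
    for stratum in (list(enriched), list(random_sections)):
        n = n_train_per_stratum
        if len(stratum) < n_train_per_stratum:
            frac = min(n_train_per_stratum / expected_stratum_size, 1.0)
            n = round(len(stratum) * frac)
            warnings.warn(
                f"stratum of {len(stratum)} sections is smaller than "
                f"{n_train_per_stratum}; falling back to a proportional "
                f"split ({n} to train)",
                stacklevel=2,
            )
        idx = list(range(len(stratum)))
        rng.shuffle(idx)
        train += [stratum[i] for i in sorted(idx[:n])]
        test += [stratum[i] for i in sorted(idx[n:])]
    return train, test
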