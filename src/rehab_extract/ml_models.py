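"""Per-concept binary classifiers over an uncased bag-of-words space.

One independent model per (family, concept): logistic regression,
degree-2 polynomial SVM, AdaBoost (100 estimators) and gradient boosting
(50 estimators), each predicting whether its concept is mentioned at
least once in an exercise sequence. Features are raw token counts from a
vocabulary fitted on the training texts only; tokens are maximal
alphanumeric runs, so dosage compounds like ``2x10`` survive as single
tokens. Concepts whose training labels are single-class cannot be fitted
and are recorded as skipped (their bank predictions fall back to the
constant observed class).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import joblib
import numpy as np
from sklearn.ensemble import AdaBoostClassifier, GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.svm import SVC

from .ontology import Ontology
from .rule_extractor import SequenceLabels

FAMILIES = ("lr", "svm", "ada", "gb")

_TOKEN_PATTERN = r"[A-Za-z0-9]+"


class DegenerateLabelsError(ValueError):
    """Training labels contain a single class."""


def make_estimator(family: str, random_state: Optional[int] = 0, **overrides):
    """Reference estimator for a family.

    lr: balanced class weights, tol=1e-4 (the stated learning rate has no
    logistic-regression counterpart here and is read as the convergence
    tolerance). svm: polynomial kernel of degree 2, balanced class
    weights. ada: 100 estimators. gb: 50 estimators. Everything else at
    library defaults; ``overrides`` are passed through.
    """
    if family == "lr":
        params = {"class_weight": "balanced", "tol": 1e-4}
    elif family == "svm":
        params = {"kernel": "poly", "degree": 2, "class_weight": "balanced"}
    elif family == "ada":
        params = {"n_estimators": 100, "random_state": random_state}
    elif family == "gb":
        params = {"n_estimators": 50, "random_state": random_state}
    else:
        raise ValueError(f"unknown model family {family!r}; expected one of {FAMILIES}")
    params.update(overrides)
    cls = {
        "lr": LogisticRegression,
        "svm": SVC,
        "ada": AdaBoostClassifier,
        "gb": GradientBoostingClassifier,
    }[family]
    return cls(**params)


@dataclass
class BowVocabulary:
    """Uncased bag-of-words vocabulary fitted on training texts only."""

    vectorizer: CountVectorizer

    @classmethod
    def fit(cls, train_texts: Sequence[str]) -> "BowVocabulary":
        if not list(train_texts):
            raise ValueError("cannot fit a vocabulary on an empty corpus")
        vec = CountVectorizer(lowercase=True, token_pattern=_TOKEN_PATTERN)
        try:
            vec.fit(train_texts)
        except ValueError as exc:  # only stop-words / empty tokens
            raise ValueError(f"cannot fit vocabulary: {exc}") from exc
        return cls(vec)

    @property
    def tokens(self) -> dict[str, int]:
        return self.vectorizer.vocabulary_

    def __len__(self) -> int:
        return len(self.vectorizer.vocabulary_)

    def transform(self, texts: Sequence[str]):
        return self.vectorizer.transform(texts)

    def content_hash(self) -> str:
        items = sorted(self.tokens.items(), key=lambda kv: kv[1])
        return hashlib.sha256(json.dumps(items).encode()).hexdigest()[:16]


def fit_vocabulary(train_texts: Sequence[str]) -> BowVocabulary:
    return BowVocabulary.fit(train_texts)


@dataclass
class ConceptModel:
    """A fitted (concept, family) classifier."""

    concept_id: str
    family: str
    estimator: object
    hyperparameters: dict = field(default_factory=dict)
    fitted: bool = False
    constant: Optional[int] = None  # set instead of estimator when skipped

    def predict(self, X) -> np.ndarray:
        if self.constant is not None:
            return np.full(X.shape[0], self.constant, dtype=int)
        if not self.fitted:
            raise RuntimeError(
                f"model ({self.family}, {self.concept_id}) is not fitted"
            )
        return np.asarray(self.estimator.predict(X)).astype(int)


def train(
    vocab: BowVocabulary,
    X_texts: Sequence[str],
    y: Sequence[int],
    family: str,
    concept_id: str = "",
    random_state: Optional[int] = 0,
    allow_constant: bool = False,
    **hyperparameters,
) -> ConceptModel:
    """Fit one per-concept model. Single-class ``y`` raises unless
    ``allow_constant`` asks for an explicit constant predictor."""
    y = np.asarray(list(y), dtype=int)
    if len(y) != len(list(X_texts)):
        raise ValueError("X and y lengths differ")
    classes = np.unique(y)
    if classes.size < 2:
        if allow_constant:
            value = int(classes[0]) if classes.size else 0
            return ConceptModel(concept_id, family, None, constant=value)
        raise DegenerateLabelsError(
            f"labels for {concept_id or 'concept'} are single-class "
            f"({classes.tolist()}); cannot fit {family}"
        )
    est = make_estimator(family, random_state=random_state, **hyperparameters)
    est.fit(vocab.transform(X_texts), y)
    return ConceptModel(
        concept_id, family, est, hyperparameters=dict(hyperparameters), fitted=True
    )


@dataclass
class ModelBank:
    """All (family, concept) slots plus the shared vocabulary."""

    vocab: BowVocabulary
    slots: dict[str, dict[str, ConceptModel]]
    skipped: dict[tuple[str, str], str] = field(default_factory=dict)

    def n_slots(self, family: str) -> int:
        return len(self.slots[family])

    def predict(
        self, texts: Sequence[str], families: Optional[Iterable[str]] = None
    ) -> dict[str, dict[str, np.ndarray]]:
        """{family: {concept: 0/1 vector over texts}}; deterministic."""
        X = self.vocab.transform(texts)
        out: dict[str, dict[str, np.ndarray]] = {}
        for fam in families or self.slots:
            out[fam] = {cid: m.predict(X) for cid, m in self.slots[fam].items()}
        return out

    # -- serialization ---------------------------------------------------
    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = {
            "vocabulary_hash": self.vocab.content_hash(),
            "families": {
                fam: {
                    cid: {
                        "fitted": m.fitted,
                        "constant": m.constant,
                        "hyperparameters": m.hyperparameters,
                    }
                    for cid, m in models.items()
                }
                for fam, models in self.slots.items()
            },
            "skipped": [
                {"family": f, "concept": c, "reason": r}
                for (f, c), r in self.skipped.items()
            ],
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        joblib.dump(self, out_dir / "bank.joblib")

    @classmethod
    def load(cls, out_dir: str | Path) -> "ModelBank":
        return joblib.load(Path(out_dir) / "bank.joblib")


def _binary_targets(
    labels: Sequence[SequenceLabels | set], concept_id: str
) -> np.ndarray:
    out = []
    for lab in labels:
        binary = lab.binary if isinstance(lab, SequenceLabels) else lab
        out.append(1 if concept_id in binary else 0)
    return np.asarray(out, dtype=int)


def train_all(
    train_set: Sequence[tuple[str, SequenceLabels | set]],
    ontology: Ontology,
    families: Iterable[str] = FAMILIES,
    concepts: Optional[Sequence[str]] = None,
    random_state: Optional[int] = 0,
) -> ModelBank:
    """One model slot per (family, binary concept).

    Numeric categories are structurally excluded — the concept universe
    is the ontology's 101 binary concepts (or a subset via ``concepts``).
    Slots whose training labels are single-class are recorded as skipped,
    with a constant fallback predictor.
    """
    data = list(train_set)
    if not data:
        raise ValueError("empty training set")
    universe = ontology.binary_concept_ids
    if concepts is not None:
        unknown = sorted(set(concepts) - set(universe))
        if unknown:
            raise ValueError(
                f"not binary-classifiable concepts (numeric or unknown): {unknown}"
            )
        universe = list(concepts)
    texts = [t for t, _ in data]
    labels = [l for _, l in data]
    vocab = fit_vocabulary(texts)
    X = vocab.transform(texts)

    bank = ModelBank(vocab=vocab, slots={f: {} for f in families})
    for fam in bank.slots:
        if fam not in FAMILIES:
            raise ValueError(f"unknown model family {fam!r}")
        for cid in universe:
            y = _binary_targets(labels, cid)
            classes = np.unique(y)
            if classes.size < 2:
                bank.slots[fam][cid] = ConceptModel(
                    cid, fam, None, constant=int(classes[0])
                )
                bank.skipped[(fam, cid)] = (
                    f"single-class training labels (all {int(classes[0])})"
                )
                continue
            est = make_estimator(fam, random_state=random_state)
            est.fit(X, y)
            bank.slots[fam][cid] = ConceptModel(cid, fam, est, fitted=True)
    return bank
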