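"""Sentence-level interest-group classification and its evaluation.

Every sentence is assigned to exactly one of five mutually exclusive
interest groups — patient (PA), caregiver (CG), patient's association
(PAA), scientific/medical community (SC), or other (O) — by a few-shot
classifier: sentence embeddings feed a multinomial logistic-regression
head. The production embedding is a contrastively fine-tuned sentence
transformer; the reference path embeds with the deterministic hashing
embedder and trains only the head, so the suite runs offline. A seeded
contrastive adaptation step can be plugged in through the ``adapter`` hook.

Because perspectives shift within a post, post-level output is multi-label:
the union of the non-O sentence labels, or {O} when no sentence is
informative.
"""

from __future__ import annotations

from collections import Counter
from typing import Callable, Iterable, Sequence

import numpy as np
from pydantic import BaseModel
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from .backends import Embedder, HashingEmbedder, embed_sentences
from .errors import ConfigurationError

PA, CG, PAA, SC, O = "PA", "CG", "PAA", "SC", "O"
#: Fixed label order: also the tie-break order for equal probabilities.
LABELS = (PA, CG, PAA, SC, O)


class InterestGroupClassifier(BaseEstimator, ClassifierMixin):
    """Few-shot sentence classifier: embeddings + multinomial linear head.

    Parameters
    ----------
    embedder:
        Embedding backend; defaults to the deterministic hashing embedder.
    adapter:
        Optional contrastive-adaptation hook ``(embedder, texts, labels,
        random_state) -> Embedder`` run before head training (the Siamese
        fine-tuning step of the production path); skipped when ``None``.
    random_state:
        Seed for the head (and the adapter); fixed seed + reference
        embedder => deterministic predictions.

    Attributes
    ----------
    classes_ : labels seen during fit, in the fixed canonical order.
    head_ : the fitted logistic-regression head.
    """

    def __init__(
        self,
        embedder: Embedder | None = None,
        adapter: Callable | None = None,
        random_state: int = 0,
        max_iter: int = 1000,
    ):
        self.embedder = embedder
        self.adapter = adapter
        self.random_state = random_state
        self.max_iter = max_iter

    def _effective_embedder(self) -> Embedder:
        return self.embedder if self.embedder is not None else HashingEmbedder()

    def fit(self, X: Sequence[str], y: Sequence[str]):
        X, y = list(X), list(y)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if len(X) == 0:
            raise ConfigurationError("empty training set")
        unknown = set(y) - set(LABELS)
        if unknown:
            raise ConfigurationError(f"unknown labels: {sorted(unknown)}")
        if len(set(y)) < 2:
            raise ConfigurationError("training set must contain at least two labels")
        embedder = self._effective_embedder()
        if self.adapter is not None:
            embedder = self.adapter(embedder, X, y, self.random_state)
        self.embedder_ = embedder
        self.classes_ = np.array([l for l in LABELS if l in set(y)])
        self.head_ = LogisticRegression(
            max_iter=self.max_iter, random_state=self.random_state
        )
        self.head_.fit(embed_sentences(X, embedder), y)
        return self

    def predict_proba(self, X: Sequence[str]) -> np.ndarray:
        """Probabilities over ``classes_`` (canonical order); rows sum to 1."""
        check_is_fitted(self, "head_")
        raw = self.head_.predict_proba(embed_sentences(list(X), self.embedder_))
        order = [list(self.head_.classes_).index(c) for c in self.classes_]
        return raw[:, order]

    def predict(self, X: Sequence[str]) -> np.ndarray:
        """Argmax label; probability ties break by canonical label order."""
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]


def predict_interest_group(
    text: str, model: InterestGroupClassifier
) -> tuple[str, np.ndarray]:
    """Label one sentence; returns (label, probability vector over classes_)."""
    proba = model.predict_proba([text])[0]
    return str(model.classes_[int(np.argmax(proba))]), proba


def train_classifier(
    texts: Sequence[str],
    labels: Sequence[str],
    embedder: Embedder | None = None,
    seed: int = 0,
    adapter: Callable | None = None,
) -> InterestGroupClassifier:
    """Thin functional wrapper over :class:`InterestGroupClassifier`."""
    return InterestGroupClassifier(
        embedder=embedder, adapter=adapter, random_state=seed
    ).fit(texts, labels)


def aggregate_post_labels(sentence_labels: Iterable[str]) -> set[str]:
    """Multi-label post aggregation: union of non-O labels; {O} iff all O."""
    labels = list(sentence_labels)
    if not labels:
        return set()
    informative = {l for l in labels if l != O}
    return informative if informative else {O}


def stratified_split(
    texts: Sequence[str],
    labels: Sequence[str],
    seed: int = 0,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
):
    """Reproducible class-proportional 60/20/20 train/validation/test split."""
    f_train, f_val, f_test = fractions
    idx = np.arange(len(texts))
    train_idx, rest_idx = train_test_split(
        idx, test_size=f_val + f_test, random_state=seed, stratify=np.asarray(labels)
    )
    rest_labels = np.asarray(labels)[rest_idx]
    val_idx, test_idx = train_test_split(
        rest_idx,
        test_size=f_test / (f_val + f_test),
        random_state=seed,
        stratify=rest_labels,
    )
    return train_idx, val_idx, test_idx


class EvalReport(BaseModel):
    """Per-label and averaged classification metrics on the percent scale."""

    labels: list[str]
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    support: dict[str, int]
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float


def evaluate_classifier(gold: Sequence[str], predicted: Sequence[str]) -> EvalReport:
    """Standard per-label precision/recall/F1 (percent scale).

    Macro averages are unweighted means over labels with nonzero gold
    support; weighted averages use support weights; accuracy is the fraction
    correct x 100.
    """
    gold, predicted = list(gold), list(predicted)
    if len(gold) != len(predicted):
        raise ValueError("gold and predicted lengths differ")
    if not gold:
        raise ValueError("empty evaluation set")
    labels = [l for l in LABELS if l in set(gold) | set(predicted)]
    p, r, f, s = precision_recall_fscore_support(
        gold, predicted, labels=labels, zero_division=0
    )
    support = {l: int(n) for l, n in zip(labels, s)}
    supported = [i for i, l in enumerate(labels) if support[l] > 0]
    weights = np.array([s[i] for i in supported], dtype=float)
    weights /= weights.sum()

    def pct(x) -> float:
        return float(x) * 100.0

    return EvalReport(
        labels=labels,
        precision={l: pct(v) for l, v in zip(labels, p)},
        recall={l: pct(v) for l, v in zip(labels, r)},
        f1={l: pct(v) for l, v in zip(labels, f)},
        support=support,
        accuracy=pct(np.mean(np.asarray(gold) == np.asarray(predicted))),
        macro_precision=pct(np.mean([p[i] for i in supported])),
        macro_recall=pct(np.mean([r[i] for i in supported])),
        macro_f1=pct(np.mean([f[i] for i in supported])),
        weighted_precision=pct(np.dot(weights, [p[i] for i in supported])),
        weighted_recall=pct(np.dot(weights, [r[i] for i in supported])),
        weighted_f1=pct(np.dot(weights, [f[i] for i in supported])),
    )
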