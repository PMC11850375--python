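"""Model contracts and deterministic reference implementations.

Every learned step in the pipeline hides behind one of three small contracts:

* :class:`EntailmentScorer` — given a premise and a hypothesis, return a
  single entailment probability in [0, 1] (entailment-vs-rest; the pipeline
  treats inference as a binary decision);
* :class:`Answerer` — extractive question answering over a sentence context;
* :class:`Embedder` — fixed-dimension sentence embeddings.

The reference implementations below are pure functions of their inputs and
dependency-free, so the whole pipeline is testable offline. Transformer-backed
adapters plug in through the same interfaces via :func:`register_backend`;
swapping one in changes scores, never interfaces.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Protocol, Sequence, runtime_checkable

import numpy as np

from ._resources import read_text
from .errors import BackendError, ConfigurationError

# ---------------------------------------------------------------------------
# Contracts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnswerSpan:
    """An extractive answer: a contiguous substring of the context."""

    text: str
    start: int
    end: int
    confidence: float = 1.0


@runtime_checkable
class EntailmentScorer(Protocol):
    def score(self, premise: str, hypothesis: str) -> float: ...


@runtime_checkable
class Answerer(Protocol):
    def answer(self, question: str, context: str) -> AnswerSpan | None: ...


@runtime_checkable
class Embedder(Protocol):
    dimension: int

    def embed(self, texts: Sequence[str]) -> np.ndarray: ...


def score_entailment(premise: str, hypothesis: str, scorer: EntailmentScorer) -> float:
    """Score a (premise, hypothesis) pair, clamped to [0, 1]."""
    if not premise or not hypothesis:
        raise BackendError("premise and hypothesis must be non-empty")
    value = float(scorer.score(premise, hypothesis))
    if np.isnan(value):
        raise BackendError("scorer returned NaN")
    return min(1.0, max(0.0, value))


def extract_answer(question: str, context: str, answerer: Answerer) -> AnswerSpan | None:
    """Answer a question over a context; enforces the extractive guarantee."""
    span = answerer.answer(question, context)
    if span is None:
        return None
    if context[span.start : span.end] != span.text:
        raise BackendError("answerer violated the extractive guarantee")
    return span


def embed_sentences(texts: Sequence[str], embedder: Embedder) -> np.ndarray:
    """One vector per text, order preserved, constant dimension."""
    vectors = embedder.embed(list(texts))
    vectors = np.asarray(vectors, dtype=float)
    if len(texts) == 0:
        return vectors.reshape(0, embedder.dimension)
    if vectors.shape != (len(texts), embedder.dimension):
        raise BackendError(
            f"embedder returned shape {vectors.shape}, "
            f"expected {(len(texts), embedder.dimension)}"
        )
    return vectors


# ---------------------------------------------------------------------------
# Reference entailment scorer
# ---------------------------------------------------------------------------

#: Function words and slot placeholders excluded from content tokens.
STOPWORDS = frozenset(
    """a an the is are was were be been being am do does did has have had
    i you he she it we they my your his her its our their me him them us
    of in on at to for from with by about as into over after before and
    or but not no so that this these those there here then than
    someone something somebody anybody anything""".split()
)

_TOKEN_RE = re.compile(r"[a-z0-9][a-z0-9'-]*")


def content_tokens(text: str) -> list[str]:
    return [t for t in _TOKEN_RE.findall(text.lower()) if t not in STOPWORDS]


def stem(token: str) -> str:
    """Crude inflection stripper: 's, plural/3sg -s/-es, -ed, -ing."""
    if token.endswith("'s"):
        token = token[:-2]
    for suffix in ("ing", "ed", "es", "s"):
        if token.endswith(suffix) and len(token) - len(suffix) >= 3:
            return token[: len(token) - len(suffix)]
    return token


def _stems_match(a: str, b: str) -> bool:
    if a == b:
        return True
    shorter, longer = sorted((a, b), key=len)
    return len(shorter) >= 4 and longer.startswith(shorter)


class OverlapEntailmentScorer:
    """Normalized content-token overlap with an exact-phrase bonus.

    Documented formula (so tests can compute expected scores by hand):

    1. content tokens = lowercase word tokens minus stopwords and the slot
       placeholders *someone*/*something*; each token reduced to a crude stem;
    2. a hypothesis stem is *covered* when some premise stem equals it or one
       is a >= 4-character prefix of the other;
    3. base score = covered hypothesis stems / total hypothesis stems
       (0 when the hypothesis has no content tokens);
    4. +0.1 bonus when >= 2 consecutive hypothesis content tokens occur
       verbatim (case-insensitive) in the premise; clamped to [0, 1].

    A fixture-grade stand-in for a natural-language-inference model.
    """

    PHRASE_BONUS = 0.1

    def score(self, premise: str, hypothesis: str) -> float:
        hyp_tokens = content_tokens(hypothesis)
        if not hyp_tokens:
            return 0.0
        prem_stems = {stem(t) for t in content_tokens(premise)}
        covered = sum(
            1 for t in hyp_tokens if any(_stems_match(stem(t), p) for p in prem_stems)
        )
        score = covered / len(hyp_tokens)
        premise_lower = premise.lower()
        for n in range(len(hyp_tokens), 1, -1):
            for i in range(len(hyp_tokens) - n + 1):
                if " ".join(hyp_tokens[i : i + n]) in premise_lower:
                    return min(1.0, score + self.PHRASE_BONUS)
        return min(1.0, score)


# ---------------------------------------------------------------------------
# Reference answerer
# ---------------------------------------------------------------------------


class PatternAnswerer:
    """Pattern-table extractive answerer.

    Maps each known question to capture regexes (packaged table
    ``qa_patterns.tsv``); the first matching pattern wins. Adequate for
    fixtures, explicitly not for production quality.
    """

    def __init__(self, patterns: Iterable[tuple[str, str]] | None = None):
        if patterns is None:
            patterns = _load_qa_patterns()
        self._table: dict[str, list[re.Pattern]] = {}
        for question, regex in patterns:
            self._table.setdefault(question, []).append(
                re.compile(regex, re.IGNORECASE)
            )

    def answer(self, question: str, context: str) -> AnswerSpan | None:
        for pattern in self._table.get(question, []):
            m = pattern.search(context)
            if m:
                start, end = m.span("answer")
                return AnswerSpan(text=context[start:end], start=start, end=end)
        return None


def _load_qa_patterns() -> list[tuple[str, str]]:
    rows = []
    for line in read_text("qa_patterns.tsv").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        question, regex = line.split("\t", 1)
        rows.append((question, regex))
    return rows


# ---------------------------------------------------------------------------
# Reference embedder
# ---------------------------------------------------------------------------


class HashingEmbedder:
    """Seeded feature-hashing bag-of-words embedder (default dimension 256).

    Tokens are hashed (md5, salted with the seed) into a fixed-width vector
    with +/-1 signs, then L2-normalized. Fully deterministic across processes.
    """

    def __init__(self, dimension: int = 256, seed: int = 0):
        self.dimension = dimension
        self.seed = seed

    def _token_slot(self, token: str) -> tuple[int, int]:
        digest = hashlib.md5(f"{self.seed}:{token}".encode()).digest()
        idx = int.from_bytes(digest[:4], "little") % self.dimension
        sign = 1 if digest[4] % 2 == 0 else -1
        return idx, sign

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        out = np.zeros((len(texts), self.dimension))
        for row, text in enumerate(texts):
            for token in _TOKEN_RE.findall(text.lower()):
                idx, sign = self._token_slot(token)
                out[row, idx] += sign
            norm = np.linalg.norm(out[row])
            if norm > 0:
                out[row] /= norm
        return out


# ---------------------------------------------------------------------------
# Backend registry
# ---------------------------------------------------------------------------

_REGISTRY: dict[str, dict[str, Callable[[], object]]] = {
    "entailment": {"reference": OverlapEntailmentScorer},
    "qa": {"reference": PatternAnswerer},
    "embedding": {"reference": HashingEmbedder},
}


def register_backend(kind: str, name: str, factory: Callable[[], object]) -> None:
    """Register a backend factory under ``backends.<kind> = <name>``."""
    if kind not in _REGISTRY:
        raise ConfigurationError(f"unknown backend kind {kind!r}")
    _REGISTRY[kind][name] = factory


def resolve_backend(kind: str, name: str):
    try:
        factory = _REGISTRY[kind][name]
    except KeyError:
        raise ConfigurationError(f"no backend {name!r} registered for {kind!r}") from None
    return factory()
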