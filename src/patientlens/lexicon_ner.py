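"""Lexicon/ontology-based biomedical named entity recognition.

Primary biomedical entities — disease (DI), drug (DR), symptom (SY),
treatment (TR) — are found by case-insensitive, token-boundary-aligned
dictionary matching against concept lexicons extracted from ontologies.
Because ontology terms are largely unambiguous, matching is exact (no
stemming); precision is protected by three filters:

* per-source blacklists for overly broad terms ("group", "role",
  "application");
* dropping matches inside ORGANIZATION spans (disease names inside
  foundation names);
* dropping matches whose phrase head is not a noun or proper noun.

The latter two require annotator capabilities (organization spans,
part-of-speech); when the configured annotator lacks one, the filter is
skipped with a logged warning so the offline regex annotator still runs.

Terms occurring in both the disease and the symptom lexicon are resolved to
symptom: lay authors rarely draw the clinical distinction, and the ontology
overlap itself suggests the symptom reading.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Literal, Mapping, Sequence

from pydantic import BaseModel

from .corpus_io import Sentence
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

#: Primary concept type codes.
DI, DR, SY, TR = "DI", "DR", "SY", "TR"
PRIMARY_TYPES = (DI, DR, SY, TR)

#: Precedence when distinct concept types match the identical span
#: (the DI/SY overlap has its own rule and is handled separately).
DEFAULT_TYPE_PRECEDENCE = (DR, TR, DI, SY)

_WS = re.compile(r"\s+")
_TOKEN_RE = re.compile(r"\w+(?:['’-]\w+)*")


def normalize_term(term: str) -> str:
    """Casefold + internal-whitespace collapse; no stemming."""
    return _WS.sub(" ", term.casefold()).strip()


class LexiconEntry(BaseModel):
    term: str
    concept_type: Literal["DI", "DR", "SY", "TR"]
    canonical_id: str
    source: str


class EntityMention(BaseModel):
    """A typed, offset-anchored span within a sentence."""

    sentence_id: str
    concept_type: str
    surface: str
    start: int
    end: int
    canonical_id: str = ""
    source: str = ""

    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


# ---------------------------------------------------------------------------
# Token-annotation contract
# ---------------------------------------------------------------------------


@dataclass
class TokenAnnotation:
    """Token boundaries plus optional capabilities.

    ``pos`` holds one coarse tag per token (``NOUN``/``PROPN``/...);
    ``org_spans`` holds ORGANIZATION entity spans. Either may be ``None``
    when the annotator cannot provide it.
    """

    tokens: list[tuple[int, int]]
    pos: list[str] | None = None
    org_spans: list[tuple[int, int]] | None = None

    def head_index(self, first_token: int, last_token: int) -> int:
        """Head of a candidate phrase; English noun phrases are head-final."""
        return last_token


Annotator = Callable[[str], TokenAnnotation]


def regex_annotator(text: str) -> TokenAnnotation:
    """Reference annotator: regex tokenization only, no parses."""
    return TokenAnnotation(tokens=[m.span() for m in _TOKEN_RE.finditer(text)])


# ---------------------------------------------------------------------------
# Lexicons
# ---------------------------------------------------------------------------


@dataclass
class ConceptLexicon:
    """A term inventory with per-source blacklists.

    Lookup is case-insensitive; blacklisted terms are never matchable.
    """

    entries: list[LexiconEntry]
    blacklist: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index: dict[str, list[LexiconEntry]] = {}
        self._max_tokens = 0
        seen: set[tuple[str, str]] = set()
        for entry in self.entries:
            key = normalize_term(entry.term)
            if not key:
                raise ConfigurationError("empty lexicon term")
            if (key, entry.concept_type) in seen:
                continue
            seen.add((key, entry.concept_type))
            if key in self.blacklist.get(entry.source, set()):
                continue
            self._index.setdefault(key, []).append(entry)
            self._max_tokens = max(self._max_tokens, len(key.split(" ")))

    def lookup(self, normalized: str) -> list[LexiconEntry]:
        return self._index.get(normalized, [])

    @property
    def max_term_tokens(self) -> int:
        return self._max_tokens

    def overlap_terms(self) -> set[str]:
        """Normalized terms present in both the DI and the SY inventory."""
        by_type: dict[str, set[str]] = {}
        for key, entries in self._index.items():
            for e in entries:
                by_type.setdefault(e.concept_type, set()).add(key)
        return by_type.get(DI, set()) & by_type.get(SY, set())


def read_lexicon_dir(path: str | Path) -> ConceptLexicon:
    """Load every ``*.tsv`` lexicon and ``<source>.blacklist.txt`` in a directory."""
    path = Path(path)
    entries: list[LexiconEntry] = []
    blacklist: dict[str, set[str]] = {}
    for tsv in sorted(path.glob("*.tsv")):
        entries.extend(read_lexicon_tsv(tsv))
    for bl in sorted(path.glob("*.blacklist.txt")):
        source = bl.name[: -len(".blacklist.txt")]
        terms = {
            normalize_term(line)
            for line in bl.read_text(encoding="utf-8").splitlines()
            if line.strip()
        }
        blacklist[source] = terms
    return ConceptLexicon(entries=entries, blacklist=blacklist)


def read_lexicon_tsv(path: str | Path) -> list[LexiconEntry]:
    entries = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        term, concept_type, canonical_id, source = line.split("\t")
        entries.append(
            LexiconEntry(
                term=term, concept_type=concept_type,
                canonical_id=canonical_id, source=source,
            )
        )
    return entries


def fixture_lexicon() -> ConceptLexicon:
    """The packaged fixture lexicon (small stand-in term lists; the file
    formats, not these contents, are the contract)."""
    from ._resources import data_path

    return read_lexicon_dir(Path(str(data_path("fixture_lexicon"))))


# ---------------------------------------------------------------------------
# Treatment-lexicon compilation from a class hierarchy
# ---------------------------------------------------------------------------


@dataclass
class ClassHierarchy:
    """Child -> parent edge list with node labels; must be acyclic."""

    edges: list[tuple[str, str]]
    labels: dict[str, str]

    def __post_init__(self) -> None:
        self._children: dict[str, list[str]] = {}
        nodes = set()
        for child, parent in self.edges:
            self._children.setdefault(parent, []).append(child)
            nodes.update((child, parent))
        self.nodes = nodes
        self._assert_acyclic()
        missing = [n for n in sorted(nodes) if n not in self.labels]
        if missing:
            raise ConfigurationError(f"unlabeled hierarchy nodes: {missing}")

    def _assert_acyclic(self) -> None:
        WHITE, GRAY, BLACK = 0, 1, 2
        color = {n: 0 for n in self.nodes}

        def visit(node: str) -> None:
            color[node] = GRAY
            for child in self._children.get(node, []):
                if color[child] == GRAY:
                    raise ConfigurationError("hierarchy contains a cycle")
                if color[child] == WHITE:
                    visit(child)
            color[node] = BLACK

        for n in self.nodes:
            if color[n] == WHITE:
                visit(n)

    def descendants(self, root: str) -> set[str]:
        """Descendants of *root*, inclusive."""
        if root not in self.nodes:
            raise ConfigurationError(f"unknown hierarchy root {root!r}")
        seen = {root}
        stack = [root]
        while stack:
            for child in self._children.get(stack.pop(), []):
                if child not in seen:
                    seen.add(child)
                    stack.append(child)
        return seen


def read_hierarchy(edges_path: str | Path, labels_path: str | Path) -> ClassHierarchy:
    edges = []
    for line in Path(edges_path).read_text(encoding="utf-8").splitlines():
        if line.strip() and not line.startswith("#"):
            child, parent = line.split("\t")
            edges.append((child.strip(), parent.strip()))
    labels = {}
    for line in Path(labels_path).read_text(encoding="utf-8").splitlines():
        if line.strip() and not line.startswith("#"):
            node, label = line.split("\t")
            labels[node.strip()] = label.strip()
    return ClassHierarchy(edges=edges, labels=labels)


def compile_treatment_lexicon(
    hierarchy: ClassHierarchy,
    include_roots: Iterable[str],
    exclude_roots: Iterable[str] = (),
    source: str = "hierarchy",
) -> list[LexiconEntry]:
    """Terms under the include superclasses minus those under the exclude ones.

    Built for the treatment inventory: everything classified under *therapy*
    and *medical procedure*, excluding diagnostic superclasses (*health
    assessment*, *invasive test*, *medical diagnosis*, *medical test*).
    Exclusion wins when a node falls under both.
    """
    included: set[str] = set()
    for root in include_roots:
        included |= hierarchy.descendants(root)
    excluded: set[str] = set()
    for root in exclude_roots:
        excluded |= hierarchy.descendants(root)
    return [
        LexiconEntry(
            term=hierarchy.labels[node], concept_type=TR,
            canonical_id=node, source=source,
        )
        for node in sorted(included - excluded)
    ]


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------


def match_concepts(
    sentence: Sentence,
    lexicon: ConceptLexicon,
    annotator: Annotator = regex_annotator,
    type_precedence: Sequence[str] = DEFAULT_TYPE_PRECEDENCE,
) -> list[EntityMention]:
    """Find lexicon terms in a sentence.

    Matches are case-insensitive, token-boundary-aligned, and resolved
    leftmost-longest; the organization and head-noun filters run when the
    annotator provides the capability. Returned mentions never overlap.
    """
    text = sentence.text
    ann = annotator(text)
    candidates = _candidate_matches(text, ann, lexicon)
    candidates = _apply_filters(candidates, ann)
    resolved = _resolve_leftmost_longest(candidates, type_precedence)
    return [
        EntityMention(
            sentence_id=sentence.sentence_id,
            concept_type=entry.concept_type,
            surface=text[start:end],
            start=start,
            end=end,
            canonical_id=entry.canonical_id,
            source=entry.source,
        )
        for start, end, entry in resolved
    ]


def _candidate_matches(
    text: str, ann: TokenAnnotation, lexicon: ConceptLexicon
) -> list[tuple[int, int, int, int, LexiconEntry]]:
    """All (start, end, first_tok, last_tok, entry) token-aligned lexicon hits."""
    tokens = ann.tokens
    out = []
    for i in range(len(tokens)):
        for n in range(min(lexicon.max_term_tokens, len(tokens) - i), 0, -1):
            start, end = tokens[i][0], tokens[i + n - 1][1]
            # normalize the raw span: intervening punctuation blocks a match
            for entry in lexicon.lookup(normalize_term(text[start:end])):
                out.append((start, end, i, i + n - 1, entry))
    return out


_HEAD_POS = {"NOUN", "PROPN"}
_warned_capabilities: set[str] = set()


def _warn_once(capability: str) -> None:
    if capability not in _warned_capabilities:
        _warned_capabilities.add(capability)
        logger.warning("annotator provides no %s; filter skipped", capability)


def _apply_filters(candidates, ann: TokenAnnotation):
    if ann.org_spans is None:
        _warn_once("ORGANIZATION spans")
    else:
        candidates = [
            c for c in candidates
            if not any(os <= c[0] and c[1] <= oe for os, oe in ann.org_spans)
        ]
    if ann.pos is None:
        _warn_once("part-of-speech tags")
    else:
        candidates = [
            c for c in candidates
            if ann.pos[ann.head_index(c[2], c[3])] in _HEAD_POS
        ]
    return candidates


def _resolve_leftmost_longest(candidates, type_precedence: Sequence[str]):
    """Greedy leftmost-longest selection with type precedence on exact ties."""
    rank = {t: i for i, t in enumerate(type_precedence)}
    ordered = sorted(
        candidates,
        key=lambda c: (c[0], -c[1], rank.get(c[4].concept_type, len(rank)), c[4].canonical_id),
    )
    chosen: list[tuple[int, int, LexiconEntry]] = []
    last_end = 0
    for start, end, _i, _j, entry in ordered:
        if start >= last_end:
            chosen.append((start, end, entry))
            last_end = end
    return chosen


def resolve_disease_symptom_overlap(
    mentions: Iterable[EntityMention], overlap_terms: set[str]
) -> list[EntityMention]:
    """Relabel DI mentions whose term sits in both ontologies as SY."""
    out = []
    for m in mentions:
        if m.concept_type == DI and normalize_term(m.surface) in overlap_terms:
            m = m.model_copy(update={"concept_type": SY})
        out.append(m)
    return out
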