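"""Corpus ingestion: reading, deduplication, pseudonymization, sentence segmentation.

Every downstream analysis runs at the sentence level, so this module owns the
two canonical units — :class:`Post` (one social-media record) and
:class:`Sentence` (an offset-anchored span of a post) — and the cleaning steps
applied before any NLP: removal of reposted duplicates and replacement of
direct identifiers (person names by randomly generated equivalents, e-mail
addresses by a fixed placeholder).

Character offsets are 0-based half-open throughout the package.
"""

from __future__ import annotations

import datetime
import json
import logging
import random
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Literal, Sequence

from pydantic import BaseModel, Field, ValidationError

from ._resources import read_lines
from .errors import RecordError

logger = logging.getLogger(__name__)

EMAIL_PLACEHOLDER = "[EMAIL]"

#: Span detector contract: text -> list of (start, end) character spans.
SpanDetector = Callable[[str], "list[tuple[int, int]]"]

#: Sentence segmenter contract: text -> ordered, non-overlapping (start, end) spans.
Segmenter = Callable[[str], "list[tuple[int, int]]"]


class Post(BaseModel):
    """One social-media record."""

    post_id: str
    published_at: datetime.date
    text: str
    source: str = ""
    url: str = ""
    lang: str = "en"


class Sentence(BaseModel):
    """A sentence-level unit anchored into its post by character offsets."""

    post_id: str
    index: int = Field(ge=0)
    text: str
    start: int = Field(ge=0)
    end: int = Field(ge=0)

    @property
    def sentence_id(self) -> str:
        return f"{self.post_id}:{self.index}"


class Replacement(BaseModel):
    kind: Literal["person_name", "email"]
    original_span: tuple[int, int]
    replacement_text: str


class PseudonymizationReport(BaseModel):
    replacements: list[Replacement] = []
    seed: int = 0


# ---------------------------------------------------------------------------
# Reading and writing posts (JSONL, one object per line, ISO-8601 dates)
# ---------------------------------------------------------------------------

def read_posts(
    path: str | Path,
    on_error: Literal["skip", "abort"] = "skip",
    errors: list[RecordError] | None = None,
) -> list[Post]:
    """Read line-delimited posts, preserving file order.

    Malformed lines either abort the read or are skipped with a logged,
    line-numbered error (collected into *errors* when given).
    """
    posts: list[Post] = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                record = json.loads(line)
                posts.append(Post.model_validate(record))
            except (json.JSONDecodeError, ValidationError) as exc:
                err = RecordError(line_no, str(exc).splitlines()[0])
                if on_error == "abort":
                    raise err from exc
                logger.error("skipping malformed post record: %s", err)
                if errors is not None:
                    errors.append(err)
    return posts


def write_posts(posts: Iterable[Post], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for post in posts:
            fh.write(json.dumps(post.model_dump(mode="json"), ensure_ascii=False) + "\n")


def write_sentences(sentences: Iterable[Sentence], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sent in sentences:
            fh.write(json.dumps(sent.model_dump(mode="json"), ensure_ascii=False) + "\n")


def read_sentences(path: str | Path) -> list[Sentence]:
    with open(path, encoding="utf-8") as fh:
        return [Sentence.model_validate_json(line) for line in fh if line.strip()]


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------

_WS = re.compile(r"\s+")


def normalize_dedup_key(text: str) -> str:
    """Lowercase + whitespace-collapse; the content key for duplicate detection."""
    return _WS.sub(" ", text.lower()).strip()


def deduplicate_posts(posts: Sequence[Post]) -> list[Post]:
    """Keep one post per normalized-text key.

    The same content reposted under different URLs counts once; the earliest
    ``published_at`` survives, ties broken by ``post_id``. Survivors keep the
    relative order of their key's first appearance.
    """
    winners: dict[str, Post] = {}
    order: list[str] = []
    for post in posts:
        key = normalize_dedup_key(post.text)
        if key not in winners:
            winners[key] = post
            order.append(key)
        else:
            cur = winners[key]
            if (post.published_at, post.post_id) < (cur.published_at, cur.post_id):
                winners[key] = post
    return [winners[k] for k in order]


# ---------------------------------------------------------------------------
# Pseudonymization
# ---------------------------------------------------------------------------

_EMAIL_RE = re.compile(r"[A-Za-z0-9._%+-]+@[A-Za-z0-9-]+(?:\.[A-Za-z0-9-]+)*\.[A-Za-z]{2,}")
_NAME_CANDIDATE_RE = re.compile(r"\b([A-Z][a-z]+)(?: ([A-Z][a-z]+))?\b")


def detect_emails(text: str) -> list[tuple[int, int]]:
    return [m.span() for m in _EMAIL_RE.finditer(text)]


def default_name_detector(text: str) -> list[tuple[int, int]]:
    """Detect person names as capitalized tokens from the packaged name lists.

    A token-annotation stand-in for a model NER: a span is a name when it is a
    known first name, optionally followed by a capitalized surname. Precision
    over recall — unknown capitalized words (diseases, places) are left alone.
    """
    first = set(read_lines("first_names.txt"))
    spans: list[tuple[int, int]] = []
    for m in _NAME_CANDIDATE_RE.finditer(text):
        if m.group(1) in first:
            spans.append(m.span())
    return spans


def generate_name(rng: random.Random) -> str:
    return (
        rng.choice(read_lines("first_names.txt"))
        + " "
        + rng.choice(read_lines("last_names.txt"))
    )


def pseudonymize(
    text: str,
    seed: int = 0,
    name_detector: SpanDetector | None = None,
) -> tuple[str, PseudonymizationReport]:
    """Replace direct identifiers.

    Person names are replaced by randomly generated equivalents (random
    substitution, deterministic under *seed*); e-mail addresses by the literal
    placeholder ``[EMAIL]`` (tagging). Characters outside the reported spans
    are never touched.
    """
    rng = random.Random(seed)
    candidates: list[tuple[int, int, str]] = [
        (s, e, "email") for s, e in detect_emails(text)
    ]
    detector = name_detector if name_detector is not None else default_name_detector
    candidates += [(s, e, "person_name") for s, e in detector(text)]
    candidates.sort(key=lambda c: (c[0], -c[1]))

    accepted: list[tuple[int, int, str]] = []
    last_end = -1
    for s, e, kind in candidates:
        if s >= last_end:  # drop overlaps, earliest span wins
            accepted.append((s, e, kind))
            last_end = e

    replacements: list[Replacement] = []
    pieces: list[str] = []
    cursor = 0
    for s, e, kind in accepted:
        repl = EMAIL_PLACEHOLDER if kind == "email" else generate_name(rng)
        pieces.append(text[cursor:s])
        pieces.append(repl)
        cursor = e
        replacements.append(
            Replacement(kind=kind, original_span=(s, e), replacement_text=repl)
        )
    pieces.append(text[cursor:])
    return "".join(pieces), PseudonymizationReport(replacements=replacements, seed=seed)


def pseudonymize_post(post: Post, seed: int = 0, name_detector: SpanDetector | None = None) -> Post:
    """Seed per post from (seed, post_id) so a corpus run is reproducible."""
    post_seed = (seed * 1_000_003 + hash_str(post.post_id)) % (2**31)
    new_text, _ = pseudonymize(post.text, seed=post_seed, name_detector=name_detector)
    return post.model_copy(update={"text": new_text})


def hash_str(s: str) -> int:
    """Stable (process-independent) 31-bit string hash."""
    h = 0
    for ch in s:
        h = (h * 131 + ord(ch)) % (2**31)
    return h


# ---------------------------------------------------------------------------
# Sentence segmentation
# ---------------------------------------------------------------------------

#: Title abbreviations never end a sentence.
_TITLE_ABBREV = ("mr", "mrs", "ms", "dr", "prof", "st", "sr", "jr")
#: Latin/listing abbreviations end a sentence only before an uppercase start.
_SOFT_ABBREV = ("etc", "e.g", "i.e", "vs", "fig", "al", "approx", "cf", "no")

_BOUNDARY_RE = re.compile(r"[.!?]+")


def _word_before(text: str, idx: int) -> str:
    j = idx
    while j > 0 and (text[j - 1].isalnum() or text[j - 1] == "."):
        j -= 1
    return text[j:idx].lower().rstrip(".")


def rule_segmenter(text: str) -> list[tuple[int, int]]:
    """Terminal-punctuation segmenter with an abbreviation guard list.

    Newlines always break sentences. Offsets are trimmed to exclude
    surrounding whitespace.
    """
    if not text.strip():
        return []
    breaks: list[int] = []
    for m in _BOUNDARY_RE.finditer(text):
        end = m.end()
        if end < len(text) and not text[end].isspace():
            continue  # mid-token punctuation ("3.5", "a@b.com")
        word = _word_before(text, m.start())
        if word in _TITLE_ABBREV:
            continue
        nxt = text[end:].lstrip()
        if word in _SOFT_ABBREV and nxt and not nxt[0].isupper():
            continue
        breaks.append(end)
    for m in re.finditer(r"\n+", text):
        breaks.append(m.end())
    breaks = sorted(set(breaks))

    spans: list[tuple[int, int]] = []
    start = 0
    for b in breaks + [len(text)]:
        seg = text[start:b]
        s = start + (len(seg) - len(seg.lstrip()))
        e = start + len(seg.rstrip())
        if e > s:
            spans.append((s, e))
        start = b
    return spans


def segment_post(post: Post, segmenter: Segmenter | None = None) -> list[Sentence]:
    """Split a post into offset-anchored sentences.

    Concatenating the sentence spans plus the gaps between them reconstructs
    the post text exactly; every sentence satisfies
    ``post.text[start:end] == text``.
    """
    seg = segmenter if segmenter is not None else rule_segmenter
    sentences = []
    for i, (s, e) in enumerate(seg(post.text)):
        sentences.append(
            Sentence(post_id=post.post_id, index=i, text=post.text[s:e], start=s, end=e)
        )
    return sentences


def segment_posts(posts: Iterable[Post], segmenter: Segmenter | None = None) -> list[Sentence]:
    out: list[Sentence] = []
    for post in posts:
        out.extend(segment_post(post, segmenter))
    return out
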