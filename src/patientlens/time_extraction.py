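"""Time-mention extraction and day-offset normalization.

Four time classes are extracted: DATE (anchored points: *yesterday*,
*November 3rd, 2023*, *2 years ago*, and — by package convention — the
deictic present *now*/*currently*, which marks the onset of a condition as
ongoing), DURATION (*3 months*, *2 weeks*), TIME (*7 pm*, *3 o'clock*), and
SET (frequencies: *daily*, *weekly*).

Onset expressions are normalized to a non-negative integer day offset from
the post's publication date under coarse calendar conventions: one year is
counted as 365 days, one month as 30, one week as 7. Month names resolve to
day 1 of that month in the reference year (the previous year when that date
would lie in the future) and are counted in true calendar days. Expressions
that are too vague ("a while back") or future-pointing are reported as
unresolvable — onsets precede posts, so offsets are never negative.

The span-tagging backend is pluggable (the production choice is a fine-tuned
token classifier); the packaged reference extractor is pattern-based so the
test suite runs model-free. Whatever the backend returns, *now*/*currently*
are re-tagged as DATE.
"""

from __future__ import annotations

import datetime
import re
from typing import Callable, Literal

from pydantic import BaseModel

from .corpus_io import Sentence
from .errors import ContractViolationError

#: Time class codes.
DATE, DURATION, TIME, SET = "DATE", "DURATION", "TIME", "SET"
TIME_CLASSES = (DATE, DURATION, TIME, SET)

#: Coarse calendar conventions (days per unit).
UNIT_DAYS = {"year": 365, "month": 30, "week": 7, "day": 1}

_NUMBER_WORDS = {
    "a": 1, "an": 1, "one": 1, "two": 2, "three": 3, "four": 4, "five": 5,
    "six": 6, "seven": 7, "eight": 8, "nine": 9, "ten": 10, "eleven": 11,
    "twelve": 12, "couple": 2,
}

_MONTHS = {
    name: i + 1
    for i, name in enumerate(
        "january february march april may june july august september october november december".split()
    )
}


class TimeMention(BaseModel):
    sentence_id: str
    time_class: Literal["DATE", "DURATION", "TIME", "SET"]
    surface: str
    start: int
    end: int


class DayOffset(BaseModel):
    """Days elapsed between an onset expression and the reference date.

    ``days`` is meaningful only when ``resolvable`` is true; zero is a valid
    offset (an onset reported as current).
    """

    days: int = 0
    resolvable: bool = True


SpanTagger = Callable[[str], "list[tuple[int, int, str]]"]

# --- reference pattern extractor -------------------------------------------

_NUM = r"(?:\d+|a|an|one|two|three|four|five|six|seven|eight|nine|ten|eleven|twelve|couple(?: of)?|few|several)"
_UNIT = r"(?:year|month|week|day|hour|minute)s?"
_MONTH = r"(?:January|February|March|April|May|June|July|August|September|October|November|December)"

_PATTERNS: list[tuple[str, str]] = [
    # DATE: anchored points in time
    (rf"\b{_NUM} {_UNIT} ago\b", DATE),
    (r"\blast (?:year|month|week)\b", DATE),
    (r"\bearlier this (?:year|month|week)\b", DATE),
    (r"\b(?:yesterday|today|tomorrow|now|currently)\b", DATE),
    (rf"\b(?:in |since |on )?{_MONTH}(?: \d{{1,2}}(?:st|nd|rd|th)?)?(?:,? \d{{4}})?\b", DATE),
    (r"\b(?:in |since )(?:19|20)\d\d\b", DATE),
    (r"\b(?:a while back|a while ago|some time ago)\b", DATE),
    # TIME: time of day (before DURATION so "3 o'clock" is not "3 ...")
    (r"\b\d{1,2}(?::\d{2})?\s?(?:am|pm|AM|PM)\b", TIME),
    (r"\b\d{1,2} o'\s?clock\b", TIME),
    (r"\b(?:noon|midnight)\b", TIME),
    # SET: frequencies
    (r"\b(?:daily|weekly|monthly|yearly|hourly|nightly)\b", SET),
    (rf"\bevery {_UNIT}\b", SET),
    (rf"\b{_NUM} times (?:a|per) {_UNIT}\b", SET),
    # DURATION: extents
    (rf"\b(?:for )?{_NUM} {_UNIT}\b", DURATION),
    (r"\b(?:years|months|weeks|days)\b", DURATION),
]

_COMPILED = [(re.compile(p, re.IGNORECASE), cls) for p, cls in _PATTERNS]

_NOW_RE = re.compile(r"^(?:now|currently)$", re.IGNORECASE)


def pattern_tagger(text: str) -> list[tuple[int, int, str]]:
    """Reference span tagger: first-listed pattern wins, leftmost-longest."""
    candidates: list[tuple[int, int, int, str]] = []
    for order, (regex, cls) in enumerate(_COMPILED):
        for m in regex.finditer(text):
            candidates.append((m.start(), m.end(), order, cls))
    candidates.sort(key=lambda c: (c[0], -(c[1]), c[2]))
    chosen: list[tuple[int, int, str]] = []
    last_end = 0
    for s, e, _order, cls in candidates:
        if s >= last_end:
            chosen.append((s, e, cls))
            last_end = e
    return chosen


def extract_time_mentions(
    sentence: Sentence, extractor: SpanTagger = pattern_tagger
) -> list[TimeMention]:
    """Extract typed time mentions; *now*/*currently* are always DATE."""
    mentions = []
    for start, end, cls in extractor(sentence.text):
        surface = sentence.text[start:end]
        if _NOW_RE.match(surface):
            cls = DATE
        mentions.append(
            TimeMention(
                sentence_id=sentence.sentence_id,
                time_class=cls, surface=surface, start=start, end=end,
            )
        )
    return mentions


# --- normalization ----------------------------------------------------------

_AGO_RE = re.compile(rf"^(?:about |around |over |nearly |almost )?({_NUM}) ({_UNIT}) ago$", re.IGNORECASE)
_LAST_RE = re.compile(r"^last (year|month|week)$", re.IGNORECASE)
_EARLIER_RE = re.compile(r"^earlier this (?:year|month|week)$", re.IGNORECASE)
_PRESENT_RE = re.compile(r"^(?:now|currently|today)$", re.IGNORECASE)
_MONTH_RE = re.compile(
    rf"^(?:in |since |on )?({_MONTH})(?: (\d{{1,2}})(?:st|nd|rd|th)?)?(?:,? (\d{{4}}))?$",
    re.IGNORECASE,
)
_YEAR_RE = re.compile(r"^(?:in |since )?((?:19|20)\d\d)$", re.IGNORECASE)
_BARE_DURATION_RE = re.compile(rf"^(?:for )?({_NUM}) ({_UNIT})$", re.IGNORECASE)
_VAGUE_NUM_RE = re.compile(r"^(?:few|several)$", re.IGNORECASE)


def _parse_count(word: str) -> int | None:
    word = word.lower()
    if _VAGUE_NUM_RE.match(word):
        return None
    if word.isdigit():
        return int(word)
    return _NUMBER_WORDS.get(word.split(" ")[0])


def _unit_days(unit: str) -> int | None:
    return UNIT_DAYS.get(unit.lower().rstrip("s"))


def normalize_to_day_offset(
    mention: TimeMention, reference_date: datetime.date
) -> DayOffset:
    """Resolve a DATE or DURATION mention to days before the reference date.

    Pure and deterministic; vague or future-pointing expressions come back
    with ``resolvable=False``.
    """
    if mention.time_class not in (DATE, DURATION):
        raise ContractViolationError(
            f"cannot normalize a {mention.time_class} mention to a day offset"
        )
    surface = mention.surface.strip()

    if _PRESENT_RE.match(surface):
        return DayOffset(days=0)
    if surface.lower() == "yesterday":
        return DayOffset(days=1)
    if _EARLIER_RE.match(surface):
        # no finer anchor than the current unit: counted as current
        return DayOffset(days=0)

    m = _LAST_RE.match(surface)
    if m:
        return DayOffset(days=UNIT_DAYS[m.group(1).lower()])

    m = _AGO_RE.match(surface)
    if m:
        count, unit = _parse_count(m.group(1)), _unit_days(m.group(2))
        if count is None or unit is None:
            return DayOffset(resolvable=False)
        return DayOffset(days=count * unit)

    m = _MONTH_RE.match(surface)
    if m and m.group(1).lower() in _MONTHS:
        month = _MONTHS[m.group(1).lower()]
        day = int(m.group(2)) if m.group(2) else 1
        try:
            if m.group(3):
                anchor = datetime.date(int(m.group(3)), month, day)
                if anchor > reference_date:
                    return DayOffset(resolvable=False)
            else:
                anchor = datetime.date(reference_date.year, month, day)
                if anchor > reference_date:
                    anchor = datetime.date(reference_date.year - 1, month, day)
        except ValueError:
            return DayOffset(resolvable=False)
        return DayOffset(days=(reference_date - anchor).days)

    m = _YEAR_RE.match(surface)
    if m:
        anchor = datetime.date(int(m.group(1)), 1, 1)
        if anchor > reference_date:
            return DayOffset(resolvable=False)
        return DayOffset(days=(reference_date - anchor).days)

    if mention.time_class == DURATION:
        m = _BARE_DURATION_RE.match(surface)
        if m:
            count, unit = _parse_count(m.group(1)), _unit_days(m.group(2))
            if count is None or unit is None:
                return DayOffset(resolvable=False)
            return DayOffset(days=count * unit)

    return DayOffset(resolvable=False)
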