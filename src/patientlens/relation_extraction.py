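"""Zero-shot relation extraction between extracted mentions.

Relations between two concepts in a sentence are decided by scoring slotted
hypothesis templates ("{concept 1} leads to {concept 2}") against the
sentence with an entailment backend. For every admissible relation and every
template, two hypotheses are generated with the concept spans swapped — the
higher-scoring order determines the direction. Ontological pruning removes
relations a type pair cannot carry before any scoring happens. Since only
one relation can hold between two concepts, the overall argmax wins if it
clears the threshold (default 0.2); otherwise the pair is NoRel.

The specific micro-relations *ameliorates*, *creates* and *exacerbates*
additionally require a lexical trigger ("improve", "due to", "worsen"...) in
the sentence; without one the selection is demoted to its macro-relation
(*is used for* or *is associated with*). *Is associated with* is the only
symmetric relation: its instances are canonicalized so the argument with the
smaller start offset comes first.

Relations are reported as stated in the text, not as they hold in reality —
nothing in this module consults any knowledge source beyond the sentence,
its mentions and the schema.

Relation codes: AM ameliorates, CR creates, DG diagnoses, EX exacerbates,
IAW is-associated-with, IUF is-used-for, ITO is-time-of, NOREL none.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence, Union

import yaml
from pydantic import BaseModel, Field

from .backends import EntailmentScorer, score_entailment
from .corpus_io import Sentence
from .errors import ConfigurationError, ContractViolationError
from .lexicon_ner import EntityMention
from .time_extraction import DATE, DURATION, TimeMention

AM, CR, DG, EX, IAW, IUF, ITO, NOREL = "AM", "CR", "DG", "EX", "IAW", "IUF", "ITO", "NOREL"
RELATIONS = (AM, CR, DG, EX, IAW, IUF, ITO)

#: The single symmetric relation.
SYMMETRIC = frozenset({IAW})
#: Micro-relation -> macro-relation (cue-word demotion target).
MACRO_OF = {AM: IUF, CR: IAW, EX: IAW}
#: Tie-break precedence among equal scores, then forward before reverse.
PRECEDENCE = (DG, ITO, AM, EX, CR, IUF, IAW)

TIME_TYPES = frozenset({DATE, DURATION})

Mention = Union[EntityMention, TimeMention]

FORWARD, REVERSE = "forward", "reverse"


def mention_type(mention: Mention) -> str:
    return mention.concept_type if isinstance(mention, EntityMention) else mention.time_class


@dataclass
class RelationSchema:
    """Templates, type admissibility, micro-relation cues and the threshold."""

    templates: dict[str, list[str]]
    admissible: dict[str, set[tuple[str, str]]]
    cues: dict[str, list[str]]
    threshold: float = 0.2

    def __post_init__(self) -> None:
        for rel in RELATIONS:
            if not self.templates.get(rel):
                raise ConfigurationError(f"relation {rel} has no hypothesis template")
        for rel, pairs in self.admissible.items():
            for t1, t2 in pairs:
                n_time = (t1 in TIME_TYPES) + (t2 in TIME_TYPES)
                if rel == ITO and n_time != 1:
                    raise ConfigurationError("ITO requires exactly one time-typed argument")
                if rel != ITO and n_time > 0:
                    raise ConfigurationError(f"{rel} admits no time-typed argument")
        self._cue_patterns = {
            rel: [re.compile(r"\b" + re.escape(c) + r"\b", re.IGNORECASE) for c in cues]
            for rel, cues in self.cues.items()
        }

    def has_cue(self, relation: str, text: str) -> bool:
        return any(p.search(text) for p in self._cue_patterns.get(relation, []))


def read_schema(path: str | Path) -> RelationSchema:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    admissible = {
        rel: {
            (t1, t2)
            for t1 in spec["arg1"]
            for t2 in spec["arg2"]
            if t1 != t2 or t1 not in TIME_TYPES
        }
        for rel, spec in raw["admissible"].items()
    }
    return RelationSchema(
        templates={rel: list(ts) for rel, ts in raw["templates"].items()},
        admissible=admissible,
        cues={rel: list(cs) for rel, cs in raw.get("cues", {}).items()},
        threshold=float(raw.get("threshold", 0.2)),
    )


def default_schema() -> RelationSchema:
    from ._resources import data_path

    return read_schema(Path(str(data_path("relation_schema.yaml"))))


class ArgRef(BaseModel):
    """A lightweight reference to a relation argument within its sentence."""

    surface: str
    arg_type: str
    start: int
    end: int


class RelationInstance(BaseModel):
    sentence_id: str
    arg1: ArgRef
    arg2: ArgRef
    relation: str
    score: float = Field(ge=0.0, le=1.0)

    def triple(self) -> tuple[str, str, str]:
        return (self.arg1.surface, self.relation, self.arg2.surface)


# ---------------------------------------------------------------------------
# The three stages
# ---------------------------------------------------------------------------


def generate_hypotheses(
    sentence: Sentence,
    pair: tuple[Mention, Mention],
    schema: RelationSchema,
) -> list[tuple[str, str, str]]:
    """(relation, direction, hypothesis) for every admissible instantiation.

    Directed relations yield both argument orders (essential for determining
    direction); the symmetric IAW yields one, in offset-canonical order.
    Inadmissible type pairs yield nothing.
    """
    m1, m2 = pair
    if m1.sentence_id != sentence.sentence_id or m2.sentence_id != sentence.sentence_id:
        raise ContractViolationError("both mentions must belong to the sentence")
    t1, t2 = mention_type(m1), mention_type(m2)
    out: list[tuple[str, str, str]] = []
    for relation in RELATIONS:
        pairs = schema.admissible.get(relation, set())
        directions: list[tuple[str, Mention, Mention]] = []
        if relation in SYMMETRIC:
            if (t1, t2) in pairs or (t2, t1) in pairs:
                a, b = (m1, m2) if m1.start <= m2.start else (m2, m1)
                directions.append((FORWARD, a, b))
        else:
            if (t1, t2) in pairs:
                directions.append((FORWARD, m1, m2))
            if (t2, t1) in pairs:
                directions.append((REVERSE, m2, m1))
        for template in schema.templates[relation]:
            for direction, a, b in directions:
                hypothesis = template.replace("{concept 1}", a.surface).replace(
                    "{concept 2}", b.surface
                )
                out.append((relation, direction, hypothesis))
    return out


def select_relation(
    scored: Sequence[tuple[str, str, float]],
    schema: RelationSchema,
) -> tuple[str, str | None, float]:
    """Argmax over (relation, direction, score); NoRel below the threshold.

    Ties break by the fixed relation precedence DG > ITO > AM > EX > CR >
    IUF > IAW, then forward before reverse — an artifact convention for
    determinism.
    """
    if not scored:
        return (NOREL, None, 0.0)
    rank = {rel: i for i, rel in enumerate(PRECEDENCE)}
    best = min(
        scored,
        key=lambda item: (-item[2], rank.get(item[0], len(rank)), item[1] != FORWARD),
    )
    relation, direction, score = best
    if score <= schema.threshold:
        return (NOREL, None, score)
    return (relation, direction, score)


def apply_cue_demotion(
    selection: tuple[str, str | None, float],
    sentence_text: str,
    schema: RelationSchema,
) -> tuple[str, str | None, float]:
    """Demote an uncued micro-relation to its macro-relation.

    AM/CR/EX require a trigger word of their cue list in the sentence
    (case-insensitive, word-boundary); without one the selection becomes
    IUF or IAW. Any IAW outcome is canonicalized to the symmetric forward
    direction.
    """
    relation, direction, score = selection
    if relation in MACRO_OF and not schema.has_cue(relation, sentence_text):
        relation = MACRO_OF[relation]
    if relation in SYMMETRIC:
        direction = FORWARD
    return (relation, direction, score)


def extract_relations(
    sentence: Sentence,
    mentions: Sequence[Mention],
    schema: RelationSchema,
    scorer: EntailmentScorer,
    emit_norel: bool = False,
) -> list[RelationInstance]:
    """Score every unordered mention pair of a sentence and keep the winners.

    NoRel instances are suppressed by default; enable ``emit_norel`` for
    evaluation against pair datasets that include them.
    """
    for m in mentions:
        if m.sentence_id != sentence.sentence_id:
            raise ContractViolationError("mentions must belong to the sentence")
    ordered = sorted(mentions, key=lambda m: (m.start, m.end))
    instances: list[RelationInstance] = []
    for m1, m2 in itertools.combinations(ordered, 2):
        hypotheses = generate_hypotheses(sentence, (m1, m2), schema)
        scored = [
            (relation, direction, score_entailment(sentence.text, hypothesis, scorer))
            for relation, direction, hypothesis in hypotheses
        ]
        selection = select_relation(scored, schema)
        relation, direction, score = apply_cue_demotion(
            selection, sentence.text, schema
        )
        if relation == NOREL and not emit_norel:
            continue
        if relation in SYMMETRIC or direction in (FORWARD, None):
            a, b = m1, m2
        else:
            a, b = m2, m1
        instances.append(
            RelationInstance(
                sentence_id=sentence.sentence_id,
                arg1=ArgRef(surface=a.surface, arg_type=mention_type(a), start=a.start, end=a.end),
                arg2=ArgRef(surface=b.surface, arg_type=mention_type(b), start=b.start, end=b.end),
                relation=relation,
                score=score,
            )
        )
    return instances
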