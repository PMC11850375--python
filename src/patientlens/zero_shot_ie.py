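"""Zero-shot extraction of abstract entities: need, support, diagnosis, misdiagnosis.

These targets cannot be enumerated in a lexicon — a need may be social,
psychological or medical — so they are detected by scoring crafted
natural-language hypotheses against each sentence (the premise) with an
entailment backend:

* *ungrounded* targets (NEED, SUPPORT) use a fixed hypothesis such as
  "Someone needs something."; a sentence whose score exceeds the template
  threshold is then passed, with one or more questions ("What is needed?"),
  to an extractive question-answering backend that pins down the specific
  span (e.g. *a lung transplant*). Screening before answering keeps the
  false-positive rate of bare QA down, and the QA step never runs on a
  sentence that failed screening.

* *grounded* targets (DIAGNOSIS, MISDIAGNOSIS) are defined over previously
  extracted primary entities: a disease or symptom mention instantiates the
  slotted hypotheses "{entity} was diagnosed." / "{entity} was detected."
  (and the misdiagnosis counterparts); the maximum score over the pattern
  variants decides. When both statuses pass, the more specific misdiagnosis
  reading wins.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Literal, Sequence

from pydantic import BaseModel, Field, model_validator

from .backends import Answerer, AnswerSpan, EntailmentScorer, extract_answer, score_entailment
from .corpus_io import Sentence
from .errors import ConfigurationError, ContractViolationError
from .lexicon_ner import DI, SY, EntityMention

NEED, SUPPORT, DIAGNOSIS, MISDIAGNOSIS = "NEED", "SUPPORT", "DIAGNOSIS", "MISDIAGNOSIS"
ABSTRACT_TARGETS = (NEED, SUPPORT, DIAGNOSIS, MISDIAGNOSIS)
GROUNDED_TARGETS = (DIAGNOSIS, MISDIAGNOSIS)

_SLOT = "{entity}"


class HypothesisTemplate(BaseModel):
    """A slotted hypothesis with its screening threshold and follow-up questions."""

    target: Literal["NEED", "SUPPORT", "DIAGNOSIS", "MISDIAGNOSIS"]
    pattern: str
    questions: list[str] = []
    threshold: float = Field(default=0.5, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check_slots(self) -> "HypothesisTemplate":
        slots = self.pattern.count(_SLOT)
        if self.target in GROUNDED_TARGETS:
            if slots != 1:
                raise ValueError(f"grounded target {self.target} needs exactly one {_SLOT} slot")
        else:
            if slots != 0:
                raise ValueError(f"ungrounded target {self.target} takes no slot")
            if not self.questions:
                raise ValueError(f"ungrounded target {self.target} needs at least one question")
        return self

    @property
    def grounded(self) -> bool:
        return self.target in GROUNDED_TARGETS


class AbstractMention(BaseModel):
    """An extracted abstract entity with its entailment score."""

    sentence_id: str
    target: Literal["NEED", "SUPPORT", "DIAGNOSIS", "MISDIAGNOSIS"]
    score: float = Field(ge=0.0, le=1.0)
    trigger_entity: EntityMention | None = None
    answer_text: str | None = None
    answer_start: int | None = None
    answer_end: int | None = None


def read_templates(path: str | Path) -> list[HypothesisTemplate]:
    """Load the template bank (TSV: target, pattern, questions, threshold)."""
    templates = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        target, pattern, questions, threshold = line.split("\t")
        templates.append(
            HypothesisTemplate(
                target=target,
                pattern=pattern,
                questions=[q for q in questions.split("||") if q],
                threshold=float(threshold),
            )
        )
    return templates


def default_templates() -> list[HypothesisTemplate]:
    from ._resources import data_path

    return read_templates(Path(str(data_path("abstract_templates.tsv"))))


def screen_sentence(
    sentence: Sentence, template: HypothesisTemplate, scorer: EntailmentScorer
) -> tuple[float, bool]:
    """Score the sentence (premise) against an ungrounded hypothesis.

    Passing requires the score to strictly exceed the threshold.
    """
    if template.grounded:
        raise ContractViolationError("screen_sentence takes an ungrounded template")
    score = score_entailment(sentence.text, template.pattern, scorer)
    return score, score > template.threshold


def extract_target_span(
    sentence: Sentence, template: HypothesisTemplate, answerer: Answerer
) -> AnswerSpan | None:
    """Run the template's questions in priority order; first answer wins."""
    for question in template.questions:
        span = extract_answer(question, sentence.text, answerer)
        if span is not None:
            return span
    return None


def classify_diagnosis_status(
    sentence: Sentence,
    entity: EntityMention,
    templates: Sequence[HypothesisTemplate],
    scorer: EntailmentScorer,
) -> AbstractMention | None:
    """Decide whether a disease/symptom mention is reported as (mis)diagnosed.

    Each grounded pattern is instantiated with the entity surface; per target
    the maximum score over pattern variants is taken (the variants are
    alternatives). If both targets pass their thresholds the misdiagnosis
    reading wins as the more specific one.
    """
    if entity.concept_type not in (DI, SY):
        raise ContractViolationError(
            f"diagnosis grounding requires a DI or SY entity, got {entity.concept_type}"
        )
    best: dict[str, tuple[float, float]] = {}  # target -> (score, threshold)
    for template in templates:
        if not template.grounded:
            continue
        hypothesis = template.pattern.replace(_SLOT, entity.surface)
        score = score_entailment(sentence.text, hypothesis, scorer)
        cur = best.get(template.target)
        if cur is None or score > cur[0]:
            best[template.target] = (score, template.threshold)
    passing = {t: s for t, (s, thr) in best.items() if s > thr}
    if not passing:
        return None
    target = MISDIAGNOSIS if MISDIAGNOSIS in passing else DIAGNOSIS
    return AbstractMention(
        sentence_id=sentence.sentence_id,
        target=target,
        score=passing[target],
        trigger_entity=entity,
    )


def extract_abstract_mentions(
    sentence: Sentence,
    entity_mentions: Iterable[EntityMention],
    templates: Sequence[HypothesisTemplate],
    scorer: EntailmentScorer,
    answerer: Answerer,
    require_answer: bool = True,
) -> list[AbstractMention]:
    """Full abstract-entity pass over one sentence.

    Ungrounded targets: screen, then answer (suppressed without an answer
    unless ``require_answer`` is off). Grounded targets: one status decision
    per disease/symptom mention.
    """
    mentions: list[AbstractMention] = []
    for template in templates:
        if template.grounded:
            continue
        score, passed = screen_sentence(sentence, template, scorer)
        if not passed:
            continue
        span = extract_target_span(sentence, template, answerer)
        if span is None and require_answer:
            continue
        mentions.append(
            AbstractMention(
                sentence_id=sentence.sentence_id,
                target=template.target,
                score=score,
                answer_text=span.text if span else None,
                answer_start=span.start if span else None,
                answer_end=span.end if span else None,
            )
        )
    for entity in entity_mentions:
        if entity.concept_type in (DI, SY):
            mention = classify_diagnosis_status(sentence, entity, templates, scorer)
            if mention is not None:
                mentions.append(mention)
    return mentions
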