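"""Gold-annotated synthetic social-media corpora and consistent oracle backends.

Real patient-forum corpora in this domain are proprietary, so the package
ships a generator that emulates their label structure: sentences carry an
interest-group label, lexicon-matchable entity mentions, time mentions with
known day offsets, relation triples admissible under the default schema, and
abstract targets (need, support, diagnosis, misdiagnosis). Sentences are
assembled from slot templates, so every gold span is exact by construction,
and the planted entity slots are drawn from the packaged fixture lexicon, so
re-running the matcher reproduces the gold mentions (closure).

:func:`oracle_backends` derives backends that are correct *by construction*
with respect to the gold: the entailment oracle scores exactly the
hypotheses instantiated from planted relations and targets (in their true
direction) at 1.0 and everything else at 0.0; the answering oracle returns
the planted span; the embedding oracle returns label-separable vectors. A
pipeline run with these backends must recover the gold exactly — that is the
framework's end-to-end correctness check; it exercises pipeline logic, not
model quality.
"""

from __future__ import annotations

import datetime
import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .backends import AnswerSpan
from .corpus_io import Post
from .errors import ConfigurationError
from .lexicon_ner import DI, DR, SY, TR, EntityMention, fixture_lexicon
from .relation_extraction import (
    AM, CR, DG, EX, IAW, ITO, IUF, ArgRef, RelationInstance, default_schema,
)
from .time_extraction import DATE, SET, TimeMention
from .zero_shot_ie import (
    DIAGNOSIS, MISDIAGNOSIS, NEED, SUPPORT, AbstractMention, default_templates,
)
from .interest_group import CG, LABELS, O, PA, PAA, SC

#: Annotated-inventory proportions used as the default group distribution.
DEFAULT_GROUP_DISTRIBUTION = {
    PA: 230 / 1323, CG: 144 / 1323, PAA: 104 / 1323, SC: 132 / 1323, O: 713 / 1323,
}


class GenerationConfig(BaseModel):
    n_posts: int = Field(ge=0)
    seed: int
    group_distribution: dict[str, float] = DEFAULT_GROUP_DISTRIBUTION
    relation_rates: dict[str, float] = {}
    abstract_rates: dict[str, float] = {}
    min_sentences: int = Field(default=1, ge=1)
    max_sentences: int = 3
    start_date: datetime.date = datetime.date(2021, 10, 1)
    end_date: datetime.date = datetime.date(2023, 11, 30)

    @model_validator(mode="after")
    def _check(self) -> "GenerationConfig":
        if set(self.group_distribution) - set(LABELS):
            raise ConfigurationError("unknown interest-group label in distribution")
        if any(v < 0 for v in self.group_distribution.values()):
            raise ConfigurationError("negative group probability")
        if abs(sum(self.group_distribution.values()) - 1.0) > 1e-9:
            raise ConfigurationError("group distribution must sum to 1")
        if self.max_sentences < self.min_sentences:
            raise ConfigurationError("max_sentences < min_sentences")
        return self


class GoldSentence(BaseModel):
    post_id: str
    index: int
    text: str
    group: str
    entities: list[EntityMention] = []
    times: list[TimeMention] = []
    relations: list[RelationInstance] = []
    abstracts: list[AbstractMention] = []
    #: Planted onset day offset (None when the sentence carries no onset).
    onset_days: int | None = None

    @property
    def sentence_id(self) -> str:
        return f"{self.post_id}:{self.index}"


@dataclass
class GoldAnnotations:
    sentences: list[GoldSentence]
    #: sentence text -> hypothesis strings true for that sentence
    true_hypotheses: dict[str, set[str]] = field(default_factory=dict)
    #: (question, sentence text) -> gold answer span
    qa_answers: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)
    #: sentence text -> interest-group label
    label_of_text: dict[str, str] = field(default_factory=dict)

    def by_id(self) -> dict[str, GoldSentence]:
        return {s.sentence_id: s for s in self.sentences}


# ---------------------------------------------------------------------------
# Slot pools (every entity slot is a fixture-lexicon term)
# ---------------------------------------------------------------------------

_DI_POOL = [
    "idiopathic pulmonary fibrosis", "pulmonary fibrosis", "IPF", "COPD",
    "emphysema", "rheumatoid arthritis", "asthma", "pneumonia",
]
_SY_POOL = [
    "shortness of breath", "breathlessness", "clubbing", "chest pain",
    "weight loss", "dizziness", "wheezing", "cough", "fatigue", "fever",
]
#: Ontology-overlap terms: gold-typed SY (the overlap rule relabels them).
_DR_POOL = ["pirfenidone", "nintedanib", "prednisone", "azathioprine", "sildenafil"]
_TR_POOL = [
    "lung transplant", "oxygen therapy", "pulmonary rehabilitation",
    "physiotherapy", "mechanical ventilation",
]
_TIME_POOL = [
    ("Two weeks ago", 14), ("2 years ago", 730), ("Last year", 365),
    ("3 months ago", 90), ("Six months ago", 180), ("4 weeks ago", 28),
]
_NEED_POOL = [
    "a second opinion", "financial help", "a wheelchair ramp",
    "better home care", "help with paperwork", "help with transport",
    "a quieter room", "a ramp at the entrance",
]
_ORG_POOL = [
    "the regional lung association", "a local volunteer network",
    "the hospital social service", "a neighbourhood charity",
    "the community visiting service", "a patient helpline",
]
# Plain-sentence part pools; combinatorial so large corpora stay post-unique.
_O_PREFIXES = ["", "Honestly, ", "To be fair, ", "For what it is worth, "]
_O_OPENERS = [
    "We would love to travel more",
    "I was hoping for quieter roads",
    "The photos from the trip turned out lovely",
    "Thanks for sharing this with everyone",
    "Please let me know if the link works",
    "That is kind of you to say",
    "The meeting got moved to another room",
    "Our garden kept us busy all weekend",
]
_O_CLOSERS = [
    "but it is just not possible.",
    "and that is all there is to it.",
    "so we will see how it goes.",
    "which was a nice surprise.",
    "though nothing is settled yet.",
    "and everyone seemed pleased.",
]
_SC_SUBJECTS = [
    "The annual research meeting", "A new longitudinal study",
    "The latest journal issue", "A multicenter trial report",
    "The keynote lecture",
]
_SC_VERBS = ["will highlight", "summarizes", "examines", "presents"]
_SC_OBJECTS = [
    "new methods for long-term follow-up.",
    "recruitment strategies in rare conditions.",
    "open questions in study design.",
    "approaches to data sharing.",
]
_CG_SUBJECTS = ["My brother", "My mother", "My father", "My aunt", "My grandfather"]
_CG_PREDICATES = [
    "stays with us for the season.",
    "is moving in with us soon.",
    "called to check in this morning.",
    "enjoys having company in the afternoon.",
]
_PAA_TEMPLATES = [
    "Join the awareness walk organized by {org} for families living with illness.",
    "Registration is open for the family day hosted by {org}.",
    "Volunteers from {org} will greet you at the door.",
    "Save the date for the picnic that {org} is planning for members.",
]

_SCHEMA = None
_TEMPLATES = None


def _schema():
    global _SCHEMA
    if _SCHEMA is None:
        _SCHEMA = default_schema()
    return _SCHEMA


# ---------------------------------------------------------------------------
# Sentence builders
# ---------------------------------------------------------------------------


@dataclass
class _Built:
    text: str
    entities: list[tuple[str, str, int, int]] = field(default_factory=list)  # type, surface, start, end
    times: list[tuple[str, str, int, int]] = field(default_factory=list)
    relations: list[tuple[int, str, int]] = field(default_factory=list)  # (entity idx or ~time idx, rel, ...)
    abstracts: list[dict] = field(default_factory=list)
    onset_days: int | None = None
    true_hypotheses: set[str] = field(default_factory=set)
    qa_answers: dict[str, tuple[int, int]] = field(default_factory=dict)


class _Assembler:
    """Concatenates carrier text and slots while tracking offsets."""

    def __init__(self) -> None:
        self.parts: list[str] = []
        self.length = 0
        self.slots: dict[str, tuple[str, int, int]] = {}

    def lit(self, text: str) -> "_Assembler":
        self.parts.append(text)
        self.length += len(text)
        return self

    def slot(self, name: str, surface: str) -> "_Assembler":
        self.slots[name] = (surface, self.length, self.length + len(surface))
        return self.lit(surface)

    @property
    def text(self) -> str:
        return "".join(self.parts)


def _rel_hyps(rel: str, arg1: str, arg2: str) -> set[str]:
    """Hypothesis strings true for a planted relation, in its true direction."""
    hyps = set()
    for template in _schema().templates[rel]:
        hyps.add(template.replace("{concept 1}", arg1).replace("{concept 2}", arg2))
        if rel == IAW:
            hyps.add(template.replace("{concept 1}", arg2).replace("{concept 2}", arg1))
    return hyps


def _grounded_hyps(target: str, surface: str) -> set[str]:
    out = set()
    for t in default_templates():
        if t.target == target and t.grounded:
            out.add(t.pattern.replace("{entity}", surface))
    return out


def _build_onset(rng: random.Random, group: str) -> _Built:
    time_surface, days = rng.choice(_TIME_POOL)
    di = rng.choice(_DI_POOL)
    a = _Assembler()
    a.slot("time", time_surface)
    a.lit(" my mother received a diagnosis of " if group == CG else " I received a diagnosis of ")
    a.slot("di", di)
    a.lit(".")
    b = _Built(text=a.text, onset_days=days)
    ts, t0, t1 = a.slots["time"]
    ds, d0, d1 = a.slots["di"]
    b.times.append((DATE, ts, t0, t1))
    b.entities.append((DI, ds, d0, d1))
    b.relations.append(("time:0", ITO, "ent:0"))
    b.abstracts.append({"target": DIAGNOSIS, "entity": 0})
    b.true_hypotheses |= _rel_hyps(ITO, ts, ds) | _grounded_hyps(DIAGNOSIS, ds)
    return b


def _build_current_onset(rng: random.Random, group: str) -> _Built:
    di = rng.choice(_DI_POOL)
    a = _Assembler()
    a.lit("After a successful course of care, I am ")
    a.slot("time", "currently")
    a.lit(" managing my ")
    a.slot("di", di)
    a.lit(".")
    b = _Built(text=a.text, onset_days=0)
    ts, t0, t1 = a.slots["time"]
    ds, d0, d1 = a.slots["di"]
    b.times.append((DATE, ts, t0, t1))
    b.entities.append((DI, ds, d0, d1))
    b.relations.append(("time:0", ITO, "ent:0"))
    b.true_hypotheses |= _rel_hyps(ITO, ts, ds)
    return b


def _build_creates(rng: random.Random, group: str) -> _Built:
    sy, di = rng.choice(_SY_POOL), rng.choice(_DI_POOL)
    a = _Assembler()
    a.lit("I have severe ")
    a.slot("sy", sy)
    a.lit(" due to my ")
    a.slot("di", di)
    a.lit(".")
    b = _Built(text=a.text)
    ss, s0, s1 = a.slots["sy"]
    ds, d0, d1 = a.slots["di"]
    b.entities.append((SY, ss, s0, s1))
    b.entities.append((DI, ds, d0, d1))
    b.relations.append(("ent:1", CR, "ent:0"))  # disease creates symptom
    b.true_hypotheses |= _rel_hyps(CR, ds, ss)
    return b


def _build_exacerbates(rng: random.Random, group: str) -> _Built:
    di, sy = rng.choice(_DI_POOL), rng.choice(_SY_POOL)
    a = _Assembler()
    a.lit("My ")
    a.slot("di", di)
    a.lit(" makes my ")
    a.slot("sy", sy)
    a.lit(" worse.")
    b = _Built(text=a.text)
    ds, d0, d1 = a.slots["di"]
    ss, s0, s1 = a.slots["sy"]
    b.entities.append((DI, ds, d0, d1))
    b.entities.append((SY, ss, s0, s1))
    b.relations.append(("ent:0", EX, "ent:1"))
    b.true_hypotheses |= _rel_hyps(EX, ds, ss)
    return b


def _build_ameliorates(rng: random.Random, group: str) -> _Built:
    dr, sy = rng.choice(_DR_POOL), rng.choice(_SY_POOL)
    a = _Assembler()
    a.lit("Taking ")
    a.slot("dr", dr)
    a.lit(" helped improve my ")
    a.slot("sy", sy)
    a.lit(".")
    b = _Built(text=a.text)
    rs, r0, r1 = a.slots["dr"]
    ss, s0, s1 = a.slots["sy"]
    b.entities.append((DR, rs, r0, r1))
    b.entities.append((SY, ss, s0, s1))
    b.relations.append(("ent:0", AM, "ent:1"))
    b.true_hypotheses |= _rel_hyps(AM, rs, ss)
    return b


def _build_used_for(rng: random.Random, group: str) -> _Built:
    dr, di = rng.choice(_DR_POOL), rng.choice(_DI_POOL)
    a = _Assembler()
    a.lit("A new study reports that ")
    a.slot("dr", dr)
    a.lit(" is an option for patients with ")
    a.slot("di", di)
    a.lit(".")
    b = _Built(text=a.text)
    rs, r0, r1 = a.slots["dr"]
    ds, d0, d1 = a.slots["di"]
    b.entities.append((DR, rs, r0, r1))
    b.entities.append((DI, ds, d0, d1))
    b.relations.append(("ent:0", IUF, "ent:1"))
    b.true_hypotheses |= _rel_hyps(IUF, rs, ds)
    return b


def _build_associated(rng: random.Random, group: str) -> _Built:
    sy, di = rng.choice(_SY_POOL), rng.choice(_DI_POOL)
    a = _Assembler()
    a.lit("Researchers report that ")
    a.slot("sy", sy)
    a.lit(" is often seen together with ")
    a.slot("di", di)
    a.lit(".")
    b = _Built(text=a.text)
    ss, s0, s1 = a.slots["sy"]
    ds, d0, d1 = a.slots["di"]
    b.entities.append((SY, ss, s0, s1))
    b.entities.append((DI, ds, d0, d1))
    b.relations.append(("ent:0", IAW, "ent:1"))  # canonical: offset order
    b.true_hypotheses |= _rel_hyps(IAW, ss, ds)
    return b


def _build_diagnoses(rng: random.Random, group: str) -> _Built:
    tr, di = rng.choice(_TR_POOL), rng.choice(_DI_POOL)
    a = _Assembler()
    a.lit("Doctors used ")
    a.slot("tr", tr)
    a.lit(" to look for ")
    a.slot("di", di)
    a.lit(" in my father.")
    b = _Built(text=a.text)
    ts, t0, t1 = a.slots["tr"]
    ds, d0, d1 = a.slots["di"]
    b.entities.append((TR, ts, t0, t1))
    b.entities.append((DI, ds, d0, d1))
    b.relations.append(("ent:0", DG, "ent:1"))
    b.true_hypotheses |= _rel_hyps(DG, ts, ds)
    return b


def _build_misdiagnosis(rng: random.Random, group: str) -> _Built:
    di = rng.choice(_DI_POOL)
    a = _Assembler()
    a.lit("My aunt's ")
    a.slot("di", di)
    a.lit(" was missed by her physician again and again.")
    b = _Built(text=a.text)
    ds, d0, d1 = a.slots["di"]
    b.entities.append((DI, ds, d0, d1))
    b.abstracts.append({"target": MISDIAGNOSIS, "entity": 0})
    b.true_hypotheses |= _grounded_hyps(MISDIAGNOSIS, ds)
    return b


def _build_need(rng: random.Random, group: str) -> _Built:
    need = rng.choice(_NEED_POOL)
    a = _Assembler()
    a.lit("Our neighbour is in need of ")
    a.slot("need", need)
    a.lit(".")
    b = _Built(text=a.text)
    ns, n0, n1 = a.slots["need"]
    b.abstracts.append({"target": NEED, "answer": (ns, n0, n1)})
    b.true_hypotheses.add("Someone needs something.")
    b.qa_answers["What is needed?"] = (n0, n1)
    return b


def _build_support(rng: random.Random, group: str) -> _Built:
    org = rng.choice(_ORG_POOL)
    a = _Assembler()
    a.lit("The family received support from ")
    a.slot("org", org)
    a.lit(".")
    b = _Built(text=a.text)
    os_, o0, o1 = a.slots["org"]
    b.abstracts.append({"target": SUPPORT, "answer": (os_, o0, o1)})
    b.true_hypotheses.add("Someone receives support.")
    b.qa_answers["What support is provided?"] = (o0, o1)
    return b


def _build_norel_pair(rng: random.Random, group: str) -> _Built:
    di, dr = rng.choice(_DI_POOL), rng.choice(_DR_POOL)
    a = _Assembler()
    a.lit("My letter about ")
    a.slot("di", di)
    a.lit(" arrived together with the note about ")
    a.slot("dr", dr)
    a.lit(".")
    b = _Built(text=a.text)
    ds, d0, d1 = a.slots["di"]
    rs, r0, r1 = a.slots["dr"]
    b.entities.append((DI, ds, d0, d1))
    b.entities.append((DR, rs, r0, r1))
    return b


def _build_set_freq(rng: random.Random, group: str) -> _Built:
    dr = rng.choice(_DR_POOL)
    a = _Assembler()
    a.lit("I take ")
    a.slot("dr", dr)
    a.lit(" ")
    a.slot("set", "daily")
    a.lit(" and try to stay active.")
    b = _Built(text=a.text)
    rs, r0, r1 = a.slots["dr"]
    ss, s0, s1 = a.slots["set"]
    b.entities.append((DR, rs, r0, r1))
    b.times.append((SET, ss, s0, s1))
    return b


def _build_plain_paa(rng: random.Random, group: str) -> _Built:
    template = rng.choice(_PAA_TEMPLATES)
    return _Built(text=template.format(org=rng.choice(_ORG_POOL)))


def _build_plain_sc(rng: random.Random, group: str) -> _Built:
    return _Built(
        text=f"{rng.choice(_SC_SUBJECTS)} {rng.choice(_SC_VERBS)} {rng.choice(_SC_OBJECTS)}"
    )


def _build_plain_cg(rng: random.Random, group: str) -> _Built:
    return _Built(text=f"{rng.choice(_CG_SUBJECTS)} {rng.choice(_CG_PREDICATES)}")


def _build_other(rng: random.Random, group: str) -> _Built:
    prefix = rng.choice(_O_PREFIXES)
    opener = rng.choice(_O_OPENERS)
    if prefix:
        opener = opener[0].lower() + opener[1:]
    return _Built(text=f"{prefix}{opener} {rng.choice(_O_CLOSERS)}")


#: group -> [(tags licensing the recipe, builder, base weight)]
_RECIPES = {
    PA: [
        ((ITO, DIAGNOSIS), _build_onset, 2.0),
        ((ITO,), _build_current_onset, 1.0),
        ((CR,), _build_creates, 1.5),
        ((EX,), _build_exacerbates, 1.0),
        ((AM,), _build_ameliorates, 1.0),
        ((), _build_norel_pair, 1.0),
        ((), _build_set_freq, 1.0),
    ],
    CG: [
        ((ITO, DIAGNOSIS), _build_onset, 2.0),
        ((DG,), _build_diagnoses, 1.0),
        ((MISDIAGNOSIS,), _build_misdiagnosis, 1.0),
        ((), _build_plain_cg, 1.0),
    ],
    SC: [
        ((IUF,), _build_used_for, 1.5),
        ((IAW,), _build_associated, 1.5),
        ((), _build_plain_sc, 1.0),
    ],
    PAA: [
        ((SUPPORT,), _build_support, 1.5),
        ((), _build_plain_paa, 1.0),
    ],
    O: [
        ((NEED,), _build_need, 0.8),
        ((), _build_other, 2.0),
    ],
}

_RELATION_TAGS = {AM, CR, DG, EX, IAW, ITO, IUF}
_ABSTRACT_TAGS = {NEED, SUPPORT, DIAGNOSIS, MISDIAGNOSIS}


def _recipe_weight(tags: tuple, base: float, config: GenerationConfig) -> float:
    w = base
    for tag in tags:
        if tag in _RELATION_TAGS:
            w *= config.relation_rates.get(tag, 1.0)
        if tag in _ABSTRACT_TAGS:
            w *= config.abstract_rates.get(tag, 1.0)
    return w


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------


def _largest_remainder(dist: dict[str, float], total: int) -> dict[str, int]:
    """Deterministic integer allocation matching the distribution."""
    quotas = {g: p * total for g, p in dist.items()}
    counts = {g: int(q) for g, q in quotas.items()}
    short = total - sum(counts.values())
    order = sorted(dist, key=lambda g: (counts[g] - quotas[g], g))
    for g in order[:short]:
        counts[g] += 1
    return counts


def _finalize_sentence(built: _Built, post_id: str, index: int) -> GoldSentence:
    sid = f"{post_id}:{index}"
    entities = [
        EntityMention(sentence_id=sid, concept_type=t, surface=s, start=a, end=b)
        for t, s, a, b in built.entities
    ]
    times = [
        TimeMention(sentence_id=sid, time_class=t, surface=s, start=a, end=b)
        for t, s, a, b in built.times
    ]

    def ref(token: str) -> ArgRef:
        kind, i = token.split(":")
        m = entities[int(i)] if kind == "ent" else times[int(i)]
        return ArgRef(
            surface=m.surface, arg_type=(m.concept_type if kind == "ent" else m.time_class),
            start=m.start, end=m.end,
        )

    relations = [
        RelationInstance(sentence_id=sid, arg1=ref(a1), arg2=ref(a2), relation=rel, score=1.0)
        for a1, rel, a2 in built.relations
    ]
    abstracts = []
    for spec in built.abstracts:
        if "entity" in spec:
            abstracts.append(
                AbstractMention(
                    sentence_id=sid, target=spec["target"], score=1.0,
                    trigger_entity=entities[spec["entity"]],
                )
            )
        else:
            surface, a, b = spec["answer"]
            abstracts.append(
                AbstractMention(
                    sentence_id=sid, target=spec["target"], score=1.0,
                    answer_text=surface, answer_start=a, answer_end=b,
                )
            )
    return GoldSentence(
        post_id=post_id, index=index, text=built.text, group="",
        entities=entities, times=times, relations=relations, abstracts=abstracts,
        onset_days=built.onset_days,
    )


def generate_corpus(config: GenerationConfig) -> tuple[list[Post], GoldAnnotations]:
    """Generate posts plus exact gold annotations; deterministic under seed."""
    rng = random.Random(config.seed)
    n_sent_per_post = [
        rng.randint(config.min_sentences, config.max_sentences)
        for _ in range(config.n_posts)
    ]
    total = sum(n_sent_per_post)
    counts = _largest_remainder(config.group_distribution, total)
    label_list = [g for g in LABELS for _ in range(counts.get(g, 0))]
    rng.shuffle(label_list)

    gold = GoldAnnotations(sentences=[])
    posts: list[Post] = []
    used_sentence_texts: set[str] = set()
    used_post_texts: set[str] = set()
    span_days = (config.end_date - config.start_date).days
    cursor = 0
    for p, k in enumerate(n_sent_per_post):
        post_id = f"p{p:05d}"
        published = config.start_date + datetime.timedelta(days=rng.randint(0, span_days))
        groups = label_list[cursor : cursor + k]
        cursor += k
        # distinct post text by retry: reposted duplicates are what the
        # deduplication stage removes, so the generator avoids planting them
        for _post_attempt in range(40):
            builts = [
                _draw_sentence(rng, group, config, used_sentence_texts)
                for group in groups
            ]
            post_text = " ".join(b.text for b in builts)
            if post_text not in used_post_texts:
                break
        used_post_texts.add(post_text)
        for index, (built, group) in enumerate(zip(builts, groups)):
            used_sentence_texts.add(built.text)
            sentence = _finalize_sentence(built, post_id, index)
            sentence = sentence.model_copy(update={"group": group})
            gold.sentences.append(sentence)
            gold.true_hypotheses.setdefault(built.text, set()).update(built.true_hypotheses)
            for question, span in built.qa_answers.items():
                gold.qa_answers[(question, built.text)] = span
            gold.label_of_text[built.text] = group
        posts.append(
            Post(
                post_id=post_id,
                published_at=published,
                text=post_text,
                source="synthetic",
                url=f"https://example.invalid/{post_id}",
            )
        )
    return posts, gold


def _draw_sentence(
    rng: random.Random,
    group: str,
    config: GenerationConfig,
    used_texts: set[str],
) -> _Built:
    recipes = _RECIPES[group]
    weights = [_recipe_weight(tags, w, config) for tags, _b, w in recipes]
    if sum(weights) <= 0:
        weights = [1.0 if not tags else 0.0 for tags, _b, _w in recipes]
    built = None
    for _attempt in range(60):
        tags, builder, _w = rng.choices(recipes, weights=weights)[0]
        built = builder(rng, group)
        if built.text not in used_texts:
            break
    return built


# ---------------------------------------------------------------------------
# Oracle backends
# ---------------------------------------------------------------------------


class OracleEntailmentScorer:
    """1.0 exactly for hypotheses planted as true for the premise, else 0.0."""

    def __init__(self, gold: GoldAnnotations):
        self._true = {text: frozenset(h) for text, h in gold.true_hypotheses.items()}

    def score(self, premise: str, hypothesis: str) -> float:
        return 1.0 if hypothesis in self._true.get(premise, frozenset()) else 0.0


class OracleAnswerer:
    """Returns the planted answer span for a (question, context) pair."""

    def __init__(self, gold: GoldAnnotations):
        self._answers = dict(gold.qa_answers)

    def answer(self, question: str, context: str) -> AnswerSpan | None:
        span = self._answers.get((question, context))
        if span is None:
            return None
        start, end = span
        return AnswerSpan(text=context[start:end], start=start, end=end)


class OracleEmbedder:
    """Label-separable vectors: a one-hot block per gold interest group."""

    dimension = len(LABELS) + 1

    def __init__(self, gold: GoldAnnotations):
        self._label_of = dict(gold.label_of_text)
        self._index = {label: i for i, label in enumerate(LABELS)}

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        out = np.zeros((len(texts), self.dimension))
        for row, text in enumerate(texts):
            label = self._label_of.get(text)
            if label is None:
                out[row, len(LABELS)] = 1.0
            else:
                out[row, self._index[label]] = 1.0
        return out


def oracle_backends(
    gold: GoldAnnotations,
) -> tuple[OracleEntailmentScorer, OracleAnswerer, OracleEmbedder]:
    return OracleEntailmentScorer(gold), OracleAnswerer(gold), OracleEmbedder(gold)


# ---------------------------------------------------------------------------
# Serialization (posts.jsonl + gold/ directory)
# ---------------------------------------------------------------------------


def write_gold(gold: GoldAnnotations, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def dump(name: str, rows) -> None:
        with open(out / name, "w", encoding="utf-8") as fh:
            for row in rows:
                fh.write(json.dumps(row, ensure_ascii=False) + "\n")

    dump("groups.jsonl", (
        {"sentence_id": s.sentence_id, "group": s.group, "text": s.text}
        for s in gold.sentences
    ))
    dump("mentions.jsonl", (
        m.model_dump() for s in gold.sentences for m in [*s.entities, *s.times]
    ))
    dump("relations.jsonl", (
        r.model_dump() for s in gold.sentences for r in s.relations
    ))
    dump("abstract.jsonl", (
        m.model_dump() for s in gold.sentences for m in s.abstracts
    ))
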