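"""End-to-end pipeline orchestration and downstream analytics.

Stages run in a fixed order per post: ingest (dedup/pseudonymize as
configured) -> sentence segmentation -> interest-group classification ->
lexicon NER (with disease/symptom overlap resolution) -> time NER ->
abstract-entity extraction -> relation extraction. A failure on one sentence
is logged and never aborts the corpus. The result carries provenance
(config hash, seed, backend names) sufficient to re-run identically.

Two analytics consume a serialized result without re-invoking any backend:

* sentence-level co-occurrence counts of a concept type with a target
  disease and its synonyms — a screening view of challenges (symptoms) and
  support (treatments); co-occurrence makes no relation claim, which is why
  the rows carry none;
* onset-day records: for sentences where the target disease is reported as
  diagnosed (or carries an is-time-of relation), the onset expression is
  normalized to days before the posting date, stratified by interest group.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

from pydantic import BaseModel, ConfigDict, Field

from .backends import Answerer, EntailmentScorer
from .corpus_io import (
    Post, Sentence, deduplicate_posts, pseudonymize_post, segment_post,
)
from .errors import ConfigurationError
from .interest_group import InterestGroupClassifier
from .lexicon_ner import (
    DI, ConceptLexicon, EntityMention, fixture_lexicon, match_concepts,
    normalize_term, resolve_disease_symptom_overlap,
)
from .relation_extraction import (
    ITO, RelationInstance, RelationSchema, default_schema, extract_relations,
)
from .time_extraction import (
    DATE, DURATION, TimeMention, extract_time_mentions, normalize_to_day_offset,
)
from .zero_shot_ie import (
    DIAGNOSIS, AbstractMention, HypothesisTemplate, default_templates,
    extract_abstract_mentions,
)

logger = logging.getLogger(__name__)

#: Default target-disease synonym list (the focus condition and its aliases).
DEFAULT_DISEASE_SYNONYMS = (
    "idiopathic pulmonary fibrosis",
    "IPF",
    "pulmonary fibrosis",
    "idiopathic lung fibrosis",
)


class SentenceResult(BaseModel):
    sentence: Sentence
    group: str | None = None
    entities: list[EntityMention] = []
    times: list[TimeMention] = []
    abstracts: list[AbstractMention] = []
    relations: list[RelationInstance] = []


class PipelineResult(BaseModel):
    posts: list[Post]
    sentences: list[SentenceResult]
    provenance: dict = {}

    def by_post(self) -> dict[str, list[SentenceResult]]:
        out: dict[str, list[SentenceResult]] = {}
        for sr in self.sentences:
            out.setdefault(sr.sentence.post_id, []).append(sr)
        return out


class PipelineConfig(BaseModel):
    model_config = ConfigDict(arbitrary_types_allowed=True)

    scorer: EntailmentScorer
    answerer: Answerer
    classifier: InterestGroupClassifier | None = None
    lexicon: ConceptLexicon | None = None
    schema_: RelationSchema | None = None
    templates: list[HypothesisTemplate] | None = None
    deduplicate: bool = True
    pseudonymize: bool = False
    seed: int = 0
    backend_names: dict[str, str] = {}


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(
        {
            "deduplicate": config.deduplicate,
            "pseudonymize": config.pseudonymize,
            "seed": config.seed,
            "backends": config.backend_names,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(posts: Sequence[Post], config: PipelineConfig) -> PipelineResult:
    """Run every stage over a corpus; per-sentence failures are logged."""
    lexicon = config.lexicon if config.lexicon is not None else fixture_lexicon()
    schema = config.schema_ if config.schema_ is not None else default_schema()
    templates = config.templates if config.templates is not None else default_templates()
    overlap = lexicon.overlap_terms()

    posts = list(posts)
    if config.deduplicate:
        posts = deduplicate_posts(posts)
    if config.pseudonymize:
        posts = [pseudonymize_post(p, seed=config.seed) for p in posts]

    results: list[SentenceResult] = []
    for post in posts:
        for sentence in segment_post(post):
            try:
                results.append(
                    _process_sentence(sentence, config, lexicon, overlap, schema, templates)
                )
            except Exception:
                logger.exception("sentence %s failed; skipping", sentence.sentence_id)
    return PipelineResult(
        posts=posts,
        sentences=results,
        provenance={
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "backends": dict(config.backend_names),
        },
    )


def _process_sentence(
    sentence: Sentence,
    config: PipelineConfig,
    lexicon: ConceptLexicon,
    overlap: set[str],
    schema: RelationSchema,
    templates,
) -> SentenceResult:
    group = None
    if config.classifier is not None:
        group = str(config.classifier.predict([sentence.text])[0])
    entities = resolve_disease_symptom_overlap(
        match_concepts(sentence, lexicon), overlap
    )
    times = extract_time_mentions(sentence)
    abstracts = extract_abstract_mentions(
        sentence, entities, templates, config.scorer, config.answerer
    )
    relations = extract_relations(
        sentence, [*entities, *times], schema, config.scorer
    )
    return SentenceResult(
        sentence=sentence, group=group, entities=entities, times=times,
        abstracts=abstracts, relations=relations,
    )


def write_result(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "result.jsonl", "w", encoding="utf-8") as fh:
        for sr in result.sentences:
            fh.write(sr.model_dump_json() + "\n")
    with open(out / "posts.jsonl", "w", encoding="utf-8") as fh:
        for post in result.posts:
            fh.write(json.dumps(post.model_dump(mode="json")) + "\n")
    (out / "manifest.json").write_text(
        json.dumps(result.provenance, indent=2, sort_keys=True), encoding="utf-8"
    )


def read_result(out_dir: str | Path) -> PipelineResult:
    out = Path(out_dir)
    sentences = [
        SentenceResult.model_validate_json(line)
        for line in (out / "result.jsonl").read_text(encoding="utf-8").splitlines()
        if line.strip()
    ]
    posts = [
        Post.model_validate(json.loads(line))
        for line in (out / "posts.jsonl").read_text(encoding="utf-8").splitlines()
        if line.strip()
    ]
    provenance = json.loads((out / "manifest.json").read_text(encoding="utf-8"))
    return PipelineResult(posts=posts, sentences=sentences, provenance=provenance)


# ---------------------------------------------------------------------------
# Analytics
# ---------------------------------------------------------------------------


class CooccurrenceRow(BaseModel):
    surface: str
    concept_type: str
    count: int = Field(ge=0)


class OnsetRecord(BaseModel):
    post_id: str
    interest_group: str | None
    sentence_text: str
    abs_days: int = Field(ge=0)
    #: which linkage produced the record: an is-time-of relation or a
    #: diagnosis mention co-occurring with one resolvable time expression.
    via: str


def _mentions_target(entities: Iterable[EntityMention], targets: set[str]) -> bool:
    return any(normalize_term(e.surface) in targets for e in entities)


def cooccurrence_table(
    result: PipelineResult,
    target_terms: Sequence[str] = DEFAULT_DISEASE_SYNONYMS,
    concept_type: str = "SY",
) -> list[CooccurrenceRow]:
    """Count sentences where a target-disease mention co-occurs with a
    mention of the filtered concept type; ranked descending, ties
    alphabetical. Co-occurrence carries no relation claim."""
    targets = {normalize_term(t) for t in target_terms}
    counts: dict[str, int] = {}
    for sr in result.sentences:
        if not _mentions_target(sr.entities, targets):
            continue
        surfaces = {
            normalize_term(e.surface)
            for e in sr.entities
            if e.concept_type == concept_type and normalize_term(e.surface) not in targets
        }
        for surface in surfaces:
            counts[surface] = counts.get(surface, 0) + 1
    rows = [
        CooccurrenceRow(surface=s, concept_type=concept_type, count=n)
        for s, n in counts.items()
    ]
    rows.sort(key=lambda r: (-r.count, r.surface))
    return rows


def compute_onset_days(
    result: PipelineResult,
    target_terms: Sequence[str] = DEFAULT_DISEASE_SYNONYMS,
) -> list[OnsetRecord]:
    """Onset-day records for the target disease.

    A sentence qualifies through either linkage: (a) an is-time-of relation
    whose biomedical argument is a target-disease mention — the relation's
    time argument is the onset expression; or (b) a diagnosis mention of the
    target disease co-occurring with exactly one resolvable past-pointing
    time expression. Unresolvable expressions are skipped. The posting date
    is the reference.
    """
    targets = {normalize_term(t) for t in target_terms}
    published = {p.post_id: p.published_at for p in result.posts}
    records: list[OnsetRecord] = []
    for sr in result.sentences:
        post_id = sr.sentence.post_id
        reference = published.get(post_id)
        if reference is None:
            continue
        time_by_span = {(t.start, t.end): t for t in sr.times}

        record = None
        for rel in sr.relations:
            if rel.relation != ITO:
                continue
            time_arg, bio_arg = rel.arg1, rel.arg2
            if time_arg.arg_type not in (DATE, DURATION):
                time_arg, bio_arg = bio_arg, time_arg
            if normalize_term(bio_arg.surface) not in targets:
                continue
            mention = time_by_span.get((time_arg.start, time_arg.end))
            if mention is None or mention.time_class not in (DATE, DURATION):
                continue
            offset = normalize_to_day_offset(mention, reference)
            if offset.resolvable:
                record = (offset.days, "ito")
                break
        if record is None:
            diagnosed = any(
                a.target == DIAGNOSIS
                and a.trigger_entity is not None
                and normalize_term(a.trigger_entity.surface) in targets
                for a in sr.abstracts
            )
            if diagnosed:
                resolvable = [
                    normalize_to_day_offset(t, reference)
                    for t in sr.times
                    if t.time_class in (DATE, DURATION)
                ]
                resolvable = [o for o in resolvable if o.resolvable]
                if len(resolvable) == 1:
                    record = (resolvable[0].days, "diagnosis")
        if record is not None:
            records.append(
                OnsetRecord(
                    post_id=post_id,
                    interest_group=sr.group,
                    sentence_text=sr.sentence.text,
                    abs_days=record[0],
                    via=record[1],
                )
            )
    return records
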