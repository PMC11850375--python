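import datetime
import logging

import pytest

from patientlens.corpus_io import Post, Sentence
from patientlens.interest_group import InterestGroupClassifier
from patientlens.pipeline_analytics import PipelineConfig, run_pipeline
from patientlens.synthetic_corpus import (
    GenerationConfig, generate_corpus, oracle_backends,
)

# the reference annotator legitimately lacks parse capabilities; do not spam
logging.getLogger("patientlens.lexicon_ner").setLevel(logging.ERROR)


def make_sentence(text: str, post_id: str = "p0", index: int = 0) -> Sentence:
    """Sentence wrapper for single-sentence fixtures (offsets are post-local)."""
    return Sentence(post_id=post_id, index=index, text=text, start=0, end=len(text))


def make_post(text: str, post_id: str = "p0", date: str = "2023-06-01", **kw) -> Post:
    return Post(
        post_id=post_id, published_at=datetime.date.fromisoformat(date), text=text, **kw
    )


@pytest.fixture(scope="session")
def oracle_run():
    """A 50-post synthetic corpus, its gold, and a pipeline run with oracle backends."""
    posts, gold = generate_corpus(GenerationConfig(n_posts=50, seed=1))
    scorer, answerer, embedder = oracle_backends(gold)
    classifier = InterestGroupClassifier(embedder=embedder, random_state=0).fit(
        [s.text for s in gold.sentences], [s.group for s in gold.sentences]
    )
    config = PipelineConfig(scorer=scorer, answerer=answerer, classifier=classifier)
    result = run_pipeline(posts, config)
    return posts, gold, result, config
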