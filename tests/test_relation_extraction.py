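import itertools

import pytest

from patientlens.errors import ConfigurationError, ContractViolationError
from patientlens.lexicon_ner import DI, DR, SY, TR, EntityMention
from patientlens.relation_extraction import (
    AM, CR, DG, EX, FORWARD, IAW, ITO, IUF, NOREL, REVERSE,
    RelationSchema,
    apply_cue_demotion,
    default_schema,
    extract_relations,
    generate_hypotheses,
    select_relation,
)
from patientlens.time_extraction import DATE, TimeMention

from conftest import make_sentence

SCHEMA = default_schema()


def ent(sentence, surface, ctype):
    start = sentence.text.index(surface)
    return EntityMention(
        sentence_id=sentence.sentence_id, concept_type=ctype, surface=surface,
        start=start, end=start + len(surface),
    )


def tm(sentence, surface, cls=DATE):
    start = sentence.text.index(surface)
    return TimeMention(
        sentence_id=sentence.sentence_id, time_class=cls, surface=surface,
        start=start, end=start + len(surface),
    )


class TestHypothesisGeneration:
    def test_causal_pair_generates_both_directions(self):
        s = make_sentence("clubbing due to pulmonary fibrosis")
        pair = (ent(s, "pulmonary fibrosis", DI), ent(s, "clubbing", SY))
        hyps = generate_hypotheses(s, pair, SCHEMA)
        texts = {h for r, d, h in hyps if r == CR}
        assert texts == {
            "pulmonary fibrosis leads to clubbing",
            "clubbing leads to pulmonary fibrosis",
        }

    def test_disease_time_pair_prunes_causal_keeps_temporal(self):
        s = make_sentence("idiopathic pulmonary fibrosis since yesterday")
        pair = (ent(s, "idiopathic pulmonary fibrosis", DI), tm(s, "yesterday"))
        hyps = generate_hypotheses(s, pair, SCHEMA)
        relations = {r for r, _, _ in hyps}
        assert CR not in relations and IAW not in relations
        assert relations == {ITO}
        # time is always the first concept of the temporal hypothesis
        assert all(h.startswith("yesterday") for r, d, h in hyps)

    def test_symmetric_relation_single_canonical_instantiation(self):
        s = make_sentence("cough with IPF")
        pair = (ent(s, "IPF", DI), ent(s, "cough", SY))
        iaw = [(d, h) for r, d, h in generate_hypotheses(s, pair, SCHEMA) if r == IAW]
        assert iaw == [(FORWARD, "cough is associated with IPF")]

    def test_foreign_mention_rejected(self):
        s = make_sentence("text")
        other = make_sentence("other text", post_id="p9")
        with pytest.raises(ContractViolationError):
            generate_hypotheses(s, (ent(other, "other", DI), ent(other, "text", SY)), SCHEMA)

    def test_schema_validation_rejects_time_in_causal(self):
        with pytest.raises(ConfigurationError):
            RelationSchema(
                templates={r: ["{concept 1} x {concept 2}"] for r in
                           (AM, CR, DG, EX, IAW, IUF, ITO)},
                admissible={CR: {(DATE, DI)}},
                cues={},
            )


class TestSelection:
    def test_argmax_wins(self):
        scored = [(CR, FORWARD, 0.9), (CR, REVERSE, 0.1), (IAW, FORWARD, 0.6)]
        assert select_relation(scored, SCHEMA) == (CR, FORWARD, 0.9)

    def test_all_below_threshold_is_norel(self):
        scored = [(CR, FORWARD, 0.2), (IAW, FORWARD, 0.15)]
        relation, direction, _ = select_relation(scored, SCHEMA)
        assert relation == NOREL and direction is None

    def test_empty_candidates_norel(self):
        assert select_relation([], SCHEMA) == (NOREL, None, 0.0)

    def test_tie_breaks_by_precedence_then_direction(self):
        scored = [(IUF, FORWARD, 0.8), (DG, REVERSE, 0.8), (DG, FORWARD, 0.8)]
        assert select_relation(scored, SCHEMA) == (DG, FORWARD, 0.8)


class TestCueDemotion:
    def test_uncued_ameliorates_demotes_to_used_for(self):
        out = apply_cue_demotion((AM, FORWARD, 0.9), "pirfenidone for my cough", SCHEMA)
        assert out == (IUF, FORWARD, 0.9)

    def test_cued_exacerbates_unchanged(self):
        out = apply_cue_demotion((EX, FORWARD, 0.9), "smoke will worsen the cough", SCHEMA)
        assert out == (EX, FORWARD, 0.9)

    def test_uncued_creates_demotes_to_symmetric_canonical(self):
        out = apply_cue_demotion((CR, REVERSE, 0.9), "IPF and clubbing together", SCHEMA)
        assert out == (IAW, FORWARD, 0.9)

    def test_cue_match_is_word_boundary(self):
        # a trigger embedded in a longer word does not license the micro-relation
        assert SCHEMA.has_cue(EX, "it got worse") is True
        assert SCHEMA.has_cue(EX, "norse mythology") is False
        out = apply_cue_demotion((EX, FORWARD, 0.9), "norse mythology", SCHEMA)
        assert out[0] == IAW


class TestExtraction:
    def test_worked_causal_sentence(self):
        s = make_sentence(
            "I have severe clubbing of my fingers due to my Pulmonary Fibrosis "
            "and I sometimes do not read what I have tweeted"
        )
        mentions = [ent(s, "Pulmonary Fibrosis", DI), ent(s, "clubbing", SY)]

        class OracleLike:
            def score(self, premise, hypothesis):
                return 1.0 if hypothesis == "Pulmonary Fibrosis leads to clubbing" else 0.0

        instances = extract_relations(s, mentions, SCHEMA, OracleLike())
        assert len(instances) == 1
        assert instances[0].triple() == ("Pulmonary Fibrosis", CR, "clubbing")

    def test_no_mentions_no_relations(self):
        s = make_sentence("nothing to pair up")
        assert extract_relations(s, [], SCHEMA, None) == []

    def test_three_mentions_three_pairs(self):
        s = make_sentence("cough and IPF treated with pirfenidone")
        mentions = [ent(s, "cough", SY), ent(s, "IPF", DI), ent(s, "pirfenidone", DR)]

        class Counting:
            def __init__(self):
                self.pairs = set()

            def score(self, premise, hypothesis):
                self.pairs.add(hypothesis)
                return 0.0

        scorer = Counting()
        instances = extract_relations(s, mentions, SCHEMA, scorer, emit_norel=True)
        assert len(instances) == len(list(itertools.combinations(mentions, 2)))
        assert all(i.relation == NOREL for i in instances)

    def test_norel_suppressed_by_default(self):
        s = make_sentence("cough and IPF")
        mentions = [ent(s, "cough", SY), ent(s, "IPF", DI)]

        class Zero:
            def score(self, premise, hypothesis):
                return 0.0

        assert extract_relations(s, mentions, SCHEMA, Zero()) == []

    def test_iaw_invariant_under_argument_swap(self):
        s = make_sentence("researchers link cough with IPF broadly")
        m1, m2 = ent(s, "cough", SY), ent(s, "IPF", DI)

        class IawScorer:
            def score(self, premise, hypothesis):
                return 0.9 if "associated" in hypothesis else 0.0

        a = extract_relations(s, [m1, m2], SCHEMA, IawScorer())
        b = extract_relations(s, [m2, m1], SCHEMA, IawScorer())
        assert a == b
        assert a[0].relation == IAW
        assert a[0].arg1.start < a[0].arg2.start

    def test_micro_relation_requires_trigger_in_sentence(self):
        s = make_sentence("my IPF and my cough")  # no causal connective
        mentions = [ent(s, "IPF", DI), ent(s, "cough", SY)]

        class CrScorer:
            def score(self, premise, hypothesis):
                return 0.9 if hypothesis == "IPF leads to cough" else 0.0

        instances = extract_relations(s, mentions, SCHEMA, CrScorer())
        assert [i.relation for i in instances] == [IAW]

    def test_no_external_knowledge_dependency(self):
        """Relations come from the stated text only: same mentions, different
        sentence text, different outcome."""
        s1 = make_sentence("my cough is due to my IPF")
        s2 = make_sentence("my cough is unrelated to my IPF")

        class TextScorer:
            def score(self, premise, hypothesis):
                return 0.9 if "due to" in premise and hypothesis == "IPF leads to cough" else 0.0

        r1 = extract_relations(s1, [ent(s1, "cough", SY), ent(s1, "IPF", DI)], SCHEMA, TextScorer())
        r2 = extract_relations(s2, [ent(s2, "cough", SY), ent(s2, "IPF", DI)], SCHEMA, TextScorer())
        assert [i.relation for i in r1] == [CR]
        assert r2 == []
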