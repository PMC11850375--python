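import pytest

from patientlens.backends import OverlapEntailmentScorer, PatternAnswerer
from patientlens.errors import ContractViolationError
from patientlens.lexicon_ner import DI, DR, EntityMention
from patientlens.zero_shot_ie import (
    DIAGNOSIS, MISDIAGNOSIS, NEED,
    HypothesisTemplate,
    classify_diagnosis_status,
    default_templates,
    extract_abstract_mentions,
    extract_target_span,
    screen_sentence,
)

from conftest import make_sentence


class FixedScorer:
    """Scores by hypothesis lookup; unknown hypotheses get a default."""

    def __init__(self, table, default=0.0):
        self.table, self.default = table, default

    def score(self, premise, hypothesis):
        return self.table.get(hypothesis, self.default)


def di_mention(sentence, surface):
    start = sentence.text.index(surface)
    return EntityMention(
        sentence_id=sentence.sentence_id, concept_type=DI, surface=surface,
        start=start, end=start + len(surface),
    )


NEED_TEMPLATE = HypothesisTemplate(
    target=NEED, pattern="Someone needs something.", questions=["What is needed?"], threshold=0.5
)


class TestTemplates:
    def test_grounded_requires_exactly_one_slot(self):
        with pytest.raises(ValueError):
            HypothesisTemplate(target=DIAGNOSIS, pattern="no slot here.")

    def test_ungrounded_requires_questions(self):
        with pytest.raises(ValueError):
            HypothesisTemplate(target=NEED, pattern="Someone needs something.", questions=[])

    def test_default_bank_loads_with_canonical_items(self):
        bank = default_templates()
        patterns = {t.pattern for t in bank}
        assert "Someone needs something." in patterns
        assert "{entity} was diagnosed." in patterns
        assert "{entity} was detected." in patterns


class TestScreening:
    def test_printed_need_sentence_passes_with_reference_scorer(self):
        sentence = make_sentence(
            "A local resident in need of a lung transplant is struggling to survive "
            "due to severe complications arising from COVID-19 infection"
        )
        score, passed = screen_sentence(sentence, NEED_TEMPLATE, OverlapEntailmentScorer())
        assert passed and score > 0.5

    def test_score_exactly_at_threshold_fails(self):
        scorer = FixedScorer({"Someone needs something.": 0.5})
        _, passed = screen_sentence(make_sentence("anything"), NEED_TEMPLATE, scorer)
        assert not passed

    def test_grounded_template_rejected(self):
        grounded = HypothesisTemplate(target=DIAGNOSIS, pattern="{entity} was diagnosed.")
        with pytest.raises(ContractViolationError):
            screen_sentence(make_sentence("x"), grounded, FixedScorer({}))


class TestQuestionAnswering:
    def test_worked_example_span(self):
        sentence = make_sentence("A local resident in need of a lung transplant is struggling")
        span = extract_target_span(sentence, NEED_TEMPLATE, PatternAnswerer())
        assert span.text == "a lung transplant"

    def test_no_matching_question_absent(self):
        sentence = make_sentence("totally unrelated content")
        assert extract_target_span(sentence, NEED_TEMPLATE, PatternAnswerer()) is None

    def test_question_order_is_priority(self):
        class Recorder:
            def __init__(self):
                self.asked = []

            def answer(self, question, context):
                from patientlens.backends import AnswerSpan
                self.asked.append(question)
                return AnswerSpan(text=context[:3], start=0, end=3)

        template = HypothesisTemplate(
            target=NEED, pattern="Someone needs something.",
            questions=["first question?", "second question?"],
        )
        answerer = Recorder()
        span = extract_target_span(make_sentence("abcdef"), template, answerer)
        assert span.text == "abc"
        assert answerer.asked == ["first question?"]


class TestDiagnosisGrounding:
    def test_diagnosis_detected(self):
        sentence = make_sentence(
            "my health took a turn in 2022 when I received a diagnosis of pulmonary fibrosis"
        )
        entity = di_mention(sentence, "pulmonary fibrosis")
        scorer = FixedScorer({"pulmonary fibrosis was diagnosed.": 0.9})
        result = classify_diagnosis_status(sentence, entity, default_templates(), scorer)
        assert result.target == DIAGNOSIS
        assert result.trigger_entity == entity
        assert result.score == 0.9

    def test_misdiagnosis_wins_when_both_pass(self):
        sentence = make_sentence(
            "passed away from pulmonary fibrosis which remained unacknowledged by his physician"
        )
        entity = di_mention(sentence, "pulmonary fibrosis")
        scorer = FixedScorer(
            {
                "pulmonary fibrosis was diagnosed.": 0.6,
                "pulmonary fibrosis was missed.": 0.8,
            }
        )
        result = classify_diagnosis_status(sentence, entity, default_templates(), scorer)
        assert result.target == MISDIAGNOSIS

    def test_max_over_pattern_variants(self):
        sentence = make_sentence("imaging scans revealed that I have developed pulmonary fibrosis")
        entity = di_mention(sentence, "pulmonary fibrosis")
        scorer = FixedScorer(
            {
                "pulmonary fibrosis was diagnosed.": 0.1,
                "pulmonary fibrosis was detected.": 0.7,
            }
        )
        result = classify_diagnosis_status(sentence, entity, default_templates(), scorer)
        assert result.target == DIAGNOSIS and result.score == 0.7

    def test_below_threshold_absent(self):
        sentence = make_sentence("pulmonary fibrosis is a disease")
        entity = di_mention(sentence, "pulmonary fibrosis")
        assert classify_diagnosis_status(
            sentence, entity, default_templates(), FixedScorer({})
        ) is None

    def test_drug_entity_violates_contract(self):
        sentence = make_sentence("she takes pirfenidone")
        entity = EntityMention(
            sentence_id=sentence.sentence_id, concept_type=DR,
            surface="pirfenidone", start=10, end=21,
        )
        with pytest.raises(ContractViolationError):
            classify_diagnosis_status(sentence, entity, default_templates(), FixedScorer({}))


class TestPipelineOrdering:
    def test_failed_screening_never_reaches_answering(self):
        class ExplodingAnswerer:
            def answer(self, question, context):
                raise AssertionError("answerer must not run after failed screening")

        sentence = make_sentence("nothing here")
        mentions = extract_abstract_mentions(
            sentence, [], [NEED_TEMPLATE], FixedScorer({}), ExplodingAnswerer()
        )
        assert mentions == []

    def test_all_emitted_mentions_exceed_threshold(self):
        sentence = make_sentence("Our neighbour is in need of a second opinion.")
        scorer = FixedScorer({"Someone needs something.": 0.9})
        mentions = extract_abstract_mentions(
            sentence, [], [NEED_TEMPLATE], scorer, PatternAnswerer()
        )
        assert mentions and all(m.score > 0.5 for m in mentions)
        assert mentions[0].answer_text == "a second opinion"

    def test_screened_but_unanswered_suppressed_by_default(self):
        sentence = make_sentence("so much is required of us these days")
        scorer = FixedScorer({"Someone needs something.": 0.9})
        assert extract_abstract_mentions(
            sentence, [], [NEED_TEMPLATE], scorer, PatternAnswerer()
        ) == []
        kept = extract_abstract_mentions(
            sentence, [], [NEED_TEMPLATE], scorer, PatternAnswerer(), require_answer=False
        )
        assert len(kept) == 1 and kept[0].answer_text is None
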