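import random

import pytest

from patientlens.errors import ConfigurationError
from patientlens.lexicon_ner import (
    DEFAULT_TYPE_PRECEDENCE,
    DI, DR, SY, TR,
    ClassHierarchy,
    ConceptLexicon,
    LexiconEntry,
    TokenAnnotation,
    compile_treatment_lexicon,
    fixture_lexicon,
    match_concepts,
    normalize_term,
    regex_annotator,
    resolve_disease_symptom_overlap,
)

from conftest import make_sentence


def entry(term, ctype, cid="X", source="src"):
    return LexiconEntry(term=term, concept_type=ctype, canonical_id=cid, source=source)


# ---------------------------------------------------------------------------
# Brute-force oracle: scan every substring, check token-boundary-aligned
# lexicon membership, filters, then leftmost-longest with type precedence.
# ---------------------------------------------------------------------------

def brute_force_match(sentence, lexicon, annotator=regex_annotator):
    text = sentence.text
    ann = annotator(text)
    starts = {s for s, _ in ann.tokens}
    ends = {e for _, e in ann.tokens}
    head_of = {}
    for i in range(len(text) + 1):
        for j in range(i + 1, len(text) + 1):
            if i in starts and j in ends:
                for e in lexicon.lookup(normalize_term(text[i:j])):
                    last_tok = max(k for k, (_, te) in enumerate(ann.tokens) if te <= j)
                    head_of[(i, j, e.canonical_id, e.concept_type)] = (e, last_tok)
    candidates = []
    for (i, j, _cid, _ct), (e, last_tok) in head_of.items():
        if ann.org_spans is not None and any(
            os <= i and j <= oe for os, oe in ann.org_spans
        ):
            continue
        if ann.pos is not None and ann.pos[last_tok] not in {"NOUN", "PROPN"}:
            continue
        candidates.append((i, j, e))
    rank = {t: k for k, t in enumerate(DEFAULT_TYPE_PRECEDENCE)}
    chosen = []
    while candidates:
        best = min(
            candidates,
            key=lambda c: (c[0], -c[1], rank[c[2].concept_type], c[2].canonical_id),
        )
        chosen.append(best)
        candidates = [c for c in candidates if c[0] >= best[1]]
    return [(i, j, e.concept_type) for i, j, e in chosen]


class TestTreatmentLexiconCompilation:
    def toy(self):
        return ClassHierarchy(
            edges=[
                ("oxygen_therapy", "therapy"),
                ("spirometry", "medical_test"),
                ("medical_test", "medical_procedure"),
            ],
            labels={
                "therapy": "therapy",
                "oxygen_therapy": "oxygen therapy",
                "spirometry": "spirometry",
                "medical_test": "medical test",
                "medical_procedure": "medical procedure",
            },
        )

    def test_include_minus_exclude_descendants(self):
        entries = compile_treatment_lexicon(
            self.toy(), {"therapy", "medical_procedure"}, {"medical_test"}
        )
        terms = {e.term for e in entries}
        assert terms == {"therapy", "oxygen therapy", "medical procedure"}
        assert all(e.concept_type == TR for e in entries)
        # brute-force reachability oracle
        hierarchy = self.toy()
        reach = (
            hierarchy.descendants("therapy") | hierarchy.descendants("medical_procedure")
        ) - hierarchy.descendants("medical_test")
        assert terms == {hierarchy.labels[n] for n in reach}

    def test_empty_exclude_returns_all_included(self):
        entries = compile_treatment_lexicon(self.toy(), {"medical_procedure"})
        assert {e.term for e in entries} == {"medical procedure", "medical test", "spirometry"}

    def test_exclusion_wins_for_node_under_both(self):
        hierarchy = ClassHierarchy(
            edges=[("x", "inc"), ("x", "exc")],
            labels={"x": "x label", "inc": "inc", "exc": "exc"},
        )
        entries = compile_treatment_lexicon(hierarchy, {"inc"}, {"exc"})
        assert {e.term for e in entries} == {"inc"}

    def test_unknown_root_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            compile_treatment_lexicon(self.toy(), {"nonexistent"})

    def test_cycle_detected(self):
        with pytest.raises(ConfigurationError):
            ClassHierarchy(edges=[("a", "b"), ("b", "a")], labels={"a": "a", "b": "b"})


class TestMatcher:
    def test_single_drug_match(self):
        lex = ConceptLexicon(entries=[entry("pirfenidone", DR), entry("nintedanib", DR)])
        mentions = match_concepts(make_sentence("She takes pirfenidone daily"), lex)
        assert [(m.concept_type, m.surface) for m in mentions] == [(DR, "pirfenidone")]

    def test_no_terms_no_mentions(self):
        lex = ConceptLexicon(entries=[entry("placeholder", DI)])
        assert match_concepts(make_sentence("nothing matches here"), lex) == []
        assert match_concepts(make_sentence(""), lex) == []

    def test_organization_span_filter(self):
        text = "donated to the Canadian Pulmonary Fibrosis Foundation"
        lex = ConceptLexicon(entries=[entry("pulmonary fibrosis", DI)])

        def annotator(t):
            ann = regex_annotator(t)
            ann.org_spans = [(text.index("Canadian"), len(text))]
            return ann

        assert match_concepts(make_sentence(text), lex, annotator=annotator) == []
        # without the capability the mention is (knowingly) kept
        assert len(match_concepts(make_sentence(text), lex)) == 1

    def test_head_noun_filter(self):
        lex = ConceptLexicon(entries=[entry("cough", SY)])
        text = "I cough all night"

        def annotator(t):
            ann = regex_annotator(t)
            ann.pos = ["PRON", "VERB", "DET", "NOUN"]
            return ann

        assert match_concepts(make_sentence(text), lex, annotator=annotator) == []

    def test_blacklisted_term_never_matches(self):
        lex = ConceptLexicon(
            entries=[entry("application", DR, source="dron")],
            blacklist={"dron": {"application"}},
        )
        assert match_concepts(make_sentence("submit the application"), lex) == []

    def test_blacklist_monotonicity(self):
        entries = [entry("cough", SY), entry("pulmonary fibrosis", DI, source="mesh")]
        text = "pulmonary fibrosis with cough"
        before = match_concepts(make_sentence(text), ConceptLexicon(entries=entries))
        after = match_concepts(
            make_sentence(text),
            ConceptLexicon(entries=entries, blacklist={"mesh": {"pulmonary fibrosis"}}),
        )
        kept = {(m.start, m.end) for m in after}
        assert kept <= {(m.start, m.end) for m in before}
        assert len(after) < len(before)

    def test_leftmost_longest_wins(self):
        lex = ConceptLexicon(
            entries=[entry("idiopathic pulmonary fibrosis", DI), entry("pulmonary fibrosis", DI)]
        )
        mentions = match_concepts(make_sentence("idiopathic pulmonary fibrosis is rare"), lex)
        assert [m.surface for m in mentions] == ["idiopathic pulmonary fibrosis"]

    def test_no_overlapping_mentions_returned(self):
        lex = fixture_lexicon()
        text = "idiopathic pulmonary fibrosis and pulmonary fibrosis with cough and oxygen therapy"
        mentions = match_concepts(make_sentence(text), lex)
        spans = sorted((m.start, m.end) for m in mentions)
        assert all(e1 <= s2 for (_, e1), (s2, _) in zip(spans, spans[1:]))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle_on_random_sentences(self, seed):
        rng = random.Random(seed)
        lex = fixture_lexicon()
        terms = sorted({e.term for e in lex.entries})
        fillers = "the and with from since about after while some very really my her".split()
        for _ in range(40):
            words = []
            while len(" ".join(words)) < 120:
                words.append(rng.choice(terms) if rng.random() < 0.4 else rng.choice(fillers))
            sentence = make_sentence(" ".join(words)[:200])
            got = [(m.start, m.end, m.concept_type) for m in match_concepts(sentence, lex)]
            assert got == brute_force_match(sentence, lex)


class TestDiseaseSymptomOverlap:
    def test_overlap_term_relabeled_to_symptom(self):
        lex = ConceptLexicon(entries=[entry("cough", DI), entry("cough", SY)])
        mentions = match_concepts(make_sentence("a cough since March"), lex)
        assert [m.concept_type for m in mentions] == [DI]  # precedence DI > SY
        resolved = resolve_disease_symptom_overlap(mentions, lex.overlap_terms())
        assert [m.concept_type for m in resolved] == [SY]

    def test_empty_overlap_set_is_identity(self):
        lex = ConceptLexicon(entries=[entry("asthma", DI)])
        mentions = match_concepts(make_sentence("asthma runs in the family"), lex)
        assert resolve_disease_symptom_overlap(mentions, set()) == mentions

    def test_mixed_batch_relabels_exactly_overlapping(self):
        overlap = {"cough", "fatigue"}
        mentions = [
            m for text, ct in [
                ("cough", DI), ("fatigue", DI), ("asthma", DI), ("emphysema", DI), ("copd", DI)
            ]
            for m in match_concepts(
                make_sentence(text), ConceptLexicon(entries=[entry(text, ct)])
            )
        ]
        resolved = resolve_disease_symptom_overlap(mentions, overlap)
        assert sum(1 for m in resolved if m.concept_type == SY) == 2
        assert sum(1 for m in resolved if m.concept_type == DI) == 3
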