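# patientlens

Social-media listening (SML) NLP for patient-focused drug development
(PFDD): given a focus disease — idiopathic pulmonary fibrosis (IPF) is the
packaged default — extract from social-media posts **who** is speaking
(patients, caregivers, patient associations, the scientific community),
**which challenges** they report (symptoms, drugs, treatments, needs,
diagnoses and misdiagnoses, disease onset), and **which support** they
receive. It is written for text-mining practitioners and pharma teams who
need structured patient-experience data from forums and social platforms
without annotating large corpora.

All analysis is sentence-level: perspectives and topics shift within a
post, and sentence units keep annotation and evaluation unambiguous.

## Method

The pipeline combines four components, each hidden behind a small backend
contract so learned models are swappable configuration, not method:

1. **Interest-group classification** (few-shot). Sentence embeddings feed a
   multinomial logistic head over five mutually exclusive labels
   {PA, CG, PAA, SC, O}; post-level output is the multi-label union of the
   non-O sentence labels.
2. **Primary biomedical NER** (lexicon/ontology lookup). Disease (DI), drug
   (DR), symptom (SY) and treatment (TR) terms are matched
   case-insensitively at token boundaries, leftmost-longest, with
   per-source blacklists, an ORGANIZATION-span filter, a head-noun filter,
   and the convention that terms occurring in both disease and symptom
   inventories count as symptoms. A treatment inventory can be compiled
   from a class hierarchy (descendants of *therapy* and *medical procedure*
   minus diagnostic subclasses).
3. **Zero-shot extraction of abstract entities** via natural-language
   inference (NLI). A hypothesis *H* ("Someone needs something.") is scored
   against each sentence (the premise *P*); sentences whose entailment
   score exceeds a threshold are passed to an extractive
   question-answering step ("What is needed?" → *a lung transplant*).
   Diagnosis/misdiagnosis hypotheses are grounded in previously extracted
   DI/SY mentions ("{entity} was diagnosed.").
4. **Zero-shot relation extraction**. For each admissible mention pair and
   relation template ("{concept 1} leads to {concept 2}"), hypotheses are
   generated in both argument orders (the winning order fixes the
   direction), scored with the NLI backend, and the argmax wins if it
   exceeds the threshold (default 0.2), else the pair is NoRel. The
   micro-relations *ameliorates*, *creates*, *exacerbates* additionally
   require an in-sentence lexical trigger ("improve", "due to", "worsen");
   otherwise they are demoted to their macro-relations *is used for* / *is
   associated with*. *Is associated with* is symmetric and canonicalized
   by offset order.

Time mentions (DATE, DURATION, TIME, SET; "now"/"currently" always DATE)
are normalized to day offsets from the posting date under coarse calendar
conventions (year = 365 d, month = 30 d, week = 7 d), yielding per-group
disease-onset records.

Deterministic reference backends (token-overlap entailment scorer,
pattern-table answerer, hashing embedder) ship with the package so
everything runs offline; `synthetic_corpus` generates gold-annotated
corpora with oracle backends for exact end-to-end verification. See
`docs/methods.md` for conventions, parameters and limitations.

## Worked example

```python
import datetime
from patientlens import Post
from patientlens.backends import OverlapEntailmentScorer, PatternAnswerer
from patientlens.pipeline_analytics import PipelineConfig, run_pipeline, compute_onset_days

posts = [Post(post_id="p1", published_at=datetime.date(2023, 6, 1),
              text="Two weeks ago I received a diagnosis of IPF.")]
config = PipelineConfig(scorer=OverlapEntailmentScorer(), answerer=PatternAnswerer())
result = run_pipeline(posts, config)
for sr in result.sentences:
    for m in sr.entities:  print("entity:", m.concept_type, m.surface)
    for t in sr.times:     print("time:  ", t.time_class, t.surface)
    for a in sr.abstracts: print("abstract:", a.target, a.trigger_entity.surface)
    for r in sr.relations: print("relation:", r.arg1.surface, f"-{r.relation}->", r.arg2.surface)
for rec in compute_onset_days(result):
    print("onset days:", rec.abs_days, "via", rec.via)
```

prints

```
entity: DI IPF
time:   DATE Two weeks ago
abstract: DIAGNOSIS IPF
relation: Two weeks ago -ITO-> IPF
onset days: 14 via ito
```

i.e. the sentence reports the focus disease as diagnosed, links the date
expression to it as its onset time (ITO = *is time of*), and the onset is
normalized to 14 days before the posting date. The same flow runs from the
shell: `patientlens simulate | run | analyze` (see `patientlens --help`).

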