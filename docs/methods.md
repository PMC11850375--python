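# Methods

This note documents the conventions, parameters and design choices behind
`patientlens`, and what the test suite does and does not establish.

## Data model and ingestion

A corpus is a set of posts (id, source, URL, ISO-8601 publication date,
text, language tag); every analysis runs on sentences carrying 0-based
half-open character offsets into their post. Offsets are the package-wide
convention; every mention and answer span is validated as a substring of
its carrier text.

**Deduplication.** The same content is frequently reposted under different
URLs, which would bias counts. The duplicate key is the full text,
lowercased with whitespace collapsed — exact-after-normalization. The
earliest publication date survives (ties by post id), preserving the order
of first appearance. Near-duplicate detection (small edits, added
hashtags) is deliberately out of scope; the key function is the hook for
plugging one in.

**Pseudonymization.** Person names are replaced by randomly generated
equivalents (random substitution keeps text readable) and e-mail-shaped
tokens by the literal placeholder `[EMAIL]` (tagging). Replacement names
come from a packaged name list indexed by a PRNG seeded per post from
(global seed, post id), so corpus runs are reproducible. The packaged name
detector is list-based and precision-oriented: a known first name followed
by a capitalized token. A model NER can be plugged in through the span
detector contract. Characters outside reported replacement spans are never
modified (asserted by a splicing test).

**Segmentation.** The reference segmenter is rule-based — terminal
punctuation and newlines, with an abbreviation guard list (titles never
split; "e.g."-style abbreviations split only before an uppercase
continuation) — so tests need no model. Any segmenter returning ordered,
non-overlapping spans may replace it.

## Backend contracts

Three contracts isolate every learned step: an entailment scorer
(premise, hypothesis → probability in [0, 1], entailment-vs-rest — the
pipeline treats inference as binary), an extractive answerer
(question, context → span or absent; answers are always substrings of the
context), and a sentence embedder (fixed dimension per provider). Scores
are clamped to [0, 1] and never NaN; a backend failure raises a typed
error distinguishable from a low score.

The reference implementations are deterministic, dependency-free and
fixture-grade by design:

* **Overlap entailment scorer** — content tokens (stopwords and the slot
  placeholders *someone*/*something* removed, crude suffix stemming) are
  matched between hypothesis and premise (equal stems, or a ≥ 4-character
  prefix relation); the score is the covered fraction of hypothesis
  stems, +0.1 when ≥ 2 consecutive hypothesis tokens occur verbatim in
  the premise. The formula is documented so tests can compute expected
  values by hand. It cannot model negation or paraphrase and does not
  reliably separate closely related hypotheses (e.g. diagnosed vs.
  misdiagnosed when the shared entity dominates the token overlap); a
  transformer NLI model is the production choice.
* **Pattern answerer** — a packaged question → capture-regex table.
* **Hashing embedder** — seeded feature-hashing bag-of-words, dimension
  256, L2-normalized; deterministic across processes.

## Lexicon NER

Terms are matched case-insensitively at token boundaries; the normalized
form is casefold + whitespace collapse with no stemming, because ontology
terms are largely unambiguous and stemming would cost precision.
Overlapping candidates resolve leftmost-longest (the standard dictionary
matcher convention; deterministic); when distinct concept types match the
identical span, precedence is DR > TR > DI > SY (configurable — the
package's own tie-break). Intervening punctuation blocks a multi-token
match. Three precision filters apply: per-source blacklists; matches
inside ORGANIZATION spans are dropped (disease names inside foundation
names); matches whose phrase head (head-final by default) is not a
noun/proper noun are dropped. The latter two need annotator capabilities;
with the packaged regex annotator they are skipped with a one-time logged
warning rather than failing, trading recall of the filters for an
offline-runnable default.

Disease/symptom ambiguity: terms present in both the DI and SY
inventories are relabeled SY after matching — lay authors rarely draw the
clinical distinction, and the ontology overlap itself argues for the
symptom reading.

The treatment inventory can be compiled from a class-hierarchy edge list:
all labels under the include superclasses (*therapy*, *medical
procedure*) minus all labels under the exclude superclasses (diagnostic
categories); exclusion wins for nodes under both. The packaged lexicons
are small fixture stand-ins; the TSV/blacklist file formats are the
contract, not the contents.

## Time normalization

Four classes: DATE, DURATION, TIME, SET. The deictic present ("now",
"currently") is always re-tagged DATE regardless of the backend, because
it marks an onset as current. Onset expressions resolve to non-negative
day offsets from the posting date under a coarse calendar — year = 365,
month = 30, week = 7 days — chosen to match the arithmetic of the worked
onset examples (2 years → 730; last year → 365; two weeks → 14). Further
conventions: "last X" is exactly one unit; "earlier this year" without a
finer anchor is 0; a bare month name resolves to day 1 of that month in
the reference year (previous year if that would lie in the future) and is
counted in true calendar days — the month rule is a stated convention, not
verifiable without a posting date. Vague ("a while back") and
future-pointing expressions are reported unresolvable; onsets precede
posts, so offsets are never negative. Normalization is a pure function.

## Abstract entities

Ungrounded targets (NEED, SUPPORT) are screened by a fixed hypothesis;
passing requires the score to *strictly* exceed the template threshold.
Questions then run in priority order; the first answer wins, and a
screened sentence without an answer is suppressed by default. Screening
before answering is what keeps bare-QA false positives down, and the QA
step provably never runs on a failed sentence.

Grounded targets (DIAGNOSIS, MISDIAGNOSIS) instantiate slotted hypotheses
with each DI/SY mention; variants ("diagnosed"/"detected") aggregate by
maximum since they are alternatives. When both statuses pass, misdiagnosis
wins as the more specific reading. Default thresholds are 0.5 for all four
targets (a neutral midpoint; per-target override in the template file).
The template bank ships as an editable TSV; the need hypothesis/question
pair and the diagnosed/detected patterns are the canonical core, the rest
are package defaults.

## Relation extraction

Relations: ameliorates (AM), creates (CR), diagnoses (DG), exacerbates
(EX), is associated with (IAW, the only symmetric one), is used for
(IUF), is time of (ITO), NoRel. AM ⊂ IUF and CR, EX ⊂ IAW
(micro → macro).

Type admissibility prunes hypotheses before scoring: AM/IUF/DG require a
(TR|DR, DI|SY) pair, CR/EX admit any ordered biomedical pair, IAW any
biomedical pair, ITO exactly one DATE/DURATION argument (time first). Both
argument orders are scored for directed relations; only one relation can
hold per pair, so the global argmax wins if it strictly exceeds the
threshold (default 0.2, the operating point of the method; per-run
override). Score ties break by the fixed precedence
DG > ITO > AM > EX > CR > IUF > IAW, then forward direction — an artifact
convention for determinism. Multiple templates per relation aggregate by
max, consistent with argmax selection.

Micro-relations must be licensed by a lexical trigger in the sentence
(case-insensitive, word-boundary; the AM/EX lists are the documented
inventories plus common inflections, the CR list is a package default of
explicit causal connectives; all are data files). Unlicensed selections
demote to their macro-relation, and IAW outcomes are canonicalized with
the lower-offset argument first, so extraction is invariant under argument
swap. NoRel instances are suppressed by default (flag to emit them for
pair-dataset evaluation). The module consults nothing beyond the sentence,
its mentions and the schema: relations are reported as stated in the text,
not as they hold in reality.

## Interest groups

The classifier is a scikit-learn estimator: embeddings → multinomial
logistic head, seeded; probability ties break by the fixed label order
PA, CG, PAA, SC, O. The reference path trains only the head on fixed
hashing embeddings so the suite is offline; a contrastive Siamese
adaptation of the embedder (the production few-shot recipe) is an
`adapter` hook run before head training, with pair sampling left to the
plugin. Training requires at least two observed labels. Post-level
aggregation takes the union of non-O sentence labels, {O} only when every
sentence is O — O exists to absorb non-informative sentences, so it never
dilutes an informative post label. Evaluation reports per-label
precision/recall/F1 on the percent scale with accuracy, macro (unweighted
over labels with nonzero gold support — the degenerate-eval choice) and
support-weighted averages; a stratified, seeded 60/20/20 split utility is
provided.

## Synthetic corpus and oracles

Real annotated corpora in this domain are proprietary, so correctness is
established on generated data. Sentences are assembled from slot templates
per interest group (onset reports, causal/worsening/improving statements,
diagnostic use, misdiagnosis, needs, support, temporal frequency, NoRel
pairs, and content-free filler), with entity slots drawn from the packaged
fixture lexicon — gold offsets are exact by construction and the matcher
reproduces every planted mention (closure). Group proportions follow the
annotated-inventory distribution (PA .174, CG .109, PAA .079, SC .100,
O .539) by deterministic largest-remainder allocation; planting rates per
relation and abstract target are configurable weights (rate 0 removes the
construct). Posts carry 1–3 sentences and unique text (duplicates would be
removed by the deduplication stage and are avoided by retry). Everything
is driven by one seed.

Oracle backends are consistent with generation by construction: the
entailment oracle scores exactly the hypotheses instantiated from planted
relations/targets in their true direction at 1.0 and all else at 0.0; the
answering oracle returns the planted span; the embedding oracle emits
one-hot label vectors. A pipeline run with oracle backends recovers the
gold exactly (entity/relation/group F1 = 1.0) — this verifies pipeline
*logic* (ordering, pruning, argmax, demotion, canonicalization,
aggregation), not model quality. Passing says nothing about accuracy on
real posts with real NLI/QA models, where scores are graded and
correlated; the reference backends likewise only exercise the plumbing at
fixture scale. Suite problem sizes — 50-post corpora for end-to-end
recovery, 200 random sentences for matcher/oracle equivalence, 100 random
vectors for metric agreement — keep the whole suite in a few seconds while
exercising every code path.

## Known limitations

* Exact-term entity linking only; no knowledge-base disambiguation.
* Within-sentence relations only; one coarse temporal relation (ITO).
* The coarse calendar ignores actual month lengths by design.
* Reference backends are fixture-grade; production quality requires
  transformer NLI/QA/embedding adapters, which change scores but no
  interfaces.
* English-only defaults; language identification is out of scope.
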