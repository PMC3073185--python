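# Methods

## Task and data model

The unit of classification is the sentence; the unit of sequence modeling
and of cross-validation splitting is the abstract.  A corpus is a JSONL
file, one abstract per line, each sentence pre-segmented and carrying one or
more gold labels from the six-way EBM tagset (Background, Intervention,
Outcome, Population, Study Design, Other).  The first-listed gold label is
the *primary* label, used for single-gold confusion matrices.  Sentence
segmentation is out of scope: the corpus format is already segmented.

Two tasks are derived from a corpus: *six-way* classifies every sentence;
*five-way* labels key sentences only — the Other component is dropped from
every gold set, sentences left without labels are removed (indices
re-packed), and emptied abstracts are dropped.  Co-labeled key sentences are
kept.  Corpora are further split into structured (S) abstracts, which carry
section headings, and unstructured (U) ones.

### Heading detection

A section heading is 1–4 leading tokens, each capitalized or ALL-CAPS
("and"/"&" allowed), terminated by a colon at the start of a sentence —
e.g. `RESULTS:`, `Patients and Methods:`.  This pattern covers every common
heading style while essentially never firing mid-sentence (a mid-text colon
is preceded by at least one lowercase token).  The heading is stripped from
the sentence's text and tokens and propagated to every following sentence
until the next heading; a heading-only line is metadata for the sentences
below it, not a classified sentence.  An abstract is structured iff at
least one heading was detected.

### POS tagging

Tagging is a pluggable contract (surface tokens → Penn-style tags).  The
bundled default is a compact rule-based tagger: a ~90-entry closed-class
lexicon, digit/percentage patterns, capitalization, and suffix heuristics,
defaulting to NN.  Its accuracy is deliberately modest — features only need
a *stable* tag per surface form to disambiguate homographs in feature
strings, not treebank-grade tagging.

## Features

All features are binary presence indicators (no counts), namespaced by
family so no two families can collide.  Surfaces are lowercased in feature
strings; POS tags are kept verbatim.  Within a sentence repeated unigrams
deduplicate (set semantics).  Extraction is a pure function of
(abstract, config, resources).

* Lexical: `U=word_POS` unigrams; `B=w1_p1__w2_p2` bigrams over consecutive
  pairs, POS on both members.
* Semantic: `CUI=` per-token concept ids from a thesaurus TSV
  (token → CUI → pipe-separated synonyms); `SYN=` whole synonym strings;
  `SYNB=` synonyms broken into single words; `MM=` concept ids from a
  pre-computed per-sentence annotation TSV standing in for a concept
  analyser run.  All CUIs of an ambiguous token are emitted — no
  disambiguation, a documented weakness of direct thesaurus lookup.  A
  missing annotation record is an explicit error, never a silent empty set.
* Structural: position as both the capped absolute 1-based index
  (`POSN=1..10`) and the decile-relative bucket (`RELPOS=0..9`), so short
  and long abstracts share a comparable encoding; headings either raw
  (`SEC=`, normalized: uppercase, trailing colon stripped, whitespace
  collapsed) or mapped (`SECM=`) onto four rhetorical roles (Aim, Method,
  Results, Conclusions) via a bundled, editable ~60-entry table; unmapped
  headings fall back to `SECM=Other` with a logged warning.  Heading
  features are inert on unstructured abstracts.
* Sequential: *indirect* — unigram features of up to three previous
  sentences re-emitted with `P1_`/`P2_`/`P3_` prefixes, `<BOS>` sentinels at
  the boundary; *windowed* — previous plus next sentence (`P1_`, `NX_`,
  `<EOS>` sentinel); *direct* — predicted labels of previous sentences as
  `PLAB1=..PLAB3=` (window 1 or 3) or, for the all-window, positional
  features back to the start plus an order-free `PLABANY=` bag.

Named presets (`1.P`, `B`, `B+3 Prev Labels`, …) mirror the standard
experimental grid; `B` is unigrams+POS, position, and raw headings.

## CRF

The reference model is a first-order linear-chain CRF written here from
first principles: state weights F×L over sparse feature ids, transition
weights (L+1)×L with a begin-of-sequence row.  Log-partition and marginals
come from forward–backward in log space (log-sum-exp; stable for scores up
to ±700); decoding is Viterbi with ties broken toward the lowest label id,
so an all-zero model decodes deterministically.  Training minimises the
penalized negative log-likelihood

    −Σ log P(y|x) + ||w||² / 2σ²,   σ² = 1.0 by default,

by batch L-BFGS from zero initialisation — fully deterministic; the
convergence criterion is the projected-gradient norm (1e−5) with a 500
iteration cap (experiment drivers typically use 60 iterations, which is
past convergence on desk-scale corpora).  Unseen test-time features are
dropped.  The gradient implementation is validated against central finite
differences and the partition/decoder against exhaustive path enumeration
on small instances.  A backend protocol allows an external CRF toolkit to
be swapped in behind the same fit/decode contract; only the reference
backend ships.

## Stacked direct features

When direct features are active the classifier is a two-stage stack.  The
base CRF uses the basic set `B`; at training time its predictions for the
training abstracts are produced by internal 5-fold prediction *within the
training set*, so the stage-two model sees direct features of test-time
quality.  Training on gold previous labels instead would make the feature
far more reliable during training than at prediction time and invite error
cascades.  At prediction time the base model decodes first; its labels feed
the stage-two decoder, which never consumes its own outputs.

## Evaluation semantics

One prediction per sentence against a possibly multi-label gold set: a true
positive for class c requires prediction = c and c ∈ gold set; per-class
predicted counts accumulate per prediction, gold counts per gold label
instance.  Micro averages pool these counts over all test instances.  A
consequence worth stating: micro precision ≥ micro recall always (given one
prediction and ≥1 gold per sentence), with equality when all gold sets are
singletons or no prediction is correct.  Confusion matrices are single-gold
(primary label), so row sums equal primary per-class sentence counts;
per-class P/R/F derived from a matrix (diagonal / column sum / row sum) is
valid only for single-gold data.  Reported percentages are rounded half-up
to two decimals; internal arithmetic is unrounded.  Two published six-way
benchmark confusion matrices (structured and unstructured abstracts) ship
as TSV fixtures, and the per-class scores derived from them are pinned in
the test suite.  Cohen's kappa is computed per class from 2×2
presence/absence tables, κ = (p_o − p_e)/(1 − p_e), defined as 1.0 in the
degenerate all-agree case.

Cross-validation assigns whole abstracts to folds (sizes differ by at most
one; a pure function of ids and seed, default seed 13, recorded in every
report) and pools all test predictions into one report.  Internal stacking
folds are nested inside each training split, so no test abstract ever
influences its own model.

## Synthetic corpus generator

The generator emulates the statistical structure the method exploits:
labels from a first-order Markov chain ((L+1)×L row-stochastic matrix, last
row initial), words drawn per sentence from a mixture of the label's
vocabulary and a shared vocabulary, headings coupled to the first sentence
of each label run in structured abstracts (then extracted by the standard
heading detector, exercising the real pipeline), and occasional second
labels drawn from the first label's transition row (adjacent-topic
overlap).  Every draw is recorded in a truth ledger for exact bookkeeping
assertions.

Default ("paper-like") constants: 6–14 sentences per abstract and 6–12
words per sentence (≈10 sentences per abstract on average); transition
matrix with strong self-loops and a Background → Population/Intervention →
Outcome → Other flow whose empirical label mass ranks Outcome first (≈43%)
and Study Design last (≈2%), matching the shape of real EBM corpora;
structured fraction 0.376; multi-label probability 0.05; class-word
probability 0.65 over 12-word class vocabularies — a deliberately
high-signal regime under which a unigram CRF recovers held-out labels at
≥90% accuracy, the package's parameter-recovery check.

What the generator does *not* emulate: grammar, discourse, realistic
clinical language, vocabulary burstiness, or any label dependence beyond
first order.  Passing tests therefore demonstrate correctness of the
machinery and the qualitative feature effects under the generator's
assumptions — not expected performance on real abstracts.

One consequence of the first-order design deserves emphasis: since the
chain CRF's transition weights already capture all sequential information
in a first-order label process, explicitly copied previous-sentence
features are informationally redundant here and measurably add estimation
noise (their cross-validated lift oscillates around zero and is often
slightly negative).  Direct previous-label features, which add only a
handful of parameters, sit at parity with the basic set.  On real corpora,
whose rhetorical structure is not first-order and whose features are far
sparser, sequential features are reported to help, especially on
unstructured abstracts; the synthetic world cannot reproduce that
mechanism, and the package's directional checks accordingly assert
non-degradation of the direct-label preset rather than a positive lift.
The heading channel, by contrast, injects genuinely new information and
shows a large, robust lift on structured abstracts.

## Numerical and design choices

* Half-up decimal rounding at the reporting surface only.
* Viterbi ties → lowest label id; deterministic throughout (no RNG in
  training; all generator and fold RNG is seeded `numpy` Generators).
* Heading regex and heading→role table are re-specified here (the original
  instruments are unpublished); both are bundled as editable package data,
  and edge-case headings may therefore classify differently than in the
  original system.
* Position encoding emits both capped-absolute and decile-relative forms
  because neither alone serves both short and long abstracts.
* Problem sizes in the test suite and acceptance script (60–120 synthetic
  abstracts, 3–4 folds, 60 L-BFGS iterations) are chosen as the smallest
  scales at which the measured properties are stable.

## Known limitations

* The bundled tagger is heuristic; swap in a stronger tagger through the
  annotator contract for serious use.
* Thesaurus/concept-annotation interfaces are file-backed stand-ins; no
  live terminology services are queried.
* Five-way mode assumes the Other label is never the sole signal of
  interest; macro-averaging is computed nowhere (micro is the headline
  metric for this task).
* The CRF is strictly first-order with binary features; no L1
  regularization, feature conjunctions or higher-order chains.
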