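# Methods

## Problem setting

A primary-care consultation is a conversation between a clinician (GP) and a
patient. After the encounter, the problem(s) discussed are recorded as
ICPC-2 codes; at the granularity this package targets, each consultation
receives a *set* of single-letter chapter codes drawn from a 16-chapter
inventory (A, B, D, F, H, K, L, N, P, R, S, T, U, W, X, Y — every ICPC-2
chapter except Z, which does not occur in the reference consultation
dataset whose summary statistics ship with the package). The task is
multilabel text classification of the verbatim transcript; label sets may
be empty and average roughly 1.6 chapters per consultation in the reference
summary.

Real chapter-coded consultation corpora are access-restricted, so the
package is built to be fully exercisable on synthetic dialogue (below).
Absolute scores obtained on synthetic corpora characterise the pipeline,
not real consultations.

## Text model

Transcripts are reduced to token sequences: lower-cased maximal runs of
letters with internal apostrophes kept, digits and punctuation dropped.
Speaker filtering happens before tokenization — either both speakers' turns
or the clinician's turns only (`clinician_only`), the latter used to measure
the contribution of patient speech.

Stopwords come in three tiers. The `english` tier defaults to the standard
318-word scikit-learn English list; `medical` and `custom` tiers ship as
small editable placeholder files (generic clinical-encounter vocabulary and
conversational filler respectively) because the tier *mechanism*, not any
particular membership, is the tested contract. Removal uses the union of
the active tiers and happens **before** bigram formation, so removal can
create new word adjacencies (configurable; this is a genuine design choice
the task description leaves open — removing first mirrors how an idiom like
"keeping an eye on it" collapses once its function words are gone).

Documents are encoded as count vectors (not tf-idf) over a vocabulary of
the `max_features = 5000` most frequent unigrams and adjacent bigrams of
the training corpus, ties at the cutoff broken lexicographically, frozen
after building. Out-of-vocabulary n-grams are ignored at prediction time.

## Classifiers

Two assignment modes are used throughout:

* **multilabel** — one binary yes/no classifier per chapter; a document may
  receive several chapters or none;
* **multiclass** — a single classifier assigns exactly one chapter; the
  training label of a multi-chapter document is its alphabetically first
  gold chapter. Evaluation always uses the full gold label set, which puts
  a structural ceiling on multiclass recall: a singleton prediction can
  fully recall at most the documents with one gold chapter.

**Multinomial naive Bayes** is implemented in-package with Laplace
smoothing `alpha = 1` by default (configurable): per class,
`P(w|c) = (n_cw + alpha) / (n_c + alpha·V)`; priors are training label
frequencies. Multilabel mode thresholds the binary posterior at 0.5;
multiclass mode takes the argmax posterior with ties broken to the
alphabetically first chapter; a zero count vector falls back to the priors.
The per-feature class weights `P(c|w) ∝ P(w|c)P(c)`, normalized per feature,
expose which n-grams drive each chapter (columns sum to one by
construction). Correctness is established against a brute-force enumeration
of the smoothed multinomial formula and cross-checked against
scikit-learn's MultinomialNB in the test suite; neither stands in for the
implementation.

**Nearest centroid** uses per-class arithmetic-mean vectors and Euclidean
distance, ties alphabetical. **The RBF max-margin classifier** delegates
its numerics to scikit-learn's SVC; its contract here is behavioural
(determinism for fixed hyperparameters, correctness on separable toys).
Its `C × gamma` grid (default {0.1, 1, 10} × {0.001, 0.01, 0.1}) is a
configuration default, selected by mean cross-validation macro F1 with
ties broken to the smallest C then the smallest gamma.

Models serialize to JSON carrying a SHA-256 hash of the training
vocabulary; prediction against a different vocabulary is refused. The
margin model is an in-memory object only (its fitted state lives in the
delegated optimizer), which is the one deliberate gap in the serialization
surface.

## Distant supervision

Instead of labelled transcripts, training documents can be surrogates:

* **code descriptions** — per chapter, the space-joined keyword
  descriptions of its low-level codes (code identifiers are excluded: they
  are not conversational features);
* **health topics** — per chapter, the concatenated prose of every topic
  hand-mapped to it, restricted to clinically descriptive sections
  (Causes, Definition, Diagnosis, Clinical features, History, Presentation,
  Signs and symptoms, When to suspect). A topic mapped to k chapters
  contributes its text to all k documents.

Combining both sources keeps two documents per class rather than
concatenating them — the sources' relative weight then remains controllable
through naive-Bayes priors (uniform by default). Whether to concatenate or
pool was genuinely open; pooling is strictly more general since
concatenation is recoverable from it. A chapter can be dropped from an
inventory (e.g. the catch-all A: General); dropping removes it from every
label set but keeps the transcripts as negative evidence.

## Chunking and prompt-based classification

Transformer-style encoders cap input length (512 tokens in the BERT
family), so documents are split into chunks of whole sentences packed
greedily under the token budget; a single over-budget sentence is
hard-split with a warning. Sentence boundaries come from a rule-based
splitter on terminal punctuation with an abbreviation guard (Dr., e.g., …)
— adequate for transcribed speech, which rarely uses elaborate punctuation.
Token counting uses the backend's tokenizer when it provides one,
whitespace tokens otherwise.

Training chunks inherit the parent document's full label set; document
predictions are the set union of per-chunk predictions (commutative,
associative, idempotent — properties the suite verifies). Union semantics
are applied uniformly to all three prompt-era classifiers, including the
conventional fine-tuned head, so a multiclass chunk model can still yield a
multi-chapter document prediction when its chunks disagree.

Few-shot classification scores chunks against the one-blank prompt
`"this is a problem of ___"` filled with a verbalizer name per chapter
(single tokens: general, blood, digestive, eye, ear, circulatory,
musculoskeletal, neurological, psychological, respiratory, skin, metabolic,
urinary, pregnancy, gynaecological, genital — the two genital chapters need
one-word proxies, and the mapping is a config file, not a constant):

* **NSP mode** (multilabel): pair-score each (chunk, filled prompt); keep
  chapters scoring above 0.5;
* **MLM mode** (multiclass): fill-in-the-blank probabilities over the
  verbalized names; argmax per chunk, ties to the alphabetically first
  chapter.

The scoring backend is an interface (`pair_score`, `fill_scores`, optional
`fit`/`predict_label`), registered by name. The packaged backend is a
deterministic keyword-lookup scorer; it exists so the chunk/prompt logic is
fully testable offline, and it is documented as what it is — a keyword
scorer, with none of a neural encoder's generalisation. A transformer
backend can be plugged into the registry without touching any call site.

## Evaluation statistics

Macro precision/recall/F1 over the configured inventory with the
zero-division → 0 convention (the convention was open; 0 is the
conservative choice and matches scikit-learn's default). Macro F1 is the
mean of per-class F1 values, not the harmonic mean of macro P and macro R.

Uncertainty: percentile bootstrap over document resamples, B = 1000 and
95% by default. System comparison: one-sided paired bootstrap on the
macro-F1 difference — p is the fraction of paired resamples with
difference ≤ 0, ties counted against the putatively better system.

Splitting stratifies on each document's alphabetically first gold chapter
(`"none"` for empty label sets), mirroring the multiclass label-selection
rule; per-stratum test counts use proportional allocation with
largest-remainder rounding, so 20% of 239 documents yields exactly 48 test
documents. Fivefold cross-validation uses the same stratification key,
dealing stratum members round-robin into folds with a rotating offset so
small strata spread across folds.

The random baseline assigns each (document, chapter) pair independently
with probability q = 0.5; its macro recall estimates q and its precision
estimates class prevalence.

## Synthetic data generator

The generator emulates the *structure* of chapter-coded consultation
corpora: per transcript, a label count drawn from a configurable
distribution, chapters drawn without replacement proportional to marginal
weights, alternating clinician/patient turns, and per-token keyword
emission — each content token is a keyword of one of the transcript's
chapters with the speaker's emission probability (default 0.12 for both
speakers), otherwise a filler word.

Defaults are the reference dataset's printed summary: marginal weights
proportional to its per-chapter transcript counts, and the label-count
distribution renormalized over 1–4+ labels (zero-label consultations are
excluded by default so every transcript is usable for multiclass training;
a flag restores them). The printed summary itself ships as a fixture and
contains a genuine internal inconsistency — its per-consultation code-count
rows sum to 240 while its unique-consultation total is 239 — which the
fixture preserves verbatim rather than silently correcting.

Lexicons are pronounceable pseudo-words (2–3 consonant–vowel syllables),
never real medical terms, so they cannot collide with shipped stopword
lists; filler vocabulary deliberately includes the English stopword list so
stopword removal has a measurable effect. A cross-chapter overlap rate
`m = round(overlap·k)` puts m of each chapter's k keywords into one block
shared by *all* chapters — every chapter pair then shares exactly m
keywords, and classification difficulty rises smoothly with overlap. The
same lexicons materialise as synthetic code-description entries and
synthetic health topics, so distant supervision is testable end to end.

The ablation variant emits the keywords of designated chapters **only in
patient turns**, guaranteeing by construction that clinician-only text is
uninformative for those chapters.

What the generator does *not* model: real dialogue pragmatics, colloquial
or idiomatic symptom descriptions, speech-recognition noise, correlated
chapter co-occurrence, or vocabulary shared between genuinely related
chapters. Passing tests on synthetic corpora therefore demonstrate pipeline
correctness and sensitivity, not expected performance on real
consultations, where published chapter-coding F1 sits near 0.5.

## Experiment protocols and problem sizes

* **conventional** — stratified 80/20 split, fivefold CV on the training
  split for hyperparameters, final fit on the training split, metrics on
  train / validation / test with a bootstrap CI on test macro F1.
* **distant** — train on per-chapter surrogate documents only; evaluate on
  the entire labelled corpus, repurposed as a validation set since it
  played no part in training.
* **ablation** — the identical conventional pipeline run twice
  (both-speakers vs clinician-only), compared with the paired bootstrap.

The quantitative suites run at sizes chosen to make their expected effects
decisive under the generator's statistics: distant-supervision recovery on
500 transcripts, the speaker ablation on 400, overlap degradation across
{0, 0.4, 0.8}. Two further design choices matter for interpreting them:

* Recovery and ablation runs use **single-chapter transcripts**. With
  multi-chapter gold sets the multiclass recall ceiling (above) caps macro
  F1 near 0.78 regardless of signal quality; single-label corpora make
  macro F1 a measure of keyword-signal recovery, which is the property
  under test. The multi-label regime is exercised separately by the
  multilabel classifiers and the ceiling property test.
* The ablation experiments use **balanced chapter marginals** and emission
  probability 0.3. Balance keeps every chapter represented in every
  cross-validation fold at these corpus sizes, isolating the speaker effect
  from class-imbalance noise; the raised emission rate saturates the
  keyword signal so that the clinician's half of the text alone suffices
  when nothing is hidden from it — which is precisely what a negative
  control (no patient-only chapters) must look like. Under these conditions
  the hidden-keyword corpus yields a large F1 drop with p < 0.001 and the
  control yields a near-zero difference with p ≈ 1.

## Known limitations

* The shipped medical/custom stopword tiers are placeholders; swapping in
  curated lists changes absolute scores.
* The margin classifier does not serialize.
* The keyword stub backend makes chunk/prompt logic testable but says
  nothing about the behaviour of a real pretrained encoder.
* Stratification by first-alphabetical chapter is one of several defensible
  multilabel stratification schemes; iterative stratification would balance
  rare chapters better at small n.
* The random baseline's printed reference values in the literature are not
  reproducible under any single independent-assignment scheme (precision
  and recall appear exchanged); the implementation follows the stated
  scheme and makes no attempt to match those numbers.
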