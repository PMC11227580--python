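# Methods

## The surprisal model

Under a causal (autoregressive) language model M, the surprisal of word
`w_t` given its left context is

    S(w_t | w_1 … w_{t-1}) = −log_b P_M(w_t | w_1 … w_{t-1})

with log base `b = 2` (bits) by default; the base is configurable and all
scores change by the constant factor `ln 2` under base *e* (tested as an
invariant). An utterance's surprisal is the sum of its word surprisals
divided by the utterance length — the mean surprisal per word — and a
paragraph's surprisal is the *unweighted* mean over its utterances' scores:
each utterance counts equally regardless of length. Empty or excluded
utterances are skipped before reduction, because the quantity is undefined
on empty input.

When a tokenizer splits a word into several subword tokens, the word-level
surprisal defaults to the mean of the subtoken surprisals (the convention of
standard probing utilities). Two alternatives are exposed for sensitivity
checks — `mean-prob` (average the subtoken probabilities, then take the
surprisal of that average) and `sum` — because the aggregation choice is a
genuine degree of freedom in surprisal pipelines and the two log/probability
domains do not commute.

The scoring window resets at each utterance by default (`context=
"utterance"`); `"cumulative"` conditions each utterance on all preceding
words of the paragraph. The first word of a window is scored against the
model's start-of-sequence context (a padded start symbol for the
self-contained backends), so every word has a defined surprisal and
length normalization is well-posed.

### Backends

* **Uniform backend** — every token has probability 1/V in every context;
  surprisal is exactly log2 V bits, giving closed-form oracles for every
  downstream reduction.
* **N-gram backend** — add-k smoothing,
  `P(w|c) = (count(c,w)+k) / (count(c)+k·|V|)`, context truncated to the
  n−1 most recent words, start-symbol padding, out-of-vocabulary words
  mapped to an unknown symbol counted in |V|. Conditional distributions sum
  to one in every context (audited), and summed word surprisals reproduce
  −log2 of the brute-force sequence probability to 1e−9.
* **Pretrained adapter** — wraps autoregressive transformer models
  (GPT-2-family and similar) behind the same contract via teacher forcing,
  exposing per-subtoken log probabilities. It requires the optional
  `transformers`/`torch` extra plus, on first use, network access for the
  weights, and is therefore exercised only as an opt-in integration path;
  nothing else in the package depends on it.

## Transcript input

Transcripts are plain UTF-8 text, one utterance per line, with a minimal
subset of CHAT conventions interpreted: `&=word` non-speech codes are
deleted and `[+ exc]` marks the whole utterance excluded. Any other
bracketed span is deleted without interpretation — the pipeline is
deliberately agnostic to richer CHAT coding, since its premise is analysis
of minimally annotated orthographic transcripts. Cleaning lower-cases the
text and splits on whitespace, stripping edge punctuation while keeping
word-internal apostrophes and hyphens, so "haven't" is one word and
utterance length is deterministic.

Participants carry group (control/aphasia), subtype (none/Broca/Wernicke/
Anomic), WAB-R Aphasia Quotient (AQ, a 0–100 severity score), age, and sex
in a CSV/TSV manifest. The inclusion rule keeps aphasia-group participants
with AQ ≤ 92.8 — the WAB-R diagnostic cutoff — and never touches controls;
it is idempotent, and a missing AQ in the aphasia group is an error by
default (configurable to exclude-with-warning).

## The twelve discourse indices

Productivity/fluency: MLU (words per utterance) and number of utterances.
Lexical diversity: type-token ratio over lemmas. Syntactic complexity:
open/closed class ratio, clauses per sentence, nouns/verbs, nouns/
prepositions, V/(V+N), and noun/verb/adjective/adverb percentages of all
words (stored as proportions in [0,1]).

Open class is {NOUN, VERB, ADJ, ADV}; auxiliaries are closed-class and
excluded from verb counts, keeping "verbs" lexical as in the agrammatism
literature. Sentence count equals utterance count (transcripts carry no
other sentence boundary). Clause counting uses a finite-verb heuristic —
one clause per lexical verb — which is deterministic, matches the synthetic
generator's gold counts exactly on omission-free text, and can be replaced
by a parser-based adapter where available. Zero denominators produce
missing values (never infinities); the classifier pipeline imputes them
with training-fold medians.

Tagging is pluggable. The packaged tagger is a deterministic lexicon
lookup shipped with the synthetic vocabulary (out-of-lexicon words tag
OTHER/closed with a warning); any callable with the same signature can
stand in for it, e.g. an adapter over a statistical tagger, at the cost of
gold-tag reproducibility.

## Propensity matching

Group balance uses the probability of aphasia-group membership given age
and sex, fitted by maximum-likelihood probit regression (converged by
gradient tolerance 1e−8 within 100 Newton iterations; scores clipped to
(1e−6, 1−1e−6)). Under perfect separation or non-convergence the score
falls back, with a warning, to one minus the scaled Euclidean distance to
the treated centroid in standardized covariate space — monotone in
similarity, so greedy matching still behaves sensibly.

Matching is greedy 1:1 nearest-neighbour without replacement, processing
units in descending score order. When controls are outnumbered, the smaller
arm does the selecting: each control takes the nearest treated unit. This
matters — having the larger arm select provably retains its most extreme
members and can worsen balance. No caliper is applied by default (one is
available in configuration). Balance is reported as standardized mean
differences before and after matching.

## Classification harness

The observation table is split stratified-by-label into training (2/3) and
a gold test partition (1/3) that is touched exactly once, at final
evaluation. Splits are grouped by participant by default — no speaker
contributes rows to both sides — with an ungrouped flag reproducing
observation-level splitting. Hyperparameters are tuned by nested
cross-validation (k = 3 inner and outer): each outer fold's inner grid
search nominates a configuration, and the configuration with the best mean
outer-fold weighted F1 is refit on the full training partition. Median
imputation (and, for the SVM, standardization) lives inside the model
pipeline, so its statistics are always training-fold-only.

Four families are searched over deliberately small "essential" grids:
decision tree (depth {3,5,10,None}), random forest (trees {100,300}, depth
{5,None}), gradient boosting (trees {100,300}, learning rate {0.05,0.1}),
RBF SVM (C {0.1,1,10}, gamma {scale,0.1}). Metrics are support-weighted
precision/recall/F1 (macro versions are also emitted), with per-class
values and the confusion matrix. The subtype task is 3-class; SVM uses its
native one-vs-one decision scheme, and one-vs-rest per-class ROC AUC is
reported for the random forest as mean ± sd over a stratified two-fold
split of the gold test set.

**Observation unit.** The packaged presence analysis uses whole-transcript
observations (one per participant — a diagnosis is per-person), while the
subtype and statistics analyses chunk transcripts into 10-utterance
paragraphs to obtain many observations per participant. Both are
configuration values (`chunk_size`), not assumptions baked into the code.

### Shapley attribution

Feature attribution uses the background-sample value function
v(S) = E_z[f(x_S, z_{\S})]: exact coalition enumeration up to 12 features
(efficiency holds to 1e−6 and null players receive exactly zero, both
tested), Monte Carlo permutation sampling above. The baseline is the mean
model output over the background sample. Multiclass attributions average
per-class mean |φ|. Inside the experiment driver, attribution runs on a
30-row gold-test subsample with 300 permutation draws when sampling is
needed; exact and sampled modes agree to < 0.02 mean absolute deviation at
5000 draws on small problems (tested).

## Statistics

Spearman correlations use the product-moment formula on average ranks
(identical by construction to correlation-of-ranks, tested on tied data),
pairwise-complete deletion, α = 0.05, |ρ| ≥ 0.5 labelled strong;
p-values come from the t-approximation, with full permutation enumeration
below n = 9 (enumerating beyond 8! permutations buys nothing at study
scale). Cells failing α are blanked in the heatmap export; constant
variables or fewer than five complete pairs yield missing cells.

"Wilcoxon test" here is the two-sample rank-sum (Mann–Whitney) form, since
all compared groups are independent: exact permutation null when the
smaller sample has ≤ 8 observations and the pooled sample is tie-free,
tie-corrected normal approximation otherwise, always two-sided. Shapiro–
Wilk (3 ≤ n ≤ 5000; constant samples reported as non-normal) gates the
choice of nonparametric tests. Multiple comparisons use Bonferroni,
`min(1, p·m)` with m = 3 pairwise tests per metric by default
(configurable), starred at the conventional cutpoints (*, **, ***, ****
at 0.05, 0.01, 0.001, 0.0001). Descriptives report median and IQR.

## The synthetic corpus generator

The generator produces story-retell-shaped corpora whose *statistical*
contrasts — not linguistic realism — match what the measurement modules
assume:

| profile  | utts/participant | MLU     | omission | noun bias | clause rate | substitution | AQ        |
|----------|------------------|---------|----------|-----------|-------------|--------------|-----------|
| control  | 47 ± 31 (min 7)  | 9 ± 3   | 0.02     | 0         | 0.30        | 0            | —         |
| Broca    | 33 ± 24 (min 1)  | 4.5 ± 2 | 0.40     | 1.0       | 0.05        | 0            | 55 ± 12   |
| Wernicke | 33 ± 24 (min 1)  | 8 ± 3   | 0.05     | 0         | 0.15        | 0.30         | 65 ± 12   |
| Anomic   | 33 ± 24 (min 1)  | 7 ± 3   | 0.08     | 0         | 0.20        | 0.10         | 82 ± 8    |

Utterance counts and demographic distributions (aphasia age 60.17 ± 10.95
clipped to [30, 91]; control 50.92 ± 21.38 clipped to [18, 89]; AQ
truncated to [10.8, 92.8]) reproduce the shape of the archived story-retell
corpora the pipeline is designed for, so the matching module faces
realistic age imbalance. The per-subtype generative parameters are
invented: clinical shape is encoded qualitatively (agrammatic omission and
noun bias for Broca; fluent-but-substituting output for Wernicke; mild
word-finding noise for Anomic), with the severity ordering chosen so AQ
correlates negatively with surprisal, as severity scales do.

Utterances are built from a template grammar — Det N (Aux) V (Det N)
(ADP Det N), with optional adjectives/adverbs, pronoun subjects, "and"
coordination to reach the drawn target length, and "that" subordinate
embedding at the clause rate — over a deterministic ~500-entry lexicon
(pseudo-word open-class lemmas with one inflected variant each, real
English function words, Zipf sampling weights). The noun bias is a log-odds
boost applied to every noun-selection decision: noun fragments intrude into
the verb slot and lexical NPs are preferred over pronoun subjects. Omission
then deletes closed-class tokens; substitution swaps open-class tokens for
weight-proportional same-POS words. The generator emits gold tags and gold
clause counts, which the fixture tagger and the finite-verb heuristic
reproduce exactly.

One root seed drives everything; each participant's stream is keyed by a
stable hash of (seed, id), so corpora are byte-for-byte reproducible and
independent of generation order.

The **reference backend** is a bigram model (add-k = 0.1) trained on 2000
noise-free healthy-profile utterances. It stands in for a pre-trained
causal LM in all offline analyses: text with omitted function words or
substituted content words forms word pairs the healthy corpus never
produced, hence scores higher — the same mechanism by which agrammatic
speech surprises a large LM, at toy scale.

**What passing tests do and do not show.** The synthetic corpus
demonstrates that the pipeline recovers designed contrasts (higher Broca
surprisal, lower MLU, higher nouns-over-verbs; monotone response to the
omission rate; ≥ 0.90 presence-task gold F1) end to end. It says nothing
about effect sizes on real clinical transcripts, which carry disfluencies,
discourse structure, semantic content and annotation noise the generator
deliberately does not model.

## Numerical choices and limitations

* Problem sizes in the packaged analyses: 50 participants per group, a
  2000-utterance reference training corpus, 10-utterance chunks for
  sub-transcript observations, 30-row/300-draw attribution subsampling —
  chosen as the smallest sizes at which the designed contrasts are stable
  across seeds.
* Probabilities are clipped nowhere in the backends (smoothing guarantees
  positivity); propensity scores are clipped at 1e−6.
* Greedy matching is order-deterministic (descending score, lexicographic
  tie-break) but not globally optimal; optimal/full matching is out of
  scope.
* The n-gram reference backend has no notion of syntax beyond adjacency;
  contrasts driven purely by long-range structure would need the
  pretrained adapter.
* The fixture tagger cannot tag out-of-lexicon words; real-transcript use
  requires plugging in a statistical tagger, at which point index values
  inherit that tagger's errors.
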