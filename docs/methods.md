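# Methods

This note documents the models and procedures implemented by
`stressense`, the parameters that matter, and the design choices made
where the problem statement was genuinely open.

## Problem setting

Each micro-blog post (tweet) by a teenager may express psychological
stress in one or more of four categories — academic, affection
(romantic), interpersonal, self-cognition — at an ordinal level 0–3
(none, light, moderate, strong). A tweet is *stressful* if any category
has a nonzero level. When no categorical word appears anywhere in the
tweet, the stress is carried by a fifth pseudo-category, *unknown*.
Detection is per (tweet, category): five feature vectors per tweet, one
classifier over the pooled vectors.

## Text analysis

**Segmentation.** Sentences split on 。！？!?… and newline, with runs
of terminators kept attached; clauses split on ，,、；; with separators
kept. Segmentation is lossless up to stripped inter-sentence
whitespace. The ASCII full stop is deliberately *not* a sentence
terminator: in the emulated platform's text the Chinese full stop and
the emotional marks do that work, and treating "." as a terminator
would split decimals and abbreviations in mixed text.

**Tokenization** is a pluggable contract `(clause, lexicon) → tokens`,
registered by name. The default tokenizer greedily longest-matches the
union of all lexicon vocabularies (multi-word entries such as
"a little" are single tokens), then splits the remainder on whitespace
with punctuation characters as their own tokens. Word boundaries are
enforced only against ASCII alphanumerics so the same matcher works
inside unspaced CJK runs; a morphological analyzer can be registered
for real Chinese text.

**Category labeling.** A clause is labeled with the union of categories
of its own categorical words; failing that, with the categories of the
other clauses in its sentence; failing that, with the nearest
*following* sentence carrying any category, then the nearest preceding
one; else {unknown}. Forward-before-backward is a design choice: the
stated fallback examines the "next" sentence, and the backward scan
only exists so that clauses in trailing sentences are never left
unlabeled. "unknown" only ever appears as a singleton label, and only
when no categorical word exists in the whole tweet.

**Negative-emotion scoring (FW1).** Each emotion word (negative or
positive) is scored with the negators and at most one degree adverb in
the window of the **two immediately preceding tokens** (the nearest
adverb wins). Rules:

1. one negator flips the polarity (negated positive words count as
   negative; negated negative words are ignored);
2. two negators force positive meaning for either polarity — the
   contribution is 0;
3. if the adverb is itself preceded by a negator within its own 2-token
   window, or shares the emotion word's window with a negator, its
   degree d is converted to 4−d.

An unmodified negative word has degree 1. The window size 2 is the
smallest that covers the canonical "not so happy" pattern (negator +
adverb + word) while avoiding long-range false attachments; 4−d is the
unique order-reversing involution on {1,2,3} consistent with the
documented 3→1 conversion. Rule 2 is applied literally: "not not sad"
is treated as positive meaning (contribution 0) rather than as a
polarity involution — a crude but deliberate reading of double
negation as softened/positive, which the test-suite oracle encodes
independently. A single negator is allowed to both flip the word's
polarity and convert the adverb's degree, which is exactly what "not so
happy" requires; stacked adverbs take the nearest only.

**FW2/FW4.** Negative emoticons are counted by a left-to-right
non-overlapping scan of literal patterns. Special punctuation counts
each ! ？ ? ！ and … occurrence once; Chinese full stops count only in
ellipsis-like runs of length ≥ 3, since a lone 。 is an ordinary
terminator and the feature targets *duplicated* marks.

**FW3** is the fraction of the tweet's sentences containing an
*effectively* negative word (post-negation) or a negative emoticon
within a clause labeled C — so "not happy" makes a sentence negative
while "not sad" does not.

## Posting, interaction and media features

FP2 uses per-user counts over 24 hour-slots × 3 schedules (holiday
months 1, 2, 7, 8; otherwise weekend/weekday by the civil calendar, no
timezone arithmetic). An empty cell returns 0 — the cold-start default;
imputing from similar users is out of scope. FI3 matches caring markers
as casefolded substrings of the comment text. FI4 (responses/comments)
is left uncapped: a teen replying more often than friends comment is
signal, not noise. FW5 matches the music title case- and
whitespace-insensitively against the sad-title pool; FW6 averages the
two color-theme components over all images, 0 with no images.

## Comment-response combination (FWC)

Responses group by addressee; maximal consecutive runs to one friend
collapse into a single sentence, and each friend's collapsed responses
form a pseudo-tweet scored exactly like a tweet (FC1–FC4). If a
pseudo-tweet reveals no category, categorical words from that friend's
comments are adopted. Combination:

- **Case 1** (tweet reveals category C): FWC1/2/4(C) = FW + Σ_f FC;
  FWC3(C) pools category-restricted negative-sentence counts over the
  tweet and *all* pseudo-tweets' sentence totals. The
  negative-sentence counts are restricted to C (the per-category FW3/
  FC3 definitions force this; unrestricted counts would make FWC3
  identical across categories).
- **Case 2** (tweet category unknown): each category C′ detected in the
  responses receives a *copy* of the tweet's unknown-category values
  (no summation — the responses may not discuss the tweet), and the
  unknown vector keeps its own values so that detections in the unknown
  category remain possible. Case 2 triggers only when the tweet
  reveals *no* deterministic category. Categories detected in neither
  tweet nor responses get zeros, including response-only categories
  when Case 1 applies.

FW5/FW6 are category-independent and are included in every F(C) by
default (`include_media=False` drops them), since they are defined as
content features even though the classifier-input tuple is sometimes
written without them.

## Detection and evaluation

Classifiers are scikit-learn estimators behind a registry
(`naive_bayes`, `logistic_regression`, `random_forest` (default, 100
trees), `svm`; the latter two wrapped with standardization where
needed) — the contribution is the feature space, not the classifiers.
Cross-validation (default k = 10) splits folds at the **tweet** level,
stratified by stressful-or-not, so a tweet's five vectors never leak
across folds; stratification falls back to plain shuffled folds when a
stratum is smaller than k.

Before scoring, a nonzero detection in the unknown category is
attributed to an annotated-stressful category currently detected as 0,
preferring an exact level match, then the highest annotated level, then
the fixed category order — tie-breaks that are conventions, verified in
tests to maximize exact matches over the admissible single
reassignments. Metrics are per (tweet, category): exact-level
precision (nonzero detections whose level equals the annotation) and
recall (annotated-stressful pairs detected at the exact level), their
binary stressful-or-not reduction, and the lower/equal/higher
level-difference proportions over pairs both annotated and detected
nonzero. Macro averages are over the four deterministic categories;
the unknown row reports residual unattributed detections. Zero
denominators yield 0 with a logged note (level-difference proportions
become null).

## Information gain

InfoGain(L,C|F) = H(L,C) − H(L,C|F) with the standard negative-sum
entropy in **all** terms and natural log (any base only rescales; the
ranking is base-invariant). The conditional-entropy term is used in its
standard negative-sum form; without it the gain would be systematically
negative, contradicting the premise that informative features have
positive impact. Continuous features are discretized into 10 equal-width
bins over the observed range (configurable); features with ≤ 10
distinct values (flags, counts, levels) are used as-is; 0·log 0 = 0.
The impact report computes the gain within each category's vector
subset and averages across the five categories.

## Synthetic data

The generator's defaults mirror the emulated study conditions:
stressful prevalence 5.26 %, category mix proportional to the
439/385/342/203 per-category stressful counts, two-category overlap
probability 230/1139, and caring-comment rates (0.5 stressful vs 0.02
neutral at one comment per tweet on average) leaving a few percent of
tweets with a caring comment. Quantities the conditions do not fix were
chosen once as field-plausible and documented here: level distribution
(0.5, 0.3, 0.2) over light/moderate/strong; suppressed (response-only)
expression probability 0.1; response rate 0.4 per comment; Poisson
like/retweet means 3.0/1.0 for neutral and 0.5/0.2 for stressful posts
(stressful posts attract fewer likes); late-night posting bias 0.6;
sad-music probability 0.15 stressful vs 0.005 neutral; image
probability 0.1 with Beta(5,2)/Beta(2,5) negativity scores.

A stressful tweet of level ℓ in category C emits one sentence whose
first clause carries a single-category word of C and whose
emotion-word contributions sum to exactly ℓ (optionally via degree
adverbs); under suppression the categorical word moves into a response,
emulating the unknown-category scenario. The emission vocabulary is the
lexicon itself, so extraction inverts generation exactly — the module's
core testing device. A single pseudo-random stream consumed in (user,
tweet-index) order makes generation reproducible byte-for-byte.
`table1_corpus()` deterministically reproduces the benchmark scale
(21,648 tweets, 1,139 stressful, 439/385/342/203 per category, the
surplus as 230 two-category tweets paired greedily by remaining
counts). What the generator does **not** emulate: realistic syntax,
topic drift between tweet and thread, annotation noise, vocabulary
outside the lexicon, or platform artifacts — so passing recovery tests
demonstrates pipeline correctness, not real-world accuracy.

## Problem sizes and limitations

The recovery experiment uses 2,000 tweets (10,000 vectors) with
10-fold cross-validation — comfortably desk-scale (seconds) while large
enough that per-category binary F ≥ 0.9 and exact-level macro F ≥ 0.6
are meaningful; the benchmark corpus is generated at its full 21,648
tweets since only its counts are asserted. Known limitations: the
fixture lexicon is a toy stand-in (full stress/psychological
dictionaries must be dropped in for real text); the default tokenizer
is not a morphological analyzer; FP2's cold start returns 0; headline
accuracies from any real user study are not reproducible without that
study's data and are out of scope here.
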