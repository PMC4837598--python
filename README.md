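# stressense

Sensing teenager psychological stress from micro-blog posts. Teens often
release academic, romantic (affection), interpersonal and self-cognition
stress on micro-blog platforms, but a single short post rarely tells the
whole story: the category of the stress may surface only in the
comment/response thread underneath it, and friends' caring replies
("What happened?", "Don't worry!") are themselves a stress cue.
`stressense` implements a 4-dimensional micro-blog feature space and a
per-category stress-level detection pipeline for researchers in
computational mental health who want to study this signal on annotated
or simulated corpora.

## The feature space

For each tweet and each stress category
C ∈ {academic, affection, interpersonal, self-cognition, unknown} a
feature vector F(C) = (FP, FI, FWC(C), FW5, FW6) is extracted:

- **FP (posting behaviour)** — FP1: original tweet vs. retweet;
  FP2: *AbnormalPostTime* = SNum(k,s)/Num(k,s), the historical fraction
  of the user's stressful posts in the tweet's hour-slot k under
  schedule s ∈ {holiday, non-holiday weekend, non-holiday weekday}.
- **FW (tweeting content, per category)** — computed over the clauses
  associated with C (a clause without a categorical word inherits
  categories from its sentence, then from neighbouring sentences, else
  "unknown"): FW1 *NegEmotion*, the sum of negative-emotion degrees
  with negation and degree-adverb handling (a single negator flips
  polarity, double negators force positive meaning, a negated adverb's
  degree d converts to 4−d); FW2 negative-emoticon count;
  FW3 negative-sentence ratio; FW4 special-punctuation count
  (!, ?, …, duplicated Chinese full stops). FW5 flags a shared sad
  music title; FW6 is the mean image color-theme negativity.
- **FI (interaction)** — like count, retweet count, caring-comment
  ratio, response ratio.
- **FC / FWC (comment-response augmentation)** — the teen's responses
  to each commenting friend f form a pseudo-tweet resp(tweet, f)
  (consecutive responses collapse into one sentence), scored with the
  same four content features. When the tweet reveals a category C,
  FWCi(C) = FWi(C) + Σ_f FCi(f, C) (FWC3 pools sentence counts); when
  the tweet's category is unknown but a response reveals C′,
  FWCi(C′) = FWi(unknown).

A classifier (Naive Bayes, logistic regression, random forest or SVM
via scikit-learn) maps each F(C) to a stress level 0–3 (none / light /
moderate / strong). Evaluation follows the study protocol: tweet-level
10-fold cross-validation, attribution of unknown-category detections to
annotated categories seeking the maximal level match, exact-level and
stressful-or-not precision/recall/F per category, and a
lower/equal/higher level-difference breakdown. Feature impact is ranked
by information gain InfoGain(L,C|F) = H(L,C) − H(L,C|F).

Because real annotated teen micro-blog data cannot be redistributed,
the package ships a synthetic-corpus generator that plants stress
structure (level-proportional emissions drawn from the lexicon itself,
caring comments, suppressed categories surfacing in responses,
late-night posting bias) so the whole pipeline is testable end to end,
plus a small fixture lexicon standing in for full stress/psychological
dictionaries.

## Worked example

```python
from datetime import datetime
import stressense as ss

lex = ss.fixture_lexicon()
tweet = ss.Tweet(
    "t1", "u1",
    "Terrible grade, hypocritical friendship, my world is really bad!!!",
    datetime(2014, 3, 10, 22, 30))
fw = ss.fw_content_features(tweet, lex)
print(sorted(fw.cs), fw.fw1["academic"], fw.fw1["interpersonal"], fw.fw4["academic"])
```

prints

```
['academic', 'interpersonal'] 3 3 3
```

Clause 1 ("Terrible grade") reveals academic stress with one light
(degree-1) negative word; clause 2 reveals interpersonal stress the
same way; clause 3 has no categorical word, inherits both categories
from its sentence, and its "really bad" pair contributes degree 2 — so
*NegEmotion* is 1+2 = 3 in both categories, and the three exclamation
marks give *PunctuationNum* = 3. See `examples/` for the
comment-response (unknown-category) scenario, a full
simulate → cross-validate → evaluate run, and the information-gain
ranking; `stressense --help` lists the equivalent CLI subcommands
(`simulate`, `extract`, `train`, `detect`, `evaluate`, `impact`).

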