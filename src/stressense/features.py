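"""Per-tweet, per-category feature extraction.

For every tweet and every stress category C in {academic, affection,
interpersonal, self-cognition, unknown} a feature vector F(C) is built
from four feature families:

FP  posting behaviour: originality (FP1) and the historical fraction of
    stressful posts in the tweet's (hour-slot, schedule) cell (FP2);
FWC tweet content features FW1-FW4 (negative emotion, negative
    emoticons, negative-sentence ratio, special punctuation) combined
    with the same features recomputed on the author's responses to each
    commenting friend (FC1-FC4);
FW5/FW6 shared sad music flag and mean image color-theme negativity;
FI  social interaction: likes, retweets, caring-comment ratio, response
    ratio.

FP, FI, FW5 and FW6 are category-independent and identical across the
five vectors of one tweet.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Optional

import pandas as pd

from .corpus_io import ALL_CATEGORIES, Corpus, Tweet
from .lexicon import Lexicon, _norm
from .text_analysis import (
    UNKNOWN,
    ClauseLabel,
    Segmented,
    Tokenizer,
    count_neg_emoticons,
    count_special_punct,
    default_tokenizer,
    label_categories,
    neg_emotion_units,
    segment,
    split_clauses,
)

SCHEDULES = ("holiday", "nonholiday_weekend", "nonholiday_weekday")

#: classifier input columns, in canonical order
FEATURE_COLUMNS = ["FP1", "FP2", "FWC1", "FWC2", "FWC3", "FWC4",
                   "FW5", "FW6", "FI1", "FI2", "FI3", "FI4"]


# ---------------------------------------------------------------------------
# posting features FP

def schedule_of(posted_at: datetime) -> str:
    """Civil-calendar schedule: winter (Jan-Feb) and summer (Jul-Aug)
    months are holidays; otherwise weekends vs. weekdays."""
    if posted_at.month in (1, 2, 7, 8):
        return "holiday"
    if posted_at.weekday() >= 5:
        return "nonholiday_weekend"
    return "nonholiday_weekday"


@dataclass
class UserPostHistory:
    """Per-user post counts over 24 hour-slots x 3 schedules.

    ``num[(user, schedule, hour)]`` counts all posts in the cell and
    ``snum`` the stressful ones; SNum <= Num cell-wise.
    """

    num: dict[tuple[str, str, int], int] = field(
        default_factory=lambda: defaultdict(int))
    snum: dict[tuple[str, str, int], int] = field(
        default_factory=lambda: defaultdict(int))

    def add(self, tweet: Tweet, stressful: bool) -> None:
        key = (tweet.user_id, schedule_of(tweet.posted_at),
               tweet.posted_at.hour)
        self.num[key] += 1
        if stressful:
            self.snum[key] += 1

    def cell(self, tweet: Tweet) -> tuple[int, int]:
        key = (tweet.user_id, schedule_of(tweet.posted_at),
               tweet.posted_at.hour)
        return self.num.get(key, 0), self.snum.get(key, 0)


def build_history(tweets: Iterable[tuple[Tweet, bool]]) -> UserPostHistory:
    history = UserPostHistory()
    for tweet, stressful in tweets:
        history.add(tweet, stressful)
    return history


def history_from_corpus(corpus: Corpus) -> UserPostHistory:
    """History with stressfulness taken from the corpus annotations."""
    ann = corpus.annotation_index()
    return build_history(
        (t, ann[t.tweet_id].stressful if t.tweet_id in ann else False)
        for t in corpus.tweets)


def abnormal_post_time(tweet: Tweet, history: UserPostHistory) -> float:
    """SNum(k,s)/Num(k,s) for the tweet's cell; 0 on an empty cell
    (cold start: a user with no history in the slot)."""
    num, snum = history.cell(tweet)
    return snum / num if num > 0 else 0.0


# ---------------------------------------------------------------------------
# content features FW / FC

@dataclass
class PerCategoryContentFeatures:
    """FW1-FW4 per category plus the sentence counts feeding FWC3.

    ``cs`` is the category set detected in the text: either a set of
    deterministic categories or the singleton {"unknown"}.
    """

    fw1: dict[str, int]
    fw2: dict[str, int]
    fw3: dict[str, float]
    fw4: dict[str, int]
    num_neg_sent: dict[str, int]
    num_sent: int
    cs: frozenset[str]


def _clause_is_negative(units, emoticon_count: int) -> bool:
    return emoticon_count > 0 or any(u.contribution > 0 for u in units)


def _content_features(segmented: Segmented, labels: list[ClauseLabel],
                      lexicon: Lexicon) -> PerCategoryContentFeatures:
    fw1 = {c: 0 for c in ALL_CATEGORIES}
    fw2 = {c: 0 for c in ALL_CATEGORIES}
    fw4 = {c: 0 for c in ALL_CATEGORIES}
    neg_sentences: dict[str, set[int]] = {c: set() for c in ALL_CATEGORIES}
    for label in labels:
        clause = label.clause
        units = neg_emotion_units(clause.tokens, lexicon)
        emo = count_neg_emoticons(clause.raw_text, lexicon)
        punct = count_special_punct(clause.raw_text)
        contribution = sum(u.contribution for u in units)
        negative = _clause_is_negative(units, emo)
        for cat in label.categories:
            fw1[cat] += contribution
            fw2[cat] += emo
            fw4[cat] += punct
            if negative:
                neg_sentences[cat].add(clause.sentence_index)
    num_sent = segmented.n_sentences
    num_neg_sent = {c: len(neg_sentences[c]) for c in ALL_CATEGORIES}
    fw3 = {c: (num_neg_sent[c] / num_sent if num_sent else 0.0)
           for c in ALL_CATEGORIES}
    detected = frozenset().union(
        frozenset(), *(l.categories for l in labels)) - {UNKNOWN}
    cs = detected if detected else frozenset({UNKNOWN})
    return PerCategoryContentFeatures(
        fw1=fw1, fw2=fw2, fw3=fw3, fw4=fw4,
        num_neg_sent=num_neg_sent, num_sent=num_sent, cs=cs)


def fw_content_features(tweet: Tweet, lexicon: Lexicon,
                        tokenizer: Tokenizer = default_tokenizer
                        ) -> PerCategoryContentFeatures:
    """FW1-FW4 per category for the tweet text itself."""
    segmented = segment(tweet.text, lexicon, tokenizer)
    labels = label_categories(segmented, lexicon)
    return _content_features(segmented, labels, lexicon)


def fw_media_features(tweet: Tweet, lexicon: Lexicon) -> tuple[int, float]:
    """(FW5 sad-music flag, FW6 mean image color-theme negativity)."""
    fw5 = int(tweet.music_title is not None
              and _norm(tweet.music_title) in lexicon.sad_music_titles)
    if tweet.image_scores:
        fw6 = sum((w + h) / 2.0 for w, h in tweet.image_scores) \
            / len(tweet.image_scores)
    else:
        fw6 = 0.0
    return fw5, fw6


def fi_features(tweet: Tweet, lexicon: Lexicon
                ) -> tuple[int, int, float, float]:
    """(FI1 likes, FI2 retweets, FI3 caring-comment ratio, FI4 response
    ratio). FI4 is deliberately uncapped: a teen may reply more often
    than friends comment."""
    n_comments = len(tweet.comments)
    if n_comments == 0:
        return tweet.like_count, tweet.retweet_count, 0.0, 0.0
    caring = sum(
        1 for c in tweet.comments
        if any(marker in _norm(c.text) for marker in lexicon.caring_markers))
    return (tweet.like_count, tweet.retweet_count,
            caring / n_comments, len(tweet.responses) / n_comments)


# ---------------------------------------------------------------------------
# comment-response pseudo-tweets

@dataclass
class PseudoTweet:
    """The teen's responses to one friend, viewed as a new tweet.

    Each (collapsed) response is one sentence; the friend's comment
    texts are kept for the category fallback.
    """

    friend_id: str
    sentences: list[str]
    comment_texts: list[str] = field(default_factory=list)


def build_pseudotweets(tweet: Tweet) -> list[PseudoTweet]:
    """Group responses by addressee; maximal runs of consecutive
    responses to the same friend collapse into one sentence."""
    sentences_by_friend: dict[str, list[str]] = defaultdict(list)
    order: list[str] = []
    run_friend: Optional[str] = None
    run_texts: list[str] = []

    def flush() -> None:
        if run_friend is not None and run_texts:
            if run_friend not in sentences_by_friend:
                order.append(run_friend)
            sentences_by_friend[run_friend].append(" ".join(run_texts))

    for resp in tweet.responses:
        if resp.addressee_friend_id != run_friend:
            flush()
            run_friend, run_texts = resp.addressee_friend_id, []
        run_texts.append(resp.text)
    flush()

    comments_by_friend: dict[str, list[str]] = defaultdict(list)
    for c in tweet.comments:
        comments_by_friend[c.friend_id].append(c.text)

    return [PseudoTweet(friend_id=f, sentences=sentences_by_friend[f],
                        comment_texts=comments_by_friend.get(f, []))
            for f in order]


def _segment_pseudotweet(pt: PseudoTweet, lexicon: Lexicon,
                         tokenizer: Tokenizer) -> Segmented:
    # each response is one sentence by construction, regardless of its
    # internal punctuation
    from .text_analysis import Clause
    sentences = []
    for si, sent in enumerate(pt.sentences):
        clauses = [Clause(raw_text=c, tokens=tokenizer(c, lexicon),
                          sentence_index=si, clause_index=ci)
                   for ci, c in enumerate(split_clauses(sent))]
        sentences.append(clauses)
    return Segmented(sentences=sentences)


def fc_features(pt: PseudoTweet, lexicon: Lexicon,
                tokenizer: Tokenizer = default_tokenizer
                ) -> PerCategoryContentFeatures:
    """FC1-FC4 per category, computed exactly like FW1-FW4 on the
    pseudo-tweet. If the responses reveal no category, categorical words
    from the friend's comments are adopted instead."""
    segmented = _segment_pseudotweet(pt, lexicon, tokenizer)
    labels = label_categories(segmented, lexicon)
    feats = _content_features(segmented, labels, lexicon)
    if feats.cs == frozenset({UNKNOWN}) and pt.comment_texts:
        comment_cats: set[str] = set()
        for text in pt.comment_texts:
            for tok in tokenizer(text, lexicon):
                comment_cats |= lexicon.categorical.get(_norm(tok), frozenset())
        if comment_cats:
            relabeled = [ClauseLabel(l.clause, frozenset(comment_cats),
                                     "comment_fallback") for l in labels]
            feats = _content_features(segmented, relabeled, lexicon)
    return feats


# ---------------------------------------------------------------------------
# FWC combination

@dataclass
class CombinedContentFeatures:
    """FWC1-FWC4 per category plus the detected category sets."""

    fwc1: dict[str, float]
    fwc2: dict[str, float]
    fwc3: dict[str, float]
    fwc4: dict[str, float]
    cs: frozenset[str]
    csr: frozenset[str]


def combine_fwc(tweet_features: PerCategoryContentFeatures,
                fc_list: list[PerCategoryContentFeatures]
                ) -> CombinedContentFeatures:
    """Combine tweet content features with per-friend response features.

    Case 1 (a deterministic category C is detected in the tweet): the
    response features of the same category are summed onto the tweet's,
    and FWC3 pools negative/total sentence counts over tweet and
    responses. Case 2 (the tweet's category is unknown): each category
    detected only in the responses receives a copy of the tweet's
    unknown-category feature values; the unknown vector keeps its own.
    """
    fwc1 = {c: 0.0 for c in ALL_CATEGORIES}
    fwc2 = {c: 0.0 for c in ALL_CATEGORIES}
    fwc3 = {c: 0.0 for c in ALL_CATEGORIES}
    fwc4 = {c: 0.0 for c in ALL_CATEGORIES}
    cs = tweet_features.cs
    csr = frozenset().union(
        frozenset(), *(fc.cs for fc in fc_list)) - {UNKNOWN}

    if cs != frozenset({UNKNOWN}):
        total_sent = tweet_features.num_sent + sum(
            fc.num_sent for fc in fc_list)
        for c in cs:
            fwc1[c] = tweet_features.fw1[c] + sum(fc.fw1[c] for fc in fc_list)
            fwc2[c] = tweet_features.fw2[c] + sum(fc.fw2[c] for fc in fc_list)
            fwc4[c] = tweet_features.fw4[c] + sum(fc.fw4[c] for fc in fc_list)
            neg = tweet_features.num_neg_sent[c] + sum(
                fc.num_neg_sent[c] for fc in fc_list)
            fwc3[c] = neg / total_sent if total_sent else 0.0
    else:
        targets = set(csr) | {UNKNOWN}
        for c in targets:
            fwc1[c] = float(tweet_features.fw1[UNKNOWN])
            fwc2[c] = float(tweet_features.fw2[UNKNOWN])
            fwc3[c] = float(tweet_features.fw3[UNKNOWN])
            fwc4[c] = float(tweet_features.fw4[UNKNOWN])
    return CombinedContentFeatures(fwc1=fwc1, fwc2=fwc2, fwc3=fwc3,
                                   fwc4=fwc4, cs=cs, csr=csr)


# ---------------------------------------------------------------------------
# vector assembly

@dataclass
class CategoryFeatureVector:
    tweet_id: str
    category: str
    fp1: int
    fp2: float
    fwc1: float
    fwc2: float
    fwc3: float
    fwc4: float
    fw5: int
    fw6: float
    fi1: int
    fi2: int
    fi3: float
    fi4: float

    def as_row(self) -> dict:
        return {
            "tweet_id": self.tweet_id, "category": self.category,
            "FP1": self.fp1, "FP2": self.fp2,
            "FWC1": self.fwc1, "FWC2": self.fwc2,
            "FWC3": self.fwc3, "FWC4": self.fwc4,
            "FW5": self.fw5, "FW6": self.fw6,
            "FI1": self.fi1, "FI2": self.fi2,
            "FI3": self.fi3, "FI4": self.fi4,
        }


@dataclass
class TweetFeatures:
    """The five per-category vectors of one tweet plus the detected
    category sets (needed for labeling and unknown handling)."""

    tweet_id: str
    vectors: dict[str, CategoryFeatureVector]
    cs: frozenset[str]
    csr: frozenset[str]


def assemble_vectors(tweet: Tweet, lexicon: Lexicon,
                     history: Optional[UserPostHistory] = None,
                     include_media: bool = True,
                     tokenizer: Tokenizer = default_tokenizer
                     ) -> TweetFeatures:
    """Build exactly five per-category feature vectors for a tweet.

    ``include_media`` keeps FW5/FW6 in the vectors (set False to drop
    them to zero and restrict the classifier input to FP+FI+FWC).
    """
    tweet_feats = fw_content_features(tweet, lexicon, tokenizer)
    fc_list = [fc_features(pt, lexicon, tokenizer)
               for pt in build_pseudotweets(tweet)]
    combined = combine_fwc(tweet_feats, fc_list)
    fw5, fw6 = fw_media_features(tweet, lexicon) if include_media else (0, 0.0)
    fi1, fi2, fi3, fi4 = fi_features(tweet, lexicon)
    fp1 = int(tweet.is_original)
    fp2 = abnormal_post_time(tweet, history) if history is not None else 0.0
    vectors = {
        c: CategoryFeatureVector(
            tweet_id=tweet.tweet_id, category=c, fp1=fp1, fp2=fp2,
            fwc1=combined.fwc1[c], fwc2=combined.fwc2[c],
            fwc3=combined.fwc3[c], fwc4=combined.fwc4[c],
            fw5=fw5, fw6=fw6, fi1=fi1, fi2=fi2, fi3=fi3, fi4=fi4)
        for c in ALL_CATEGORIES
    }
    return TweetFeatures(tweet_id=tweet.tweet_id, vectors=vectors,
                         cs=combined.cs, csr=combined.csr)


def extract_features(corpus: Corpus, lexicon: Lexicon,
                     history: Optional[UserPostHistory] = None,
                     include_media: bool = True,
                     tokenizer: Tokenizer = default_tokenizer
                     ) -> list[TweetFeatures]:
    """Per-category vectors for every tweet in the corpus.

    When no history is supplied and the corpus carries annotations, the
    posting history (FP2) is built from the annotated stressfulness.
    """
    if history is None and corpus.annotations is not None:
        history = history_from_corpus(corpus)
    return [assemble_vectors(t, lexicon, history, include_media, tokenizer)
            for t in corpus.tweets]


def features_to_frame(features: list[TweetFeatures]) -> pd.DataFrame:
    """Flatten to a table with one row per (tweet_id, category)."""
    rows = [vec.as_row() for tf in features
            for vec in (tf.vectors[c] for c in ALL_CATEGORIES)]
    return pd.DataFrame(rows, columns=["tweet_id", "category"] + FEATURE_COLUMNS)
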