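"""Synthetic micro-blog corpora with planted stress structure.

The generator emulates the study conditions of a teen micro-blog
dataset: a low prevalence of stressful tweets (~5 %), four stress
categories with occasional two-category tweets, level-proportional
negative-emotion emissions, caring comments arriving more often under
stressful tweets, suppressed stress that surfaces only in the teen's
responses, late-night posting bias, and depressed like counts on
stressful posts.

Emission vocabulary is drawn from the configured lexicon itself so that
feature extraction can invert generation exactly: a planted
single-category tweet of level ℓ (no suppression, no adverbs) yields
FW1(C) = ℓ.

Generated text is lexicon-token concatenation with punctuation — it
makes no attempt at realistic syntax.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Optional

import numpy as np

from .corpus_io import CATEGORIES, Comment, Corpus, Response, StressAnnotation, Tweet
from .lexicon import Lexicon, fixture_lexicon

#: Table-style per-category stressful-tweet counts used for the default
#: category mix (academic : affection : interpersonal : self-cognition).
_CATEGORY_MIX = {"academic": 439, "affection": 385,
                 "interpersonal": 342, "self-cognition": 203}

_FILLER = ["nice", "day", "today", "walk", "park", "weather", "lunch",
           "movie", "tonight", "morning", "sunny", "coffee", "game"]
_NEUTRAL_COMMENTS = ["haha cool", "nice one", "same here", "ok ok",
                     "good photo", "see you tomorrow"]
_NEUTRAL_RESPONSES = ["ok thanks", "yes indeed", "see you", "sure thing"]
_NEUTRAL_MUSIC = ["sunny pop song", "dance mix"]


class ConfigError(ValueError):
    """Raised for invalid generator configurations."""


@dataclass
class GeneratorConfig:
    """Study conditions for corpus generation.

    Defaults mirror the emulated dataset: ~5.26 % stressful tweets with
    the category mix above, a ~20 % chance that a stressful tweet
    carries a second category, and caring-comment rates that leave a few
    percent of all tweets with at least one caring comment.
    """

    n_users: int = 20
    n_tweets_per_user: int = 100
    stress_prevalence: float = 0.0526
    category_weights: dict[str, float] = field(
        default_factory=lambda: dict(_CATEGORY_MIX))
    overlap_prob: float = 230 / 1139
    level_probs: tuple[float, float, float] = (0.5, 0.3, 0.2)
    p_unknown_expression: float = 0.1
    comment_rate: float = 1.0
    p_caring_given_stressful: float = 0.5
    p_caring_given_neutral: float = 0.02
    response_rate: float = 0.4
    like_mean_neutral: float = 3.0
    like_mean_stressful: float = 0.5
    retweet_mean_neutral: float = 1.0
    retweet_mean_stressful: float = 0.2
    late_night_bias: float = 0.6
    p_exclamation_per_level: float = 0.25
    p_sad_music_given_stressful: float = 0.15
    p_sad_music_given_neutral: float = 0.005
    p_image: float = 0.1
    use_degree_adverbs: bool = False
    lexicon: Optional[Lexicon] = None
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "stress_prevalence": self.stress_prevalence,
            "overlap_prob": self.overlap_prob,
            "p_unknown_expression": self.p_unknown_expression,
            "p_caring_given_stressful": self.p_caring_given_stressful,
            "p_caring_given_neutral": self.p_caring_given_neutral,
            "response_rate": self.response_rate,
            "late_night_bias": self.late_night_bias,
            "p_sad_music_given_stressful": self.p_sad_music_given_stressful,
            "p_sad_music_given_neutral": self.p_sad_music_given_neutral,
            "p_image": self.p_image,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} outside [0,1]")
        if not self.p_caring_given_stressful > self.p_caring_given_neutral:
            raise ConfigError("caring-comment probability must be higher "
                              "under stressful tweets")
        if self.n_users < 1 or self.n_tweets_per_user < 1:
            raise ConfigError("need at least one user and one tweet")
        if abs(sum(self.level_probs) - 1.0) > 1e-9 or \
                any(p < 0 for p in self.level_probs):
            raise ConfigError("level_probs must be a distribution over {1,2,3}")
        missing = set(CATEGORIES) - set(self.category_weights)
        if missing or any(w < 0 for w in self.category_weights.values()):
            raise ConfigError("category_weights must cover all four "
                              "categories with non-negative weights")

    def resolved_lexicon(self) -> Lexicon:
        return self.lexicon if self.lexicon is not None else fixture_lexicon()


def easy_recovery_config(seed: int = 0) -> GeneratorConfig:
    """An easily recoverable configuration: 2,000 tweets, strong exact
    level-proportional emissions, no suppressed (unknown) expression."""
    return GeneratorConfig(
        n_users=20, n_tweets_per_user=100,
        stress_prevalence=0.2,
        category_weights={c: 1.0 for c in CATEGORIES},
        overlap_prob=0.15,
        level_probs=(0.4, 0.35, 0.25),
        p_unknown_expression=0.0,
        use_degree_adverbs=False,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# emission helpers

def _pools(lexicon: Lexicon) -> dict:
    vocab = lexicon.vocabulary
    cat_words = {c: sorted(w for w, cats in lexicon.categorical.items()
                           if cats == frozenset({c}))
                 for c in CATEGORIES}
    for c, words in cat_words.items():
        if not words:
            raise ConfigError(
                f"lexicon has no single-category word for {c!r}")
    return {
        "cat_words": cat_words,
        "neg_words": sorted(lexicon.neg_words),
        "adverbs": sorted(lexicon.degree_adverbs.items()),
        "caring": sorted(lexicon.caring_markers),
        "sad_music": sorted(lexicon.sad_music_titles),
        "filler": [w for w in _FILLER if w not in vocab],
    }


def _pick(rng: np.random.Generator, seq):
    return seq[rng.integers(len(seq))]


def _emission_clauses(rng, cfg, pools, level: int) -> list[str]:
    """Clauses whose emotion-unit contributions sum to exactly level."""
    neg = pools["neg_words"]
    if not cfg.use_degree_adverbs:
        return [_pick(rng, neg) for _ in range(level)]
    # greedy: one adverb-modified word covering as much degree as possible
    clauses = []
    remaining = level
    while remaining > 0:
        usable = [(w, d) for w, d in pools["adverbs"] if d <= remaining]
        if usable and remaining > 1 and rng.random() < 0.5:
            adv, d = usable[rng.integers(len(usable))]
            clauses.append(f"{adv} {_pick(rng, neg)}")
            remaining -= d
        else:
            clauses.append(_pick(rng, neg))
            remaining -= 1
    return clauses


def _stress_sentence(rng, cfg, pools, category: str, level: int,
                     suppress: bool) -> str:
    clauses = _emission_clauses(rng, cfg, pools, level)
    if not suppress:
        catword = _pick(rng, pools["cat_words"][category])
        if clauses:
            clauses[0] = f"{clauses[0]} {catword}"
        else:
            clauses = [catword]
    if rng.random() < min(1.0, cfg.p_exclamation_per_level * level):
        terminator = "!" * int(rng.integers(2, 4))
    else:
        terminator = "。"
    return ", ".join(clauses) + terminator


def _neutral_sentence(rng, pools) -> str:
    words = [_pick(rng, pools["filler"])
             for _ in range(int(rng.integers(2, 5)))]
    return " ".join(words) + "。"


def _posted_at(rng, stressful: bool, cfg) -> datetime:
    day = int(rng.integers(0, 850))
    base = datetime(2013, 1, 1) + timedelta(days=day)
    if stressful and rng.random() < cfg.late_night_bias:
        hour = int(_pick(rng, [23, 0, 1, 2]))
    else:
        hour = int(rng.integers(7, 23))
    return base.replace(hour=hour, minute=int(rng.integers(0, 60)))


def _emit_tweet(rng, cfg, pools, user_id: str, tweet_id: str,
                assignment: list[tuple[str, int]], suppress: bool
                ) -> tuple[Tweet, StressAnnotation]:
    stressful = bool(assignment)
    if stressful:
        text = "".join(_stress_sentence(rng, cfg, pools, c, lvl, suppress)
                       for c, lvl in assignment)
    else:
        text = _neutral_sentence(rng, pools)

    n_comments = int(rng.poisson(cfg.comment_rate))
    p_caring = (cfg.p_caring_given_stressful if stressful
                else cfg.p_caring_given_neutral)
    comments, responses = [], []
    seq_r = 0
    for i in range(n_comments):
        friend = f"f{int(rng.integers(1, 7))}"
        if rng.random() < p_caring:
            ctext = _pick(rng, pools["caring"]).capitalize() + "!"
        else:
            ctext = _pick(rng, _NEUTRAL_COMMENTS)
        comments.append(Comment(seq=i + 1, friend_id=friend, text=ctext))
        if rng.random() < cfg.response_rate:
            seq_r += 1
            responses.append(Response(
                seq=seq_r, addressee_friend_id=friend,
                text=_pick(rng, _NEUTRAL_RESPONSES)))
    if suppress and stressful:
        # the stress surfaces only in a response revealing the category
        friend = comments[0].friend_id if comments else "f1"
        catword = _pick(rng, pools["cat_words"][assignment[0][0]])
        seq_r += 1
        responses.append(Response(
            seq=seq_r, addressee_friend_id=friend,
            text=f"it is about my {catword}"))

    like_mean = cfg.like_mean_stressful if stressful else cfg.like_mean_neutral
    rt_mean = (cfg.retweet_mean_stressful if stressful
               else cfg.retweet_mean_neutral)
    music = None
    p_music = (cfg.p_sad_music_given_stressful if stressful
               else cfg.p_sad_music_given_neutral)
    if rng.random() < p_music:
        music = _pick(rng, pools["sad_music"])
    elif rng.random() < 0.05:
        music = _pick(rng, _NEUTRAL_MUSIC)
    images = None
    if rng.random() < cfg.p_image:
        a, b = (5, 2) if stressful else (2, 5)
        images = [(float(np.round(rng.beta(a, b), 4)),
                   float(np.round(rng.beta(a, b), 4)))
                  for _ in range(int(rng.integers(1, 3)))]

    tweet = Tweet(
        tweet_id=tweet_id, user_id=user_id, text=text,
        posted_at=_posted_at(rng, stressful, cfg),
        is_original=bool(rng.random() < (0.95 if stressful else 0.8)),
        like_count=int(rng.poisson(like_mean)),
        retweet_count=int(rng.poisson(rt_mean)),
        music_title=music, image_scores=images,
        comments=comments, responses=responses,
    )
    levels = {c: 0 for c in CATEGORIES}
    for c, lvl in assignment:
        levels[c] = lvl
    return tweet, StressAnnotation(tweet_id=tweet_id, levels=levels)


def _draw_assignment(rng, cfg) -> list[tuple[str, int]]:
    weights = np.array([cfg.category_weights[c] for c in CATEGORIES], float)
    weights /= weights.sum()
    levels = (1, 2, 3)
    first = CATEGORIES[rng.choice(len(CATEGORIES), p=weights)]
    assignment = [(first, int(rng.choice(levels, p=cfg.level_probs)))]
    if rng.random() < cfg.overlap_prob:
        others = [c for c in CATEGORIES if c != first]
        w = np.array([cfg.category_weights[c] for c in others], float)
        w /= w.sum()
        second = others[rng.choice(len(others), p=w)]
        assignment.append((second, int(rng.choice(levels, p=cfg.level_probs))))
    return assignment


def generate_corpus(config: GeneratorConfig) -> Corpus:
    """Generate an annotated corpus; deterministic given the seed.

    A single pseudo-random stream consumed in (user, tweet index) order
    guarantees reproducibility independent of iteration order.
    """
    config.validate()
    lexicon = config.resolved_lexicon()
    pools = _pools(lexicon)
    rng = np.random.default_rng(config.seed)
    tweets, annotations = [], []
    for u in range(config.n_users):
        user_id = f"u{u:03d}"
        for i in range(config.n_tweets_per_user):
            tweet_id = f"{user_id}-t{i:04d}"
            if rng.random() < config.stress_prevalence:
                assignment = _draw_assignment(rng, config)
                suppress = (len(assignment) == 1
                            and rng.random() < config.p_unknown_expression)
            else:
                assignment, suppress = [], False
            tweet, ann = _emit_tweet(rng, config, pools, user_id, tweet_id,
                                     assignment, suppress)
            tweets.append(tweet)
            annotations.append(ann)
    corpus = Corpus(tweets=tweets, annotations=annotations)
    corpus.validate()
    return corpus


# ---------------------------------------------------------------------------
# deterministic benchmark corpus

#: printed study totals the benchmark corpus reproduces
TABLE1_TOTALS = {"total": 21648, "stressful": 1139,
                 "academic": 439, "affection": 385,
                 "interpersonal": 342, "self-cognition": 203}


def _pair_assignments(rng) -> list[list[str]]:
    """230 two-category + 909 single-category bundles hitting the
    per-category totals exactly (greedy pairing of largest remainders)."""
    remaining = {c: TABLE1_TOTALS[c] for c in CATEGORIES}
    bundles: list[list[str]] = []
    for _ in range(230):
        first, second = sorted(remaining, key=remaining.get, reverse=True)[:2]
        bundles.append([first, second])
        remaining[first] -= 1
        remaining[second] -= 1
    for c in CATEGORIES:
        bundles.extend([c] for _ in range(remaining[c]))
    rng.shuffle(bundles)
    return bundles


def table1_corpus(seed: int = 20160419) -> Corpus:
    """A deterministic corpus reproducing the emulated study's scale:
    21,648 tweets from 36 users, exactly 1,139 distinct stressful tweets
    with per-category counts 439/385/342/203 (the surplus realized as
    230 two-category tweets)."""
    cfg = replace(GeneratorConfig(), seed=seed)
    lexicon = cfg.resolved_lexicon()
    pools = _pools(lexicon)
    rng = np.random.default_rng(seed)

    n_users, total = 36, TABLE1_TOTALS["total"]
    per_user = [total // n_users + (1 if u < total % n_users else 0)
                for u in range(n_users)]
    stress_slots = set(rng.choice(total, TABLE1_TOTALS["stressful"],
                                  replace=False).tolist())
    bundles = _pair_assignments(rng)
    levels = (1, 2, 3)

    tweets, annotations = [], []
    slot = 0
    bundle_idx = 0
    for u in range(n_users):
        user_id = f"u{u:03d}"
        for i in range(per_user[u]):
            tweet_id = f"{user_id}-t{i:04d}"
            if slot in stress_slots:
                cats = bundles[bundle_idx]
                bundle_idx += 1
                assignment = [(c, int(rng.choice(levels, p=cfg.level_probs)))
                              for c in cats]
                suppress = (len(assignment) == 1
                            and rng.random() < cfg.p_unknown_expression)
            else:
                assignment, suppress = [], False
            tweet, ann = _emit_tweet(rng, cfg, pools, user_id, tweet_id,
                                     assignment, suppress)
            tweets.append(tweet)
            annotations.append(ann)
            slot += 1
    corpus = Corpus(tweets=tweets, annotations=annotations)
    corpus.validate()
    return corpus
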