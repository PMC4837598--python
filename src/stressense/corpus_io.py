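"""Reading, validating and writing micro-blog corpora.

A corpus file is line-delimited JSON (one record per line, UTF-8). Two
record kinds are distinguished by a ``"kind"`` field:

``tweet``
    One micro-blog post with its text, posting timestamp (local civil
    time, ISO-8601), originality flag, like/retweet counters, optional
    shared-music title, optional per-image color-theme scores, and the
    ordered comment / response threads underneath it.
``annotation``
    Ground-truth stress levels (0-3) for one tweet, one entry per
    deterministic stress category.

Timestamps are stored and interpreted in the user's local civil time;
no timezone arithmetic is performed anywhere in the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Optional

#: The four deterministic stress categories, in canonical order.
CATEGORIES = ("academic", "affection", "interpersonal", "self-cognition")

#: The full category set used for per-tweet feature vectors.
ALL_CATEGORIES = CATEGORIES + ("unknown",)

#: Ordinal stress levels: 0 none, 1 light, 2 moderate, 3 strong.
LEVELS = (0, 1, 2, 3)


class CorpusError(ValueError):
    """Raised for malformed or invariant-violating corpus records."""


@dataclass
class Comment:
    """A friend's comment under a tweet."""

    seq: int
    friend_id: str
    text: str

    def validate(self) -> None:
        if not self.friend_id:
            raise CorpusError("comment with empty friend_id")


@dataclass
class Response:
    """The tweet author's reply addressed to one friend's comment."""

    seq: int
    addressee_friend_id: str
    text: str

    def validate(self) -> None:
        if not self.addressee_friend_id:
            raise CorpusError("response with empty addressee_friend_id")


@dataclass
class Tweet:
    """One micro-blog post.

    ``image_scores`` holds one ``(warm_cool, hard_soft)`` pair per posted
    image; each component lies in [0, 1] with 1 maximally negative.
    """

    tweet_id: str
    user_id: str
    text: str
    posted_at: datetime
    is_original: bool = True
    like_count: int = 0
    retweet_count: int = 0
    music_title: Optional[str] = None
    image_scores: Optional[list[tuple[float, float]]] = None
    comments: list[Comment] = field(default_factory=list)
    responses: list[Response] = field(default_factory=list)

    def validate(self) -> None:
        if not self.tweet_id:
            raise CorpusError("tweet with empty tweet_id")
        if self.like_count < 0 or self.retweet_count < 0:
            raise CorpusError(
                f"tweet {self.tweet_id!r}: negative like/retweet count"
            )
        for name, seq_items in (("comments", self.comments),
                                ("responses", self.responses)):
            seqs = [item.seq for item in seq_items]
            if any(b <= a for a, b in zip(seqs, seqs[1:])):
                raise CorpusError(
                    f"tweet {self.tweet_id!r}: {name} sequence numbers "
                    "not strictly increasing"
                )
        for c in self.comments:
            c.validate()
        for r in self.responses:
            r.validate()
        if self.image_scores is not None:
            for pair in self.image_scores:
                if len(pair) != 2 or not all(0.0 <= v <= 1.0 for v in pair):
                    raise CorpusError(
                        f"tweet {self.tweet_id!r}: image score {pair!r} "
                        "outside [0,1]"
                    )


@dataclass
class StressAnnotation:
    """Ground-truth stress levels for one tweet.

    ``levels`` maps each of the four deterministic categories to a level
    in {0,1,2,3}; the "unknown" pseudo-category is never annotated.
    """

    tweet_id: str
    levels: dict[str, int]

    def validate(self) -> None:
        for cat, lvl in self.levels.items():
            if cat not in CATEGORIES:
                raise CorpusError(
                    f"annotation {self.tweet_id!r}: invalid category {cat!r}"
                )
            if lvl not in LEVELS:
                raise CorpusError(
                    f"annotation {self.tweet_id!r}: level {lvl!r} "
                    "outside {0,1,2,3}"
                )

    def level(self, category: str) -> int:
        return self.levels.get(category, 0)

    @property
    def stressful(self) -> bool:
        return any(v > 0 for v in self.levels.values())


@dataclass
class Corpus:
    tweets: list[Tweet] = field(default_factory=list)
    annotations: Optional[list[StressAnnotation]] = None

    def validate(self) -> None:
        seen: set[str] = set()
        for t in self.tweets:
            if t.tweet_id in seen:
                raise CorpusError(f"duplicate tweet_id {t.tweet_id!r}")
            seen.add(t.tweet_id)
            t.validate()
        if self.annotations is not None:
            for a in self.annotations:
                a.validate()
                if a.tweet_id not in seen:
                    raise CorpusError(
                        f"annotation for unknown tweet_id {a.tweet_id!r}"
                    )

    def annotation_index(self) -> dict[str, StressAnnotation]:
        return {a.tweet_id: a for a in (self.annotations or [])}

    def __len__(self) -> int:
        return len(self.tweets)


# ---------------------------------------------------------------------------
# (de)serialization

def _tweet_to_record(t: Tweet) -> dict:
    rec: dict = {
        "kind": "tweet",
        "tweet_id": t.tweet_id,
        "user_id": t.user_id,
        "text": t.text,
        "posted_at": t.posted_at.isoformat(),
        "is_original": t.is_original,
        "like_count": t.like_count,
        "retweet_count": t.retweet_count,
        "comments": [
            {"seq": c.seq, "friend_id": c.friend_id, "text": c.text}
            for c in t.comments
        ],
        "responses": [
            {"seq": r.seq, "addressee_friend_id": r.addressee_friend_id,
             "text": r.text}
            for r in t.responses
        ],
    }
    # optional fields are encoded as absent, not as sentinels
    if t.music_title is not None:
        rec["music_title"] = t.music_title
    if t.image_scores is not None:
        rec["image_scores"] = [list(p) for p in t.image_scores]
    return rec


def _tweet_from_record(rec: dict) -> Tweet:
    image_scores = rec.get("image_scores")
    if image_scores is not None:
        image_scores = [tuple(p) for p in image_scores]
    return Tweet(
        tweet_id=rec["tweet_id"],
        user_id=rec["user_id"],
        text=rec["text"],
        posted_at=datetime.fromisoformat(rec["posted_at"]),
        is_original=bool(rec["is_original"]),
        like_count=int(rec["like_count"]),
        retweet_count=int(rec["retweet_count"]),
        music_title=rec.get("music_title"),
        image_scores=image_scores,
        comments=[Comment(c["seq"], c["friend_id"], c["text"])
                  for c in rec.get("comments", [])],
        responses=[Response(r["seq"], r["addressee_friend_id"], r["text"])
                   for r in rec.get("responses", [])],
    )


def read_corpus(path: str | Path) -> Corpus:
    """Read and validate a line-delimited corpus file.

    Raises :class:`CorpusError` naming the offending line for malformed
    records and for any invariant violation.
    """
    tweets: list[Tweet] = []
    annotations: list[StressAnnotation] = []
    saw_annotation = False
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                kind = rec["kind"]
                if kind == "tweet":
                    tweets.append(_tweet_from_record(rec))
                elif kind == "annotation":
                    saw_annotation = True
                    annotations.append(StressAnnotation(
                        tweet_id=rec["tweet_id"],
                        levels={k: int(v) for k, v in rec["levels"].items()},
                    ))
                else:
                    raise CorpusError(f"unknown record kind {kind!r}")
            except CorpusError:
                raise
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise CorpusError(f"line {lineno}: malformed record: {exc}") from exc
    corpus = Corpus(tweets=tweets,
                    annotations=annotations if saw_annotation else None)
    corpus.validate()
    return corpus


def write_corpus(corpus: Corpus, path: str | Path) -> Path:
    """Write a validated corpus; ``read_corpus`` round-trips it exactly."""
    corpus.validate()
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for t in corpus.tweets:
            fh.write(json.dumps(_tweet_to_record(t), ensure_ascii=False))
            fh.write("\n")
        for a in (corpus.annotations or []):
            fh.write(json.dumps(
                {"kind": "annotation", "tweet_id": a.tweet_id,
                 "levels": a.levels},
                ensure_ascii=False))
            fh.write("\n")
    return path
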