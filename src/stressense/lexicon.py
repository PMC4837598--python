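"""Word and emoticon resources driving category labeling and emotion scoring.

A :class:`Lexicon` bundles eight resources: categorical words (mapping a
word to the stress categories it reveals), negative and positive emotion
words, degree adverbs valued 1 (light) to 3 (strong), negators, negative
emoticon patterns, caring-comment markers, and a pool of sad music titles.

The package ships a small synthetic fixture lexicon
(:func:`fixture_lexicon`) sufficient for every worked example; real
deployments drop in full stress and psychological dictionaries in the
same file format.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .corpus_io import CATEGORIES

DEGREES = (1, 2, 3)


class LexiconError(ValueError):
    """Raised for invalid lexicon files."""


def _norm(s: str) -> str:
    """Canonical form used for all lexicon matching: casefolded, squeezed."""
    return " ".join(s.casefold().split())


@dataclass
class Lexicon:
    categorical: dict[str, frozenset[str]] = field(default_factory=dict)
    neg_words: set[str] = field(default_factory=set)
    pos_words: set[str] = field(default_factory=set)
    degree_adverbs: dict[str, int] = field(default_factory=dict)
    negators: set[str] = field(default_factory=set)
    neg_emoticons: set[str] = field(default_factory=set)
    caring_markers: set[str] = field(default_factory=set)
    sad_music_titles: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.categorical = {_norm(w): frozenset(c)
                            for w, c in self.categorical.items()}
        self.neg_words = {_norm(w) for w in self.neg_words}
        self.pos_words = {_norm(w) for w in self.pos_words}
        self.degree_adverbs = {_norm(w): int(d)
                               for w, d in self.degree_adverbs.items()}
        self.negators = {_norm(w) for w in self.negators}
        self.caring_markers = {_norm(w) for w in self.caring_markers}
        self.sad_music_titles = {_norm(w) for w in self.sad_music_titles}
        # emoticons are literal patterns; only strip surrounding space
        self.neg_emoticons = {w.strip() for w in self.neg_emoticons}
        self.validate()

    def validate(self) -> None:
        both = self.neg_words & self.pos_words
        if both:
            raise LexiconError(
                f"words in both polarity sets: {sorted(both)}"
            )
        for w, d in self.degree_adverbs.items():
            if d not in DEGREES:
                raise LexiconError(f"degree adverb {w!r}: degree {d} "
                                   "outside {1,2,3}")
        for w, cats in self.categorical.items():
            if not cats:
                raise LexiconError(f"categorical word {w!r} maps to no category")
            bad = set(cats) - set(CATEGORIES)
            if bad:
                raise LexiconError(
                    f"categorical word {w!r}: invalid categories {sorted(bad)}"
                )

    @property
    def vocabulary(self) -> frozenset[str]:
        """Union of all word/phrase entries (used by the default tokenizer)."""
        return frozenset(
            set(self.categorical) | self.neg_words | self.pos_words
            | set(self.degree_adverbs) | self.negators | self.caring_markers
        )

    def emotion_polarity(self, token: str) -> str | None:
        t = _norm(token)
        if t in self.neg_words:
            return "negative"
        if t in self.pos_words:
            return "positive"
        return None


def load_lexicon(path: str | Path) -> Lexicon:
    """Load a lexicon from a JSON file with the eight top-level keys."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    try:
        return Lexicon(
            categorical={w: frozenset(c)
                         for w, c in raw.get("categorical", {}).items()},
            neg_words=set(raw.get("neg_words", [])),
            pos_words=set(raw.get("pos_words", [])),
            degree_adverbs=dict(raw.get("degree_adverbs", {})),
            negators=set(raw.get("negators", [])),
            neg_emoticons=set(raw.get("neg_emoticons", [])),
            caring_markers=set(raw.get("caring_markers", [])),
            sad_music_titles=set(raw.get("sad_music_titles", [])),
        )
    except (TypeError, AttributeError) as exc:
        raise LexiconError(f"malformed lexicon file {path}: {exc}") from exc


def write_lexicon(lexicon: Lexicon, path: str | Path) -> Path:
    path = Path(path)
    raw = {
        "categorical": {w: sorted(c) for w, c in lexicon.categorical.items()},
        "neg_words": sorted(lexicon.neg_words),
        "pos_words": sorted(lexicon.pos_words),
        "degree_adverbs": dict(sorted(lexicon.degree_adverbs.items())),
        "negators": sorted(lexicon.negators),
        "neg_emoticons": sorted(lexicon.neg_emoticons),
        "caring_markers": sorted(lexicon.caring_markers),
        "sad_music_titles": sorted(lexicon.sad_music_titles),
    }
    path.write_text(json.dumps(raw, ensure_ascii=False, indent=1),
                    encoding="utf-8")
    return path


def fixture_lexicon() -> Lexicon:
    """The bundled synthetic toy lexicon.

    Small English stand-in for the full stress/psychological dictionaries;
    it covers every worked example in the documentation and test suite
    (e.g. "so" is a strong (degree-3) adverb, "really" moderate (2),
    "a little" light (1); "boyfriend" reveals affection stress).
    """
    ref = resources.files("stressense") / "data" / "fixture_lexicon.json"
    with resources.as_file(ref) as path:
        return load_lexicon(path)
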