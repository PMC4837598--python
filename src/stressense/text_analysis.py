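"""Clause-level text analysis for stress sensing.

Tweets are segmented into sentences and clauses (the finest unit of
stress-category detection). Each clause is labeled with stress
categories via its own categorical words, falling back to the rest of
its sentence, then to neighbouring sentences, and finally to "unknown".

Negative-emotion scoring pairs each emotion word with the degree adverb
and negators bound to it (a window of the two immediately preceding
tokens) under three semantic rules:

1. a negative emotion word under a single negator turns positive and is
   ignored, while a negated positive word counts as negative;
2. two negators force positive meaning;
3. a degree adverb bound with a negator has its degree converted
   (d -> 4 - d), so "not so happy" scores like "a little unhappy".

An unmodified negative word carries degree 1 (light).
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from typing import Callable

from .lexicon import Lexicon, _norm

UNKNOWN = "unknown"

#: window size (tokens) within which negators/adverbs bind to an emotion word
ATTACH_WINDOW = 2

_SENT_RE = re.compile(r"[^。！？!?…\n]*[。！？!?…]+|[^。！？!?…\n]+")
_CLAUSE_RE = re.compile(r"[^，,、；;]*[，,、；;]|[^，,、；;]+")
_CN_FULLSTOP_RUN = re.compile(r"。{3,}")

_WORD_EXTRA = set("'’-_")


def split_sentences(text: str) -> list[str]:
    """Split on 。！？!?… and newline, terminators kept with their sentence.

    Runs of terminators ("bad!!!") stay attached, so the example tweet
    "Terrible grade, hypocritical friendship, my world is really bad!!!"
    is a single sentence. Empty segments are dropped.
    """
    out = []
    for seg in _SENT_RE.findall(text):
        seg = seg.strip()
        if seg:
            out.append(seg)
    return out


def split_clauses(sentence: str) -> list[str]:
    """Split a sentence on ， , 、 ； ; keeping the separators attached."""
    clauses = [c for c in _CLAUSE_RE.findall(sentence) if c.strip()]
    return clauses if clauses else [sentence]


def _is_punct(ch: str) -> bool:
    return unicodedata.category(ch).startswith("P") and ch not in _WORD_EXTRA


def _boundary_ok(text: str, start: int, end: int) -> bool:
    # enforce word boundaries only against ASCII alphanumerics so that
    # longest-match still works inside unspaced CJK runs
    if start > 0:
        prev = text[start - 1]
        if prev.isascii() and prev.isalnum():
            return False
    if end < len(text):
        nxt = text[end]
        if nxt.isascii() and nxt.isalnum():
            return False
    return True


def default_tokenizer(clause: str, lexicon: Lexicon) -> list[str]:
    """Greedy longest-match against the lexicon vocabulary.

    Lexicon phrases (including multi-word entries like "a little") are
    matched case-insensitively at word boundaries; the remainder is split
    on whitespace with punctuation characters as their own tokens.
    """
    phrases = sorted(lexicon.vocabulary, key=len, reverse=True)
    lower = clause.casefold()
    tokens: list[str] = []
    i, n = 0, len(clause)
    while i < n:
        ch = clause[i]
        if ch.isspace():
            i += 1
            continue
        matched = False
        for phrase in phrases:
            end = i + len(phrase)
            if lower.startswith(phrase, i) and _boundary_ok(lower, i, end):
                tokens.append(phrase)
                i = end
                matched = True
                break
        if matched:
            continue
        if _is_punct(ch):
            tokens.append(ch)
            i += 1
            continue
        j = i
        while j < n and not clause[j].isspace() and not _is_punct(clause[j]):
            j += 1
        tokens.append(clause[i:j])
        i = j
    return tokens


Tokenizer = Callable[[str, Lexicon], list[str]]

_TOKENIZERS: dict[str, Tokenizer] = {"default": default_tokenizer}


def register_tokenizer(name: str, fn: Tokenizer) -> None:
    """Register a pluggable tokenizer (e.g. a morphological CJK analyzer)."""
    _TOKENIZERS[name] = fn


def get_tokenizer(name: str) -> Tokenizer:
    try:
        return _TOKENIZERS[name]
    except KeyError:
        raise KeyError(f"unknown tokenizer {name!r}; "
                       f"registered: {sorted(_TOKENIZERS)}") from None


# ---------------------------------------------------------------------------
# segmentation


@dataclass
class Clause:
    raw_text: str
    tokens: list[str]
    sentence_index: int
    clause_index: int


@dataclass
class Segmented:
    """A tweet segmented into sentences of clauses (lossless)."""

    sentences: list[list[Clause]] = field(default_factory=list)

    @property
    def clauses(self) -> list[Clause]:
        return [c for s in self.sentences for c in s]

    @property
    def n_sentences(self) -> int:
        return len(self.sentences)


def segment(text: str, lexicon: Lexicon,
            tokenizer: Tokenizer = default_tokenizer) -> Segmented:
    sentences = []
    for si, sent in enumerate(split_sentences(text)):
        clauses = [
            Clause(raw_text=c, tokens=tokenizer(c, lexicon),
                   sentence_index=si, clause_index=ci)
            for ci, c in enumerate(split_clauses(sent))
        ]
        sentences.append(clauses)
    return Segmented(sentences=sentences)


# ---------------------------------------------------------------------------
# category labeling


@dataclass
class ClauseLabel:
    clause: Clause
    categories: frozenset[str]
    provenance: str  # own | same_sentence | forward_sentence | backward_sentence | unknown


def _own_categories(clause: Clause, lexicon: Lexicon) -> frozenset[str]:
    cats: set[str] = set()
    for tok in clause.tokens:
        cats |= lexicon.categorical.get(_norm(tok), frozenset())
    return frozenset(cats)


def label_categories(segmented: Segmented, lexicon: Lexicon) -> list[ClauseLabel]:
    """Assign stress categories to every clause.

    Priority: the clause's own categorical words; else the other clauses
    of the same sentence; else the nearest following sentence carrying
    any category; else the nearest preceding one; else {"unknown"}.
    """
    own = [[_own_categories(c, lexicon) for c in sent]
           for sent in segmented.sentences]
    sent_cats = [frozenset().union(*cs) if cs else frozenset() for cs in own]
    labels: list[ClauseLabel] = []
    for si, sent in enumerate(segmented.sentences):
        for ci, clause in enumerate(sent):
            if own[si][ci]:
                labels.append(ClauseLabel(clause, own[si][ci], "own"))
                continue
            others = frozenset().union(
                frozenset(), *(own[si][cj] for cj in range(len(sent)) if cj != ci))
            if others:
                labels.append(ClauseLabel(clause, others, "same_sentence"))
                continue
            forward = next((sent_cats[sj] for sj in
                            range(si + 1, len(sent_cats)) if sent_cats[sj]), None)
            if forward:
                labels.append(ClauseLabel(clause, forward, "forward_sentence"))
                continue
            backward = next((sent_cats[sj] for sj in
                             range(si - 1, -1, -1) if sent_cats[sj]), None)
            if backward:
                labels.append(ClauseLabel(clause, backward, "backward_sentence"))
                continue
            labels.append(ClauseLabel(clause, frozenset({UNKNOWN}), UNKNOWN))
    return labels


# ---------------------------------------------------------------------------
# negation/degree-aware emotion scoring


@dataclass
class EmotionUnit:
    """One emotion word with its resolved polarity and degree.

    ``degree`` is the effective degree after any negator conversion;
    ``contribution`` equals ``degree`` when the unit is effectively
    negative and 0 otherwise.
    """

    emotion_word: str
    original_polarity: str
    effective_polarity: str
    degree: int
    contribution: int


def neg_emotion_units(tokens: list[str], lexicon: Lexicon) -> list[EmotionUnit]:
    units: list[EmotionUnit] = []
    norm = [_norm(t) for t in tokens]
    for i, tok in enumerate(norm):
        original = lexicon.emotion_polarity(tok)
        if original is None:
            continue
        lo = max(0, i - ATTACH_WINDOW)
        window = list(range(lo, i))
        n_neg = sum(1 for j in window if norm[j] in lexicon.negators)
        if n_neg == 0:
            effective = original
        elif n_neg == 1:
            effective = "positive" if original == "negative" else "negative"
        else:
            # double negators force positive meaning
            effective = "positive"
        # nearest degree adverb in the window wins
        adv_pos = next((j for j in reversed(window)
                        if norm[j] in lexicon.degree_adverbs), None)
        if adv_pos is None:
            degree = 1
        else:
            degree = lexicon.degree_adverbs[norm[adv_pos]]
            adv_lo = max(0, adv_pos - ATTACH_WINDOW)
            negated_adverb = any(norm[j] in lexicon.negators
                                 for j in range(adv_lo, adv_pos))
            # the adverb shares the emotion word's window with any negator
            if negated_adverb or n_neg >= 1:
                degree = 4 - degree
        contribution = degree if effective == "negative" else 0
        units.append(EmotionUnit(
            emotion_word=tokens[i], original_polarity=original,
            effective_polarity=effective, degree=degree,
            contribution=contribution))
    return units


def count_neg_emoticons(raw_text: str, lexicon: Lexicon) -> int:
    """Left-to-right, non-overlapping count of negative emoticon patterns."""
    patterns = sorted(lexicon.neg_emoticons, key=len, reverse=True)
    count, i = 0, 0
    while i < len(raw_text):
        for pat in patterns:
            if pat and raw_text.startswith(pat, i):
                count += 1
                i += len(pat)
                break
        else:
            i += 1
    return count


def count_special_punct(raw_text: str) -> int:
    """Count emotional punctuation: ! ？ ? ！ and … each once; Chinese
    full stops only when duplicated in ellipsis-like runs of >= 3."""
    count = sum(1 for ch in raw_text if ch in "!！?？…")
    for m in _CN_FULLSTOP_RUN.finditer(raw_text):
        count += len(m.group())
    return count
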