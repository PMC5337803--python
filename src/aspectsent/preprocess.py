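"""Tweet normalization, tokenization, sentence splitting, tagging, lemmatization.

Normalization removes the Twitter-specific noise that carries no sentiment
signal — @-mentions, URLs, the ``#`` of hashtags (the hashtag body is kept:
it is usually a content word) — then expands abbreviations against optional
SMS and domain dictionaries and hands remaining out-of-dictionary words to a
pluggable spell corrector. Every change is recorded in an edit log; replaying
the log over the raw text reproduces the normalized text exactly.

Analysis turns the normalized text into tokens with Penn Treebank tags and
lowercase lemmas, grouped into sentences that end at an unattached ``.``,
``!`` or ``?``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Protocol, Sequence

from .errors import ContractViolation, FormatError
from .tagging import TaggerBackend, get_tagger

# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class RawTweet:
    """An unprocessed microtext: opaque id plus UTF-8 text."""

    id: str
    text: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ContractViolation("tweet id must be nonempty")


@dataclass(frozen=True)
class Token:
    surface: str
    lemma: str
    pos: str
    index: int
    is_word: bool


@dataclass(frozen=True)
class Sentence:
    """Half-open token index range [start, end)."""

    start: int
    end: int


@dataclass(frozen=True)
class Edit:
    """One normalization change: replace ``original`` at char ``position``
    (an offset into the text as it stood when the edit was applied) with
    ``replacement``."""

    kind: str  # mention | url | hashtag | abbreviation | spelling | whitespace
    position: int
    original: str
    replacement: str


@dataclass
class Tweet:
    id: str
    raw_text: str
    normalized_text: str
    tokens: list[Token] = field(default_factory=list)
    sentences: list[Sentence] = field(default_factory=list)
    edit_log: list[Edit] = field(default_factory=list)

    def word_indices(self) -> list[int]:
        return [t.index for t in self.tokens if t.is_word]


@dataclass
class AbbreviationDictionary:
    """Case-insensitive abbreviation -> expansion map with a source tag."""

    mapping: dict[str, str]
    source: str = "domain"

    def __post_init__(self) -> None:
        lowered: dict[str, str] = {}
        for key, expansion in self.mapping.items():
            k = key.lower()
            if not expansion:
                raise FormatError(f"empty expansion for abbreviation {key!r}")
            if k in lowered:
                raise FormatError(f"duplicate abbreviation key {key!r}")
            lowered[k] = expansion
        self.mapping = lowered

    @classmethod
    def from_tsv(cls, path: str, source: str = "domain") -> "AbbreviationDictionary":
        mapping: dict[str, str] = {}
        with open(path, encoding="utf-8") as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise FormatError(
                        "expected 2 tab-separated columns (abbreviation, expansion)",
                        line=lineno, source=path,
                    )
                key, expansion = parts
                if key.lower() in mapping:
                    raise FormatError(
                        f"duplicate abbreviation key {key!r}", line=lineno, source=path
                    )
                mapping[key.lower()] = expansion
        return cls(mapping=mapping, source=source)


# ---------------------------------------------------------------------------
# Spell correction interface


class SpellCorrector(Protocol):
    def correct(self, word: str) -> str: ...


class NoOpCorrector:
    """Default corrector: leaves every word unchanged."""

    def correct(self, word: str) -> str:
        return word


class DictionaryCorrector:
    """Suggests the lexicographically first in-vocabulary word at minimal
    edit distance (bounded by ``max_distance``); known and unfixable words
    pass through unchanged. Deterministic by construction."""

    def __init__(self, vocabulary: Iterable[str], max_distance: int = 1):
        self.vocabulary = sorted({w.lower() for w in vocabulary})
        self.max_distance = max_distance

    def correct(self, word: str) -> str:
        low = word.lower()
        if low in self.vocabulary or not low.isalpha():
            return word
        best_word, best_dist = None, self.max_distance + 1
        for candidate in self.vocabulary:
            if abs(len(candidate) - len(low)) >= best_dist:
                continue
            d = _edit_distance(low, candidate, cutoff=best_dist)
            if d < best_dist:  # strict: earlier candidate wins ties
                best_word, best_dist = candidate, d
        return best_word if best_word is not None else word


def _edit_distance(a: str, b: str, cutoff: int) -> int:
    """Levenshtein distance, short-circuiting above ``cutoff``."""
    if a == b:
        return 0
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        row_min = i
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
            row_min = min(row_min, cur[j])
        if row_min > cutoff:
            return cutoff + 1
        prev = cur
    return prev[-1]


# ---------------------------------------------------------------------------
# Normalization

_MENTION_RE = re.compile(r"(?<!\S)@\S+[ \t]*")
_URL_RE = re.compile(r"(?:https?://\S*|(?<!\S)t\.co/\S+)[ \t]*")
_WORD_RE = re.compile(r"[A-Za-z][A-Za-z0-9'\-]*")
_WS_RUN_RE = re.compile(r"\s+")


def _apply_edit(text: str, edits: list[Edit], kind: str, pos: int,
                old: str, new: str) -> str:
    edits.append(Edit(kind=kind, position=pos, original=old, replacement=new))
    return text[:pos] + new + text[pos + len(old):]


def _strip_pattern(text: str, pattern: re.Pattern, kind: str,
                   edits: list[Edit]) -> str:
    while True:
        match = pattern.search(text)
        if match is None:
            return text
        text = _apply_edit(text, edits, kind, match.start(), match.group(0), "")


def _expand_abbreviations(text: str, dicts: Sequence[AbbreviationDictionary],
                          edits: list[Edit]) -> str:
    """Token-wise, case-insensitive expansion. Dictionaries are consulted in
    the order given (callers put the domain dictionary first); multiword keys
    are supported and the longest key wins at each position."""
    ordered = list(dicts)
    max_key_words = max(
        (len(k.split()) for d in ordered for k in d.mapping), default=0
    )
    pos = 0
    while True:
        match = _WORD_RE.search(text, pos)
        if match is None:
            return text
        replaced = False
        for span_words in range(max_key_words, 0, -1):
            end = match.end()
            words = 1
            while words < span_words:
                nxt = _WORD_RE.search(text, end)
                if nxt is None or text[end:nxt.start()].strip():
                    break
                end, words = nxt.end(), words + 1
            if words != span_words:
                continue
            key = _WS_RUN_RE.sub(" ", text[match.start():end]).lower()
            for d in ordered:
                expansion = d.mapping.get(key)
                if expansion is not None:
                    text = _apply_edit(text, edits, "abbreviation",
                                       match.start(), text[match.start():end],
                                       expansion)
                    pos = match.start() + len(expansion)
                    replaced = True
                    break
            if replaced:
                break
        if not replaced:
            pos = match.end()


def _spell_correct(text: str, corrector: SpellCorrector,
                   known: set[str], edits: list[Edit]) -> str:
    pos = 0
    while True:
        match = _WORD_RE.search(text, pos)
        if match is None:
            return text
        word = match.group(0)
        if word.lower() in known:
            pos = match.end()
            continue
        fixed = corrector.correct(word)
        if fixed != word:
            text = _apply_edit(text, edits, "spelling", match.start(), word, fixed)
            pos = match.start() + len(fixed)
        else:
            pos = match.end()


def _collapse_whitespace(text: str, edits: list[Edit]) -> str:
    pos = 0
    while True:
        match = _WS_RUN_RE.search(text, pos)
        if match is None:
            return text
        run = match.group(0)
        at_edge = match.start() == 0 or match.end() == len(text)
        replacement = "" if at_edge else " "
        if run == replacement:
            pos = match.end()
            continue
        text = _apply_edit(text, edits, "whitespace", match.start(), run, replacement)
        pos = match.start() + len(replacement)


def normalize(raw: RawTweet,
              dicts: Sequence[AbbreviationDictionary] = (),
              corrector: SpellCorrector | None = None) -> tuple[str, list[Edit]]:
    """Apply the normalization cascade to one tweet.

    Order: drop @-mention tokens, drop URLs, strip ``#``, expand
    abbreviations (domain dictionaries before SMS, so jargon like "Hypo" is
    expanded rather than spell-"corrected"), spell-correct remaining
    out-of-dictionary words, collapse whitespace. Returns the normalized
    text plus the ordered edit log; never raises on pathological text.
    """
    corrector = corrector or NoOpCorrector()
    ordered = sorted(dicts, key=lambda d: 0 if d.source == "domain" else 1)
    edits: list[Edit] = []
    text = raw.text
    text = _strip_pattern(text, _MENTION_RE, "mention", edits)
    text = _strip_pattern(text, _URL_RE, "url", edits)
    while "#" in text:
        text = _apply_edit(text, edits, "hashtag", text.index("#"), "#", "")
    text = _expand_abbreviations(text, ordered, edits)
    known = {w for d in ordered for e in d.mapping.values() for w in e.lower().split()}
    known.update(k for d in ordered for k in d.mapping)
    text = _spell_correct(text, corrector, known, edits)
    text = _collapse_whitespace(text, edits)
    return text, edits


def apply_edits(raw_text: str, edits: Sequence[Edit]) -> str:
    """Replay an edit log over the raw text (the edit-log contract:
    the result equals the normalized text byte for byte)."""
    text = raw_text
    for e in edits:
        if text[e.position:e.position + len(e.original)] != e.original:
            raise ContractViolation(
                f"edit log out of sync at position {e.position}: "
                f"expected {e.original!r}"
            )
        text = text[:e.position] + e.replacement + text[e.position + len(e.original):]
    return text


# ---------------------------------------------------------------------------
# Tokenization, sentences, tagging

_ELLIPSIS_RE = r"\.{2,}|…"
_TOKEN_RE = re.compile(
    rf"{_ELLIPSIS_RE}|[A-Za-z][A-Za-z0-9'\-]*|\d+(?:\.\d+)?|[^\w\s]"
)
_SENTENCE_END = {".", "!", "?"}


def tokenize(text: str) -> list[str]:
    return _TOKEN_RE.findall(text)


def analyze(normalized_text: str,
            tweet_id: str = "",
            raw_text: str | None = None,
            edit_log: Sequence[Edit] | None = None,
            tagger: TaggerBackend | None = None) -> Tweet:
    """Tokenize, sentence-split, tag and lemmatize normalized text.

    Sentences end at an unattached ``.``, ``!`` or ``?`` token (an ellipsis
    is a single non-terminating token). Punctuation-class tokens are flagged
    ``is_word=False``. Deterministic for a fixed input and backend.
    """
    tagger = tagger or get_tagger("rule")
    surfaces = tokenize(normalized_text)
    tagged = tagger.tag(surfaces)
    tokens = [
        Token(surface=s, lemma=lemma, pos=pos, index=i,
              is_word=any(c.isalnum() for c in s))
        for i, (s, (pos, lemma)) in enumerate(zip(surfaces, tagged))
    ]
    sentences: list[Sentence] = []
    start = 0
    for tok in tokens:
        if tok.surface in _SENTENCE_END:
            sentences.append(Sentence(start=start, end=tok.index + 1))
            start = tok.index + 1
    if start < len(tokens):
        sentences.append(Sentence(start=start, end=len(tokens)))
    return Tweet(
        id=tweet_id,
        raw_text=normalized_text if raw_text is None else raw_text,
        normalized_text=normalized_text,
        tokens=tokens,
        sentences=sentences,
        edit_log=list(edit_log or []),
    )


def preprocess_tweet(raw: RawTweet,
                     dicts: Sequence[AbbreviationDictionary] = (),
                     corrector: SpellCorrector | None = None,
                     tagger: TaggerBackend | None = None) -> Tweet:
    """normalize + analyze in one step."""
    normalized, edits = normalize(raw, dicts, corrector)
    return analyze(normalized, tweet_id=raw.id, raw_text=raw.text,
                   edit_log=edits, tagger=tagger)
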