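"""Prior-polarity lexicon scoring and the strict-inequality polarity rule.

The lexicon is SentiWordNet 3.0's tab-separated text format: one synset per
line with POS category (a/n/r/v), 8-digit synset id, positive and negative
scores, the lemma#rank member list and a gloss. The neutral (objectivity)
score is always recomputed as ``1 - pos - neg``, so each sense's triple sums
to one.

An aspect's sentiment triple is the element-wise sum of the triples of its
context-window words. Each word contributes the triple of one chosen sense —
sense choice is a pluggable strategy whose deterministic default is the
most-frequent-sense baseline (smallest sense rank) — or (0, 0, 0) when the
word has no entry under its POS category. The polarity label is *positive*
iff the positive aggregate strictly exceeds both others, symmetrically for
*negative* and *neutral*; any tie for the maximum is labelled neutral.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

from .errors import ContractViolation, FormatError
from .gazetteer import AspectMention
from .preprocess import Tweet
from .windows import ContextWindow

POSITIVE = "positive"
NEGATIVE = "negative"
NEUTRAL = "neutral"
LABELS = (POSITIVE, NEGATIVE, NEUTRAL)

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class SentimentTriple:
    pos: float = 0.0
    neg: float = 0.0
    neu: float = 0.0

    def __post_init__(self) -> None:
        if self.pos < 0 or self.neg < 0 or self.neu < 0:
            raise ContractViolation(f"sentiment scores must be >= 0, got {self}")

    def __add__(self, other: "SentimentTriple") -> "SentimentTriple":
        return SentimentTriple(self.pos + other.pos, self.neg + other.neg,
                               self.neu + other.neu)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.pos, self.neg, self.neu)


ZERO = SentimentTriple(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class LexiconEntry:
    pos_category: str  # one of a, n, r, v
    synset_id: str  # 8-digit offset
    triple: SentimentTriple
    terms: tuple[tuple[str, int], ...]  # (lemma, sense_rank)
    gloss: str = ""


@dataclass
class Lexicon:
    entries: dict[tuple[str, str], LexiconEntry] = field(default_factory=dict)
    # (lemma, pos_category) -> entries ordered by sense_rank
    by_lemma: dict[tuple[str, str], list[tuple[int, LexiconEntry]]] = field(
        default_factory=dict)

    def add(self, entry: LexiconEntry) -> None:
        key = (entry.pos_category, entry.synset_id)
        if key in self.entries:
            raise FormatError(f"duplicate lexicon entry {key}")
        self.entries[key] = entry
        for lemma, rank in entry.terms:
            senses = self.by_lemma.setdefault((lemma, entry.pos_category), [])
            senses.append((rank, entry))
            senses.sort(key=lambda pair: pair[0])

    def senses(self, lemma: str, pos_category: str) -> list[LexiconEntry]:
        return [e for _, e in self.by_lemma.get((lemma, pos_category), [])]

    def __len__(self) -> int:
        return len(self.entries)


_VALID_POS = {"a", "n", "r", "v"}


def parse_lexicon_lines(lines, source: str = "<string>") -> Lexicon:
    lexicon = Lexicon()
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 5:
            raise FormatError(
                f"expected >= 5 tab-separated columns, got {len(parts)}",
                line=lineno, source=source,
            )
        pos_cat, synset_id, pos_s, neg_s, terms_s = parts[:5]
        gloss = parts[5] if len(parts) > 5 else ""
        if pos_cat not in _VALID_POS:
            raise FormatError(f"invalid POS category {pos_cat!r}",
                              line=lineno, source=source)
        try:
            pos_score, neg_score = float(pos_s), float(neg_s)
        except ValueError:
            raise FormatError(f"non-numeric score in {pos_s!r}/{neg_s!r}",
                              line=lineno, source=source)
        if pos_score < 0 or neg_score < 0:
            raise FormatError("negative sentiment score", line=lineno, source=source)
        if pos_score + neg_score > 1 + _SUM_TOL:
            raise FormatError(
                f"PosScore + NegScore = {pos_score + neg_score} exceeds 1",
                line=lineno, source=source,
            )
        neu_score = max(0.0, 1.0 - pos_score - neg_score)
        terms: list[tuple[str, int]] = []
        for item in terms_s.split():
            if "#" not in item:
                raise FormatError(f"term {item!r} lacks a #rank suffix",
                                  line=lineno, source=source)
            lemma, _, rank_s = item.rpartition("#")
            try:
                rank = int(rank_s)
            except ValueError:
                raise FormatError(f"non-integer sense rank in {item!r}",
                                  line=lineno, source=source)
            terms.append((lemma.lower(), rank))
        if not terms:
            raise FormatError("entry has no terms", line=lineno, source=source)
        lexicon.add(LexiconEntry(
            pos_category=pos_cat, synset_id=synset_id,
            triple=SentimentTriple(pos_score, neg_score, neu_score),
            terms=tuple(terms), gloss=gloss,
        ))
    return lexicon


def load_lexicon(path: str) -> Lexicon:
    """Load a SentiWordNet 3.0 format lexicon file.

    Comment ('#') lines are skipped; a malformed line or a line whose
    positive and negative scores sum above 1 raises a format error naming
    the line number.
    """
    with open(path, encoding="utf-8") as handle:
        return parse_lexicon_lines(handle, source=path)


# ---------------------------------------------------------------------------
# Sense selection


def penn_to_swn(penn_pos: str) -> str | None:
    """Map a Penn Treebank tag onto the lexicon's POS category
    (NN* -> n, VB* -> v, JJ* -> a, RB* -> r); None when unmappable."""
    if penn_pos.startswith("NN"):
        return "n"
    if penn_pos.startswith("VB"):
        return "v"
    if penn_pos.startswith("JJ"):
        return "a"
    if penn_pos.startswith("RB"):
        return "r"
    return None


class SenseSelector(Protocol):
    def select(self, lemma: str, pos_category: str,
               candidates: Sequence[LexiconEntry]) -> LexiconEntry | None: ...


class MostFrequentSenseSelector:
    """Deterministic word-sense disambiguation fallback: take the sense with
    the smallest sense rank, the standard most-frequent-sense baseline."""

    def select(self, lemma: str, pos_category: str,
               candidates: Sequence[LexiconEntry]) -> LexiconEntry | None:
        return candidates[0] if candidates else None


DEFAULT_SELECTOR = MostFrequentSenseSelector()


def select_sense(lemma: str, penn_pos: str, lexicon: Lexicon,
                 selector: SenseSelector | None = None) -> LexiconEntry | None:
    """Choose one lexicon sense for (lemma, Penn tag); None when the tag has
    no lexicon category or the lemma is absent under that category —
    absence is a valid outcome, not an error."""
    selector = selector or DEFAULT_SELECTOR
    category = penn_to_swn(penn_pos)
    if category is None:
        return None
    return selector.select(lemma, category, lexicon.senses(lemma, category))


# ---------------------------------------------------------------------------
# Aggregation and the polarity rule


@dataclass
class AspectSentiment:
    aspect: AspectMention
    window: ContextWindow
    triple: SentimentTriple
    label: str
    per_word: list[tuple[int, str | None, SentimentTriple]] = field(
        default_factory=list)


def classify_polarity(triple: SentimentTriple) -> str:
    """Strict-inequality polarity rule: a label wins only when its aggregate
    strictly exceeds both others; any tie for the maximum is neutral."""
    if triple.pos < 0 or triple.neg < 0 or triple.neu < 0:
        raise ContractViolation(f"negative component in {triple}")
    if triple.pos > triple.neg and triple.pos > triple.neu:
        return POSITIVE
    if triple.neg > triple.pos and triple.neg > triple.neu:
        return NEGATIVE
    if triple.neu > triple.pos and triple.neu > triple.neg:
        return NEUTRAL
    return NEUTRAL


def score_aspect(window: ContextWindow, tweet: Tweet, lexicon: Lexicon,
                 selector: SenseSelector | None = None) -> AspectSentiment:
    """Aggregate sentiment over a context window.

    Each window word contributes its selected sense's triple, or (0, 0, 0)
    when no sense applies; the aspect triple is the element-wise sum and the
    label follows :func:`classify_polarity`. An empty window therefore sums
    to (0, 0, 0) and is labelled neutral.
    """
    per_word: list[tuple[int, str | None, SentimentTriple]] = []
    total = ZERO
    for idx in window.token_indices:
        token = tweet.tokens[idx]
        entry = select_sense(token.lemma, token.pos, lexicon, selector)
        contributed = entry.triple if entry is not None else ZERO
        per_word.append((idx, entry.synset_id if entry else None, contributed))
        total = total + contributed
    return AspectSentiment(
        aspect=window.aspect, window=window, triple=total,
        label=classify_polarity(total), per_word=per_word,
    )
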