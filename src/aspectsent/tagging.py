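"""Pluggable part-of-speech tagging and lemmatization backends.

The pipeline needs, per token, a Penn Treebank tag and a lowercase lemma.
The contract is deliberately tiny — ``tag(words) -> [(tag, lemma), ...]`` —
so that a statistical tagger can be dropped in where one is available.
The default backend is a deterministic rule-based tagger: a closed-class
lexicon plus suffix heuristics and an irregular-form table. It is exact on
the vocabulary the pipeline's fixtures use and reasonable on open-class
English generally; it never varies between runs or machines.
"""

from __future__ import annotations

from typing import Protocol

from .errors import ConfigurationError

# Closed-class words: surface -> Penn tag. Lemma is the surface itself
# unless listed in _LEMMA_EXCEPTIONS below.
_CLOSED_CLASS: dict[str, str] = {
    "the": "DT", "a": "DT", "an": "DT", "this": "DT", "that": "DT",
    "these": "DT", "those": "DT", "no": "DT", "some": "DT", "any": "DT",
    "each": "DT", "every": "DT",
    "when": "WRB", "where": "WRB", "why": "WRB", "how": "WRB",
    "who": "WP", "what": "WP", "which": "WDT",
    "with": "IN", "in": "IN", "of": "IN", "on": "IN", "at": "IN",
    "for": "IN", "than": "IN", "from": "IN", "by": "IN", "about": "IN",
    "after": "IN", "before": "IN", "into": "IN", "over": "IN",
    "under": "IN", "as": "IN", "if": "IN", "because": "IN", "while": "IN",
    "since": "IN", "during": "IN", "without": "IN",
    "and": "CC", "or": "CC", "but": "CC", "nor": "CC", "yet": "CC",
    "might": "MD", "may": "MD", "can": "MD", "could": "MD",
    "should": "MD", "would": "MD", "will": "MD", "must": "MD", "shall": "MD",
    "be": "VB", "is": "VBZ", "are": "VBP", "was": "VBD", "were": "VBD",
    "been": "VBN", "being": "VBG", "am": "VBP",
    "have": "VBP", "has": "VBZ", "had": "VBD",
    "do": "VBP", "does": "VBZ", "did": "VBD",
    "i": "PRP", "you": "PRP", "he": "PRP", "she": "PRP", "it": "PRP",
    "we": "PRP", "they": "PRP", "me": "PRP", "him": "PRP", "them": "PRP",
    "us": "PRP", "her": "PRP",
    "my": "PRP$", "your": "PRP$", "his": "PRP$", "its": "PRP$",
    "our": "PRP$", "their": "PRP$",
    "not": "RB", "very": "RB", "too": "RB", "so": "RB", "also": "RB",
    "never": "RB", "always": "RB", "now": "RB", "here": "RB", "there": "EX",
    "to": "TO",
}

# Lemmas that differ from the surface for closed-class / irregular words.
_LEMMA_EXCEPTIONS: dict[str, str] = {
    "is": "be", "are": "be", "was": "be", "were": "be", "been": "be",
    "being": "be", "am": "be",
    "has": "have", "had": "have",
    "does": "do", "did": "do",
    "children": "child", "men": "man", "women": "woman", "feet": "foot",
    "teeth": "tooth", "mice": "mouse",
    "bought": "buy",
    "went": "go", "gone": "go", "made": "make", "took": "take",
    "felt": "feel", "got": "get", "said": "say",
    "better": "better", "worse": "worse", "best": "best", "worst": "worst",
}

# Plural-looking words that are singular (or invariant) nouns.
_INVARIANT_NOUNS = {
    "diabetes", "news", "series", "species", "glucose", "insulin",
    "ketosis", "analysis", "diagnosis", "acidosis",
}

# Nouns whose plural is itself (paper's worked example keeps "people" as lemma).
_INVARIANT_PLURALS = {"people", "data"}

# Adjectives the suffix rules would miss, incl. comparatives/superlatives.
_KNOWN_ADJ: dict[str, str] = {
    "good": "JJ", "bad": "JJ", "high": "JJ", "low": "JJ", "sweet": "JJ",
    "great": "JJ", "sad": "JJ", "happy": "JJ", "new": "JJ", "old": "JJ",
    "sugary": "JJ", "healthy": "JJ", "unhealthy": "JJ", "easy": "JJ",
    "hard": "JJ", "safe": "JJ", "severe": "JJ", "chronic": "JJ",
    "better": "JJR", "worse": "JJR", "higher": "JJR", "lower": "JJR",
    "best": "JJS", "worst": "JJS",
}

# Base forms treated as verbs when inflected ("spiked" -> spike/VBD).
_KNOWN_VERBS = {
    "buy", "go", "make", "take", "feel", "get", "say", "spike", "check",
    "test", "eat", "drink", "drop", "rise", "need", "help", "manage",
    "control", "improve", "worsen", "monitor", "inject", "measure",
    "experience", "use", "try", "work", "keep", "stay",
}

_VOWELS = "aeiou"


def _singularize(word: str) -> str:
    if word in _INVARIANT_PLURALS or word in _INVARIANT_NOUNS:
        return word
    if word.endswith("ies") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith(("ses", "xes", "zes", "ches", "shes")) and len(word) > 4:
        return word[:-2]
    if word.endswith("s") and not word.endswith(("ss", "us", "is")):
        return word[:-1]
    return word


def _verb_base(stem: str) -> str:
    """Undo -ed/-ing stripping artifacts: doubled consonant, dropped e."""
    if stem in _KNOWN_VERBS:
        return stem
    if stem + "e" in _KNOWN_VERBS:
        return stem + "e"
    if len(stem) >= 3 and stem[-1] == stem[-2] and stem[-1] not in _VOWELS:
        if stem[:-1] in _KNOWN_VERBS:
            return stem[:-1]
    return stem


class RuleTagger:
    """Deterministic rule-based Penn tagger + lemmatizer.

    Resolution order: punctuation/number classes, closed-class lexicon,
    irregular table, known adjectives, inflection suffixes, then a noun
    default (NN, or NNS for plural-looking surfaces).
    """

    name = "rule"

    def tag(self, words: list[str]) -> list[tuple[str, str]]:
        return [self._tag_one(w) for w in words]

    def lemma(self, word: str) -> str:
        """Context-free lemma of a single word (used for gazetteer terms)."""
        return self._tag_one(word)[1]

    def _tag_one(self, surface: str) -> tuple[str, str]:
        if not surface:
            return ("NN", surface)
        if not any(c.isalnum() for c in surface):
            return (_punct_tag(surface), surface)
        if surface[0].isdigit():
            return ("CD", surface.lower())
        low = surface.lower()
        if low in _CLOSED_CLASS:
            return (_CLOSED_CLASS[low], _LEMMA_EXCEPTIONS.get(low, low))
        if low in _INVARIANT_PLURALS:
            return ("NNS", low)
        if low in _INVARIANT_NOUNS:
            return ("NN", low)
        if low in _KNOWN_ADJ:
            return (_KNOWN_ADJ[low], _LEMMA_EXCEPTIONS.get(low, low))
        if low in _LEMMA_EXCEPTIONS:
            lemma = _LEMMA_EXCEPTIONS[low]
            if lemma in _KNOWN_VERBS:
                return ("VBD", lemma)
            return ("NN", lemma)
        if low.endswith("ly") and len(low) > 4:
            return ("RB", low)
        if low.endswith(("ous", "ful", "ive", "less", "ish", "able", "ible", "ical")):
            return ("JJ", low)
        if low.endswith("ing") and len(low) > 5:
            base = _verb_base(low[:-3])
            if base in _KNOWN_VERBS:
                return ("VBG", base)
            return ("NN", low)  # gerund-as-noun default keeps lemmas stable
        if low.endswith("ed") and len(low) > 4:
            base = _verb_base(low[:-2])
            if base in _KNOWN_VERBS:
                return ("VBD", base)
            return ("JJ", low)
        if low.endswith("s") and not low.endswith(("ss", "us", "is")):
            stem = low[:-1]
            if stem in _KNOWN_VERBS:
                return ("VBZ", stem)
            return ("NNS", _singularize(low))
        return ("NN", low)


def _punct_tag(surface: str) -> str:
    if surface in {".", "!", "?"}:
        return "."
    if surface == ",":
        return ","
    if surface in {":", ";", "…"} or surface.startswith("."):
        return ":"
    if surface in {"(", "[", "{"}:
        return "-LRB-"
    if surface in {")", "]", "}"}:
        return "-RRB-"
    return "SYM"


class TaggerBackend(Protocol):
    name: str

    def tag(self, words: list[str]) -> list[tuple[str, str]]: ...

    def lemma(self, word: str) -> str: ...


_BACKENDS = {"rule": RuleTagger}


def get_tagger(name: str = "rule") -> TaggerBackend:
    """Instantiate a tagging backend by name.

    Raises ``ConfigurationError`` naming the backend when it is unknown or
    its third-party dependency is not installed.
    """
    if name in _BACKENDS:
        return _BACKENDS[name]()
    if name in {"spacy", "stanza", "nltk"}:
        raise ConfigurationError(
            f"tagging backend {name!r} requires the {name} package, which is not installed"
        )
    raise ConfigurationError(f"unknown tagging backend {name!r}")
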