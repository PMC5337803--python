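"""Concept gazetteer construction and dictionary-based aspect detection.

Aspects are domain-ontology concepts (drugs, complications, lab tests,
symptoms, physical-examination findings). The gazetteer maps lemmatized term
sequences to concept identifiers. Terms come either from a flat two-column
TSV (the canonical runtime format) or from an OWL ontology, whose class
labels and synonym annotations are harvested by :func:`owl_to_terms` — the
ontology is used purely as a term source; its axioms are ignored.

Detection scans a tweet's lemma sequence with a leftmost-longest policy, so
"blood sugar" beats "sugar" when both are gazetteer terms, and the returned
mentions never overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .errors import ContractViolation, FormatError
from .preprocess import Tweet
from .tagging import TaggerBackend, get_tagger


@dataclass(frozen=True)
class ConceptEntry:
    concept_id: str
    terms: tuple[tuple[str, ...], ...]
    preferred_label: str

    def __post_init__(self) -> None:
        if not self.terms:
            raise ContractViolation(f"concept {self.concept_id} has no terms")
        for term in self.terms:
            if not term or any(not w for w in term):
                raise ContractViolation(
                    f"concept {self.concept_id} has an empty term word"
                )


@dataclass
class BuildReport:
    n_concepts: int = 0
    n_terms: int = 0
    collisions: list[tuple[tuple[str, ...], str, str]] = field(default_factory=list)


@dataclass
class Gazetteer:
    entries: list[ConceptEntry]
    index: dict[tuple[str, ...], str]
    max_term_len: int
    report: BuildReport = field(default_factory=BuildReport)

    def __contains__(self, term: tuple[str, ...]) -> bool:
        return term in self.index


@dataclass(frozen=True)
class AspectMention:
    """A detected concept occurrence: token span [start, end) in its tweet."""

    tweet_id: str
    start: int
    end: int
    concept_id: str
    surface: str
    sentence_index: int = 0

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def _lemmatize_term(term: str, tagger: TaggerBackend) -> tuple[str, ...]:
    return tuple(tagger.lemma(w) for w in term.lower().split())


def build_gazetteer(pairs: list[tuple[str, str]],
                    tagger: TaggerBackend | None = None) -> Gazetteer:
    """Build a gazetteer from (concept_id, term) pairs.

    Each term is lowercased and lemmatized word by word so that detection on
    token lemmas matches inflected surfaces ("glucose tablets" matches a
    "glucose tablet" term). A term claimed by two concepts is assigned to the
    lexicographically smallest concept id, with a warning in the build report.
    """
    tagger = tagger or get_tagger("rule")
    report = BuildReport()
    index: dict[tuple[str, ...], str] = {}
    by_concept: dict[str, dict] = {}
    for concept_id, term in pairs:
        if not concept_id or not term.strip():
            raise FormatError(f"empty concept id or term in pair ({concept_id!r}, {term!r})")
        words = _lemmatize_term(term, tagger)
        info = by_concept.setdefault(concept_id, {"terms": [], "label": term})
        if words not in info["terms"]:
            info["terms"].append(words)
        existing = index.get(words)
        if existing is None:
            index[words] = concept_id
        elif existing != concept_id:
            winner = min(existing, concept_id)
            loser = max(existing, concept_id)
            report.collisions.append((words, winner, loser))
            warnings.warn(
                f"gazetteer term {' '.join(words)!r} claimed by {existing} and "
                f"{concept_id}; resolved to {winner}"
            )
            index[words] = winner
    if not index:
        raise FormatError("zero terms: gazetteer source contained no usable entries")
    entries = [
        ConceptEntry(concept_id=cid, terms=tuple(info["terms"]),
                     preferred_label=info["label"])
        for cid, info in sorted(by_concept.items())
    ]
    report.n_concepts = len(entries)
    report.n_terms = len(index)
    return Gazetteer(entries=entries, index=index,
                     max_term_len=max(len(t) for t in index), report=report)


def load_gazetteer_tsv(path: str, tagger: TaggerBackend | None = None) -> Gazetteer:
    """Read the canonical 2-column TSV (concept_id <TAB> term, one per row;
    '#' comment lines ignored) and build the gazetteer."""
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(
                    "expected 2 tab-separated columns (concept_id, term)",
                    line=lineno, source=path,
                )
            pairs.append((parts[0], parts[1]))
    if not pairs:
        raise FormatError("zero terms: gazetteer source contained no usable entries",
                          source=path)
    return build_gazetteer(pairs, tagger)


def save_gazetteer_tsv(pairs: list[tuple[str, str]], path: str) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("# concept_id\tterm\n")
        for concept_id, term in pairs:
            handle.write(f"{concept_id}\t{term}\n")


def owl_to_terms(path: str) -> list[tuple[str, str]]:
    """Harvest (concept_id, term) pairs from an OWL 2 ontology.

    Extracts every ``rdfs:label`` of an ``owl:Class`` plus the value of any
    annotation property whose local name contains "synonym" (this covers
    oboInOwl hasExactSynonym/hasRelatedSynonym and skos altLabel-style
    custom properties).
    """
    try:
        import rdflib
        from rdflib.namespace import OWL, RDF, RDFS
    except ImportError as exc:  # pragma: no cover - rdflib is a hard dependency
        raise FormatError(f"OWL ingestion requires rdflib: {exc}")
    graph = rdflib.Graph()
    try:
        graph.parse(path)
    except Exception as exc:
        raise FormatError(f"cannot parse ontology: {exc}", source=path)
    classes = set(graph.subjects(RDF.type, OWL.Class))
    pairs: list[tuple[str, str]] = []
    for cls in sorted(classes, key=str):
        if not isinstance(cls, rdflib.URIRef):
            continue
        cid = str(cls)
        for label in graph.objects(cls, RDFS.label):
            pairs.append((cid, str(label)))
        for pred, obj in graph.predicate_objects(cls):
            local = str(pred).rsplit("#", 1)[-1].rsplit("/", 1)[-1]
            if "synonym" in local.lower() and isinstance(obj, rdflib.Literal):
                pairs.append((cid, str(obj)))
    if not pairs:
        raise FormatError("zero terms: ontology has no class labels or synonyms",
                          source=path)
    return pairs


def detect_aspects(tweet: Tweet, gaz: Gazetteer) -> list[AspectMention]:
    """Find gazetteer concepts in a tweet: leftmost-longest matching on
    lemma sequences, returning ordered, non-overlapping mentions."""
    lemmas = [t.lemma for t in tweet.tokens]
    mentions: list[AspectMention] = []
    i = 0
    n = len(lemmas)
    while i < n:
        matched = False
        for length in range(min(gaz.max_term_len, n - i), 0, -1):
            key = tuple(lemmas[i:i + length])
            concept_id = gaz.index.get(key)
            if concept_id is not None:
                surface = " ".join(t.surface for t in tweet.tokens[i:i + length])
                mentions.append(AspectMention(
                    tweet_id=tweet.id, start=i, end=i + length,
                    concept_id=concept_id, surface=surface,
                    sentence_index=_sentence_of(tweet, i),
                ))
                i += length
                matched = True
                break
        if not matched:
            i += 1
    return mentions


def _sentence_of(tweet: Tweet, token_index: int) -> int:
    for si, sent in enumerate(tweet.sentences):
        if sent.start <= token_index < sent.end:
            return si
    return 0
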