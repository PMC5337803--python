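# Methods

## The model

The pipeline implements lexicon-based (semantic-orientation) aspect-level
sentiment analysis. Its core assumption is proximity: the sentiment
expressed toward a concept is carried by the words immediately around its
mention, so an aspect's score is the element-wise sum of the prior-polarity
triples of the words in an N-gram window, and its label follows from
strict comparison of the three aggregates. The approach is fully
deterministic: no training, no sampled inference, no remote services.

Three stages feed that computation.

**Normalization.** Twitter-specific noise is removed in a fixed cascade:
whole @-mention tokens, URLs (`http://`, `https://`, bare `t.co/` —
shorteners dominate tweet URLs, so matching only `http://` would leave
most of them in), the `#` character of hashtags (the body is kept: hashtag
bodies are usually content words), then token-based case-insensitive
abbreviation expansion with the domain dictionary consulted before the SMS
dictionary and the longest key winning, then spell correction of remaining
out-of-dictionary words, then whitespace collapse. Expansion runs before
correction so domain jargon ("Hypo") is expanded rather than "corrected"
away. Every change is logged as a positioned edit; replaying the log over
the raw text reproduces the normalized text exactly, which the tests
assert on arbitrary input. CamelCase hashtag bodies are kept as single
tokens rather than split; splitting is a tokenization policy we did not
want to entangle with sentiment scoring.

**Tagging.** Tagging and lemmatization sit behind a two-method backend
contract (`tag(words)`, `lemma(word)`), so a statistical tagger can be
plugged in. The default backend is a deterministic rule-based Penn tagger:
a closed-class lexicon, an irregular-form table, and suffix heuristics
with a noun default. It reproduces the canonical worked tweet's tag/lemma
sequence exactly ("When/WRB/when … tablets/NNS/tablet …
better/JJR/better") and behaves sensibly on open-class English; it is
byte-stable across machines, which a model-based tagger is not. Requesting
an unavailable backend (e.g. a spaCy adapter without spaCy installed)
raises a configuration error naming the backend. Lemmas are lowercase;
spans are 0-based half-open throughout.

**Aspect detection.** The gazetteer maps lemmatized, lowercased term
sequences to concept ids. Matching is on lemma sequences rather than
surfaces — lemmatization exists precisely so "glucose tablets" can match
a "glucose tablet" term — with leftmost-longest selection and ties on
length broken by the smaller start. Term collisions across concepts
resolve to the lexicographically smallest concept id with a build warning.
OWL ingestion (via rdflib) harvests `rdfs:label` plus any annotation
property whose local name contains "synonym", and nothing else: the
ontology is a term source, not a reasoning substrate. Matching is
tweet-wide rather than per-sentence; tweets are short enough that sentence
scoping would mostly create boundary artifacts.

## Windows and scoring

Windows count *word* tokens: punctuation is skipped and does not consume
window slots (a comma carries no sentiment and should not crowd out a word
that does). Windows truncate at tweet boundaries but deliberately cross
sentence boundaries, and tokens of other aspects count as ordinary context
words. For multiword aspects, *before* anchors at the span's first token
and *after* at its last. The invariant around(N) = before(N) ⊎ after(N)
holds exactly and is asserted in tests.

Sense selection maps Penn tags to lexicon categories (NN*→n, VB*→v,
JJ*→a, RB*→r; anything else contributes nothing) and then applies a
pluggable `SenseSelector`. The default is the most-frequent-sense
baseline — smallest sense rank — chosen because it is the standard
download-free WSD fallback and is exactly reproducible; a
disambiguation-service adapter can be slotted in without touching the
scoring code. Words with no mappable tag or no lexicon entry contribute
(0, 0, 0), not a neutral prior of (⅓, ⅓, ⅓): the aggregate is defined as a
sum of lexicon-returned scores, and padding it with priors would let
out-of-vocabulary words vote. The neutral score of each sense is always
recomputed as 1 − pos − neg on load, so the sum-to-1 invariant cannot be
broken by an inconsistent file, and a file whose pos + neg exceeds 1 is
rejected with its line number.

The strict-inequality rule leaves ties undefined; we label every tie
neutral. This keeps the rule total, and it is conservative: an aspect is
only called polar when one polarity strictly dominates, which also gives
the empty window a well-defined neutral outcome. Aggregates are raw sums,
not length-normalized — the comparison is within one aspect's window, so a
common scale factor would not change the argmax, but normalization would
change tie behavior at truncated windows; raw sums match the additive
definition.

## Evaluation

Identification matches predicted to gold spans greedily 1-to-1, leftmost
first, either exact-span (default) or ≥1-token overlap. Polarity is scored
only on identification-matched aspects, one-vs-rest per class; macro
averaging (the default headline) takes the unweighted mean of the three
classes' P, R and F — note the macro F is the mean of per-class F values,
not the harmonic mean of macro P and macro R — and micro averaging pools
counts, which for single-label data makes micro P = R = F = accuracy. Zero
denominators yield 0 with a warning instead of NaN so sweep grids never
crash on degenerate cells. Both matching criterion and averaging scheme
are explicit parameters rather than baked-in choices.

## The synthetic-data generator

The generator emulates the statistical structure the method assumes —
polar words concentrated immediately around aspect mentions — not real
Twitter language. Each tweet carries one planted aspect term (drawn from a
generated gazetteer of 30 concepts, about a third multiword) flanked by
1–3 context words per side drawn from positive / negative / neutral pools,
wrapped in out-of-lexicon filler, with optional reversible Twitter noise:
a prepended @-mention, an appended URL, a `#` on a filler word, or a
context word written as an abbreviation that the generated dictionaries
expand back. The default corpus size is 900 tweets with an even label mix,
matching the scale of a manually annotated research corpus in this domain.

Label planting is margin-based: positive-pool words carry (p, 0, 1−p)
with p ∈ [0.6, 0.9] (symmetrically for negative), neutral-pool words are
≥0.9 objective, so the gold label's aggregate beats the runner-up by at
least 0.1 — enough that the strict inequalities recover every gold label
when nothing is lost; the generator verifies the margin and refuses
configurations that cannot achieve it (e.g. zero context width). Two
degradation dials exist: `noise` swaps a planted word's occurrence for an
out-of-lexicon word (its contribution becomes (0, 0, 0), pulling polar
aspects toward neutral), and `decoys` plants near-miss phrases sharing a
word with a multiword term that must *not* be detected. Pseudo-words are
CV-syllable strings filtered so the default tagger treats them as plain
nouns with identity lemmas, keeping gazetteer and lexicon lookups exact.
One seeded RNG stream drives everything; the manifest records the full
configuration and regeneration from it is byte-identical.

What passing tests show, and what they do not: perfect recovery on a
noiseless corpus demonstrates that the pipeline's stages compose without
loss under the method's own proximity assumption; it says nothing about
real tweets, where sentiment words may sit outside the window, senses are
ambiguous, and the lexicon's priors may be wrong for the health domain.
The degradation tests show the failure mode is graceful, not that the
real-data error rate is small.

## Problem sizes and numerics

The bundled checks run the full pipeline on corpora of 100–300 tweets (and
20 seeds for the dropout average), sizes at which every quantity is exact
and the whole suite completes in seconds; the pipeline itself is linear in
corpus size and handles the 900-tweet default just as quickly. Score
comparisons in tests use absolute tolerances of 1e-9 (sum-to-1) or exact
equality on rational-friendly fixture values. The F-measure recomputed
from a published, already-rounded precision/recall pair can differ from
the published F in the final decimal; the check allows 0.01 after rounding
to two decimals.

## Known limitations

No negation or intensifier handling ("not better" scores as "better");
no emoji/emoticon polarity; no domain-adapted lexicon — general-purpose
prior polarities are known to misfire on clinical vocabulary; the default
tagger's open-class accuracy is below a trained tagger's on unrestricted
text; gazetteer recall is bounded by the ontology's synonym coverage (the
"oral antihyperglycemic" fixture tweet exists to make that miss visible);
and the sense-selection default ignores context entirely.
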