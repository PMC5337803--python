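# aspectsent

Aspect-level sentiment analysis for health-domain microtexts, built around
the diabetes domain. Instead of assigning one polarity to a whole tweet,
the pipeline finds each domain concept mentioned in it — a drug, a symptom,
a lab test — and labels the sentiment expressed toward that concept.

It is aimed at health-NLP practitioners who want a fully deterministic,
lexicon-based (semantic-orientation) baseline that runs offline: no web
services, no model downloads, and a synthetic-corpus generator so every
stage is testable without any external data.

## Method

For a tweet, the pipeline:

1. **Preprocess** — remove @-mentions and URLs, strip the `#` of hashtags
   (keeping the body), expand SMS and domain abbreviations ("Hypo" →
   hypoglycemia, "carbs" → carbohydrates), optionally spell-correct, then
   tokenize, sentence-split, POS-tag (Penn Treebank) and lemmatize.
2. **Detect aspects** — scan token lemmas against a gazetteer of concept
   terms built from a domain ontology's class labels and synonyms
   (leftmost-longest matching, so "blood sugar" beats "sugar").
3. **Select context** — for each aspect *aᵢ*, take the word set *w(aᵢ)*
   with an N-gram window: *before* (N words preceding), *after*
   (N following) or *around* (both), N ∈ 2..6 by default.
4. **Score** — each context word *w* contributes the (pos, neg, neu)
   triple of one SentiWordNet sense (most-frequent sense by default; the
   word-sense-disambiguation strategy is pluggable):

   ScorePos(aᵢ) = Σ_{w∈w(aᵢ)} ScorePosSWN(w), and likewise ScoreNeg,
   ScoreNeu. Each single sense satisfies pos + neg + neu = 1.

5. **Classify** — *aᵢ* is positive iff ScorePos strictly exceeds both
   ScoreNeg and ScoreNeu; symmetrically for negative and neutral; ties are
   neutral.

Evaluation reports precision, recall and F-measure (harmonic mean) for
aspect identification (exact or overlap span matching) and for polarity
(per class one-vs-rest, macro- and micro-averaged), and a sweep runner
fills the full window-method × N grid.

## Worked example

```bash
python examples/score_aspect.py
```

prints (abridged):

```
When people with diabetes experience a dangerous drop in blood sugar,
glucose tablets might be a better option than a sugary food or drink

aspect 'blood sugar' (DDO:0000002)
  window: ['dangerous', 'drop', 'in', 'glucose', 'tablets', 'might']
  scores: pos=0.000 neg=1.375 neu=0.625
  label:  negative

window sensitivity for 'glucose tablets':
  around N=3: pos=0.000 neg=0.000 neu=0.000 -> neutral
  after  N=4: pos=0.875 neg=0.000 neu=0.125 -> positive
```

"blood sugar" is negative because "dangerous" and "drop" contribute
negative sense triples inside its window; "glucose tablets" flips to
positive once the window reaches the adjective "better", whose
most-frequent adjective sense carries (0.875, 0, 0.125). The other
examples cover preprocessing (`preprocess_tweet.py`), gazetteer
construction from an OWL ontology (`ontology_to_gazetteer.py`), metric
arithmetic (`evaluate_metrics.py`) and the full grid (`run_sweep.py`).

A thin CLI wraps the same library calls:

```bash
aspectsent simulate --out-dir fixtures/          # synthetic corpus + resources
aspectsent annotate --in fixtures/tweets.jsonl --gazetteer fixtures/gazetteer.tsv \
    --lexicon fixtures/lexicon.txt --method around --n 3 --out aspects.jsonl
aspectsent evaluate --pred aspects.jsonl --gold fixtures/gold.jsonl
aspectsent sweep --in fixtures/tweets.jsonl --gold fixtures/gold.jsonl \
    --gazetteer fixtures/gazetteer.tsv --lexicon fixtures/lexicon.txt
aspectsent owl2gazetteer --in ddo.owl --out gaz.tsv
```

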