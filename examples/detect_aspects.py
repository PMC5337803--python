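"""Detect domain-concept aspects in the bundled worked tweet.

The gazetteer maps lemmatized term sequences to concept ids, so the plural
surface "glucose tablets" matches the "glucose tablet" term; matching is
leftmost-longest, so "blood sugar" wins over any single-word sub-term.
"""

from aspectsent import detect_aspects, fixture_minimal, preprocess_tweet

fixture = fixture_minimal()
gazetteer = fixture.gazetteer()
tweet = preprocess_tweet(fixture.tweets[0], fixture.abbrev_dicts())

print(tweet.normalized_text)
for m in detect_aspects(tweet, gazetteer):
    print(f"  tokens [{m.start}, {m.end})  {m.concept_id}  surface={m.surface!r}")
# Each line is one aspect mention: its token span, the ontology concept it
# resolves to, and the matched surface text.
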