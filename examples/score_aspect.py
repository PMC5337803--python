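"""Score the polarity of each aspect in the worked tweet.

For every detected aspect the around/N=3 window collects up to three word
tokens on each side; each word contributes the (pos, neg, neu) triple of
its most-frequent lexicon sense, the triples are summed, and the strict-
inequality rule assigns the label. A second pass shows how the choice of
method and N changes the verdict for one aspect.
"""

from aspectsent import (detect_aspects, extract_window, fixture_minimal,
                        preprocess_tweet, score_aspect)

fixture = fixture_minimal()
gazetteer = fixture.gazetteer()
lexicon = fixture.lexicon()
tweet = preprocess_tweet(fixture.tweets[0], fixture.abbrev_dicts())

print(tweet.normalized_text)
mentions = detect_aspects(tweet, gazetteer)
for mention in mentions:
    window = extract_window(tweet, mention, "around", 3)
    result = score_aspect(window, tweet, lexicon)
    words = [tweet.tokens[i].surface for i in window.token_indices]
    print(f"\naspect {mention.surface!r} ({mention.concept_id})")
    print(f"  window: {words}")
    print(f"  scores: pos={result.triple.pos:.3f} neg={result.triple.neg:.3f} "
          f"neu={result.triple.neu:.3f}")
    print(f"  label:  {result.label}")

# "blood sugar" comes out negative: "dangerous" and "drop" contribute their
# negative triples. "glucose tablets" is neutral at around/N=3 because the
# positive word "better" sits four words downstream — widen or shift the
# window and the verdict changes:
tablets = mentions[-1]
print(f"\nwindow sensitivity for {tablets.surface!r}:")
for method, n in [("around", 3), ("after", 4), ("around", 5)]:
    window = extract_window(tweet, tablets, method, n)
    result = score_aspect(window, tweet, lexicon)
    print(f"  {method:6s} N={n}: pos={result.triple.pos:.3f} "
          f"neg={result.triple.neg:.3f} neu={result.triple.neu:.3f} "
          f"-> {result.label}")
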