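"""Normalize and analyze one noisy tweet.

Shows mention/URL removal, hashtag stripping and abbreviation expansion,
then the token / Penn tag / lemma view of the cleaned text.
"""

from aspectsent import AbbreviationDictionary, RawTweet, preprocess_tweet

domain = AbbreviationDictionary({"carbs": "carbohydrates",
                                 "Hypo": "hypoglycemia"}, source="domain")
sms = AbbreviationDictionary({"u": "you"}, source="sms")

raw = RawTweet(id="demo",
               text="@user1 my carbs spiked http://t.co/xyz #diabetes")
tweet = preprocess_tweet(raw, [domain, sms])

print("raw:       ", raw.text)
print("normalized:", tweet.normalized_text)
print("edits:")
for e in tweet.edit_log:
    print(f"  {e.kind:12s} {e.original!r} -> {e.replacement!r}")
print("tokens (surface/POS/lemma):")
print(" ", " ".join(f"{t.surface}/{t.pos}/{t.lemma}" for t in tweet.tokens))
# The normalized text keeps only content words: the mention and URL carry no
# sentiment, the hashtag body does, and "carbs" is domain jargon for
# carbohydrates.
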