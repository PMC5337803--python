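"""Readers and writers for the pipeline's plain-text interchange formats.

Tweets travel as JSONL ({"id", "text"}) or two-column TSV; aspect
annotations as JSONL with one record per scored aspect.
"""

from __future__ import annotations

import json
from typing import Iterable, Sequence

from .errors import FormatError
from .preprocess import RawTweet, Tweet
from .scoring import AspectSentiment


def read_tweets_jsonl(path: str) -> list[RawTweet]:
    tweets: list[RawTweet] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                tweets.append(RawTweet(id=str(obj["id"]), text=str(obj["text"])))
            except (KeyError, ValueError) as exc:
                raise FormatError(f"bad tweet record: {exc}", line=lineno, source=path)
    return tweets


def read_tweets_tsv(path: str) -> list[RawTweet]:
    tweets: list[RawTweet] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t", 1)
            if len(parts) != 2:
                raise FormatError("expected 2 tab-separated columns (id, text)",
                                  line=lineno, source=path)
            tweets.append(RawTweet(id=parts[0], text=parts[1]))
    return tweets


def read_tweets(path: str) -> list[RawTweet]:
    """Dispatch on extension: .jsonl/.json -> JSONL, otherwise TSV."""
    if path.endswith((".jsonl", ".json")):
        return read_tweets_jsonl(path)
    return read_tweets_tsv(path)


def write_tokens_jsonl(tweets: Iterable[Tweet], path: str) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for tweet in tweets:
            handle.write(json.dumps({
                "id": tweet.id,
                "normalized_text": tweet.normalized_text,
                "tokens": [
                    {"surface": t.surface, "lemma": t.lemma, "pos": t.pos,
                     "index": t.index, "is_word": t.is_word}
                    for t in tweet.tokens
                ],
                "sentences": [[s.start, s.end] for s in tweet.sentences],
                "edits": [
                    {"kind": e.kind, "position": e.position,
                     "original": e.original, "replacement": e.replacement}
                    for e in tweet.edit_log
                ],
            }, sort_keys=True) + "\n")


def write_aspects_jsonl(results: Sequence[AspectSentiment], path: str) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for r in results:
            handle.write(json.dumps({
                "tweet_id": r.aspect.tweet_id,
                "start": r.aspect.start,
                "end": r.aspect.end,
                "concept_id": r.aspect.concept_id,
                "surface": r.aspect.surface,
                "method": r.window.method.value,
                "n": r.window.n,
                "pos": round(r.triple.pos, 6),
                "neg": round(r.triple.neg, 6),
                "neu": round(r.triple.neu, 6),
                "label": r.label,
            }, sort_keys=True) + "\n")
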