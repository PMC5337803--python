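"""N-gram proximity context windows around aspect mentions.

The sentiment of an aspect is read off the words near it. Three selection
methods are supported: *before* takes up to N word tokens immediately
preceding the mention, *after* up to N immediately following it, and
*around* the union of both. Counting is in word tokens — punctuation is
skipped and does not use up window slots — and windows are truncated at the
tweet boundary but deliberately cross sentence boundaries (the unit of
context is the tweet).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .errors import ContractViolation
from .gazetteer import AspectMention
from .preprocess import Tweet


class WindowMethod(str, Enum):
    BEFORE = "before"
    AFTER = "after"
    AROUND = "around"


@dataclass(frozen=True)
class ContextWindow:
    aspect: AspectMention
    method: WindowMethod
    n: int
    token_indices: tuple[int, ...]


def extract_window(tweet: Tweet, aspect: AspectMention,
                   method: WindowMethod | str, n: int) -> ContextWindow:
    """Select the context word set for one aspect.

    For a multiword aspect, *before* is anchored at the span's first token
    and *after* at its last. Tokens inside the aspect span are never part of
    its own window; tokens of other aspects are ordinary context words.
    """
    method = WindowMethod(method)
    if n < 1:
        raise ContractViolation(f"window size n must be >= 1, got {n}")
    if not (0 <= aspect.start < aspect.end <= len(tweet.tokens)):
        raise ContractViolation(
            f"aspect span [{aspect.start}, {aspect.end}) out of range for a "
            f"{len(tweet.tokens)}-token tweet"
        )

    before: list[int] = []
    i = aspect.start - 1
    while i >= 0 and len(before) < n:
        if tweet.tokens[i].is_word:
            before.append(i)
        i -= 1
    before.reverse()

    after: list[int] = []
    i = aspect.end
    while i < len(tweet.tokens) and len(after) < n:
        if tweet.tokens[i].is_word:
            after.append(i)
        i += 1

    if method is WindowMethod.BEFORE:
        indices = before
    elif method is WindowMethod.AFTER:
        indices = after
    else:
        indices = before + after
    return ContextWindow(aspect=aspect, method=method, n=n,
                         token_indices=tuple(indices))
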