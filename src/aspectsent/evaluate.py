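"""Span-level evaluation of aspect identification and aspect polarity.

Identification is scored as precision, recall and F-measure over predicted
versus gold aspect spans, with either exact-span or token-overlap matching.
Polarity is scored one-vs-rest per class over the identification-matched
aspects, then averaged: *macro* is the unweighted mean of the three classes'
P, R and F (note the macro F is the mean of per-class F values, not the
harmonic mean of macro P and macro R); *micro* pools the counts, which for
single-label classification makes micro P = R = F = accuracy.

All metrics are percentages in [0, 100]; a zero denominator yields 0 with a
warning rather than NaN, so parameter sweeps never crash on degenerate cells.

:func:`run_sweep` executes the whole pipeline over a corpus for every
(window method, N) combination and returns a grid report of macro and micro
polarity scores plus the single identification score.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import ContractViolation, FormatError
from .gazetteer import AspectMention, Gazetteer, detect_aspects
from .preprocess import AbbreviationDictionary, RawTweet, SpellCorrector, Tweet, preprocess_tweet
from .scoring import LABELS, AspectSentiment, Lexicon, SenseSelector, score_aspect
from .tagging import TaggerBackend
from .windows import WindowMethod, extract_window


@dataclass(frozen=True)
class GoldAnnotation:
    tweet_id: str
    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ContractViolation(
                f"gold label {self.label!r} not in {LABELS}"
            )
        if not (0 <= self.start < self.end):
            raise ContractViolation(f"invalid gold span [{self.start}, {self.end})")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class PRF:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f_measure: float


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def prf_from_counts(tp: int, fp: int, fn: int, warn_context: str = "") -> PRF:
    if min(tp, fp, fn) < 0:
        raise ContractViolation("negative count")
    if tp + fp == 0:
        precision = 0.0
        if warn_context:
            warnings.warn(f"{warn_context}: no predictions; precision set to 0")
    else:
        precision = 100.0 * tp / (tp + fp)
    if tp + fn == 0:
        recall = 0.0
        if warn_context:
            warnings.warn(f"{warn_context}: no gold items; recall set to 0")
    else:
        recall = 100.0 * tp / (tp + fn)
    return PRF(tp=tp, fp=fp, fn=fn, precision=precision, recall=recall,
               f_measure=f_measure(precision, recall))


# ---------------------------------------------------------------------------
# Aspect identification


def _validate_gold(gold: Sequence[GoldAnnotation]) -> None:
    seen: set[tuple[str, int, int]] = set()
    for g in gold:
        key = (g.tweet_id, g.start, g.end)
        if key in seen:
            raise ContractViolation(f"duplicate gold span {key}")
        seen.add(key)


def match_identification(pred: Sequence[AspectMention],
                         gold: Sequence[GoldAnnotation],
                         mode: str = "exact",
                         ) -> tuple[list[tuple[AspectMention, GoldAnnotation]],
                                    list[AspectMention], list[GoldAnnotation]]:
    """Greedy 1-to-1 matching of predictions to gold spans.

    exact: spans must be identical; overlap: spans must share >= 1 token.
    Matching is leftmost-first within each tweet. Returns (matched pairs,
    unmatched predictions, unmatched gold).
    """
    if mode not in {"exact", "overlap"}:
        raise ContractViolation(f"unknown matching mode {mode!r}")
    _validate_gold(gold)
    pred_sorted = sorted(pred, key=lambda m: (m.tweet_id, m.start, m.end))
    gold_sorted = sorted(gold, key=lambda g: (g.tweet_id, g.start, g.end))
    taken: set[int] = set()
    pairs: list[tuple[AspectMention, GoldAnnotation]] = []
    unmatched_pred: list[AspectMention] = []
    for m in pred_sorted:
        hit = None
        for gi, g in enumerate(gold_sorted):
            if gi in taken or g.tweet_id != m.tweet_id:
                continue
            if mode == "exact":
                ok = (g.start, g.end) == (m.start, m.end)
            else:
                ok = m.start < g.end and g.start < m.end
            if ok:
                hit = gi
                break
        if hit is None:
            unmatched_pred.append(m)
        else:
            taken.add(hit)
            pairs.append((m, gold_sorted[hit]))
    unmatched_gold = [g for gi, g in enumerate(gold_sorted) if gi not in taken]
    return pairs, unmatched_pred, unmatched_gold


def eval_identification(pred: Sequence[AspectMention],
                        gold: Sequence[GoldAnnotation],
                        mode: str = "exact") -> PRF:
    """Score aspect identification: matched pairs are true positives,
    unmatched predictions false positives, unmatched gold false negatives."""
    pairs, unmatched_pred, unmatched_gold = match_identification(pred, gold, mode)
    return prf_from_counts(len(pairs), len(unmatched_pred), len(unmatched_gold),
                           warn_context="identification")


# ---------------------------------------------------------------------------
# Aspect polarity


@dataclass
class PolarityReport:
    per_class: dict[str, PRF]
    macro: PRF
    micro: PRF
    n_matched: int

    def overall(self, averaging: str = "macro") -> PRF:
        if averaging == "macro":
            return self.macro
        if averaging == "micro":
            return self.micro
        raise ContractViolation(f"unknown averaging {averaging!r}")


def eval_polarity(pred: Sequence[AspectSentiment],
                  gold: Sequence[GoldAnnotation],
                  mode: str = "exact") -> PolarityReport:
    """Compare predicted and gold labels on identification-matched aspects.

    Each class is scored one-vs-rest; macro averages the three classes with
    equal weight, micro pools the counts. Zero matched aspects yields all-0
    metrics with a warning.
    """
    mentions = [p.aspect for p in pred]
    by_mention = {id(p.aspect): p for p in pred}
    pairs, _, _ = match_identification(mentions, gold, mode)
    labelled = [(by_mention[id(m)].label, g.label) for m, g in pairs]
    return polarity_report_from_pairs(labelled)


def polarity_report_from_pairs(
        labelled: Sequence[tuple[str, str]]) -> PolarityReport:
    """Build the per-class / macro / micro report from (predicted label,
    gold label) pairs."""
    for predicted, actual in labelled:
        if actual not in LABELS:
            raise ContractViolation(f"gold label {actual!r} not in {LABELS}")
        if predicted not in LABELS:
            raise ContractViolation(f"predicted label {predicted!r} not in {LABELS}")
    if not labelled:
        warnings.warn("polarity evaluation over zero matched aspects; all metrics 0")
        zero = prf_from_counts(0, 0, 0)
        return PolarityReport(per_class={c: zero for c in LABELS},
                              macro=zero, micro=zero, n_matched=0)
    per_class: dict[str, PRF] = {}
    pooled_tp = pooled_fp = pooled_fn = 0
    for cls in LABELS:
        tp = sum(1 for p, a in labelled if p == cls and a == cls)
        fp = sum(1 for p, a in labelled if p == cls and a != cls)
        fn = sum(1 for p, a in labelled if p != cls and a == cls)
        per_class[cls] = prf_from_counts(tp, fp, fn)
        pooled_tp, pooled_fp, pooled_fn = (pooled_tp + tp, pooled_fp + fp,
                                           pooled_fn + fn)
    macro_p = sum(v.precision for v in per_class.values()) / len(LABELS)
    macro_r = sum(v.recall for v in per_class.values()) / len(LABELS)
    macro_f = sum(v.f_measure for v in per_class.values()) / len(LABELS)
    macro = PRF(tp=pooled_tp, fp=pooled_fp, fn=pooled_fn,
                precision=macro_p, recall=macro_r, f_measure=macro_f)
    micro = prf_from_counts(pooled_tp, pooled_fp, pooled_fn)
    return PolarityReport(per_class=per_class, macro=macro, micro=micro,
                          n_matched=len(labelled))


# ---------------------------------------------------------------------------
# Pipeline sweep


@dataclass
class SweepCell:
    method: str
    n: int
    macro: PRF
    micro: PRF
    n_matched: int


@dataclass
class SweepReport:
    identification: PRF
    cells: dict[tuple[str, int], SweepCell] = field(default_factory=dict)

    def to_rows(self) -> list[dict]:
        rows = []
        for (method, n), cell in sorted(self.cells.items(),
                                        key=lambda kv: (kv[0][1], kv[0][0])):
            rows.append({
                "method": method, "n": n,
                "precision_macro": round(cell.macro.precision, 2),
                "recall_macro": round(cell.macro.recall, 2),
                "f_measure_macro": round(cell.macro.f_measure, 2),
                "precision_micro": round(cell.micro.precision, 2),
                "recall_micro": round(cell.micro.recall, 2),
                "f_measure_micro": round(cell.micro.f_measure, 2),
                "n_matched": cell.n_matched,
            })
        return rows

    def to_tsv(self) -> str:
        rows = self.to_rows()
        header = ["method", "n", "precision_macro", "recall_macro",
                  "f_measure_macro", "precision_micro", "recall_micro",
                  "f_measure_micro", "n_matched"]
        lines = ["\t".join(header)]
        for row in rows:
            lines.append("\t".join(str(row[h]) for h in header))
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps({
            "identification": {
                "precision": round(self.identification.precision, 2),
                "recall": round(self.identification.recall, 2),
                "f_measure": round(self.identification.f_measure, 2),
                "tp": self.identification.tp,
                "fp": self.identification.fp,
                "fn": self.identification.fn,
            },
            "cells": self.to_rows(),
        }, indent=2, sort_keys=True)


DEFAULT_METHODS = (WindowMethod.BEFORE, WindowMethod.AFTER, WindowMethod.AROUND)
DEFAULT_N_VALUES = (2, 3, 4, 5, 6)


def analyze_corpus(tweets: Iterable[RawTweet],
                   dicts: Sequence[AbbreviationDictionary] = (),
                   corrector: SpellCorrector | None = None,
                   tagger: TaggerBackend | None = None) -> list[Tweet]:
    return [preprocess_tweet(t, dicts, corrector, tagger) for t in tweets]


def annotate_corpus(analyzed: Sequence[Tweet], gazetteer: Gazetteer,
                    lexicon: Lexicon, method: WindowMethod | str, n: int,
                    selector: SenseSelector | None = None,
                    ) -> list[AspectSentiment]:
    """Detect aspects and score each one with the given window method/size."""
    results: list[AspectSentiment] = []
    for tweet in analyzed:
        for mention in detect_aspects(tweet, gazetteer):
            window = extract_window(tweet, mention, method, n)
            results.append(score_aspect(window, tweet, lexicon, selector))
    return results


def run_sweep(tweets: Sequence[RawTweet],
              gold: Sequence[GoldAnnotation],
              lexicon: Lexicon,
              gazetteer: Gazetteer,
              methods: Sequence[WindowMethod | str] = DEFAULT_METHODS,
              n_values: Sequence[int] = DEFAULT_N_VALUES,
              selector: SenseSelector | None = None,
              dicts: Sequence[AbbreviationDictionary] = (),
              corrector: SpellCorrector | None = None,
              tagger: TaggerBackend | None = None,
              mode: str = "exact") -> SweepReport:
    """Run the full pipeline over every (method, N) grid cell.

    Preprocessing and aspect detection are shared across cells (they do not
    depend on the window); each cell re-scores the detected aspects with its
    own window and evaluates polarity on identification-matched aspects.
    Deterministic for fixed inputs.
    """
    if not methods or not n_values:
        raise ContractViolation("sweep grid must contain at least one cell")
    analyzed = analyze_corpus(tweets, dicts, corrector, tagger)
    identification: PRF | None = None
    report_cells: dict[tuple[str, int], SweepCell] = {}
    detected = [(tweet, detect_aspects(tweet, gazetteer)) for tweet in analyzed]
    all_mentions = [m for _, ms in detected for m in ms]
    identification = eval_identification(all_mentions, gold, mode)
    for method in methods:
        method = WindowMethod(method)
        for n in n_values:
            scored: list[AspectSentiment] = []
            for tweet, mentions in detected:
                for mention in mentions:
                    window = extract_window(tweet, mention, method, n)
                    scored.append(score_aspect(window, tweet, lexicon, selector))
            polarity = eval_polarity(scored, gold, mode)
            report_cells[(method.value, n)] = SweepCell(
                method=method.value, n=n, macro=polarity.macro,
                micro=polarity.micro, n_matched=polarity.n_matched,
            )
    return SweepReport(identification=identification, cells=report_cells)


def load_gold_jsonl(path: str) -> list[GoldAnnotation]:
    gold: list[GoldAnnotation] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                gold.append(GoldAnnotation(tweet_id=str(obj["tweet_id"]),
                                           start=int(obj["start"]),
                                           end=int(obj["end"]),
                                           label=str(obj["label"])))
            except (KeyError, ValueError, ContractViolation) as exc:
                raise FormatError(f"bad gold record: {exc}", line=lineno, source=path)
    return gold
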