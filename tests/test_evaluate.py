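"""Precision/recall/F arithmetic, identification and polarity scoring, sweep."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aspectsent import (ContractViolation, GeneratorConfig, GoldAnnotation,
                        eval_identification, eval_polarity, f_measure,
                        generate, prf_from_counts, run_sweep)
from aspectsent.evaluate import polarity_report_from_pairs
from aspectsent.gazetteer import AspectMention
from aspectsent.scoring import AspectSentiment, SentimentTriple
from aspectsent.windows import ContextWindow, WindowMethod


def mention(tid, start, end):
    return AspectMention(tweet_id=tid, start=start, end=end,
                         concept_id="C:1", surface="x")


def sentiment(tid, start, end, label):
    m = mention(tid, start, end)
    w = ContextWindow(aspect=m, method=WindowMethod.AROUND, n=3, token_indices=())
    return AspectSentiment(aspect=m, window=w, triple=SentimentTriple(),
                           label=label)


class TestPRFArithmetic:
    def test_counts_to_percentages(self):
        prf = prf_from_counts(tp=3, fp=1, fn=2)
        assert prf.precision == pytest.approx(75.00)
        assert prf.recall == pytest.approx(60.00)
        assert prf.f_measure == pytest.approx(66.67, abs=0.005)

    def test_harmonic_mean_of_printed_precision_recall(self):
        # 85.71 / 80.00 are themselves rounded, so the recomputed harmonic
        # mean may differ from the printed 82.75 in the last decimal
        cents = round(f_measure(85.71, 80.00) * 100)
        assert abs(cents - 8275) <= 1  # within 0.01 of 82.75

    def test_undefined_metrics_are_zero(self):
        prf = prf_from_counts(0, 0, 0)
        assert (prf.precision, prf.recall, prf.f_measure) == (0.0, 0.0, 0.0)

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    @settings(max_examples=200, deadline=None)
    def test_f_between_min_and_max_of_p_r(self, tp, fp, fn):
        prf = prf_from_counts(tp, fp, fn)
        lo, hi = sorted([prf.precision, prf.recall])
        assert lo - 1e-9 <= prf.f_measure <= hi + 1e-9
        if prf.precision == prf.recall:
            assert prf.f_measure == pytest.approx(prf.precision)


class TestIdentification:
    def test_identity_gives_perfect_scores(self):
        pred = [mention("t1", 0, 2), mention("t2", 1, 3)]
        gold = [GoldAnnotation("t1", 0, 2, "neutral"),
                GoldAnnotation("t2", 1, 3, "positive")]
        prf = eval_identification(pred, gold)
        assert (prf.precision, prf.recall, prf.f_measure) == (100.0, 100.0, 100.0)

    def test_exact_mode_counts(self):
        pred = [mention("t1", 0, 2), mention("t1", 4, 5), mention("t2", 0, 1)]
        gold = [GoldAnnotation("t1", 0, 2, "neutral"),
                GoldAnnotation("t2", 3, 4, "positive")]
        prf = eval_identification(pred, gold, mode="exact")
        assert (prf.tp, prf.fp, prf.fn) == (1, 2, 1)

    def test_overlap_mode_matches_partial_spans(self):
        pred = [mention("t1", 1, 3)]
        gold = [GoldAnnotation("t1", 2, 4, "neutral")]
        assert eval_identification(pred, gold, mode="exact").tp == 0
        assert eval_identification(pred, gold, mode="overlap").tp == 1

    def test_overlap_matching_is_one_to_one_greedy(self):
        pred = [mention("t1", 0, 5)]
        gold = [GoldAnnotation("t1", 0, 2, "neutral"),
                GoldAnnotation("t1", 3, 5, "neutral")]
        prf = eval_identification(pred, gold, mode="overlap")
        assert (prf.tp, prf.fp, prf.fn) == (1, 0, 1)

    def test_swapping_pred_and_gold_swaps_p_and_r(self):
        pred = [mention("t1", 0, 2), mention("t1", 4, 5), mention("t2", 0, 1)]
        gold = [GoldAnnotation("t1", 0, 2, "neutral"),
                GoldAnnotation("t2", 3, 4, "positive")]
        ab = eval_identification(pred, gold)
        gold_as_pred = [mention(g.tweet_id, g.start, g.end) for g in gold]
        pred_as_gold = [GoldAnnotation(m.tweet_id, m.start, m.end, "neutral")
                        for m in pred]
        ba = eval_identification(gold_as_pred, pred_as_gold)
        assert ab.precision == pytest.approx(ba.recall)
        assert ab.recall == pytest.approx(ba.precision)

    def test_duplicate_gold_span_rejected(self):
        gold = [GoldAnnotation("t1", 0, 2, "neutral"),
                GoldAnnotation("t1", 0, 2, "positive")]
        with pytest.raises(ContractViolation, match="duplicate"):
            eval_identification([], gold)


class TestPolarity:
    def test_all_correct_macro_is_perfect(self):
        pred = [sentiment("t1", 0, 1, "positive"),
                sentiment("t2", 0, 1, "negative"),
                sentiment("t3", 0, 1, "neutral")]
        gold = [GoldAnnotation("t1", 0, 1, "positive"),
                GoldAnnotation("t2", 0, 1, "negative"),
                GoldAnnotation("t3", 0, 1, "neutral")]
        report = eval_polarity(pred, gold)
        assert report.macro.precision == 100.0
        assert report.macro.recall == 100.0
        assert report.macro.f_measure == 100.0

    def test_confusion_against_brute_force_counts(self):
        # gold (pos, pos, neg, neu) vs pred (pos, neg, neg, neu)
        labelled = [("positive", "positive"), ("negative", "positive"),
                    ("negative", "negative"), ("neutral", "neutral")]
        report = polarity_report_from_pairs(labelled)
        # positive: tp=1 fp=0 fn=1 -> P=100 R=50 F=66.67
        pos = report.per_class["positive"]
        assert (pos.tp, pos.fp, pos.fn) == (1, 0, 1)
        assert pos.f_measure == pytest.approx(200 / 3, abs=0.01)
        # negative: tp=1 fp=1 fn=0 -> P=50 R=100 F=66.67
        neg = report.per_class["negative"]
        assert (neg.tp, neg.fp, neg.fn) == (1, 1, 0)
        # neutral: perfect
        assert report.per_class["neutral"].f_measure == 100.0
        assert report.macro.precision == pytest.approx((100 + 50 + 100) / 3)
        assert report.macro.recall == pytest.approx((50 + 100 + 100) / 3)
        assert report.micro.precision == pytest.approx(75.0)

    def test_micro_recall_equals_accuracy(self):
        labelled = [("positive", "positive"), ("negative", "positive"),
                    ("neutral", "negative"), ("neutral", "neutral"),
                    ("positive", "neutral")]
        report = polarity_report_from_pairs(labelled)
        accuracy = 100.0 * 2 / 5
        assert report.micro.recall == pytest.approx(accuracy)
        assert report.micro.precision == pytest.approx(accuracy)

    def test_zero_matched_aspects_warns_and_zeroes(self):
        pred = [sentiment("t1", 0, 1, "positive")]
        gold = [GoldAnnotation("t1", 3, 4, "negative")]
        with pytest.warns(UserWarning, match="zero matched"):
            report = eval_polarity(pred, gold)
        assert report.n_matched == 0
        assert report.macro.f_measure == 0.0

    def test_invalid_gold_label_rejected(self):
        with pytest.raises(ContractViolation):
            GoldAnnotation("t1", 0, 1, "mixed")


class TestSweep:
    def test_grid_has_one_cell_per_method_n(self, small_corpus):
        c = small_corpus
        report = run_sweep(c.tweets, c.gold, c.lexicon(), c.gazetteer(),
                           methods=["before"], n_values=[3],
                           dicts=c.abbrev_dicts())
        assert set(report.cells) == {("before", 3)}

    def test_full_grid_deterministic_and_serializable(self, small_corpus):
        c = small_corpus
        kwargs = dict(tweets=c.tweets, gold=c.gold, lexicon=c.lexicon(),
                      gazetteer=c.gazetteer(), dicts=c.abbrev_dicts())
        r1 = run_sweep(**kwargs)
        r2 = run_sweep(**kwargs)
        assert len(r1.cells) == 15
        assert r1.to_tsv() == r2.to_tsv()
        assert r1.to_json() == r2.to_json()
        header = r1.to_tsv().splitlines()[0].split("\t")
        assert header[:2] == ["method", "n"]

    def test_noiseless_corpus_fully_recovered_with_around_3(self, small_corpus):
        c = small_corpus
        report = run_sweep(c.tweets, c.gold, c.lexicon(), c.gazetteer(),
                           methods=["around"], n_values=[3],
                           dicts=c.abbrev_dicts())
        cell = report.cells[("around", 3)]
        assert report.identification.f_measure == 100.0
        assert cell.macro.precision == 100.0
        assert cell.macro.recall == 100.0
        assert cell.macro.f_measure == 100.0

    def test_sweep_cell_matches_brute_force_pipeline(self):
        """Whole-pipeline oracle: flat-loop reimplementation on 20 tweets."""
        from aspectsent import (detect_aspects, preprocess_tweet,
                                select_sense, classify_polarity)
        corpus = generate(GeneratorConfig(n_tweets=20, seed=23))
        lexicon, gaz = corpus.lexicon(), corpus.gazetteer()
        dicts = corpus.abbrev_dicts()
        labelled = []
        predicted = {}
        for raw in corpus.tweets:
            tweet = preprocess_tweet(raw, dicts)
            for m in detect_aspects(tweet, gaz):
                words = [i for i, t in enumerate(tweet.tokens) if t.is_word]
                before = [i for i in words if i < m.start][-3:]
                after = [i for i in words if i >= m.end][:3]
                pos = neg = neu = 0.0
                for i in before + after:
                    tok = tweet.tokens[i]
                    entry = select_sense(tok.lemma, tok.pos, lexicon)
                    if entry is not None:
                        pos += entry.triple.pos
                        neg += entry.triple.neg
                        neu += entry.triple.neu
                label = classify_polarity(SentimentTriple(pos, neg, neu))
                predicted[(m.tweet_id, m.start, m.end)] = label
        for g in corpus.gold:
            key = (g.tweet_id, g.start, g.end)
            if key in predicted:
                labelled.append((predicted[key], g.label))
        oracle = polarity_report_from_pairs(labelled)
        report = run_sweep(corpus.tweets, corpus.gold, lexicon, gaz,
                           methods=["around"], n_values=[3], dicts=dicts)
        cell = report.cells[("around", 3)]
        assert cell.macro.f_measure == pytest.approx(oracle.macro.f_measure)
        assert cell.micro.f_measure == pytest.approx(oracle.micro.f_measure)

    def test_empty_grid_rejected(self, small_corpus):
        c = small_corpus
        with pytest.raises(ContractViolation):
            run_sweep(c.tweets, c.gold, c.lexicon(), c.gazetteer(),
                      methods=[], n_values=[3])
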