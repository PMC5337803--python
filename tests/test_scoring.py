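"""Lexicon parsing, sense selection, score aggregation, polarity rule."""

import io
import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aspectsent import (ContractViolation, FormatError, SentimentTriple,
                        analyze, classify_polarity, parse_lexicon_lines,
                        penn_to_swn, score_aspect, select_sense)
from aspectsent.gazetteer import AspectMention
from aspectsent.windows import extract_window


def parse(text):
    return parse_lexicon_lines(io.StringIO(text))


class TestLoadLexicon:
    def test_worked_adjective_entry_triple(self, minimal_lexicon):
        entry = minimal_lexicon.entries[("a", "00230335")]
        assert entry.triple.as_tuple() == (0.875, 0.0, 0.125)
        assert ("better", 1) in entry.terms

    def test_neutral_derived_as_complement(self):
        lex = parse("a\t00000001\t0.25\t0.5\tword#1\tgloss\n")
        assert lex.entries[("a", "00000001")].triple.as_tuple() == (0.25, 0.5, 0.25)

    def test_comment_lines_skipped(self):
        lex = parse("# SentiWordNet v3.0\n# header\nn\t00000001\t0\t0\tword#1\tg\n")
        assert len(lex) == 1

    def test_scores_summing_above_one_rejected(self):
        with pytest.raises(FormatError, match="exceeds 1"):
            parse("a\t00000001\t0.7\t0.6\tword#1\tgloss\n")

    @pytest.mark.parametrize("line,message", [
        ("a\t0001\t0.5", "columns"),
        ("x\t00000001\t0.5\t0\tword#1\tg", "POS category"),
        ("a\t00000001\tabc\t0\tword#1\tg", "non-numeric"),
        ("a\t00000001\t0.5\t0\tword\tg", "rank"),
    ])
    def test_malformed_lines_reported_with_line_number(self, line, message):
        with pytest.raises(FormatError, match=message) as err:
            parse("# comment\n" + line + "\n")
        assert "line 2" in str(err.value)

    def test_single_sense_sum_to_one_preserved(self, minimal_lexicon):
        for entry in minimal_lexicon.entries.values():
            total = sum(entry.triple.as_tuple())
            assert abs(total - 1.0) < 1e-9


class TestSelectSense:
    @pytest.mark.parametrize("penn,swn", [
        ("NN", "n"), ("NNS", "n"), ("NNP", "n"),
        ("VB", "v"), ("VBZ", "v"), ("VBG", "v"),
        ("JJ", "a"), ("JJR", "a"), ("JJS", "a"),
        ("RB", "r"), ("RBR", "r"),
        ("DT", None), ("IN", None), ("MD", None), ("WRB", None), (",", None),
    ])
    def test_penn_to_lexicon_category(self, penn, swn):
        assert penn_to_swn(penn) == swn

    def test_adjective_resolved_for_comparative_tag(self, minimal_lexicon):
        entry = select_sense("better", "JJR", minimal_lexicon)
        assert entry is not None and entry.pos_category == "a"

    def test_unmappable_tag_yields_none(self, minimal_lexicon):
        assert select_sense("the", "DT", minimal_lexicon) is None

    def test_fallback_prefers_smallest_sense_rank(self, minimal_lexicon):
        # fixture has better#1 (0.875, 0, 0.125) and better#2 (0.25, 0.125)
        entry = select_sense("better", "JJR", minimal_lexicon)
        assert entry.synset_id == "00230335"
        ranked = minimal_lexicon.senses("better", "a")
        assert len(ranked) == 2  # the rank-2 sense exists and was not chosen

    def test_absent_lemma_is_not_an_error(self, minimal_lexicon):
        assert select_sense("zzz", "NN", minimal_lexicon) is None


def windowed(text, start, end, method="around", n=3):
    tweet = analyze(text, tweet_id="x")
    aspect = AspectMention(tweet_id="x", start=start, end=end, concept_id="C:1",
                           surface=" ".join(t.surface for t in tweet.tokens[start:end]))
    return tweet, extract_window(tweet, aspect, method, n)


class TestScoreAspect:
    def test_empty_window_is_neutral_zero(self, minimal_lexicon):
        tweet, window = windowed("insulin", 0, 1)
        result = score_aspect(window, tweet, minimal_lexicon)
        assert result.triple.as_tuple() == (0.0, 0.0, 0.0)
        assert result.label == "neutral"

    def test_single_word_window_carries_entry_triple(self, minimal_lexicon):
        tweet, window = windowed("better insulin", 1, 2, method="before", n=1)
        result = score_aspect(window, tweet, minimal_lexicon)
        assert result.triple.as_tuple() == (0.875, 0.0, 0.125)
        assert result.label == "positive"

    def test_triple_is_elementwise_sum_of_contributions(self, minimal_lexicon):
        # "sugary" contributes (0.125, 0.5, 0.375), "better" (0.875, 0, 0.125)
        tweet, window = windowed("sugary better insulin", 2, 3, method="before", n=2)
        result = score_aspect(window, tweet, minimal_lexicon)
        assert result.triple.as_tuple() == pytest.approx((1.0, 0.5, 0.5))
        assert result.label == "positive"
        total = SentimentTriple()
        for _, _, contributed in result.per_word:
            total = total + contributed
        assert total.as_tuple() == pytest.approx(result.triple.as_tuple())

    def test_out_of_lexicon_words_contribute_zero(self, minimal_lexicon):
        tweet, window = windowed("zzzq better insulin", 2, 3, method="before", n=2)
        result = score_aspect(window, tweet, minimal_lexicon)
        assert result.triple.as_tuple() == (0.875, 0.0, 0.125)
        none_contribs = [c for _, sid, c in result.per_word if sid is None]
        assert none_contribs and none_contribs[0].as_tuple() == (0, 0, 0)

    @given(st.permutations(["better", "sugary", "terrible", "zzzq", "safely"]))
    @settings(max_examples=40, deadline=None)
    def test_permutation_invariance_vs_brute_force(self, minimal_lexicon, words):
        from aspectsent import select_sense as sel
        text = " ".join(words) + " insulin"
        tweet, window = windowed(text, len(words), len(words) + 1,
                                 method="before", n=len(words))
        result = score_aspect(window, tweet, minimal_lexicon)
        # brute-force accumulator over the same window words
        pos = neg = neu = 0.0
        for i in window.token_indices:
            tok = tweet.tokens[i]
            entry = sel(tok.lemma, tok.pos, minimal_lexicon)
            if entry is not None:
                pos += entry.triple.pos
                neg += entry.triple.neg
                neu += entry.triple.neu
        assert result.triple.as_tuple() == pytest.approx((pos, neg, neu))


class TestClassifyPolarity:
    @pytest.mark.parametrize("triple,label", [
        ((0.875, 0, 0.125), "positive"),
        ((0, 0, 0), "neutral"),
        ((0.2, 0.5, 0.3), "negative"),
        ((0.1, 0.1, 0.8), "neutral"),
        ((0.5, 0.5, 0.1), "neutral"),  # tie for the maximum
        ((0.4, 0.1, 0.4), "neutral"),
    ])
    def test_strict_inequality_rule(self, triple, label):
        assert classify_polarity(SentimentTriple(*triple)) == label

    def test_negative_component_rejected(self):
        with pytest.raises(ContractViolation):
            SentimentTriple(-0.1, 0.5, 0.6)

    def test_total_and_single_valued_on_dense_grid(self):
        grid = [x / 20 for x in range(21)]
        for p, n, u in itertools.product(grid, repeat=3):
            label = classify_polarity(SentimentTriple(p, n, u))
            assert label in {"positive", "negative", "neutral"}
            best = max(p, n, u)
            if [p, n, u].count(best) > 1:
                assert label == "neutral"
            elif best == p:
                assert label == "positive"
            elif best == n:
                assert label == "negative"
            else:
                assert label == "neutral"

    @given(st.floats(min_value=0.01, max_value=5, allow_nan=False))
    @settings(max_examples=60, deadline=None)
    def test_pure_positive_addition_never_flips_positive_to_negative(self, p):
        base = SentimentTriple(0.6, 0.4, 0.2)
        assert classify_polarity(base) == "positive"
        bumped = base + SentimentTriple(p, 0, 0)
        assert classify_polarity(bumped) != "negative"
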