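"""Self-contained synthetic corpora for exercising every pipeline stage.

The generator emulates the structure the method assumes: each tweet carries
a domain-concept mention (the aspect) whose gold polarity is determined by
polar words planted immediately around it, plus optional Twitter noise
(@-mentions, URLs, hashtags, abbreviations) that the normalization step must
strip or expand, and neutral out-of-lexicon filler elsewhere in the tweet.

Label planting is margin-based: the planted context words are sampled from
pools whose score triples guarantee the aggregate's winning component
exceeds the runner-up by at least 0.1, so the strict-inequality polarity
rule recovers the gold label exactly when nothing is lost. The *noise*
probability drops a planted word's lexicon entry (the occurrence is swapped
for an out-of-lexicon word while the gold label is kept), which is the
knob that degrades recovery; *decoys* insert near-miss phrases that share a
word with a multiword gazetteer term but must not be detected.

Everything is driven by one seeded RNG stream; regeneration from the
manifest is byte-identical.
"""

from __future__ import annotations

import io
import json
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .errors import GenerationError
from .evaluate import GoldAnnotation
from .gazetteer import Gazetteer, build_gazetteer
from .preprocess import AbbreviationDictionary, RawTweet
from .scoring import Lexicon, parse_lexicon_lines
from .tagging import RuleTagger

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"
_MARGIN = 0.1

_LABELS = ("positive", "negative", "neutral")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic corpus.

    Defaults mirror the scale of a manually annotated diabetes-tweet
    corpus: 900 tweets, a few dozen domain concepts (a third of them
    multiword), one aspect per tweet with 1-3 polar context words per side,
    and an even positive/negative/neutral label mix.
    """

    n_tweets: int = 900
    concepts: int = 30
    multiword_share: float = 0.3
    polar_vocab_size: int = 60
    context_width: tuple[int, int] = (1, 3)  # words per side, inclusive range
    label_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    noise: float = 0.0       # P(planted word has no lexicon entry)
    decoys: float = 0.0      # P(tweet carries a near-miss non-gazetteer phrase)
    social_noise: float = 0.25   # P(mention/URL/hashtag injected)
    abbrev_rate: float = 0.15    # P(a context word is written as an abbreviation)
    multisense_rate: float = 0.25  # P(lexicon word gets a second, lower-rank sense)
    seed: int = 0

    def validate(self) -> None:
        if self.n_tweets < 1:
            raise GenerationError("n_tweets must be >= 1")
        if abs(sum(self.label_mix) - 1.0) > 1e-9:
            raise GenerationError("label_mix proportions must sum to 1")
        for name in ("multiword_share", "noise", "decoys", "social_noise",
                     "abbrev_rate", "multisense_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise GenerationError(f"{name} must be a probability, got {value}")
        lo, hi = self.context_width
        if not (0 <= lo <= hi):
            raise GenerationError(f"invalid context_width range {self.context_width}")
        if hi == 0:
            raise GenerationError(
                "context_width (0, 0) leaves every aspect without context: no "
                "label (neutral included) can be planted with the required margin"
            )
        if self.concepts < 1 or self.polar_vocab_size < 3:
            raise GenerationError("need >= 1 concept and >= 3 polar vocabulary words")


@dataclass
class SyntheticCorpus:
    tweets: list[RawTweet]
    gold: list[GoldAnnotation]
    lexicon_text: str
    gazetteer_text: str
    abbrev_domain_text: str
    abbrev_sms_text: str
    manifest: dict

    def lexicon(self) -> Lexicon:
        return parse_lexicon_lines(io.StringIO(self.lexicon_text),
                                   source="<synthetic lexicon>")

    def gazetteer(self) -> Gazetteer:
        pairs = []
        for line in self.gazetteer_text.splitlines():
            if not line or line.startswith("#"):
                continue
            cid, term = line.split("\t")
            pairs.append((cid, term))
        return build_gazetteer(pairs)

    def abbrev_dicts(self) -> list[AbbreviationDictionary]:
        return [
            _abbrev_from_text(self.abbrev_domain_text, "domain"),
            _abbrev_from_text(self.abbrev_sms_text, "sms"),
        ]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write tweets.jsonl, gold.jsonl, lexicon.txt, gazetteer.tsv, the
        abbreviation TSVs and manifest.json; returns the path map."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "tweets": out / "tweets.jsonl",
            "gold": out / "gold.jsonl",
            "lexicon": out / "lexicon.txt",
            "gazetteer": out / "gazetteer.tsv",
            "abbrev_domain": out / "abbrev_domain.tsv",
            "abbrev_sms": out / "abbrev_sms.tsv",
            "manifest": out / "manifest.json",
        }
        with open(paths["tweets"], "w", encoding="utf-8") as handle:
            for t in self.tweets:
                handle.write(json.dumps({"id": t.id, "text": t.text},
                                        sort_keys=True) + "\n")
        with open(paths["gold"], "w", encoding="utf-8") as handle:
            for g in self.gold:
                handle.write(json.dumps(
                    {"tweet_id": g.tweet_id, "start": g.start,
                     "end": g.end, "label": g.label}, sort_keys=True) + "\n")
        paths["lexicon"].write_text(self.lexicon_text, encoding="utf-8")
        paths["gazetteer"].write_text(self.gazetteer_text, encoding="utf-8")
        paths["abbrev_domain"].write_text(self.abbrev_domain_text, encoding="utf-8")
        paths["abbrev_sms"].write_text(self.abbrev_sms_text, encoding="utf-8")
        paths["manifest"].write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True) + "\n",
            encoding="utf-8")
        return paths


def _abbrev_from_text(text: str, source: str) -> AbbreviationDictionary:
    mapping = {}
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        key, expansion = line.split("\t")
        mapping[key] = expansion
    return AbbreviationDictionary(mapping=mapping, source=source)


def _make_word(rng: random.Random, used: set[str], tagger: RuleTagger,
               syllables: tuple[int, int] = (2, 3)) -> str:
    """A pronounceable pseudo-word that the tagger treats as a plain noun
    with an identity lemma, so gazetteer and lexicon lookups are stable."""
    while True:
        k = rng.randint(*syllables)
        word = "".join(rng.choice(_CONSONANTS) + rng.choice(_VOWELS)
                       for _ in range(k))
        if word in used:
            continue
        tag, lemma = tagger.tag([word])[0]
        if tag != "NN" or lemma != word:
            continue
        used.add(word)
        return word


def generate(config: GeneratorConfig) -> SyntheticCorpus:
    """Generate a corpus, gold annotations and companion resource files.

    Deterministic under ``config.seed``: the manifest records the full
    config, and :func:`regenerate` reproduces the corpus byte for byte.
    """
    config.validate()
    rng = random.Random(config.seed)
    tagger = RuleTagger()
    used: set[str] = set()

    # --- vocabulary pools (disjoint by construction) ---
    n_multi = int(round(config.concepts * config.multiword_share))
    concept_terms: list[tuple[str, tuple[str, ...]]] = []
    for ci in range(config.concepts):
        cid = f"SYN:{ci + 1:07d}"
        if ci < n_multi:
            term = (_make_word(rng, used, tagger), _make_word(rng, used, tagger))
        else:
            term = (_make_word(rng, used, tagger),)
        concept_terms.append((cid, term))

    third = max(1, config.polar_vocab_size // 3)
    pools = {
        "positive": [_make_word(rng, used, tagger) for _ in range(third)],
        "negative": [_make_word(rng, used, tagger) for _ in range(third)],
        "neutral": [_make_word(rng, used, tagger) for _ in range(third)],
    }
    filler = [_make_word(rng, used, tagger) for _ in range(40)]

    # --- lexicon: rank-1 sense per polar word, planted triples ---
    triples: dict[str, tuple[float, float]] = {}  # word -> (pos, neg)
    lexicon_lines = ["# synthetic lexicon (SentiWordNet 3.0 format)",
                     "# POS\tID\tPosScore\tNegScore\tSynsetTerms\tGloss"]
    synset = 0
    for word in pools["positive"]:
        triples[word] = (round(rng.uniform(0.6, 0.9), 3), 0.0)
    for word in pools["negative"]:
        triples[word] = (0.0, round(rng.uniform(0.6, 0.9), 3))
    for word in pools["neutral"]:
        triples[word] = (round(rng.uniform(0.0, 0.05), 3),
                         round(rng.uniform(0.0, 0.05), 3))
    for label in _LABELS:
        for word in pools[label]:
            synset += 1
            pos_s, neg_s = triples[word]
            lexicon_lines.append(
                f"n\t{synset:08d}\t{pos_s}\t{neg_s}\t{word}#1\t"
                f"synthetic {label} sense of {word}")
            if rng.random() < config.multisense_rate:
                synset += 1
                lexicon_lines.append(
                    f"n\t{synset:08d}\t0.1\t0.1\t{word}#2\t"
                    f"synthetic secondary sense of {word}")
    lexicon_text = "\n".join(lexicon_lines) + "\n"

    gazetteer_lines = ["# concept_id\tterm"]
    gazetteer_index = set()
    for cid, term in concept_terms:
        gazetteer_lines.append(f"{cid}\t{' '.join(term)}")
        gazetteer_index.add(term)
    gazetteer_text = "\n".join(gazetteer_lines) + "\n"

    # --- abbreviation dictionaries ---
    abbrev_domain: dict[str, str] = {}
    abbreviable = sorted(triples)[:10]
    for word in abbreviable:
        key = word[:3] + "x"
        if key in used or key in abbrev_domain:
            continue
        abbrev_domain[key] = word
    abbrev_sms = {"u": "you", "gr8": "great", "pls": "please"}
    abbrev_domain_text = "# abbreviation\texpansion\n" + "".join(
        f"{k}\t{v}\n" for k, v in sorted(abbrev_domain.items()))
    abbrev_sms_text = "# abbreviation\texpansion\n" + "".join(
        f"{k}\t{v}\n" for k, v in sorted(abbrev_sms.items()))
    expansion_to_key = {v: k for k, v in abbrev_domain.items()}

    multiword_terms = [term for _, term in concept_terms if len(term) > 1]

    # --- tweets ---
    lo, hi = config.context_width
    tweets: list[RawTweet] = []
    gold: list[GoldAnnotation] = []
    for ti in range(config.n_tweets):
        tid = f"t{ti + 1:05d}"
        label = rng.choices(_LABELS, weights=config.label_mix)[0]
        while True:
            w_l, w_r = rng.randint(lo, hi), rng.randint(lo, hi)
            if w_l + w_r >= 1:
                break
        pool = pools[label]
        left = [rng.choice(pool) for _ in range(w_l)]
        right = [rng.choice(pool) for _ in range(w_r)]
        _assert_margin(left + right, triples, label)

        # noise: the occurrence loses its lexicon entry (swap for an
        # out-of-lexicon word); gold label is kept, as in real annotation.
        def maybe_drop(word: str) -> str:
            if rng.random() < config.noise:
                return _make_word(rng, used, tagger)
            return word
        left = [maybe_drop(w) for w in left]
        right = [maybe_drop(w) for w in right]

        cid, term = concept_terms[rng.randrange(len(concept_terms))]
        prefix = [rng.choice(filler) for _ in range(rng.randint(0, 2))]
        suffix = [rng.choice(filler) for _ in range(rng.randint(0, 2))]
        if multiword_terms and rng.random() < config.decoys:
            decoy = (rng.choice(multiword_terms)[0], rng.choice(filler))
            assert decoy not in gazetteer_index and (decoy[0],) not in gazetteer_index
            prefix = list(decoy) + prefix

        words = prefix + left + list(term) + right + suffix
        start = len(prefix) + len(left)
        gold.append(GoldAnnotation(tweet_id=tid, start=start,
                                   end=start + len(term), label=label))

        # raw-text rendering, with reversible Twitter noise
        raw_words = list(words)
        if rng.random() < config.abbrev_rate:
            candidates = [i for i, w in enumerate(raw_words)
                          if w in expansion_to_key]
            if candidates:
                i = rng.choice(candidates)
                raw_words[i] = expansion_to_key[raw_words[i]]
        if rng.random() < config.social_noise:
            kind = rng.choice(("mention", "url", "hashtag"))
            if kind == "hashtag":
                fillers = [i for i, w in enumerate(raw_words) if w in filler]
                if fillers:
                    i = rng.choice(fillers)
                    raw_words[i] = "#" + raw_words[i]
            elif kind == "mention":
                raw_words.insert(0, f"@user{rng.randint(1, 999)}")
            else:
                raw_words.append("http://t.co/" + "".join(
                    rng.choice("abcdefghij0123456789") for _ in range(6)))
        text = " ".join(raw_words) + "."
        tweets.append(RawTweet(id=tid, text=text))

    manifest = {
        "generator": "aspectsent.synthdata.generate",
        "format_version": 1,
        "config": _config_dict(config),
        "n_tweets": len(tweets),
        "n_gold": len(gold),
        "n_concepts": len(concept_terms),
        "n_lexicon_entries": synset,
    }
    return SyntheticCorpus(
        tweets=tweets, gold=gold, lexicon_text=lexicon_text,
        gazetteer_text=gazetteer_text, abbrev_domain_text=abbrev_domain_text,
        abbrev_sms_text=abbrev_sms_text, manifest=manifest,
    )


def _config_dict(config: GeneratorConfig) -> dict:
    d = asdict(config)
    d["context_width"] = list(config.context_width)
    d["label_mix"] = list(config.label_mix)
    return d


def config_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    if "context_width" in d:
        d["context_width"] = tuple(d["context_width"])
    if "label_mix" in d:
        d["label_mix"] = tuple(d["label_mix"])
    return GeneratorConfig(**d)


def regenerate(manifest: dict) -> SyntheticCorpus:
    """Rebuild a corpus from its manifest (byte-identical)."""
    return generate(config_from_dict(manifest["config"]))


def _assert_margin(context: list[str], triples: dict[str, tuple[float, float]],
                   label: str) -> None:
    pos = sum(triples[w][0] for w in context)
    neg = sum(triples[w][1] for w in context)
    neu = sum(1.0 - triples[w][0] - triples[w][1] for w in context)
    by_label = {"positive": pos, "negative": neg, "neutral": neu}
    winner = by_label.pop(label)
    runner_up = max(by_label.values())
    if winner - runner_up < _MARGIN:
        raise GenerationError(
            f"cannot plant label {label!r} with margin >= {_MARGIN} from "
            f"context {context} (winner {winner:.3f}, runner-up {runner_up:.3f})"
        )


# ---------------------------------------------------------------------------
# Hand-written minimal fixture


_FIXTURE_LEXICON = """\
# synthetic miniature lexicon (SentiWordNet 3.0 format)
# POS\tID\tPosScore\tNegScore\tSynsetTerms\tGloss
a\t00230335\t0.875\t0\tbetter#1\t(comparative of good) superior to another in excellence or quality
a\t00230336\t0.25\t0.125\tbetter#2\tmore than half
a\t00001740\t0\t0.75\tdangerous#1\tinvolving or causing danger
a\t00001741\t0.5\t0\tsweet#1\tpleasing to the senses
n\t00001742\t0\t0.625\tdrop#1\ta sudden sharp decrease
a\t00001743\t0.125\t0.5\tsugary#1\tcontaining sugar
v\t00001744\t0.375\t0\thelp#1\timprove a condition
a\t00001745\t0\t0.875\tterrible#1\tcausing fear or dread
n\t00001746\t0\t0\toption#1\tone of a number of alternatives
r\t00001747\t0.625\t0\tsafely#1\twith safety
n\t00001748\t0\t0.5\talert#1\ta warning signal
"""

_FIXTURE_GAZETTEER = """\
# concept_id\tterm
DDO:0000001\tdiabetes
DDO:0000002\tblood sugar
DDO:0000003\tglucose tablet
DDO:0000004\tinsulin
DDO:0000005\thypoglycemia
DDO:0000006\tcarbohydrate
DDO:0000007\toral hypoglycemic
"""

_FIXTURE_ABBREV_DOMAIN = """\
# abbreviation\texpansion
Hypo\thypoglycemia
carbs\tcarbohydrates
"""

_FIXTURE_ABBREV_SMS = """\
# abbreviation\texpansion
u\tyou
gr8\tgreat
pls\tplease
"""

_FIXTURE_TWEETS: list[tuple[str, str]] = [
    ("t1", "When people with diabetes experience a dangerous drop in blood "
           "sugar, glucose tablets might be a better option than a sugary "
           "food or drink"),
    ("t2", "@user1 my carbs spiked http://t.co/xyz #diabetes"),
    ("t3", "Hypo alert after insulin tonight"),
    ("t4", "Insulin helps keep my blood sugar safely in range"),
    ("t5", "terrible drop in blood sugar today"),
    ("t6", "glucose tablets are a sweet option"),
    ("t7", "u should check your blood sugar"),
    ("t8", "my doctor prescribed an oral hypoglycemic"),
    ("t9", "oral antihyperglycemic worked for me"),
    ("t10", "diabetes is hard! but insulin helps."),
]

# Token spans refer to the analyzed (normalized, tokenized) tweets.
_FIXTURE_GOLD: list[tuple[str, int, int, str]] = [
    ("t1", 3, 4, "neutral"),      # diabetes
    ("t1", 9, 11, "negative"),    # blood sugar: dangerous drop
    ("t1", 12, 14, "positive"),   # glucose tablets: better option
    ("t2", 1, 2, "negative"),     # carbohydrates (expanded from "carbs") spiked
    ("t2", 3, 4, "neutral"),      # diabetes (hashtag body)
    ("t3", 0, 1, "negative"),     # hypoglycemia (expanded from "Hypo") alert
    ("t3", 3, 4, "neutral"),      # insulin
    ("t4", 0, 1, "positive"),     # insulin helps
    ("t4", 4, 6, "positive"),     # blood sugar safely in range
    ("t5", 3, 5, "negative"),     # blood sugar: terrible drop
    ("t6", 0, 2, "positive"),     # glucose tablets: sweet option
    ("t7", 4, 6, "neutral"),      # blood sugar
    ("t8", 4, 6, "neutral"),      # oral hypoglycemic
    ("t9", 0, 2, "neutral"),      # "oral antihyperglycemic": absent synonym,
                                  # a gold span the gazetteer cannot find
    ("t10", 0, 1, "negative"),    # diabetes is hard
    ("t10", 5, 6, "positive"),    # insulin helps
]


def fixture_minimal() -> SyntheticCorpus:
    """A hand-written 10-tweet fixture exercising every stage: the canonical
    worked tweet ("When people with diabetes ... glucose tablets might be a
    better option ..."), a mention/URL/hashtag tweet, abbreviation tweets
    ("Hypo", "carbs", "u"), a multiword gazetteer term, an absent-synonym
    miss, and a lexicon whose "better" adjective entry carries the triple
    (0.875, 0, 0.125)."""
    tweets = [RawTweet(id=tid, text=text) for tid, text in _FIXTURE_TWEETS]
    gold = [GoldAnnotation(tweet_id=tid, start=s, end=e, label=lab)
            for tid, s, e, lab in _FIXTURE_GOLD]
    manifest = {
        "generator": "aspectsent.synthdata.fixture_minimal",
        "format_version": 1,
        "config": None,
        "n_tweets": len(tweets),
        "n_gold": len(gold),
    }
    return SyntheticCorpus(
        tweets=tweets, gold=gold, lexicon_text=_FIXTURE_LEXICON,
        gazetteer_text=_FIXTURE_GAZETTEER,
        abbrev_domain_text=_FIXTURE_ABBREV_DOMAIN,
        abbrev_sms_text=_FIXTURE_ABBREV_SMS, manifest=manifest,
    )
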