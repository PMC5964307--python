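"""Lexicon-and-rule compound sentiment scoring.

Each sentence gets a single *compound* score in [-1, 1]: the valences of
lexicon words are summed after rule adjustments and the sum s is squashed
with s / sqrt(s^2 + alpha_norm).  The implemented rule subset is valence
summation, negation within the three preceding tokens (factor -0.74),
and booster/dampener increments of magnitude 0.293 toward/away from the
term's sign.  Capitalization and punctuation emphasis rules are omitted
deliberately: upstream cleaning lowercases all text before scoring, so
those cues no longer exist at this stage.

Per-concept sentiment is the mean compound over all disease-mentioning
sentences linked to the concept within a period; a sentence mentioning k
concepts contributes to all k means.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ConfigError, TableFormatError
from .terminology import AMBIGUOUS, DEFINITIVE, DEFINITIVE_ONLY, EXPAND_AMBIGUOUS, Mention

__all__ = [
    "ValenceLexicon",
    "SentenceSentiment",
    "ConceptSentiment",
    "load_valence_lexicon",
    "score_sentence",
    "score_mention_sentences",
    "concept_sentiment",
    "sentiment_band",
    "DEFAULT_ALPHA_NORM",
]

DEFAULT_ALPHA_NORM = 15.0
NEGATION_FACTOR = -0.74
BOOSTER_INCREMENT = 0.293
NEGATION_WINDOW = 3

DEFAULT_NEGATIONS = frozenset(
    {
        "not", "no", "never", "none", "neither", "nor", "nothing", "nobody",
        "cannot", "can't", "don't", "won't", "isn't", "wasn't", "aren't",
        "weren't", "didn't", "doesn't", "hasn't", "haven't", "hadn't",
        "couldn't", "shouldn't", "wouldn't", "without", "hardly", "scarcely",
        "rarely", "seldom",
    }
)

#: term -> signed increment; positive intensifies, negative dampens.
DEFAULT_BOOSTERS: Mapping[str, float] = {
    "very": BOOSTER_INCREMENT,
    "extremely": BOOSTER_INCREMENT,
    "really": BOOSTER_INCREMENT,
    "absolutely": BOOSTER_INCREMENT,
    "completely": BOOSTER_INCREMENT,
    "highly": BOOSTER_INCREMENT,
    "hugely": BOOSTER_INCREMENT,
    "particularly": BOOSTER_INCREMENT,
    "slightly": -BOOSTER_INCREMENT,
    "somewhat": -BOOSTER_INCREMENT,
    "barely": -BOOSTER_INCREMENT,
    "marginally": -BOOSTER_INCREMENT,
    "partly": -BOOSTER_INCREMENT,
    "kind_of": -BOOSTER_INCREMENT,
}

_TOKEN_RE = re.compile(r"[a-z0-9_']+")


@dataclass(frozen=True)
class ValenceLexicon:
    """Term valences in [-4, 4] plus booster and negation word lists."""

    valences: Mapping[str, float]
    boosters: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BOOSTERS))
    negations: frozenset[str] = DEFAULT_NEGATIONS

    def __post_init__(self) -> None:
        for term, v in self.valences.items():
            if term != term.lower():
                raise ConfigError(f"valence term {term!r} is not lowercase")
            if abs(v) > 4.0:
                raise ConfigError(f"valence of {term!r} outside [-4, 4]")


@dataclass(frozen=True)
class SentenceSentiment:
    article_id: str
    sentence_index: int
    compound: float
    phewas_codes: frozenset[str]


@dataclass(frozen=True)
class ConceptSentiment:
    phewas_code: str
    period: str
    mean_compound: float
    n_sentences: int


def load_valence_lexicon(
    valence_path: str | Path,
    booster_path: str | Path | None = None,
    negation_path: str | Path | None = None,
) -> ValenceLexicon:
    """Load a TSV valence lexicon (term, valence) plus optional booster
    (term, increment) and negation (term) lists."""
    valences: dict[str, float] = {}
    with Path(valence_path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise TableFormatError(
                    f"{valence_path}: line {lineno}: expected 2 columns"
                )
            try:
                valences[parts[0].strip().lower()] = float(parts[1])
            except ValueError as exc:
                raise TableFormatError(
                    f"{valence_path}: line {lineno}: bad valence {parts[1]!r}"
                ) from exc
    boosters = dict(DEFAULT_BOOSTERS)
    if booster_path is not None:
        boosters = {}
        with Path(booster_path).open("r", encoding="utf-8") as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                term, inc = line.rstrip("\n").split("\t")[:2]
                boosters[term.strip().lower()] = float(inc)
    negations = DEFAULT_NEGATIONS
    if negation_path is not None:
        with Path(negation_path).open("r", encoding="utf-8") as fh:
            negations = frozenset(
                line.strip().lower() for line in fh if line.strip()
            )
    return ValenceLexicon(valences, boosters, negations)


def tokenize(sentence: str) -> list[str]:
    """Word tokens of a cleaned lowercase sentence."""
    return _TOKEN_RE.findall(sentence)


def score_sentence(
    tokens: Sequence[str],
    lexicon: ValenceLexicon,
    alpha_norm: float = DEFAULT_ALPHA_NORM,
) -> float:
    """Compound score of one sentence from its ordered lowercase tokens.

    For each lexicon term: boosters within the three preceding tokens add
    0.293 toward (or away from) the term's sign; a negation within that
    window multiplies by -0.74.  The adjusted valences are summed and
    normalized to s/sqrt(s^2 + alpha_norm) in (-1, 1); a sentence with no
    lexicon term scores exactly 0.
    """
    if alpha_norm <= 0:
        raise ConfigError("alpha_norm must be positive")
    s = 0.0
    for i, tok in enumerate(tokens):
        v = lexicon.valences.get(tok)
        if v is None or v == 0.0:
            continue
        window = tokens[max(0, i - NEGATION_WINDOW) : i]
        for prev in window:
            inc = lexicon.boosters.get(prev)
            if inc is not None:
                v += inc if v > 0 else -inc
        if any(prev in lexicon.negations for prev in window):
            v *= NEGATION_FACTOR
        s += v
    if s == 0.0:
        return 0.0
    return s / math.sqrt(s * s + alpha_norm)


def score_mention_sentences(
    article_sentences: Mapping[str, Sequence[str]],
    mentions: Iterable[Mention],
    lexicon: ValenceLexicon,
    alpha_norm: float = DEFAULT_ALPHA_NORM,
    policy: str = DEFINITIVE_ONLY,
) -> list[SentenceSentiment]:
    """Score every sentence that carries at least one disease mention.

    Only disease-mentioning sentences are scored (the others never enter
    any concept average).  A sentence's concept linkage is by mention
    presence in that sentence; the attribution policy decides whether
    ambiguous mentions link their candidate concepts."""
    if policy not in (DEFINITIVE_ONLY, EXPAND_AMBIGUOUS):
        raise ConfigError(f"unknown attribution policy {policy!r}")
    codes_by_sentence: dict[tuple[str, int], set[str]] = {}
    for m in mentions:
        key = (m.article_id, m.sentence_index)
        codes_by_sentence.setdefault(key, set())
        if m.mapping_class == DEFINITIVE or (
            m.mapping_class == AMBIGUOUS and policy == EXPAND_AMBIGUOUS
        ):
            codes_by_sentence[key].update(m.phewas_set)
    out: list[SentenceSentiment] = []
    for (article_id, s_idx), codes in sorted(codes_by_sentence.items()):
        sentences = article_sentences.get(article_id)
        if sentences is None or s_idx >= len(sentences):
            continue
        compound = score_sentence(tokenize(sentences[s_idx]), lexicon, alpha_norm)
        out.append(
            SentenceSentiment(
                article_id=article_id,
                sentence_index=s_idx,
                compound=compound,
                phewas_codes=frozenset(codes),
            )
        )
    return out


def concept_sentiment(
    sentence_sentiments: Iterable[SentenceSentiment],
    period_of_article: Mapping[str, str],
) -> list[ConceptSentiment]:
    """Mean compound per (concept, period).

    Concepts with zero scored sentences in a period are omitted rather
    than zero-filled: an absent mean is not a neutral mean."""
    sums: dict[tuple[str, str], list[float]] = {}
    for ss in sentence_sentiments:
        period = period_of_article.get(ss.article_id)
        if period is None:
            continue
        for code in ss.phewas_codes:
            sums.setdefault((code, period), []).append(ss.compound)
    out = []
    for (code, period) in sorted(sums):
        vals = sums[(code, period)]
        out.append(
            ConceptSentiment(
                phewas_code=code,
                period=period,
                mean_compound=sum(vals) / len(vals),
                n_sentences=len(vals),
            )
        )
    return out


def sentiment_band(
    mean_compound: float, neutral_band: tuple[float, float] = (-0.05, 0.05)
) -> str:
    """Label a mean compound as negative / neutral / positive."""
    lo, hi = neutral_band
    if not (lo < 0 < hi):
        raise ConfigError("neutral band must straddle 0")
    if mean_compound < lo:
        return "negative"
    if mean_compound > hi:
        return "positive"
    return "neutral"
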