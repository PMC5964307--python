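"""Synthetic news corpora with known ground truth.

The generator emulates the statistical shape of archive newswire data:
a small fraction (~0.5-1%) of articles mention diseases; disease names
are single- and multi-word dictionary synonyms; article text follows a
planted topic model (theta_d ~ Dirichlet(alpha_true), words from
phi_true); sentences near mentions carry valence-lexicon words chosen so
the expected sentence compound equals a per-concept target; and raw text
is decorated with wire-service noise (agency tags, editorial bylines,
service comments with hyperlinks, repeated special characters, "*"/">"
delimiters).  Every injection is logged, so cleaning, matching, coverage,
sentiment and topic stages can each be checked against the truth.

The background vocabulary is synthetic pronounceable pseudo-words; words
used by disease synonyms, the valence pool, stopwords, negations and
boosters are excluded from it, so insertions never collide with
background tokens and the matcher's output can be compared to the planted
mentions exactly.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ._language_data import STOPWORDS
from .corpus import Corpus, NewsArticle, Period, write_corpus
from .errors import ConfigError
from .sentiment import (
    DEFAULT_ALPHA_NORM,
    DEFAULT_BOOSTERS,
    DEFAULT_NEGATIONS,
    ValenceLexicon,
)
from .terminology import ConceptLexicon, MappingChain

__all__ = [
    "ConceptSpec",
    "NoiseConfig",
    "SimulationConfig",
    "GroundTruth",
    "SimulationResult",
    "generate",
    "make_noise",
    "inject_link",
    "make_planted_phi",
    "default_concepts",
]

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"


def pseudo_words(n: int, reserved: frozenset[str] = frozenset()) -> list[str]:
    """Deterministic pronounceable pseudo-words (CVCV / CVCVC patterns),
    skipping anything in ``reserved``."""
    out: list[str] = []
    for c1 in _CONSONANTS:
        for v1 in _VOWELS:
            for c2 in _CONSONANTS:
                for v2 in _VOWELS:
                    w = c1 + v1 + c2 + v2
                    if w not in reserved:
                        out.append(w)
                        if len(out) == n:
                            return out
    for c1 in _CONSONANTS:  # pragma: no cover - only for very large vocabularies
        for v1 in _VOWELS:
            for c2 in _CONSONANTS:
                for v2 in _VOWELS:
                    for c3 in _CONSONANTS:
                        w = c1 + v1 + c2 + v2 + c3
                        if w not in reserved:
                            out.append(w)
                            if len(out) == n:
                                return out
    raise ConfigError(f"cannot generate {n} pseudo-words")


@dataclass(frozen=True)
class ConceptSpec:
    """One planted disease concept: its code, display name, dictionary
    synonyms, per-period sampling weight among disease articles, and the
    target mean sentence compound for sentences mentioning it."""

    phewas_code: str
    name: str
    synonyms: tuple[str, ...]
    weight: Mapping[str, float] | float = 1.0
    target_valence: float = 0.0
    n_icd_codes: int = 1  # >1 exercises multiple-to-one (still definitive)

    def weight_in(self, period: str) -> float:
        if isinstance(self.weight, Mapping):
            return float(self.weight.get(period, 0.0))
        return float(self.weight)


@dataclass(frozen=True)
class NoiseConfig:
    """Per-article injection probabilities for wire-service noise.

    Hyperlinks ride inside removable service-comment sentences so that
    cleaning restores the noise-free text exactly."""

    tag_rate: float = 0.5
    byline_rate: float = 0.5
    comment_rate: float = 0.3
    link_rate: float = 0.5  # probability a comment carries a URL
    repeat_rate: float = 0.3
    delimiter_rate: float = 0.1  # per sentence terminator

    @classmethod
    def off(cls) -> "NoiseConfig":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


def default_periods() -> tuple[Period, ...]:
    import datetime as dt

    return (
        Period("1996/1997", dt.date(1996, 8, 20), dt.date(1997, 8, 19)),
        Period("2008", dt.date(2008, 1, 1), dt.date(2008, 12, 31)),
        Period("2016", dt.date(2016, 1, 1), dt.date(2016, 12, 31)),
    )


def default_concepts() -> tuple[ConceptSpec, ...]:
    """A small concept table mirroring the structure of the study's most
    covered concepts: dominant steady, fluctuating, and rising diseases,
    with single- and multi-word (including nested) synonyms."""
    return (
        ConceptSpec(
            "165", "other malignant neoplasm",
            ("cancer", "lung cancer", "malignant neoplasm"),
            weight={"1996/1997": 0.34, "2008": 0.34, "2016": 0.34},
            target_valence=-0.55, n_icd_codes=2,
        ),
        ConceptSpec(
            "136", "other infectious diseases",
            ("infectious disease", "zika virus", "hiv infection"),
            weight={"1996/1997": 0.22, "2008": 0.08, "2016": 0.31},
            target_valence=0.0, n_icd_codes=2,
        ),
        ConceptSpec(
            "481", "influenza",
            ("influenza", "flu", "bird flu"),
            weight={"1996/1997": 0.02, "2008": 0.24, "2016": 0.08},
            target_valence=-0.35,
        ),
        ConceptSpec(
            "250", "diabetes mellitus",
            ("diabetes", "diabetes mellitus"),
            weight={"1996/1997": 0.10, "2008": 0.14, "2016": 0.17},
            target_valence=-0.10,
        ),
        ConceptSpec(
            "296", "depression",
            ("depression", "depressive disorder"),
            weight={"1996/1997": 0.12, "2008": 0.10, "2016": 0.10},
            target_valence=-0.45,
        ),
        ConceptSpec(
            "475", "asthma",
            ("asthma",),
            weight={"1996/1997": 0.20, "2008": 0.10, "2016": 0.00},
            target_valence=0.15,
        ),
    )


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    periods: tuple[Period, ...] = field(default_factory=default_periods)
    n_articles: Mapping[str, int] | int = 1000
    disease_article_fraction: Mapping[str, float] | float = field(
        default_factory=lambda: {"1996/1997": 0.0044, "2008": 0.0057, "2016": 0.0081}
    )
    concepts: tuple[ConceptSpec, ...] = field(default_factory=default_concepts)
    K_true: int = 3
    alpha_true: float = 0.1
    vocab_size: int = 300
    doc_len: int = 120
    sentence_len: int = 12
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    ambiguous_synonyms: tuple[tuple[str, tuple[str, ...]], ...] = ()

    def n_in(self, period: str) -> int:
        if isinstance(self.n_articles, Mapping):
            return int(self.n_articles[period])
        return int(self.n_articles)

    def fraction_in(self, period: str) -> float:
        if isinstance(self.disease_article_fraction, Mapping):
            return float(self.disease_article_fraction[period])
        return float(self.disease_article_fraction)

    def validate(self) -> None:
        for p in self.periods:
            frac = self.fraction_in(p.label)
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(
                    f"disease fraction {frac} for period {p.label!r} outside [0,1]"
                )
            if self.n_in(p.label) < 0:
                raise ConfigError("n_articles must be >= 0")
        if self.vocab_size < self.K_true:
            raise ConfigError("vocab_size must be >= K_true")
        if not self.concepts:
            raise ConfigError("at least one concept required")


@dataclass
class PlantedMention:
    article_id: str
    phewas_code: str
    synonym: str
    sentence_index: int
    char_span: tuple[int, int]


@dataclass
class GroundTruth:
    """Everything the generator planted, for stage-by-stage checks."""

    mentions: list[PlantedMention]
    concept_article_counts: dict[str, dict[str, int]]  # period -> code -> n
    denominators: dict[str, int]  # period -> n disease-mentioning articles
    totals: dict[str, int]  # period -> n articles
    phi_true: np.ndarray
    theta_true: dict[str, np.ndarray]  # article id -> theta
    target_valences: dict[str, float]
    clean_texts: dict[str, str]  # article id -> noise-free text
    noise_log: list[dict]
    period_of_article: dict[str, str] = field(default_factory=dict)

    def concept_article_sets(self) -> dict[str, dict[str, set[str]]]:
        """code -> period -> article-id set, derived from planted mentions."""
        out: dict[str, dict[str, set[str]]] = {}
        for m in self.mentions:
            period = self.period_of_article[m.article_id]
            out.setdefault(m.phewas_code, {}).setdefault(period, set()).add(
                m.article_id
            )
        return out


@dataclass
class SimulationResult:
    corpus: Corpus
    lexicon: ConceptLexicon
    chain: MappingChain
    valence_lexicon: ValenceLexicon
    ground_truth: GroundTruth
    paths: dict[str, Path] = field(default_factory=dict)


def _valence_for_compound(c: float, alpha_norm: float = DEFAULT_ALPHA_NORM) -> float:
    """Invert the compound normalization: the raw valence whose lone
    occurrence in a sentence scores exactly ``c``."""
    if not -1.0 < c < 1.0:
        raise ConfigError("compound target must lie strictly inside (-1, 1)")
    return c * math.sqrt(alpha_norm / (1.0 - c * c))


_MAX_POOL_COMPOUND = 0.70  # keeps |valence| = 0.70*sqrt(15/0.51) ≈ 3.80 <= 4


def _clamp_c(c: float) -> float:
    return max(-_MAX_POOL_COMPOUND, min(_MAX_POOL_COMPOUND, c))


def make_planted_phi(K: int, V: int, main_mass: float = 0.9) -> np.ndarray:
    """Well-separated planted topics: topic k puts ``main_mass`` uniformly
    on its own block of V//K words and the rest uniformly everywhere."""
    phi = np.full((K, V), (1.0 - main_mass) / V)
    block = V // K
    for k in range(K):
        lo = k * block
        hi = V if k == K - 1 else (k + 1) * block
        phi[k, lo:hi] += main_mass / (hi - lo)
    return phi / phi.sum(axis=1, keepdims=True)


def _sample_doc(
    rng: np.random.Generator,
    phi: np.ndarray,
    cum_phi: np.ndarray,
    alpha_true: float,
    doc_len: int,
) -> tuple[np.ndarray, np.ndarray]:
    K = phi.shape[0]
    theta = rng.dirichlet(np.full(K, alpha_true))
    topics = rng.choice(K, size=doc_len, p=theta)
    u = rng.random(doc_len)
    words = np.empty(doc_len, dtype=np.int64)
    for k in range(K):
        mask = topics == k
        if mask.any():
            words[mask] = np.searchsorted(cum_phi[k], u[mask], side="right")
    return words, theta


def sample_topic_corpus(
    rng: np.random.Generator,
    phi: np.ndarray,
    alpha: float,
    n_docs: int,
    doc_len: int,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Draw documents from the planted topic model.

    Returns (list of word-index arrays, theta matrix of shape (D, K))."""
    cum_phi = np.cumsum(phi, axis=1)
    cum_phi[:, -1] = 1.0
    docs = []
    thetas = np.empty((n_docs, phi.shape[0]))
    for i in range(n_docs):
        words, theta = _sample_doc(rng, phi, cum_phi, alpha, doc_len)
        docs.append(words.astype(np.int32))
        thetas[i] = theta
    return docs, thetas


def _sentences_from_words(
    words: Sequence[str], sentence_len: int
) -> list[list[str]]:
    return [
        list(words[i : i + sentence_len]) for i in range(0, len(words), sentence_len)
    ]


def make_noise(
    text: str, config: NoiseConfig, rng: np.random.Generator
) -> tuple[str, list[dict]]:
    """Decorate clean article text with wire-service noise.

    Each injection is logged; for every configuration,
    ``clean_text(make_noise(x)) == clean_text(x)``: comments (which may
    carry dot-free hyperlinks), bylines and tags are removed wholly,
    repeated-character runs collapse to whitespace, and "*"/">" replace
    existing sentence terminators in place."""
    log: list[dict] = []
    # decorative repeated-character run at a random space (before the
    # comment goes in, so it can never split the comment's trigger phrase)
    if rng.random() < config.repeat_rate:
        run = "-" * int(rng.integers(5, 20))
        spaces = [i for i, ch in enumerate(text) if ch == " "]
        if spaces:
            pos = int(rng.choice(spaces))
            text = text[:pos] + " " + run + text[pos:]
            log.append({"kind": "repeat_run", "pos": pos, "len": len(run)})
    # service comment (optionally carrying a URL), inserted at a sentence
    # boundary; URL is dot-free so the whole comment is one sentence
    if rng.random() < config.comment_rate:
        comment = "Click on the codes in brackets to see stories"
        if rng.random() < config.link_rate:
            comment += " http://topnews-session-rservices"
            log.append({"kind": "link_in_comment"})
        comment += "."
        boundaries = [i + 1 for i, ch in enumerate(text) if ch == "."]
        pos = int(rng.choice(boundaries)) if boundaries else len(text)
        text = text[:pos] + " " + comment + text[pos:]
        log.append({"kind": "comment", "pos": pos})
    # "*" / ">" replacing sentence terminators in place
    if config.delimiter_rate > 0:
        chars = list(text)
        for i, ch in enumerate(chars):
            if ch == "." and rng.random() < config.delimiter_rate:
                chars[i] = "*" if rng.random() < 0.5 else ">"
                log.append({"kind": "delimiter", "pos": i})
        text = "".join(chars)
    # trailing editorial byline
    if rng.random() < config.byline_rate:
        name = " ".join(w.capitalize() for w in pseudo_words(2, frozenset()))
        text = text + " Editing by " + name + "."
        log.append({"kind": "byline"})
    # agency tag at the very end
    if rng.random() < config.tag_rate:
        text = text + " (Reuters)"
        log.append({"kind": "tag"})
    return text, log


def inject_link(text: str, url: str = "http://topnews.session.rservices.com") -> str:
    """Append a bare hyperlink; cleaning replaces it with the link token
    at that position (this residue is why bare links are not part of
    ``make_noise``'s reversible repertoire)."""
    return text + " see " + url + " now"


def _build_tables(
    config: SimulationConfig,
) -> tuple[ConceptLexicon, MappingChain, list[tuple[str, str]], list[tuple[str, str, str]]]:
    lex_rows: list[tuple[str, str]] = []
    cui_rows: list[tuple[str, str]] = []
    icd_rows: list[tuple[str, str, str]] = []
    code_to_cui: dict[str, str] = {}
    for i, spec in enumerate(config.concepts):
        cui = f"C{i:07d}"
        code_to_cui[spec.phewas_code] = cui
        for syn in spec.synonyms:
            lex_rows.append((syn.lower(), cui))
        for j in range(spec.n_icd_codes):
            icd = f"{100 + i}.{j}"
            cui_rows.append((cui, icd))
            icd_rows.append((icd, spec.phewas_code, spec.name))
    for syn, codes in config.ambiguous_synonyms:
        for code in codes:
            lex_rows.append((syn.lower(), code_to_cui[code]))
    entries: dict[str, set[str]] = {}
    for syn, cui in lex_rows:
        entries.setdefault(syn, set()).add(cui)
    lexicon = ConceptLexicon({k: frozenset(v) for k, v in entries.items()})
    cui_to_icd: dict[str, set[str]] = {}
    for cui, icd in cui_rows:
        cui_to_icd.setdefault(cui, set()).add(icd)
    chain = MappingChain(
        {k: frozenset(v) for k, v in cui_to_icd.items()},
        {icd: (code, name) for icd, code, name in icd_rows},
    )
    return lexicon, chain, cui_rows, icd_rows


def generate(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> SimulationResult:
    """Generate a corpus plus lexicon/chain/valence tables and ground truth.

    Same seed, same config -> byte-identical artifacts."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    lexicon, chain, cui_rows, icd_rows = _build_tables(config)
    syn_words = frozenset(
        w for spec in config.concepts for syn in spec.synonyms for w in syn.lower().split()
    ) | frozenset(w for syn, _ in config.ambiguous_synonyms for w in syn.lower().split())
    reserved = (
        syn_words
        | STOPWORDS
        | DEFAULT_NEGATIONS
        | frozenset(DEFAULT_BOOSTERS)
        | frozenset({"link", "reuters", "editing", "http"})
    )
    n_extra = 2 * len(config.concepts)
    words = pseudo_words(config.vocab_size + n_extra, reserved)
    vocab = words[: config.vocab_size]
    pool_words = words[config.vocab_size :]

    # valence pools: two words per concept whose lone compounds straddle
    # the target, picked with probabilities that make the expectation hit it
    valences: dict[str, float] = {}
    pools: dict[str, tuple[str, float, str, float, float]] = {}
    for i, spec in enumerate(config.concepts):
        c_hi = _clamp_c(spec.target_valence + 0.05)
        c_lo = _clamp_c(spec.target_valence - 0.05)
        w_hi, w_lo = pool_words[2 * i], pool_words[2 * i + 1]
        valences[w_hi] = round(_valence_for_compound(c_hi), 4)
        valences[w_lo] = round(_valence_for_compound(c_lo), 4)
        # expectation target uses the achievable (clamped) compounds
        target = _clamp_c(spec.target_valence)
        p_hi = 0.5 if c_hi == c_lo else (target - c_lo) / (c_hi - c_lo)
        pools[spec.phewas_code] = (w_hi, c_hi, w_lo, c_lo, p_hi)
    valence_lexicon = ValenceLexicon(valences)

    phi_true = make_planted_phi(config.K_true, config.vocab_size)
    cum_phi = np.cumsum(phi_true, axis=1)
    cum_phi[:, -1] = 1.0

    periods = config.periods
    articles: list[NewsArticle] = []
    mentions: list[PlantedMention] = []
    counts: dict[str, dict[str, int]] = {}
    denominators: dict[str, int] = {}
    totals: dict[str, int] = {}
    theta_true: dict[str, np.ndarray] = {}
    clean_texts: dict[str, str] = {}
    noise_log: list[dict] = []

    concept_list = list(config.concepts)
    for p_idx, period in enumerate(periods):
        n = config.n_in(period.label)
        totals[period.label] = n
        n_dis = int(round(config.fraction_in(period.label) * n))
        dis_idx = set(
            int(i) for i in rng.choice(n, size=n_dis, replace=False)
        ) if n_dis else set()
        weights = np.array([c.weight_in(period.label) for c in concept_list])
        if n_dis and weights.sum() <= 0:
            raise ConfigError(
                f"period {period.label!r}: all concept weights zero"
            )
        if weights.sum() > 0:
            weights = weights / weights.sum()
        denominators[period.label] = n_dis
        counts[period.label] = {}
        span_days = (period.end_date - period.start_date).days
        for a_i in range(n):
            art_id = f"p{p_idx}a{a_i:06d}"
            word_idx, theta = _sample_doc(
                rng, phi_true, cum_phi, config.alpha_true, config.doc_len
            )
            theta_true[art_id] = theta
            toks = [vocab[j] for j in word_idx]
            sent_tokens = _sentences_from_words(toks, config.sentence_len)
            if a_i in dis_idx:
                c_i = int(rng.choice(len(concept_list), p=weights))
                spec = concept_list[c_i]
                syn = spec.synonyms[int(rng.integers(len(spec.synonyms)))].lower()
                syn_toks = syn.split()
                s_idx = int(rng.integers(len(sent_tokens)))
                sent = sent_tokens[s_idx]
                pos = int(rng.integers(len(sent) + 1))
                sent[pos:pos] = syn_toks
                # sentiment carrier right after the disease name
                w_hi, _, w_lo, _, p_hi = pools[spec.phewas_code]
                carrier = w_hi if rng.random() < p_hi else w_lo
                sent.insert(pos + len(syn_toks), carrier)
                start = sum(len(t) for t in sent[:pos]) + pos
                mentions.append(
                    PlantedMention(
                        article_id=art_id,
                        phewas_code=spec.phewas_code,
                        synonym=syn,
                        sentence_index=s_idx,
                        char_span=(start, start + len(syn)),
                    )
                )
                counts[period.label][spec.phewas_code] = (
                    counts[period.label].get(spec.phewas_code, 0) + 1
                )
            sentences = [" ".join(s) + "." for s in sent_tokens]
            base = " ".join(sentences)
            clean_texts[art_id] = base
            raw, art_log = make_noise(base, config.noise, rng)
            for entry in art_log:
                noise_log.append({"article_id": art_id, **entry})
            date = period.start_date + _dt.timedelta(
                days=int(a_i * span_days // max(1, n))
            )
            articles.append(
                NewsArticle(
                    article_id=art_id,
                    date=date,
                    period=period.label,
                    raw_text=raw,
                )
            )

    corpus = Corpus(periods=list(periods), articles=articles)
    truth = GroundTruth(
        mentions=mentions,
        concept_article_counts=counts,
        denominators=denominators,
        totals=totals,
        phi_true=phi_true,
        theta_true=theta_true,
        target_valences={
            c.phewas_code: _clamp_c(c.target_valence) for c in config.concepts
        },
        clean_texts=clean_texts,
        noise_log=noise_log,
        period_of_article={a.article_id: a.period for a in articles},
    )

    paths: dict[str, Path] = {}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths["corpus"] = out / "corpus.jsonl"
        write_corpus(corpus, paths["corpus"])
        paths["lexicon"] = out / "lexicon.tsv"
        with paths["lexicon"].open("w", encoding="utf-8") as fh:
            for syn in sorted(lexicon.entries):
                for cui in sorted(lexicon.entries[syn]):
                    fh.write(f"{syn}\t{cui}\n")
        paths["cui_icd"] = out / "cui_icd.tsv"
        with paths["cui_icd"].open("w", encoding="utf-8") as fh:
            for cui, icd in sorted(cui_rows):
                fh.write(f"{cui}\t{icd}\n")
        paths["icd_phewas"] = out / "icd_phewas.tsv"
        with paths["icd_phewas"].open("w", encoding="utf-8") as fh:
            for icd, code, name in sorted(icd_rows):
                fh.write(f"{icd}\t{code}\t{name}\n")
        paths["valence"] = out / "valence.tsv"
        with paths["valence"].open("w", encoding="utf-8") as fh:
            for term in sorted(valences):
                fh.write(f"{term}\t{valences[term]}\n")
        paths["ground_truth"] = out / "ground_truth.json"
        truth_json = {
            "mentions": [dataclasses.asdict(m) for m in mentions],
            "concept_article_counts": counts,
            "denominators": denominators,
            "totals": totals,
            "target_valences": truth.target_valences,
            "phi_true": [[round(float(x), 10) for x in row] for row in phi_true],
            "mean_theta": [
                round(float(x), 10)
                for x in np.mean(list(theta_true.values()), axis=0)
            ],
        }
        paths["ground_truth"].write_text(
            json.dumps(truth_json, sort_keys=True, indent=None, separators=(",", ":")),
            encoding="utf-8",
        )
        paths["config"] = out / "config.json"
        cfg = dataclasses.asdict(config)
        cfg["periods"] = [
            [p.label, p.start_date.isoformat(), p.end_date.isoformat()]
            for p in config.periods
        ]
        paths["config"].write_text(
            json.dumps(cfg, sort_keys=True, default=str, separators=(",", ":")),
            encoding="utf-8",
        )
    return SimulationResult(
        corpus=corpus,
        lexicon=lexicon,
        chain=chain,
        valence_lexicon=valence_lexicon,
        ground_truth=truth,
        paths=paths,
    )


def random_mapping_chain(
    rng: np.random.Generator,
    n_synonyms: int = 50,
    n_cuis: int = 30,
    n_icds: int = 25,
    n_phewas: int = 12,
) -> tuple[ConceptLexicon, MappingChain]:
    """A random synonym→CUI→ICD→PheWAS chain with a realistic mix of
    one-to-one, multiple-to-one, ambiguous and broken paths.  Used to
    cross-check the definitive-mapping statistic against an independent
    path-enumeration oracle."""
    synonyms = [f"syn{i}" for i in range(n_synonyms)]
    cuis = [f"C{i:04d}" for i in range(n_cuis)]
    icds = [f"{i:03d}.0" for i in range(n_icds)]
    phewas = [f"PW{i:03d}" for i in range(n_phewas)]
    entries: dict[str, set[str]] = {}
    for syn in synonyms:
        k = 1 + (rng.random() < 0.25)  # 25% of synonyms get a second CUI
        entries[syn] = set(
            cuis[int(i)] for i in rng.choice(n_cuis, size=k, replace=False)
        )
    cui_to_icd: dict[str, set[str]] = {}
    for cui in cuis:
        if rng.random() < 0.15:  # some CUIs have no ICD mapping
            continue
        k = 1 + (rng.random() < 0.3)
        cui_to_icd[cui] = set(
            icds[int(i)] for i in rng.choice(n_icds, size=k, replace=False)
        )
    icd_to_phewas: dict[str, tuple[str, str]] = {}
    for icd in icds:
        if rng.random() < 0.1:  # some ICDs unmapped to PheWAS
            continue
        code = phewas[int(rng.integers(n_phewas))]
        icd_to_phewas[icd] = (code, f"concept {code}")
    lexicon = ConceptLexicon({k: frozenset(v) for k, v in entries.items()})
    chain = MappingChain(
        {k: frozenset(v) for k, v in cui_to_icd.items()}, icd_to_phewas
    )
    return lexicon, chain
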