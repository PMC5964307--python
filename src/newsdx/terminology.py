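"""Disease-synonym dictionary matching and concept normalization.

Free-text disease names are grouped to concept identifiers (CUI-like),
converted to ICD-9-CM-like codes, and aggregated to PheWAS-like disease
concepts.  A synonym whose mapping chain ends in exactly one PheWAS code
is *definitive* (one-to-one or multiple-to-one); two or more codes make
it *ambiguous*; none, *unmapped*.

Matching against cleaned, lowercased sentences is dictionary-based:
token-boundary anchored, longest-match-first, left-to-right,
non-overlapping — so "cancer" is never double-counted inside
"lung cancer".
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from .errors import ConfigError, TableFormatError, UndefinedStatisticError

__all__ = [
    "ConceptLexicon",
    "MappingChain",
    "SynonymResolution",
    "Mention",
    "load_lexicon",
    "load_chain",
    "resolve_synonym",
    "definitive_fraction",
    "find_mentions",
    "articles_by_concept",
]

logger = logging.getLogger(__name__)

_TOKEN_RE = re.compile(r"[a-z0-9_']+")

DEFINITIVE = "definitive"
AMBIGUOUS = "ambiguous"
UNMAPPED = "unmapped"


def _norm(s: str) -> str:
    return re.sub(r"\s+", " ", s.strip().lower())


@dataclass(frozen=True)
class ConceptLexicon:
    """Synonym → concept-identifier dictionary.

    A synonym may map to several CUIs; duplicate (synonym, cui) pairs are
    collapsed.  Synonyms are stored lowercase with normalized whitespace.
    """

    entries: Mapping[str, frozenset[str]]

    @property
    def synonyms(self) -> list[str]:
        return sorted(self.entries)

    def cuis(self, synonym: str) -> frozenset[str]:
        return self.entries.get(_norm(synonym), frozenset())

    def __len__(self) -> int:
        return sum(len(v) for v in self.entries.values())


@dataclass(frozen=True)
class MappingChain:
    """CUI → ICD-9-CM multimap composed with the single-valued
    ICD-9-CM → (PheWAS code, display name) map."""

    cui_to_icd: Mapping[str, frozenset[str]]
    icd_to_phewas: Mapping[str, tuple[str, str]]

    def phewas_name(self, code: str) -> str:
        for pw, name in self.icd_to_phewas.values():
            if pw == code:
                return name
        return code


@dataclass(frozen=True)
class SynonymResolution:
    synonym: str
    phewas_set: frozenset[str]

    @property
    def mapping_class(self) -> str:
        if len(self.phewas_set) == 0:
            return UNMAPPED
        if len(self.phewas_set) == 1:
            return DEFINITIVE
        return AMBIGUOUS


@dataclass(frozen=True)
class Mention:
    """One located disease-synonym occurrence.

    ``char_span`` is a half-open offset pair within the sentence; the
    sentence substring at the span equals the synonym up to whitespace
    normalization."""

    article_id: str
    sentence_index: int
    char_span: tuple[int, int]
    synonym: str
    phewas_set: frozenset[str]
    mapping_class: str


def _read_tsv(path: str | Path, n_cols: int) -> list[tuple[str, ...]]:
    rows: list[tuple[str, ...]] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < n_cols:
                raise TableFormatError(
                    f"{path}: line {lineno}: expected {n_cols} columns, "
                    f"got {len(parts)}"
                )
            rows.append(tuple(p.strip() for p in parts[:n_cols]))
    return rows


def load_lexicon(path: str | Path) -> ConceptLexicon:
    """Load a synonym TSV (columns: synonym, cui)."""
    entries: dict[str, set[str]] = {}
    for synonym, cui in _read_tsv(path, 2):
        syn = _norm(synonym)
        if not syn or not cui:
            raise TableFormatError(f"{path}: empty synonym or cui")
        entries.setdefault(syn, set()).add(cui)
    if not entries:
        logger.warning("lexicon %s is empty", path)
    return ConceptLexicon({k: frozenset(v) for k, v in entries.items()})


def load_chain(cui_icd_path: str | Path, icd_phewas_path: str | Path) -> MappingChain:
    """Load mapping TSVs: (cui, icd) and (icd, phewas_code, phewas_name)."""
    cui_to_icd: dict[str, set[str]] = {}
    for cui, icd in _read_tsv(cui_icd_path, 2):
        cui_to_icd.setdefault(cui, set()).add(icd)
    icd_to_phewas: dict[str, tuple[str, str]] = {}
    for icd, code, name in _read_tsv(icd_phewas_path, 3):
        prev = icd_to_phewas.get(icd)
        if prev is not None and prev[0] != code:
            raise TableFormatError(
                f"{icd_phewas_path}: ICD code {icd!r} maps to both "
                f"{prev[0]!r} and {code!r}"
            )
        icd_to_phewas[icd] = (code, name)
    return MappingChain(
        {k: frozenset(v) for k, v in cui_to_icd.items()}, icd_to_phewas
    )


def resolve_synonym(
    synonym: str, lexicon: ConceptLexicon, chain: MappingChain
) -> SynonymResolution:
    """Follow synonym → CUIs → ICD codes → PheWAS codes; union the ends.

    Unknown synonyms (or broken chains) resolve to the empty set, i.e.
    mapping class *unmapped*; never raises."""
    syn = _norm(synonym)
    phewas: set[str] = set()
    for cui in lexicon.cuis(syn):
        for icd in chain.cui_to_icd.get(cui, frozenset()):
            entry = chain.icd_to_phewas.get(icd)
            if entry is not None:
                phewas.add(entry[0])
    return SynonymResolution(syn, frozenset(phewas))


def definitive_fraction(lexicon: ConceptLexicon, chain: MappingChain) -> float:
    """Fraction of mapped synonyms whose chain is definitive.

    Denominator is the number of synonyms with a non-empty PheWAS set;
    raises if every synonym is unmapped."""
    n_def = 0
    n_mapped = 0
    for syn in lexicon.entries:
        res = resolve_synonym(syn, lexicon, chain)
        if res.mapping_class == DEFINITIVE:
            n_def += 1
            n_mapped += 1
        elif res.mapping_class == AMBIGUOUS:
            n_mapped += 1
    if n_mapped == 0:
        raise UndefinedStatisticError("no synonym maps to any PheWAS code")
    return n_def / n_mapped


class _SynonymIndex:
    """Token-sequence index over lexicon synonyms, longest-first."""

    def __init__(self, synonyms: Iterable[str]):
        self.by_first: dict[str, list[tuple[str, ...]]] = {}
        for syn in synonyms:
            toks = tuple(syn.split(" "))
            self.by_first.setdefault(toks[0], []).append(toks)
        for cand in self.by_first.values():
            cand.sort(key=lambda t: (-len(t), t))


def _iter_matches(
    sentence: str, index: _SynonymIndex
) -> Iterator[tuple[int, int, str]]:
    """Yield (start, end, synonym) matches: token-anchored, longest-first,
    left-to-right, non-overlapping; multi-word synonyms span single spaces."""
    spans = [(m.start(), m.end(), m.group()) for m in _TOKEN_RE.finditer(sentence)]
    i = 0
    while i < len(spans):
        tok = spans[i][2]
        matched = False
        for cand in index.by_first.get(tok, ()):
            if i + len(cand) > len(spans):
                continue
            ok = True
            for j in range(1, len(cand)):
                if spans[i + j][2] != cand[j]:
                    ok = False
                    break
                # multi-word names must be separated by exactly one space
                if sentence[spans[i + j - 1][1] : spans[i + j][0]] != " ":
                    ok = False
                    break
            if ok:
                yield spans[i][0], spans[i + len(cand) - 1][1], " ".join(cand)
                i += len(cand)
                matched = True
                break
        if not matched:
            i += 1


def find_mentions(
    article_sentences: Mapping[str, Sequence[str]] | Iterable[tuple[str, Sequence[str]]],
    lexicon: ConceptLexicon,
    chain: MappingChain,
) -> list[Mention]:
    """Locate every dictionary synonym in per-article sentence lists.

    Input sentences must already be cleaned (lowercase, whitespace
    normalized).  Each mention carries its chain resolution."""
    if isinstance(article_sentences, Mapping):
        items: Iterable[tuple[str, Sequence[str]]] = article_sentences.items()
    else:
        items = article_sentences
    index = _SynonymIndex(lexicon.entries)
    cache: dict[str, SynonymResolution] = {}
    mentions: list[Mention] = []
    for article_id, sentences in items:
        for s_idx, sentence in enumerate(sentences):
            for start, end, syn in _iter_matches(sentence, index):
                res = cache.get(syn)
                if res is None:
                    res = resolve_synonym(syn, lexicon, chain)
                    cache[syn] = res
                mentions.append(
                    Mention(
                        article_id=article_id,
                        sentence_index=s_idx,
                        char_span=(start, end),
                        synonym=syn,
                        phewas_set=res.phewas_set,
                        mapping_class=res.mapping_class,
                    )
                )
    return mentions


DEFINITIVE_ONLY = "definitive_only"
EXPAND_AMBIGUOUS = "expand_ambiguous"


def articles_by_concept(
    mentions: Iterable[Mention], policy: str = DEFINITIVE_ONLY
) -> tuple[dict[str, set[str]], set[str]]:
    """Attribute articles to PheWAS concepts.

    Returns (concept → article-id set, set of all disease-mentioning
    article ids).  Under ``definitive_only`` ambiguous mentions count
    toward the all-mentioning set but toward no concept; under
    ``expand_ambiguous`` they count toward every candidate concept."""
    if policy not in (DEFINITIVE_ONLY, EXPAND_AMBIGUOUS):
        raise ConfigError(f"unknown attribution policy {policy!r}")
    concept_articles: dict[str, set[str]] = {}
    all_ids: set[str] = set()
    for m in mentions:
        all_ids.add(m.article_id)
        if m.mapping_class == UNMAPPED:
            continue
        if m.mapping_class == AMBIGUOUS and policy == DEFINITIVE_ONLY:
            continue
        for code in m.phewas_set:
            concept_articles.setdefault(code, set()).add(m.article_id)
    return concept_articles, all_ids
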