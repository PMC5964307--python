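"""Topic modeling: preprocessing and latent Dirichlet allocation with a
collapsed Gibbs sampler.

The model: each document d draws a topic distribution theta_d ~
Dirichlet(alpha); each topic t has a word distribution phi_t ~
Dirichlet(beta); every token draws a topic from theta_d and a word from
phi_t.  Inference integrates theta and phi out and samples per-token
topic assignments z_i from the full conditional

    p(z_i = t | z_-i) ∝ (n_dt + alpha) * (n_wt + beta) / (n_t + V*beta)

where the counts exclude token i.  Point estimates are the posterior
means phi[t][w] = (n_wt + beta) / (n_t + V*beta) and theta[d][t] =
(n_dt + alpha) / (n_d + K*alpha).  An iterated-conditional-modes variant
(``mode="icm"``) replaces the draw with an argmax.  With K = 1 every
assignment is forced and phi has the closed form
(count(w) + beta) / (N + V*beta).

Preprocessing joins multi-word disease names into single underscore
tokens (so "lung cancer" survives as the unit "lung_cancer"), removes
stopwords, lemmatizes with a lookup table, and merges frequent adjacent
pairs into n-gram phrase tokens (n up to 4) by collocation score.
Per-topic term weights are reported in permille, 1000 * P(w|t).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence, Set

import numpy as np

from ._language_data import LEMMA_EXCEPTIONS, NON_PLURAL_S, STOPWORDS
from .errors import ConfigError
from .terminology import ConceptLexicon, _SynonymIndex, _iter_matches
from .sentiment import tokenize as _word_tokenize

__all__ = [
    "TopicConfig",
    "TokenizedDocs",
    "TopicModelState",
    "TopicSummary",
    "concat_compound_terms",
    "tokenize_for_topics",
    "detect_phrases",
    "fit_lda",
    "summarize_topic",
    "topics_per_concept",
    "gibbs_assignment_frequencies",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TopicConfig:
    """LDA and phrase-detection settings.

    ``alpha`` defaults to 50/K and ``beta`` to 0.01 (common symmetric
    priors); ``iterations`` is the number of full Gibbs sweeps.  ``K=1``
    follows the single-topic-per-concept design, where the fit reduces to
    a smoothed unigram distribution."""

    K: int = 1
    alpha: float | None = None
    beta: float = 0.01
    iterations: int = 500
    top_n: int = 50
    ngram_max: int = 4
    phrase_min_count: int = 5
    phrase_threshold: float = 10.0
    seed: int = 0
    mode: str = "gibbs"
    min_docs: int = 1

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ConfigError("K must be >= 1")
        if self.alpha is not None and self.alpha <= 0:
            raise ConfigError("alpha must be positive")
        if self.beta <= 0:
            raise ConfigError("beta must be positive")
        if self.iterations < 1:
            raise ConfigError("iterations must be >= 1")
        if self.top_n < 1:
            raise ConfigError("top_n must be >= 1")
        if not 1 <= self.ngram_max <= 4:
            raise ConfigError("ngram_max must be in 1..4")
        if self.mode not in ("gibbs", "icm"):
            raise ConfigError(f"unknown inference mode {self.mode!r}")

    @property
    def effective_alpha(self) -> float:
        return self.alpha if self.alpha is not None else 50.0 / self.K


@dataclass
class TokenizedDocs:
    """An indexed corpus: vocabulary plus per-document token-index lists."""

    vocabulary: list[str]
    docs: list[np.ndarray]

    @property
    def D(self) -> int:
        return len(self.docs)

    @property
    def V(self) -> int:
        return len(self.vocabulary)

    @property
    def n_tokens(self) -> int:
        return int(sum(len(d) for d in self.docs))

    @classmethod
    def from_token_lists(cls, token_lists: Sequence[Sequence[str]]) -> "TokenizedDocs":
        """Index tokens in order of first appearance (deterministic)."""
        vocab: dict[str, int] = {}
        docs = []
        for toks in token_lists:
            idx = np.empty(len(toks), dtype=np.int32)
            for i, t in enumerate(toks):
                j = vocab.get(t)
                if j is None:
                    j = len(vocab)
                    vocab[t] = j
                idx[i] = j
            docs.append(idx)
        return cls(vocabulary=list(vocab), docs=docs)


@dataclass
class TopicModelState:
    """Assignments, count tables and derived distributions of a fit.

    ``theta`` has shape (D, K) with rows summing to 1; ``phi`` has shape
    (K, V) with rows summing to 1."""

    z: np.ndarray
    n_dt: np.ndarray
    n_wt: np.ndarray
    n_t: np.ndarray
    theta: np.ndarray
    phi: np.ndarray
    vocabulary: list[str]

    @property
    def K(self) -> int:
        return int(self.n_t.shape[0])


@dataclass(frozen=True)
class TopicSummary:
    """Ranked (term, permille) pairs for one topic; permilles are
    non-increasing, permille = 1000 * P(w|t)."""

    terms: tuple[tuple[str, float], ...]


# ---------------------------------------------------------------------------
# preprocessing

def concat_compound_terms(
    sentences: Sequence[str], lexicon: ConceptLexicon
) -> list[str]:
    """Join every multi-word lexicon synonym occurrence with underscores,
    e.g. "lung cancer trial" -> "lung_cancer trial".  Uses the same
    longest-match-first matcher as mention detection."""
    index = _SynonymIndex(lexicon.entries)
    out = []
    for sentence in sentences:
        pieces = []
        pos = 0
        for start, end, syn in _iter_matches(sentence, index):
            if " " in syn:
                pieces.append(sentence[pos:start])
                pieces.append(sentence[start:end].replace(" ", "_"))
                pos = end
        pieces.append(sentence[pos:])
        out.append("".join(pieces))
    return out


def _lemmatize(word: str, exceptions: Mapping[str, str]) -> str:
    """Lookup-table lemmatizer: exception list plus plural suffix rules."""
    if word in exceptions:
        return exceptions[word]
    if word in NON_PLURAL_S or len(word) <= 3 or not word.endswith("s"):
        return word
    if word.endswith("sses"):
        return word[:-2]
    if word.endswith("ies") and len(word) > 4:
        return word[:-3] + "y"
    if word.endswith(("ss", "us", "is")):
        return word
    if word.endswith("es") and word[-3] in "sxzo" and len(word) > 4:
        return word[:-2]
    return word[:-1]


def tokenize_for_topics(
    text: str,
    stopword_list: Set[str] | None = None,
    lemmatizer_table: Mapping[str, str] | None = None,
) -> list[str]:
    """Word-tokenize cleaned text for topic modeling.

    Stopwords are dropped and words lemmatized; underscore-joined
    compound tokens pass through untouched."""
    stop = STOPWORDS if stopword_list is None else stopword_list
    table = LEMMA_EXCEPTIONS if lemmatizer_table is None else lemmatizer_table
    out = []
    for tok in _word_tokenize(text):
        if "_" in tok:
            out.append(tok)
            continue
        tok = tok.strip("'")
        if not tok or tok in stop:
            continue
        out.append(_lemmatize(tok, table))
    return out


def detect_phrases(
    docs: Sequence[Sequence[str]],
    ngram_max: int = 4,
    min_count: int = 5,
    threshold: float = 10.0,
) -> list[list[str]]:
    """Merge frequent adjacent token pairs into phrase tokens.

    One pass merges pairs (a, b) whose collocation score
    (count(ab) - min_count) * N / (count(a) * count(b)) meets
    ``threshold``, scanning left to right without overlap; ``ngram_max-1``
    passes allow phrases of up to ``ngram_max`` words."""
    current = [list(d) for d in docs]
    for _ in range(max(0, ngram_max - 1)):
        uni: dict[str, int] = {}
        bi: dict[tuple[str, str], int] = {}
        total = 0
        for doc in current:
            total += len(doc)
            for tok in doc:
                uni[tok] = uni.get(tok, 0) + 1
            for a, b in zip(doc, doc[1:]):
                bi[(a, b)] = bi.get((a, b), 0) + 1
        if total == 0:
            break
        merged_any = False
        nxt = []
        for doc in current:
            new_doc = []
            i = 0
            while i < len(doc):
                if i + 1 < len(doc):
                    a, b = doc[i], doc[i + 1]
                    c_ab = bi.get((a, b), 0)
                    score = (c_ab - min_count) * total / (uni[a] * uni[b])
                    if score >= threshold:
                        new_doc.append(a + "_" + b)
                        merged_any = True
                        i += 2
                        continue
                new_doc.append(doc[i])
                i += 1
            nxt.append(new_doc)
        current = nxt
        if not merged_any:
            break
    return current


# ---------------------------------------------------------------------------
# collapsed Gibbs sampler

def _sweep_gibbs_py(w, d, z, n_dt, n_wt, n_t, alpha, beta, v_beta, u):
    K = n_t.shape[0]
    cum = np.empty(K)
    for i in range(w.shape[0]):
        wi = w[i]
        di = d[i]
        k = z[i]
        n_dt[di, k] -= 1
        n_wt[wi, k] -= 1
        n_t[k] -= 1
        tot = 0.0
        for t in range(K):
            tot += (n_dt[di, t] + alpha) * (n_wt[wi, t] + beta) / (n_t[t] + v_beta)
            cum[t] = tot
        r = u[i] * tot
        k = 0
        while k < K - 1 and cum[k] < r:
            k += 1
        z[i] = k
        n_dt[di, k] += 1
        n_wt[wi, k] += 1
        n_t[k] += 1


def _sweep_icm_py(w, d, z, n_dt, n_wt, n_t, alpha, beta, v_beta):
    K = n_t.shape[0]
    for i in range(w.shape[0]):
        wi = w[i]
        di = d[i]
        k = z[i]
        n_dt[di, k] -= 1
        n_wt[wi, k] -= 1
        n_t[k] -= 1
        best = -1.0
        k = 0
        for t in range(K):
            p = (n_dt[di, t] + alpha) * (n_wt[wi, t] + beta) / (n_t[t] + v_beta)
            if p > best:
                best = p
                k = t
        z[i] = k
        n_dt[di, k] += 1
        n_wt[wi, k] += 1
        n_t[k] += 1


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _sweep_gibbs = njit(cache=True)(_sweep_gibbs_py)
    _sweep_icm = njit(cache=True)(_sweep_icm_py)
except ImportError:  # pragma: no cover
    _sweep_gibbs = _sweep_gibbs_py
    _sweep_icm = _sweep_icm_py


def _flatten(docs: TokenizedDocs) -> tuple[np.ndarray, np.ndarray]:
    w = np.concatenate([d for d in docs.docs if len(d)] or [np.empty(0, np.int32)])
    d_idx = np.concatenate(
        [np.full(len(doc), i, dtype=np.int32) for i, doc in enumerate(docs.docs) if len(doc)]
        or [np.empty(0, np.int32)]
    )
    return w.astype(np.int32), d_idx


def _count_tables(
    w: np.ndarray, d: np.ndarray, z: np.ndarray, D: int, V: int, K: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n_dt = np.zeros((D, K), dtype=np.int64)
    n_wt = np.zeros((V, K), dtype=np.int64)
    n_t = np.zeros(K, dtype=np.int64)
    np.add.at(n_dt, (d, z), 1)
    np.add.at(n_wt, (w, z), 1)
    np.add.at(n_t, z, 1)
    return n_dt, n_wt, n_t


def _derive(
    n_dt: np.ndarray, n_wt: np.ndarray, n_t: np.ndarray, alpha: float, beta: float
) -> tuple[np.ndarray, np.ndarray]:
    K = n_t.shape[0]
    V = n_wt.shape[0]
    n_d = n_dt.sum(axis=1, keepdims=True)
    theta = (n_dt + alpha) / (n_d + K * alpha)
    phi = ((n_wt + beta) / (n_t + V * beta)).T
    return theta, phi


def fit_lda(docs: TokenizedDocs, config: TopicConfig) -> TopicModelState:
    """Fit LDA by collapsed Gibbs sampling (or ICM) and return the state.

    Seeded runs are bit-reproducible: a single seeded generator drives
    the initialization and every sweep.  With K = 1 the assignment is
    forced, the loop is skipped, and phi equals the closed form
    (count(w) + beta) / (N + V*beta)."""
    if docs.V == 0:
        raise ConfigError("empty vocabulary")
    K = config.K
    N = docs.n_tokens
    if K > N:
        raise ConfigError(f"K={K} exceeds the {N} tokens available")
    alpha = config.effective_alpha
    beta = config.beta
    w, d = _flatten(docs)
    rng = np.random.default_rng(config.seed)
    if K == 1:
        z = np.zeros(N, dtype=np.int32)
    else:
        z = rng.integers(0, K, size=N, dtype=np.int32)
        v_beta = docs.V * beta
        n_dt, n_wt, n_t = _count_tables(w, d, z, docs.D, docs.V, K)
        for _ in range(config.iterations):
            if config.mode == "gibbs":
                u = rng.random(N)
                _sweep_gibbs(w, d, z, n_dt, n_wt, n_t, alpha, beta, v_beta, u)
            else:
                _sweep_icm(w, d, z, n_dt, n_wt, n_t, alpha, beta, v_beta)
    n_dt, n_wt, n_t = _count_tables(w, d, z, docs.D, docs.V, K)
    theta, phi = _derive(n_dt, n_wt, n_t, alpha, beta)
    return TopicModelState(
        z=z, n_dt=n_dt, n_wt=n_wt, n_t=n_t, theta=theta, phi=phi,
        vocabulary=list(docs.vocabulary),
    )


def gibbs_assignment_frequencies(
    docs: TokenizedDocs,
    config: TopicConfig,
    n_sweeps: int,
    burnin: int = 0,
) -> np.ndarray:
    """Long-run per-token topic-assignment frequencies, shape (N, K).

    Runs ``burnin + n_sweeps`` Gibbs sweeps and, after burn-in, counts
    how often each token sits in each topic.  Used to check the sampler
    against exhaustive enumeration of the collapsed joint on tiny
    corpora."""
    K = config.K
    N = docs.n_tokens
    alpha = config.effective_alpha
    beta = config.beta
    v_beta = docs.V * beta
    w, d = _flatten(docs)
    rng = np.random.default_rng(config.seed)
    z = rng.integers(0, K, size=N, dtype=np.int32)
    n_dt, n_wt, n_t = _count_tables(w, d, z, docs.D, docs.V, K)
    freq = np.zeros((N, K), dtype=np.int64)
    rows = np.arange(N)
    for sweep in range(burnin + n_sweeps):
        u = rng.random(N)
        _sweep_gibbs(w, d, z, n_dt, n_wt, n_t, alpha, beta, v_beta, u)
        if sweep >= burnin:
            freq[rows, z] += 1
    return freq / float(n_sweeps)


def summarize_topic(state: TopicModelState, topic: int, top_n: int = 50) -> TopicSummary:
    """Top terms of one topic by P(w|t), ties broken lexicographically;
    weights reported in permille (1000 * P(w|t))."""
    if not 0 <= topic < state.K:
        raise ConfigError(f"topic index {topic} out of range for K={state.K}")
    phi_t = state.phi[topic]
    order = sorted(
        range(len(state.vocabulary)),
        key=lambda i: (-phi_t[i], state.vocabulary[i]),
    )
    top = order[: min(top_n, len(order))]
    return TopicSummary(
        terms=tuple((state.vocabulary[i], 1000.0 * float(phi_t[i])) for i in top)
    )


def prepare_concept_docs(
    article_texts: Mapping[str, str],
    lexicon: ConceptLexicon,
    config: TopicConfig,
    split_sentences=None,
) -> TokenizedDocs:
    """Full preprocessing for one article group: compound-name joining,
    tokenization, stopword/lemma normalization, phrase merging."""
    from .cleaning import split_sentences as _split

    split = split_sentences or _split
    token_lists = []
    for _, text in sorted(article_texts.items()):
        sentences = concat_compound_terms(split(text), lexicon)
        toks: list[str] = []
        for s in sentences:
            toks.extend(tokenize_for_topics(s))
        token_lists.append(toks)
    merged = detect_phrases(
        token_lists,
        ngram_max=config.ngram_max,
        min_count=config.phrase_min_count,
        threshold=config.phrase_threshold,
    )
    return TokenizedDocs.from_token_lists(merged)


def topics_per_concept(
    article_texts: Mapping[str, str],
    concept_articles_by_period: Mapping[str, Mapping[str, Set[str]]],
    lexicon: ConceptLexicon,
    config: TopicConfig,
) -> dict[str, dict[str, TopicSummary]]:
    """Fit one topic model per (concept, period) article group.

    ``article_texts`` maps article id -> cleaned text.  Groups smaller
    than ``config.min_docs`` are skipped with a log entry.  Groups are
    modeled independently; each uses the same seed so reruns are
    reproducible."""
    out: dict[str, dict[str, TopicSummary]] = {}
    for code in sorted(concept_articles_by_period):
        per_period = concept_articles_by_period[code]
        for period in sorted(per_period):
            ids = sorted(per_period[period])
            if len(ids) < config.min_docs:
                logger.info(
                    "skipping concept %s period %s: %d < min_docs=%d",
                    code, period, len(ids), config.min_docs,
                )
                continue
            group = {i: article_texts[i] for i in ids if i in article_texts}
            if not group:
                continue
            docs = prepare_concept_docs(group, lexicon, config)
            if docs.V == 0 or docs.n_tokens < config.K:
                logger.info("skipping concept %s period %s: too few tokens", code, period)
                continue
            state = fit_lda(docs, config)
            out.setdefault(code, {})[period] = summarize_topic(
                state, 0, config.top_n
            )
    return out
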