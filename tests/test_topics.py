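"""Topic preprocessing and LDA inference."""

import itertools

import numpy as np
import pytest
from scipy.special import gammaln

from newsdx.errors import ConfigError
from newsdx.terminology import ConceptLexicon
from newsdx.topics import (
    TokenizedDocs,
    TopicConfig,
    concat_compound_terms,
    detect_phrases,
    fit_lda,
    gibbs_assignment_frequencies,
    summarize_topic,
    tokenize_for_topics,
)

LEX = ConceptLexicon(
    {
        "lung cancer": frozenset({"C1"}),
        "cancer": frozenset({"C1"}),
        "asthma": frozenset({"C2"}),
    }
)


class TestConcatCompoundTerms:
    def test_multiword_joined(self):
        assert concat_compound_terms(["lung cancer trial"], LEX) == ["lung_cancer trial"]

    def test_single_word_unchanged(self):
        assert concat_compound_terms(["asthma trial"], LEX) == ["asthma trial"]

    def test_longest_match_first(self):
        # nested "cancer" must not break up "lung cancer"
        out = concat_compound_terms(["cancer of lung cancer type"], LEX)
        assert out == ["cancer of lung_cancer type"]


class TestTokenizeForTopics:
    def test_stopwords_and_lemmas(self):
        assert tokenize_for_topics("the studies of drugs") == ["study", "drug"]

    def test_compound_tokens_pass_through(self):
        assert tokenize_for_topics("lung_cancer") == ["lung_cancer"]

    def test_empty(self):
        assert tokenize_for_topics("") == []

    def test_irregular_plural(self):
        assert tokenize_for_topics("women and children") == ["woman", "child"]


class TestDetectPhrases:
    def test_frequent_pair_merged(self):
        # 50 docs "zika virus", 10 decoys: count(ab)=50, count(a)=count(b)=50,
        # N=120 -> score=(50-5)*120/2500=2.16 >= 2.0
        docs = [["zika", "virus"]] * 50 + [["other", "word"]] * 10
        out = detect_phrases(docs, ngram_max=2, min_count=5, threshold=2.0)
        assert out[0] == ["zika_virus"]
        # direct count arithmetic for the score used
        score = (50 - 5) * 120 / (50 * 50)
        assert score >= 2.0

    def test_below_threshold_unchanged(self):
        docs = [["a", "b"], ["a", "c"], ["b", "c"]]
        assert detect_phrases(docs, ngram_max=4, min_count=5, threshold=10.0) == docs

    def test_passes_build_up_to_four_grams(self):
        docs = [["a", "b", "c", "d"]] * 60
        out = detect_phrases(docs, ngram_max=4, min_count=1, threshold=0.1)
        assert out[0] == ["a_b_c_d"]


def _toy_docs():
    # 2 documents, 6 tokens total, V=3
    return TokenizedDocs(
        vocabulary=["u", "v", "w"],
        docs=[np.array([0, 1, 2], dtype=np.int32), np.array([1, 2, 2], dtype=np.int32)],
    )


def _enumerate_assignment_marginals(docs, K, alpha, beta):
    """Exhaustive oracle: P(z_i = k) under the collapsed LDA joint."""
    w, d = [], []
    for di, doc in enumerate(docs.docs):
        for wi in doc:
            w.append(int(wi))
            d.append(di)
    N, V, D = len(w), docs.V, docs.D
    log_weights, configs = [], []
    for z in itertools.product(range(K), repeat=N):
        n_dt = np.zeros((D, K))
        n_wt = np.zeros((V, K))
        n_t = np.zeros(K)
        for i in range(N):
            n_dt[d[i], z[i]] += 1
            n_wt[w[i], z[i]] += 1
            n_t[z[i]] += 1
        lw = gammaln(n_dt + alpha).sum() + gammaln(n_wt + beta).sum() - gammaln(
            n_t + V * beta
        ).sum()
        log_weights.append(lw)
        configs.append(z)
    weights = np.exp(np.array(log_weights) - max(log_weights))
    weights /= weights.sum()
    marginals = np.zeros((N, K))
    for z, p in zip(configs, weights):
        for i in range(N):
            marginals[i, z[i]] += p
    return marginals


class TestFitLda:
    def test_k1_closed_form(self):
        docs = _toy_docs()
        cfg = TopicConfig(K=1, beta=0.01, iterations=3, seed=1)
        state = fit_lda(docs, cfg)
        counts = np.array([1, 2, 3])  # u, v, w occurrences
        expected = (counts + 0.01) / (6 + 3 * 0.01)
        assert np.allclose(state.phi[0], expected, atol=1e-12)
        assert np.allclose(state.theta, 1.0)

    def test_same_seed_same_assignments(self):
        docs = _toy_docs()
        cfg = TopicConfig(K=2, alpha=0.5, beta=0.5, iterations=50, seed=42)
        z1 = fit_lda(docs, cfg).z
        z2 = fit_lda(docs, cfg).z
        assert np.array_equal(z1, z2)

    def test_count_tables_are_marginals_of_z(self):
        docs = _toy_docs()
        cfg = TopicConfig(K=2, alpha=0.5, beta=0.5, iterations=7, seed=3)
        state = fit_lda(docs, cfg)
        w = np.concatenate(docs.docs)
        d = np.repeat(np.arange(2), [3, 3])
        for k in range(2):
            assert state.n_t[k] == (state.z == k).sum()
            for di in range(2):
                assert state.n_dt[di, k] == ((state.z == k) & (d == di)).sum()
            for wi in range(3):
                assert state.n_wt[wi, k] == ((state.z == k) & (w == wi)).sum()

    def test_distributions_normalized(self):
        docs = _toy_docs()
        state = fit_lda(docs, TopicConfig(K=2, alpha=0.1, beta=0.01, iterations=20, seed=0))
        assert np.allclose(state.theta.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(state.phi.sum(axis=1), 1.0, atol=1e-9)

    def test_icm_mode_deterministic_fixpoint(self):
        docs = _toy_docs()
        cfg = TopicConfig(K=2, alpha=0.5, beta=0.5, iterations=30, seed=5, mode="icm")
        state1 = fit_lda(docs, cfg)
        state2 = fit_lda(docs, cfg)
        assert np.array_equal(state1.z, state2.z)

    def test_k_exceeding_tokens_rejected(self):
        with pytest.raises(ConfigError):
            fit_lda(_toy_docs(), TopicConfig(K=7, alpha=1.0, iterations=1))

    def test_empty_vocabulary_rejected(self):
        with pytest.raises(ConfigError):
            fit_lda(TokenizedDocs([], []), TopicConfig(K=1))

    def test_gibbs_matches_enumeration_oracle_small(self):
        """Sampler long-run assignment frequencies vs exhaustive
        enumeration of the collapsed joint (reduced sweep count; the full
        check runs in the acceptance suite)."""
        docs = _toy_docs()
        alpha, beta = 0.5, 0.5
        expected = _enumerate_assignment_marginals(docs, 2, alpha, beta)
        cfg = TopicConfig(K=2, alpha=alpha, beta=beta, iterations=1, seed=11)
        freq = gibbs_assignment_frequencies(docs, cfg, n_sweeps=8000, burnin=500)
        assert np.abs(freq - expected).max() < 0.03

    def test_planted_topics_recovered_small(self):
        """Scaled-down generative recovery (full size in acceptance)."""
        from newsdx.synthetic import make_planted_phi

        rng = np.random.default_rng(0)
        K, V, D, L = 3, 90, 120, 60
        phi_true = make_planted_phi(K, V)
        docs = []
        for _ in range(D):
            theta = rng.dirichlet(np.full(K, 0.1))
            topics = rng.choice(K, size=L, p=theta)
            words = np.array(
                [rng.choice(V, p=phi_true[k]) for k in topics], dtype=np.int32
            )
            docs.append(words)
        td = TokenizedDocs([f"w{i}" for i in range(V)], docs)
        state = fit_lda(td, TopicConfig(K=K, alpha=0.1, beta=0.01, iterations=300, seed=7))
        best = _best_permutation_cosine(state.phi, phi_true)
        assert best >= 0.9


def _best_permutation_cosine(phi, phi_true):
    K = phi.shape[0]
    sims = np.zeros((K, K))
    for a in range(K):
        for b in range(K):
            sims[a, b] = phi[a] @ phi_true[b] / (
                np.linalg.norm(phi[a]) * np.linalg.norm(phi_true[b])
            )
    return max(
        np.mean([sims[a, b] for a, b in enumerate(perm)])
        for perm in itertools.permutations(range(K))
    )


class TestSummarizeTopic:
    def test_permille_unit(self):
        docs = _toy_docs()
        state = fit_lda(docs, TopicConfig(K=1, beta=0.01))
        summary = summarize_topic(state, 0, top_n=3)
        assert summary.terms[0][0] == "w"
        assert summary.terms[0][1] == pytest.approx(
            1000 * (3 + 0.01) / (6 + 3 * 0.01)
        )

    def test_uniform_phi_ties_broken_lexicographically(self):
        toks = [[f"t{i:02d}"] for i in range(50)]
        td = TokenizedDocs.from_token_lists(toks)
        state = fit_lda(td, TopicConfig(K=1, beta=0.01))
        summary = summarize_topic(state, 0, top_n=50)
        assert all(p == pytest.approx(20.0, abs=0.01) for _, p in summary.terms)
        assert [t for t, _ in summary.terms] == sorted(t for t, _ in summary.terms)

    def test_top_n_capped_at_vocabulary(self):
        state = fit_lda(_toy_docs(), TopicConfig(K=1))
        assert len(summarize_topic(state, 0, top_n=99).terms) == 3

    def test_permilles_non_increasing(self):
        state = fit_lda(_toy_docs(), TopicConfig(K=1))
        permilles = [p for _, p in summarize_topic(state, 0, 3).terms]
        assert permilles == sorted(permilles, reverse=True)

    def test_bad_topic_index_rejected(self):
        state = fit_lda(_toy_docs(), TopicConfig(K=1))
        with pytest.raises(ConfigError):
            summarize_topic(state, 1)
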