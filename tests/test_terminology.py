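"""Synonym dictionary, mapping chain, and mention matching."""

import numpy as np
import pandas as pd
import pytest

from newsdx.errors import ConfigError, TableFormatError, UndefinedStatisticError
from newsdx.synthetic import random_mapping_chain
from newsdx.terminology import (
    articles_by_concept,
    definitive_fraction,
    find_mentions,
    load_chain,
    load_lexicon,
    resolve_synonym,
)


class TestLoaders:
    def test_load_lexicon_counts_and_normalization(self, tmp_path):
        p = tmp_path / "lex.tsv"
        p.write_text("Lung  Cancer\tC1\nasthma\tC2\n", encoding="utf-8")
        lex = load_lexicon(p)
        assert len(lex) == 2
        assert lex.cuis("lung cancer") == frozenset({"C1"})

    def test_missing_column_names_line(self, tmp_path):
        p = tmp_path / "lex.tsv"
        p.write_text("flu\tC1\nonly-one-column\n", encoding="utf-8")
        with pytest.raises(TableFormatError, match="line 2"):
            load_lexicon(p)

    def test_empty_lexicon_warns(self, tmp_path, caplog):
        p = tmp_path / "lex.tsv"
        p.write_text("", encoding="utf-8")
        with caplog.at_level("WARNING"):
            lex = load_lexicon(p)
        assert len(lex) == 0
        assert any("empty" in rec.message for rec in caplog.records)

    def test_conflicting_icd_mapping_rejected(self, tmp_path):
        ci = tmp_path / "ci.tsv"
        ci.write_text("C1\t162.0\n", encoding="utf-8")
        ip = tmp_path / "ip.tsv"
        ip.write_text("162.0\t165\tneoplasm\n162.0\t166\tother\n", encoding="utf-8")
        with pytest.raises(TableFormatError, match="162.0"):
            load_chain(ci, ip)


class TestResolveSynonym:
    def test_one_to_one_definitive(self, small_lexicon, small_chain):
        res = resolve_synonym("asthma", small_lexicon, small_chain)
        assert res.phewas_set == frozenset({"475"})
        assert res.mapping_class == "definitive"

    def test_multiple_to_one_collapses_to_definitive(self, small_lexicon, small_chain):
        # C1 -> {162.0, 162.1} -> both 165: still one concept
        res = resolve_synonym("lung cancer", small_lexicon, small_chain)
        assert res.phewas_set == frozenset({"165"})
        assert res.mapping_class == "definitive"

    def test_two_concepts_is_ambiguous(self, small_lexicon, small_chain):
        res = resolve_synonym("mystery illness", small_lexicon, small_chain)
        assert res.phewas_set == frozenset({"165", "475"})
        assert res.mapping_class == "ambiguous"

    def test_unknown_and_broken_chain_unmapped(self, small_lexicon, small_chain):
        assert resolve_synonym("gout", small_lexicon, small_chain).mapping_class == "unmapped"
        assert resolve_synonym("orphan syndrome", small_lexicon, small_chain).mapping_class == "unmapped"


def _oracle_definitive_fraction(lexicon, chain):
    """Independent oracle: enumerate every synonym→CUI→ICD→PheWAS path with
    pandas merges and count distinct end-points per synonym."""
    syn_rows = [
        {"synonym": s, "cui": c} for s, cuis in lexicon.entries.items() for c in cuis
    ]
    ci_rows = [
        {"cui": c, "icd": i} for c, icds in chain.cui_to_icd.items() for i in icds
    ]
    ip_rows = [
        {"icd": i, "phewas": pw} for i, (pw, _) in chain.icd_to_phewas.items()
    ]
    paths = (
        pd.DataFrame(syn_rows)
        .merge(pd.DataFrame(ci_rows), on="cui")
        .merge(pd.DataFrame(ip_rows), on="icd")
    )
    ends = paths.groupby("synonym")["phewas"].nunique()
    if len(ends) == 0:
        return None
    return float((ends == 1).sum() / len(ends))


class TestDefinitiveFraction:
    def test_simple_counts(self, small_lexicon, small_chain):
        # definitive: lung cancer, cancer, asthma, bird flu, flu (5);
        # ambiguous: mystery illness (1); unmapped excluded from denominator
        assert definitive_fraction(small_lexicon, small_chain) == pytest.approx(5 / 6)

    def test_all_definitive(self, small_chain, small_lexicon):
        from newsdx.terminology import ConceptLexicon

        lex = ConceptLexicon({"asthma": frozenset({"C2"})})
        assert definitive_fraction(lex, small_chain) == 1.0

    def test_all_unmapped_raises(self, small_chain):
        from newsdx.terminology import ConceptLexicon

        lex = ConceptLexicon({"nonesuch": frozenset({"C404"})})
        with pytest.raises(UndefinedStatisticError):
            definitive_fraction(lex, small_chain)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_path_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        lexicon, chain = random_mapping_chain(rng, n_synonyms=200)
        expected = _oracle_definitive_fraction(lexicon, chain)
        if expected is None:
            with pytest.raises(UndefinedStatisticError):
                definitive_fraction(lexicon, chain)
        else:
            assert definitive_fraction(lexicon, chain) == pytest.approx(expected)


class TestFindMentions:
    def test_longest_match_suppresses_nested(self, small_lexicon, small_chain):
        ments = find_mentions(
            {"a1": ["patients with lung cancer and asthma improved"]},
            small_lexicon,
            small_chain,
        )
        assert [(m.synonym, m.mapping_class) for m in ments] == [
            ("lung cancer", "definitive"),
            ("asthma", "definitive"),
        ]

    def test_no_term_no_mentions(self, small_lexicon, small_chain):
        assert find_mentions({"a1": ["nothing to see here"]}, small_lexicon, small_chain) == []

    def test_spans_reproduce_synonym(self, small_lexicon, small_chain):
        sentence = "a severe bird flu case and cancer too."
        ments = find_mentions({"a1": [sentence]}, small_lexicon, small_chain)
        for m in ments:
            assert sentence[m.char_span[0] : m.char_span[1]] == m.synonym

    def test_token_boundary_anchoring(self, small_lexicon, small_chain):
        # "flue" and "influenza-like" must not match "flu"
        ments = find_mentions(
            {"a1": ["the flue was blocked, flux rose"]}, small_lexicon, small_chain
        )
        assert ments == []

    def test_mentions_never_overlap(self, small_lexicon, small_chain):
        ments = find_mentions(
            {"a1": ["lung cancer cancer lung cancer"]}, small_lexicon, small_chain
        )
        spans = sorted(m.char_span for m in ments)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2


class TestArticlesByConcept:
    def _mentions(self, small_lexicon, small_chain, sentences):
        return find_mentions(sentences, small_lexicon, small_chain)

    def test_definitive_contributes(self, small_lexicon, small_chain):
        ments = self._mentions(small_lexicon, small_chain, {"a1": ["asthma is up"]})
        concept, all_ids = articles_by_concept(ments)
        assert concept == {"475": {"a1"}}
        assert all_ids == {"a1"}

    def test_ambiguous_only_counts_in_all_set(self, small_lexicon, small_chain):
        ments = self._mentions(
            small_lexicon, small_chain, {"a1": ["a mystery illness struck"]}
        )
        concept, all_ids = articles_by_concept(ments, "definitive_only")
        assert concept == {}
        assert all_ids == {"a1"}

    def test_expand_ambiguous_counts_all_candidates(self, small_lexicon, small_chain):
        ments = self._mentions(
            small_lexicon, small_chain, {"a1": ["a mystery illness struck"]}
        )
        concept, all_ids = articles_by_concept(ments, "expand_ambiguous")
        assert concept == {"165": {"a1"}, "475": {"a1"}}
        assert all_ids == {"a1"}

    def test_unknown_policy_rejected(self):
        with pytest.raises(ConfigError):
            articles_by_concept([], "nonsense")

    def test_concept_sets_bounded_by_all_set(self, small_lexicon, small_chain):
        sentences = {
            f"a{i}": [f"cancer and flu in report {i}"] for i in range(10)
        }
        concept, all_ids = articles_by_concept(
            self._mentions(small_lexicon, small_chain, sentences)
        )
        for ids in concept.values():
            assert ids <= all_ids
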