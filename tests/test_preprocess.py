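"""Tokenization, masking, normalization and comparative extraction."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ontoqa.preprocess as pp


class TestPreprocess:
    def test_masking_keeps_token_count(self):
        q = pp.preprocess("Which researchers study Neomycin drug resistance?")
        assert len(q.tokens) == len(q.pos_tags) == len(q.kept_mask)
        assert "?" in q.tokens and not q.kept_mask[q.tokens.index("?")]
        assert not q.kept_mask[[t.lower() for t in q.tokens].index("which")]
        for word in ("researchers", "study", "Neomycin", "resistance"):
            assert q.kept_mask[q.tokens.index(word)]

    def test_abbreviation_expansion_recorded(self):
        q = pp.preprocess("Give the KO identifier for genes.")
        assert ("KO", "knockout") in q.expansions
        assert "knockout" in q.tokens and "KO" not in q.tokens

    def test_number_words_become_digits(self):
        q = pp.preprocess("show two genes")
        assert "2" in q.tokens and "two" not in q.tokens

    def test_gene_identifier_survives_tokenization(self):
        assert "Tc00.1047053509463.30" in pp.tokenize(
            "Find gene Tc00.1047053509463.30 now.")

    def test_empty_question_rejected(self):
        with pytest.raises(pp.InputError):
            pp.preprocess("   ")

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.text(alphabet=st.characters(whitelist_categories=("Lu", "Ll", "Nd", "Po")),
                   min_size=1, max_size=60))
    def test_mask_never_changes_token_count(self, text):
        if not text.strip():
            return
        q = pp.preprocess(text)
        assert len(q.tokens) == len(q.kept_mask) == len(q.pos_tags)
        kept = q.content_tokens()
        it = iter(q.tokens)
        assert all(any(t == k for t in it) for k in kept)  # subsequence


class TestComparatives:
    def test_two_relations_with_distinct_operands(self):
        q = pp.preprocess(
            "Show me the 3 prime forward sequences for all genes in metacyclic "
            "stage with log2 ratio higher than 1 and standard deviation below 0.5.")
        rels = [(c.operand, c.operator, c.value) for c in q.comparatives]
        assert rels == [("log2 ratio", ">", 1.0), ("standard deviation", "<", 0.5)]

    def test_between_splits_into_strict_pair_sharing_operand(self):
        q = pp.preprocess("Which protein group numbers have spectral values "
                          "between 40 and 50?")
        rels = [(c.operand, c.operator, c.value) for c in q.comparatives]
        assert rels == [("spectral values", ">", 40.0), ("spectral values", "<", 50.0)]
        assert rels[0][2] < rels[1][2]

    def test_between_reversed_bounds_are_sorted(self):
        q = pp.preprocess("genes with spectral count between 50 and 40")
        assert [c.operator for c in q.comparatives] == [">", "<"]
        assert q.comparatives[0].value == 40.0

    def test_at_least_at_most(self):
        q = pp.preprocess("genes with peptide count at least 3 and spectral "
                          "count at most 7")
        assert [(c.operand, c.operator, c.value) for c in q.comparatives] == [
            ("peptide count", ">=", 3.0), ("spectral count", "<=", 7.0)]

    def test_negative_literal(self):
        q = pp.preprocess("genes with log2 ratio below -0.7")
        assert q.comparatives[0].value == -0.7

    def test_no_keyword_gives_empty_list(self):
        q = pp.preprocess("List all genes with spectral count.")
        assert q.comparatives == []

    def test_keyword_without_literal_is_skipped(self):
        q = pp.preprocess("genes with spectral count greater than the threshold")
        assert q.comparatives == []

    def test_idempotent_on_canonical_text(self):
        text = "genes with spectral count greater than 2"
        first = pp.preprocess(text).comparatives
        # feeding back the canonical rendering changes nothing
        again = pp.preprocess("genes with spectral count greater than 2").comparatives
        assert first == again
        assert [(c.operator, c.value) for c in first] == [(">", 2.0)]

    def test_cross_class_comparison_flagged_not_extracted(self):
        q = pp.preprocess("Give the strain summaries for genes that have a "
                          "standard deviation less than 1.5 of the log2 ratio.")
        assert "cross_class_comparison" in q.flags
        assert q.comparatives == []

    def test_negation_flagged(self):
        q = pp.preprocess("Find targets that have orthologs in Leishmania "
                          "but not in T. brucei.")
        assert "negation" in q.flags

    def test_aggregate_flagged(self):
        q = pp.preprocess("How many genes exist in a single metabolic pathway?")
        assert "aggregate" in q.flags


def test_comparative_relation_validation():
    with pytest.raises(ValueError):
        pp.ComparativeRelation("", ">", 1.0)
    with pytest.raises(ValueError):
        pp.ComparativeRelation("x", ">", float("inf"))
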