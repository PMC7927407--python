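"""Component scores, composite identity, ranking, and oracle equivalence."""

import math

import numpy as np
import pytest

from cobm25.corpus_io import CorpusStats, Document, build_index
from cobm25.expansion import ExpandedQuery
from cobm25.scoring import (ModelParams, QueryScorer, detect_coword,
                            idf_abstract, idf_gene, idf_word, rank_corpus,
                            relevance_r, score_abstract, score_composite,
                            score_word, tf_word)
from conftest import make_random_documents, make_random_query
from oracles import oracle_breakdown

PARAMS = ModelParams()  # the "normal" preset values


def stats_with(**kw) -> CorpusStats:
    base = dict(D=4, avgdl=10.0, n_wordlist=3, avgdwl=5.0,
                df_abstract={}, df_wordlist={}, df_gene={})
    base.update(kw)
    return CorpusStats(**base)


class TestIdfVariants:
    def test_abstract_idf_direct(self):
        s = stats_with(df_abstract={"x": 2})
        assert idf_abstract("x", s) == pytest.approx(math.log(2), abs=1e-12)

    def test_abstract_idf_df_equals_D(self):
        s = stats_with(df_abstract={"x": 4})
        assert idf_abstract("x", s) == 0.0

    def test_abstract_idf_floors_missing_terms(self):
        s = stats_with()
        assert idf_abstract("absent", s) == pytest.approx(math.log(4))

    def test_word_idf_midpoint_is_zero(self):
        s = stats_with(n_wordlist=100, df_wordlist={"x": 50})
        assert idf_word(("x",), s) == 0.0

    def test_word_idf_direct(self):
        s = stats_with(n_wordlist=3, df_wordlist={"x": 1})
        assert idf_word(("x",), s) == pytest.approx(math.log(2.5 / 1.5), abs=1e-9)

    def test_word_idf_negative_preserved_and_floorable(self):
        s = stats_with(n_wordlist=3, df_wordlist={"x": 3})
        assert idf_word(("x",), s) < 0
        assert idf_word(("x",), s, floor_zero=True) == 0.0

    def test_gene_idf_monotone_in_rarity(self, tiny_index):
        vals = [idf_gene((g,), tiny_index) for g in ("braf", "cdk4")]
        # braf in 2 docs, cdk4 in 2 docs -> compare against a rare gene
        assert idf_gene(("v600e",), tiny_index) > max(vals)


class TestRelevanceR:
    def test_zero_frequency(self):
        assert relevance_r(0, 10, stats_with(), PARAMS) == 0.0

    def test_closed_form_at_avgdl(self):
        """At dl = avgdl the BM25 K collapses to k1."""
        s = stats_with(avgdl=10.0)
        r = relevance_r(2, 10.0, s, ModelParams(k1=1.2, b1=0.75))
        assert r == pytest.approx(2 * 2.2 / (2 + 1.2), abs=1e-12)
        assert r == pytest.approx(1.375)

    def test_b1_zero_is_length_invariant(self):
        p = ModelParams(b1=0.0)
        s = stats_with(avgdl=10.0)
        assert relevance_r(3, 1, s, p) == relevance_r(3, 1000, s, p)

    def test_b1_one_strictly_decreasing_in_dl(self):
        p = ModelParams(b1=1.0)
        s = stats_with(avgdl=10.0)
        vals = [relevance_r(2, dl, s, p) for dl in (5, 10, 20, 40)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestScoreAbstract:
    def test_no_match_scores_zero(self, tiny_docs, tiny_index):
        q = ExpandedQuery("1", ("zzz",), (), (("zzz",),), (("zzz",),))
        assert score_abstract(q, tiny_docs[0], tiny_index, PARAMS) == 0.0

    def test_single_term_oracle(self):
        docs = [Document.from_fields("A", "braf gene", stopwords=()),
                Document.from_fields("B", "other gene", stopwords=())]
        idx = build_index(docs)
        q = ExpandedQuery("1", ("braf",), (), (("x",),), (("x",),))
        # f=1, dl=avgdl=2, D=2, df=1 -> ln 2 * 2.2/2.2
        got = score_abstract(q, docs[0], idx, ModelParams(k1=1.2, b1=0.75))
        assert got == pytest.approx(math.log(2), abs=1e-12)

    def test_monotone_in_frequency(self):
        base = "braf filler filler filler"
        docs = [Document.from_fields("A", base, stopwords=()),
                Document.from_fields("B", "braf braf filler filler", stopwords=()),
                Document.from_fields("C", "none here at all", stopwords=())]
        idx = build_index(docs)
        q = ExpandedQuery("1", ("braf",), (), (("x",),), (("x",),))
        assert (score_abstract(q, docs[1], idx, PARAMS)
                > score_abstract(q, docs[0], idx, PARAMS))


class TestScoreWord:
    def test_tf_zero_scores_zero(self, tiny_docs, tiny_index):
        q = ExpandedQuery("1", ("x",), (("absent", "term"),), (("x",),), (("x",),))
        assert score_word(q, tiny_docs[0], tiny_index, PARAMS) == 0.0

    def test_saturation_ceiling(self, tiny_docs, tiny_index):
        q = ExpandedQuery(
            "1", ("x",),
            tuple((t,) for t in ("liposarcoma", "cdk4", "human", "kinase")),
            (("x",),), (("x",),))
        for doc in tiny_docs:
            if tf_word(q, doc, tiny_index) >= 0:
                assert score_word(q, doc, tiny_index, PARAMS) <= PARAMS.k3 + 1

    def test_unit_value_at_avgdwl(self):
        # one matching word with idf = ln(2.5/1.5), dwl = avgdwl, tf = idf:
        # score = tf (k3+1) / (tf + k3)
        docs = [Document.from_fields("A", "a", mesh_terms=["mm"], stopwords=()),
                Document.from_fields("B", "a", mesh_terms=["nn"], stopwords=()),
                Document.from_fields("C", "a", mesh_terms=["pp"], stopwords=())]
        idx = build_index(docs)
        q = ExpandedQuery("1", ("x",), (("mm",),), (("x",),), (("x",),))
        tf = math.log(2.5 / 1.5)
        expected = tf * 2.2 / (tf + 1.2)
        assert score_word(q, docs[0], idx, PARAMS) == pytest.approx(expected, abs=1e-12)

    def test_tf_word_matches_membership_scan(self, tiny_docs, tiny_index):
        q = ExpandedQuery(
            "1", ("x",),
            (("cyclin", "dependent"), ("human",), ("cdk4",)),
            (("x",),), (("x",),))
        for doc in tiny_docs:
            expected = 0.0
            for t in q.wordlist_terms:
                present = any(
                    tuple(tt[i:i + len(t)]) == t
                    for tt in doc.wordlist_token_tuples()
                    for i in range(len(tt) - len(t) + 1))
                if present:
                    expected += idf_word(t, tiny_index.stats)
            assert tf_word(q, doc, tiny_index) == pytest.approx(expected)


class TestDetectCoword:
    DISEASE = (("liposarcoma",),)
    GENE = (("cdk4",),)

    def test_cross_field_match(self, tiny_docs):
        # disease in abstract+mesh, gene in abstract+chemical+keyword
        assert detect_coword(tiny_docs[0], self.DISEASE, self.GENE, "cross")

    def test_within_requires_same_field(self):
        doc = Document.from_fields(
            "X", "liposarcoma case report",
            mesh_terms=["cdk4"], stopwords=())
        assert detect_coword(doc, self.DISEASE, self.GENE, "cross") == {("cdk4",)}
        assert detect_coword(doc, self.DISEASE, self.GENE, "within") == set()

    def test_same_field_satisfies_both_modes(self):
        doc = Document.from_fields(
            "X", "nothing relevant", keyword_terms=["liposarcoma", "cdk4"],
            stopwords=())
        for mode in ("cross", "within"):
            assert detect_coword(doc, self.DISEASE, self.GENE, mode) == {("cdk4",)}

    def test_no_substring_of_token_match(self):
        doc = Document.from_fields("X", "liposarcoma kras mutation", stopwords=())
        assert detect_coword(doc, self.DISEASE, (("ras",),), "cross") == set()

    def test_unknown_mode_rejected(self, tiny_docs):
        with pytest.raises(ValueError):
            detect_coword(tiny_docs[0], self.DISEASE, self.GENE, "sideways")

    def test_within_matches_nest_in_cross(self):
        rng = np.random.default_rng(5)
        docs = make_random_documents(rng, 60)
        for _ in range(20):
            q = make_random_query(rng)
            for doc in docs:
                within = detect_coword(doc, q.disease_terms, q.gene_terms, "within")
                cross = detect_coword(doc, q.disease_terms, q.gene_terms, "cross")
                assert within <= cross


class TestComposite:
    def test_alpha_zero_drops_coword(self, tiny_docs, tiny_index):
        q = ExpandedQuery("1", ("melanoma", "v600e"), (("human",),),
                          (("melanoma",),), (("v600e",),))
        bd = score_composite(q, tiny_docs[1], tiny_index, PARAMS.replace(alpha=0.0))
        assert bd.score_composite == bd.score_abstract + bd.score_word
        assert bd.score_coword != 0.0  # component still reported

    def test_unmatched_document_all_zero(self, tiny_docs, tiny_index):
        q = ExpandedQuery("1", ("qqq",), (("qqq",),), (("qqq",),), (("qqq",),))
        bd = score_composite(q, tiny_docs[2], tiny_index, PARAMS)
        assert (bd.score_abstract, bd.score_word, bd.score_coword,
                bd.score_composite) == (0, 0, 0, 0)
        assert not bd.coword_flag

    def test_cs_preset_alpha_contribution_exact(self, tiny_docs, tiny_index):
        q = ExpandedQuery("1", ("melanoma",), (("human",),),
                          (("melanoma",),), (("v600e",),))
        cs = ModelParams.preset("cs")
        assert cs.alpha == 4.0
        bd = score_composite(q, tiny_docs[1], tiny_index, cs)
        assert bd.score_coword != 0.0
        assert bd.score_composite == bd.score_abstract + bd.score_word + 4.0 * bd.score_coword

    def test_decomposition_identity_random(self):
        rng = np.random.default_rng(11)
        docs = make_random_documents(rng, 50)
        idx = build_index(docs)
        for _ in range(10):
            q = make_random_query(rng)
            p = ModelParams(k1=float(rng.uniform(0.1, 5)),
                            k3=float(rng.uniform(0.1, 5)),
                            b1=float(rng.uniform(0, 1)),
                            b2=float(rng.uniform(0, 1)),
                            alpha=float(rng.uniform(0, 5)))
            for doc in docs[:10]:
                bd = score_composite(q, doc, idx, p)
                assert bd.score_composite == (
                    bd.score_abstract + bd.score_word + p.alpha * bd.score_coword)


class TestRankCorpus:
    def test_sorted_by_score(self, tiny_index):
        q = ExpandedQuery("1", ("liposarcoma", "cdk4"), (("human",),),
                          (("liposarcoma",),), (("cdk4",),))
        entries = rank_corpus(q, tiny_index, PARAMS)
        scores = [e.score for e in entries]
        assert scores == sorted(scores, reverse=True)
        assert [e.rank for e in entries] == list(range(1, len(entries) + 1))

    def test_ties_break_on_doc_id(self):
        docs = [Document.from_fields(d, "same text here", stopwords=())
                for d in ("B2", "A1", "C3")]
        idx = build_index(docs)
        q = ExpandedQuery("1", ("same",), (), (("x",),), (("x",),))
        entries = rank_corpus(q, idx, PARAMS)
        assert [e.doc_id for e in entries] == ["A1", "B2", "C3"]

    def test_top_k_one(self, tiny_index):
        q = ExpandedQuery("1", ("melanoma",), (), (("melanoma",),), (("braf",),))
        entries = rank_corpus(q, tiny_index, PARAMS, top_k=1)
        assert len(entries) == 1 and entries[0].doc_id == "PMID2"


class TestOracleEquivalence:
    def test_matches_straightline_transcription(self):
        """Vectorized scorer == brute-force double loop on random corpora."""
        rng = np.random.default_rng(42)
        for trial in range(10):
            docs = make_random_documents(rng, int(rng.integers(5, 80)))
            idx = build_index(docs)
            q = make_random_query(rng)
            p = ModelParams(k1=float(rng.uniform(0.2, 4)),
                            k3=float(rng.uniform(0.2, 4)),
                            b1=float(rng.uniform(0, 1)),
                            b2=float(rng.uniform(0, 1)),
                            alpha=float(rng.uniform(0, 5)))
            for mode in ("cross", "within"):
                scorer = QueryScorer(q, idx, mode=mode)
                sa, sw, sc = scorer.component_scores(p)
                for i, doc in enumerate(docs):
                    osa, osw, osc, ocomp = oracle_breakdown(q, docs, doc, p, mode)
                    np.testing.assert_allclose(sa[i], osa, rtol=1e-9, atol=1e-12)
                    np.testing.assert_allclose(sw[i], osw, rtol=1e-9, atol=1e-12)
                    np.testing.assert_allclose(sc[i], osc, rtol=1e-9, atol=1e-12)
                    bd = score_composite(q, doc, idx, p, mode)
                    np.testing.assert_allclose(bd.score_composite, ocomp,
                                               rtol=1e-9, atol=1e-12)
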